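"""Temperature-dependent solvent and interaction parameters.

The model treats water as a continuous dielectric whose relative
permittivity falls with temperature, and encodes the thermoresponse of the
polymer through a hydrophobic well whose depth switches on sigmoidally
around a transition temperature.  All simulation energies are handled in
units of k_B*T at the run temperature; the joule-valued constants kept in
:class:`ModelParams` are converted once, when a :class:`ThermoState` is
built.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict, fields

import numpy as np

# CODATA 2018
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin: float) -> float:
    return t_kelvin - CELSIUS_OFFSET


@dataclass(frozen=True)
class ModelParams:
    """Interaction constants of the coarse-grained model.

    Energies in joule, lengths in nm, as conventionally tabulated; they are
    reduced to k_B*T units by :meth:`ThermoState.at`.

    Attributes
    ----------
    eps_wca : WCA repulsion strength (J).
    k_e : harmonic bond stiffness (N/m).
    r0 : equilibrium bond length (nm).
    k_h : hydrophobic sigmoid steepness (1/nm).
    r_h : hydrophobic interaction range (nm).
    eps_max : maximum hydrophobic well depth at high temperature (J).
    T_half : temperature at which the well depth is eps_max/2 (K).
    k_half : steepness of the depth-vs-temperature sigmoid (1/K).
    """

    eps_wca: float = 4.11e-21
    k_e: float = 0.40
    r0: float = 0.65
    k_h: float = 12.1
    r_h: float = 0.90
    eps_max: float = 5.5e-21
    T_half: float = 307.5
    k_half: float = 0.0667

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"ModelParams.{f.name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**d)


def relative_permittivity(T: float) -> float:
    """Relative permittivity of water at absolute temperature ``T`` (K).

    Empirical cubic-plus-inverse polynomial fit; ~78.4 at 25 C.
    """
    T = float(T)
    if T <= 0:
        raise ValueError(f"absolute temperature must be positive, got {T}")
    if not (273.0 <= T <= 373.0):
        warnings.warn(
            f"relative_permittivity evaluated at {T} K, outside the liquid-"
            "water fit range 273-373 K",
            stacklevel=2,
        )
    return (
        5321.0 / T
        + 233.76
        - 0.9297 * T
        + 0.1417e-2 * T * T
        - 0.8292e-6 * T * T * T
    )


def bjerrum_length(T: float) -> float:
    """Bjerrum length in nm: e^2 / (4 pi eps0 eps_r(T) k_B T)."""
    eps_r = relative_permittivity(T)
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY * eps_r * BOLTZMANN * T
    )
    return lb_m * 1e9


def hydrophobic_depth(T: float, params: ModelParams | None = None) -> float:
    """Hydrophobic well depth eps_h(T) in joule.

    Sigmoidal switch: eps_max/2 * (1 + tanh(k_half * (T - T_half))).
    Monotonically non-decreasing in T; -> eps_max as T -> inf.
    """
    if T <= 0:
        raise ValueError(f"absolute temperature must be positive, got {T}")
    p = params or ModelParams()
    return 0.5 * p.eps_max * (1.0 + math.tanh(p.k_half * (T - p.T_half)))


@dataclass(frozen=True)
class ThermoState:
    """Per-temperature derived quantities, in simulation units.

    ``eps_wca_kt``, ``eps_h_kt`` are energies over k_B*T; ``k_bond_kt`` is
    the bond stiffness in k_B*T / nm^2.
    """

    T: float
    eps_r: float
    l_B: float          # nm
    eps_h: float        # J
    kT: float           # J
    eps_wca_kt: float
    eps_h_kt: float
    k_bond_kt: float    # kT / nm^2

    @classmethod
    def at(cls, T: float, params: ModelParams | None = None) -> "ThermoState":
        p = params or ModelParams()
        eps_r = relative_permittivity(T)
        kT = BOLTZMANN * T
        eps_h = hydrophobic_depth(T, p)
        return cls(
            T=float(T),
            eps_r=eps_r,
            l_B=bjerrum_length(T),
            eps_h=eps_h,
            kT=kT,
            eps_wca_kt=p.eps_wca / kT,
            eps_h_kt=eps_h / kT,
            # k_e is in N/m = J/m^2; per nm^2 that is k_e * 1e-18 J
            k_bond_kt=p.k_e * 1e-18 / kT,
        )


def permittivity_grid(T_low: float, T_high: float, n: int = 200) -> np.ndarray:
    """Convenience: eps_r sampled on a dense temperature grid."""
    Ts = np.linspace(T_low, T_high, n)
    return np.array([relative_permittivity(t) for t in Ts])
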