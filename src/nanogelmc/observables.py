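"""Observables of the nanogel / nanocomposite trajectories.

All radial quantities are measured from the centre of mass of the polymer
network, computed on its (contiguous, unwrapped) coordinates; mobile
species are referred to that centre with minimum-image distances.  The
electrostatic potential follows from the spherically averaged enclosed
charge by Gauss' law, integrated inward from half the box length where the
potential is gauged to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SPHERE_FACTOR = np.sqrt(5.0 / 3.0)


@dataclass
class RadialProfile:
    """Frame-averaged radial quantity on contiguous bins."""

    bin_edges: np.ndarray
    values: np.ndarray
    n_frames: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self, value_name: str = "value") -> pd.DataFrame:
        return pd.DataFrame({"r": self.bin_centers, value_name: self.values})


def radius_of_gyration(positions: np.ndarray) -> float:
    """Root-mean-square distance of network beads from their centre of mass.

    Positions must be unwrapped (contiguous across the periodic boundary).
    Single-frame value; ensemble averaging is the caller's responsibility.
    """
    positions = np.atleast_2d(positions)
    if positions.shape[0] == 0:
        raise ValueError("radius_of_gyration needs at least one bead")
    cm = positions.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((positions - cm) ** 2, axis=1))))


def geometric_radius(r_gyr: float) -> float:
    """Effective spherical radius: sqrt(5/3) * R_gyr (uniform-ball relation)."""
    if r_gyr < 0:
        raise ValueError("R_gyr must be non-negative")
    return SPHERE_FACTOR * r_gyr


def _min_image_dist(points: np.ndarray, centre: np.ndarray, box: float) -> np.ndarray:
    d = points - centre
    d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=1)


def count_inside(
    np_positions: np.ndarray, network_cm: np.ndarray, r_ng: float, box: float
) -> int:
    """Nanoparticles whose centre lies within the geometric radius."""
    if r_ng < 0:
        raise ValueError("R_NG must be non-negative")
    if len(np_positions) == 0:
        return 0
    return int(np.sum(_min_image_dist(np.atleast_2d(np_positions), network_cm, box) < r_ng))


def shrink_desorb_ratios(
    r_ng_cold: float, r_ng_hot: float, n_in_cold: float, n_in_hot: float
) -> tuple[float, float]:
    """Shrinkage 1 - R_hot/R_cold and desorption (N_cold - N_hot)/N_cold."""
    if r_ng_cold <= 0:
        raise ZeroDivisionError("cold-state radius must be positive")
    if n_in_cold <= 0:
        raise ZeroDivisionError("cold-state absorbed count must be positive")
    return 1.0 - r_ng_hot / r_ng_cold, (n_in_cold - n_in_hot) / n_in_cold


def net_charge_profile(
    frames: list[np.ndarray],
    valence: np.ndarray,
    network_mask: np.ndarray,
    box: float,
    bins: np.ndarray,
) -> RadialProfile:
    """Cumulative charge (in e) enclosed by spheres around the network CM."""
    acc = np.zeros(len(bins) - 1)
    charged = valence != 0
    for pos in frames:
        cm = pos[network_mask].mean(axis=0)
        r = _min_image_dist(pos[charged], cm, box)
        hist, _ = np.histogram(r, bins=bins, weights=valence[charged])
        acc += np.cumsum(hist)
    return RadialProfile(np.asarray(bins, float), acc / len(frames), len(frames))


def net_charge_at(
    frames: list[np.ndarray],
    valence: np.ndarray,
    network_mask: np.ndarray,
    box: float,
) -> float:
    """Frame-averaged charge enclosed by the instantaneous geometric radius."""
    vals = []
    charged = valence != 0
    for pos in frames:
        net = pos[network_mask]
        cm = net.mean(axis=0)
        r_ng = geometric_radius(radius_of_gyration(net))
        r = _min_image_dist(pos[charged], cm, box)
        vals.append(float(np.sum(valence[charged][r < r_ng])))
    return float(np.mean(vals))


def potential_profile(
    charge_profile: RadialProfile, l_B: float, box: float
) -> RadialProfile:
    """Dimensionless potential e*psi/k_B*T from the enclosed-charge profile.

    E(r) = l_B Q_enc(r) / r^2 (reduced Gauss law); psi(r) is the inward
    trapezoidal integral of -E from L/2, so psi(L/2) = 0 by construction.
    """
    r = charge_profile.bin_centers
    if r[-1] < box / 2.0 - 1.5 * (r[1] - r[0]):
        raise ValueError("charge profile must extend to half the box length")
    E = l_B * charge_profile.values / r**2
    # psi(r) = -int_{L/2}^{r} E dr' = +int_{r}^{L/2} E dr'
    psi = np.zeros_like(r)
    seg = 0.5 * (E[1:] + E[:-1]) * np.diff(r)
    psi[:-1] = np.cumsum(seg[::-1])[::-1]
    return RadialProfile(charge_profile.bin_edges, psi, charge_profile.n_frames)


def surface_potential(
    frames: list[np.ndarray],
    valence: np.ndarray,
    network_mask: np.ndarray,
    box: float,
    l_B: float,
    r_ng: float,
    bin_width: float = 0.25,
) -> float:
    """Dimensionless potential at the geometric radius, via Gauss' law."""
    bins = np.arange(0.0, box / 2.0 + bin_width, bin_width)
    q = net_charge_profile(frames, valence, network_mask, box, bins)
    psi = potential_profile(q, l_B, box)
    return float(np.interp(r_ng, psi.bin_centers, psi.values))


def rdf(
    frames: list[np.ndarray],
    indices: np.ndarray,
    box: float,
    bin_width: float = 0.1,
    r_max: float | None = None,
) -> RadialProfile:
    """Radial distribution function of one species (minimum-image distances).

    Normalised by the ideal-gas expectation at the species' overall number
    density in the box.
    """
    n = len(indices)
    if n < 2:
        raise ValueError("rdf needs at least two particles")
    r_max = r_max if r_max is not None else box / 2.0
    bins = np.arange(0.0, r_max + bin_width, bin_width)
    acc = np.zeros(len(bins) - 1)
    for pos in frames:
        p = pos[indices]
        d = p[:, None, :] - p[None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        iu = np.triu_indices(n, k=1)
        hist, _ = np.histogram(r[iu], bins=bins)
        acc += hist
    shell_vol = 4.0 / 3.0 * np.pi * (bins[1:] ** 3 - bins[:-1] ** 3)
    density = n / box**3
    ideal = shell_vol * density * (n - 1) / 2.0
    return RadialProfile(bins, acc / len(frames) / ideal, len(frames))


def density_profile(
    frames: list[np.ndarray],
    indices: np.ndarray,
    network_mask: np.ndarray,
    box: float,
    bins: np.ndarray,
) -> RadialProfile:
    """Per-shell number density (1/nm^3) of a species around the network CM."""
    acc = np.zeros(len(bins) - 1)
    for pos in frames:
        cm = pos[network_mask].mean(axis=0)
        r = _min_image_dist(pos[indices], cm, box)
        hist, _ = np.histogram(r, bins=bins)
        acc += hist
    shell_vol = 4.0 / 3.0 * np.pi * (bins[1:] ** 3 - bins[:-1] ** 3)
    return RadialProfile(np.asarray(bins, float), acc / len(frames) / shell_vol, len(frames))


def summarize_runs(rows: list[dict]) -> pd.DataFrame:
    """Mean and standard deviation over independent seeds, per temperature.

    ``rows`` carry one entry per (seed, temperature) with scalar
    observables; the standard deviation over seeds is the quoted error, as
    is conventional for a small number of independent runs.
    """
    df = pd.DataFrame(rows)
    grouped = df.drop(columns=["seed"]).groupby("T")
    mean = grouped.mean().add_suffix("_mean")
    std = grouped.std(ddof=1).add_suffix("_std")
    return mean.join(std).reset_index()
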