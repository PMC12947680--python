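"""Pair potentials and the total-energy model of the simulation.

Four interactions act between beads:

* a purely repulsive WCA core truncated at 2^(1/6) of the mean diameter,
* harmonic bonds along the polymer chains,
* a sigmoidal hydrophobic well between uncharged network beads whose depth
  grows with temperature, and
* Coulomb interactions, summed over periodic images by Ewald summation
  with conducting (tinfoil) boundary conditions.

All energies are in units of k_B*T at the run temperature.  The
:class:`EnergyModel` supports both full recomputation and incremental
single-bead / rigid-cluster updates in which only terms involving the
moved beads are re-evaluated and the Ewald structure factors are updated
in place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erfc

from .thermo import ThermoState, ModelParams
from .topology import Configuration, NetworkTopology

_WCA_CUT = 2.0 ** (1.0 / 6.0)
HYDROPHOBIC_TAIL = 1.5  # nm beyond r_h at which the sigmoid is truncated


@dataclass
class EnergyBreakdown:
    wca: float = 0.0
    bond: float = 0.0
    hydrophobic: float = 0.0
    electrostatic: float = 0.0

    @property
    def total(self) -> float:
        return self.wca + self.bond + self.hydrophobic + self.electrostatic

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.wca + other.wca,
            self.bond + other.bond,
            self.hydrophobic + other.hydrophobic,
            self.electrostatic + other.electrostatic,
        )

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.wca - other.wca,
            self.bond - other.bond,
            self.hydrophobic - other.hydrophobic,
            self.electrostatic - other.electrostatic,
        )


def pair_wca(r, d_i: float, d_j: float, eps: float = 1.0):
    """WCA repulsion: eps*((d/r)^12 - (d/r)^6 + 1/4) for r <= 2^(1/6) d.

    ``r`` may be scalar or array; ``eps`` is the strength in the caller's
    energy units.  Continuous (zero) at the cutoff and purely repulsive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("overlapping beads: r must be > 0")
    d = 0.5 * (d_i + d_j)
    x6 = (d / r) ** 6
    u = eps * (x6 * x6 - x6 + 0.25)
    return np.where(r <= _WCA_CUT * d, u, 0.0)


def pair_bond(r, k_bond: float, r0: float):
    """Harmonic bond 0.5 * k * (r - r0)^2."""
    r = np.asarray(r, dtype=float)
    return 0.5 * k_bond * (r - r0) ** 2


def pair_hydrophobic(r, eps_h: float, k_h: float, r_h: float):
    """Sigmoidal square-well approximation: -(eps_h/2)(1 - tanh(k_h (r - r_h))).

    Applies only between hydrophobic-eligible (uncharged network) beads;
    the caller handles eligibility.
    """
    r = np.asarray(r, dtype=float)
    return -0.5 * eps_h * (1.0 - np.tanh(k_h * (r - r_h)))


def pair_coulomb(r, z_i, z_j, l_B: float):
    """Coulomb energy in k_B*T units: z_i z_j l_B / r."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("overlapping charges: r must be > 0")
    return np.asarray(z_i) * np.asarray(z_j) * l_B / r


@dataclass(frozen=True)
class EwaldSettings:
    """Ewald splitting parameters; unset fields are auto-tuned.

    ``accuracy`` is the target relative accuracy of the lattice sum; the
    splitting parameter alpha and the reciprocal cutoff follow the standard
    error estimates with the real-space cutoff at half the box length.
    """

    alpha: float | None = None       # 1/nm
    r_cut: float | None = None       # nm
    k_max: int | None = None         # integer bound on |n|
    accuracy: float = 1e-4

    def resolved(self, box_length: float) -> "EwaldSettings":
        if self.accuracy <= 0:
            raise ValueError("accuracy must be positive")
        s = np.sqrt(-np.log(self.accuracy))
        r_cut = self.r_cut if self.r_cut is not None else box_length / 2.0
        if r_cut > box_length / 2.0 + 1e-12:
            raise ValueError("r_cut must not exceed half the box length")
        alpha = self.alpha if self.alpha is not None else s / r_cut
        k_max = (
            self.k_max
            if self.k_max is not None
            else int(np.ceil(s * alpha * box_length / np.pi))
        )
        return replace(self, alpha=alpha, r_cut=r_cut, k_max=k_max)


class EwaldSummation:
    """Periodic Coulomb energy with incrementally updated structure factors.

    Operates on the charged subset of a configuration.  Conducting boundary
    conditions (no surface dipole term).  Energies in k_B*T via the Bjerrum
    length.
    """

    def __init__(
        self,
        box_length: float,
        valence: np.ndarray,
        l_B: float,
        settings: EwaldSettings | None = None,
    ):
        if int(np.sum(valence)) != 0:
            raise ValueError(
                "Ewald summation requires an electroneutral configuration"
            )
        self.L = float(box_length)
        self.z = np.asarray(valence, dtype=float)
        self.l_B = float(l_B)
        self.settings = (settings or EwaldSettings()).resolved(self.L)
        self.alpha = self.settings.alpha
        self.r_cut = self.settings.r_cut
        km = self.settings.k_max
        # half reciprocal space (lexicographically positive), weight 2
        ns = []
        for nx in range(-km, km + 1):
            for ny in range(-km, km + 1):
                for nz in range(-km, km + 1):
                    if (nx, ny, nz) == (0, 0, 0):
                        continue
                    if nx * nx + ny * ny + nz * nz > km * km:
                        continue
                    if (nx, ny, nz) > (0, 0, 0):
                        ns.append((nx, ny, nz))
        n_arr = np.array(ns, dtype=float)
        self.kvecs = 2.0 * np.pi / self.L * n_arr          # (Nk, 3)
        k2 = np.einsum("ij,ij->i", self.kvecs, self.kvecs)
        self.a_k = 2.0 * np.exp(-k2 / (4.0 * self.alpha**2)) / k2
        self.volume = self.L**3
        self._S: np.ndarray | None = None  # complex structure factors

    # -- structure factors -------------------------------------------------
    def _phases(self, positions: np.ndarray) -> np.ndarray:
        return np.exp(1j * positions @ self.kvecs.T)  # (N, Nk)

    def initialize(self, positions: np.ndarray) -> None:
        self._S = (self.z[:, None] * self._phases(positions)).sum(axis=0)

    # -- energy pieces -----------------------------------------------------
    def real_space(self, positions: np.ndarray) -> float:
        n = len(positions)
        if n < 2:
            return 0.0
        u = 0.0
        L = self.L
        for i in range(n - 1):
            d = positions[i + 1:] - positions[i]
            d -= L * np.round(d / L)
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            mask = r < self.r_cut
            if mask.any():
                rm = r[mask]
                u += self.z[i] * np.sum(
                    self.z[i + 1:][mask] * erfc(self.alpha * rm) / rm
                )
        return self.l_B * u

    def reciprocal(self) -> float:
        return (
            2.0 * np.pi * self.l_B / self.volume
            * float(np.sum(self.a_k * np.abs(self._S) ** 2))
        )

    def self_energy(self) -> float:
        return -self.l_B * self.alpha / np.sqrt(np.pi) * float(np.sum(self.z**2))

    def total(self, positions: np.ndarray) -> float:
        self.initialize(positions)
        return self.real_space(positions) + self.reciprocal() + self.self_energy()

    # -- incremental updates ----------------------------------------------
    def delta_move(
        self,
        positions: np.ndarray,
        moved: np.ndarray,
        new_pos: np.ndarray,
        rigid: bool = False,
    ) -> tuple[float, np.ndarray]:
        """Energy change for moving beads ``moved`` to ``new_pos``.

        Returns (delta_U, delta_S); apply ``delta_S`` with
        :meth:`apply_delta` on acceptance.  ``rigid`` marks moves that
        preserve all intra-set separations (cluster translations), letting
        the intra-set real-space terms be skipped.
        """
        moved = np.atleast_1d(np.asarray(moved, dtype=int))
        new_pos = np.atleast_2d(new_pos)
        L = self.L
        others = np.ones(len(positions), dtype=bool)
        others[moved] = False
        du_real = 0.0
        z_o = self.z[others]
        pos_o = positions[others]
        for b, i in enumerate(moved):
            if self.z[i] == 0.0 and not rigid:
                continue
            for p, sgn in ((new_pos[b], +1.0), (positions[i], -1.0)):
                d = pos_o - p
                d -= L * np.round(d / L)
                r = np.sqrt(np.einsum("ij,ij->i", d, d))
                mask = r < self.r_cut
                rm = r[mask]
                du_real += sgn * self.z[i] * np.sum(
                    z_o[mask] * erfc(self.alpha * rm) / rm
                )
        if not rigid and len(moved) > 1:
            for a in range(len(moved) - 1):
                for b in range(a + 1, len(moved)):
                    for pa, pb, sgn in (
                        (new_pos[a], new_pos[b], +1.0),
                        (positions[moved[a]], positions[moved[b]], -1.0),
                    ):
                        d = pa - pb
                        d -= L * np.round(d / L)
                        r = float(np.linalg.norm(d))
                        if r < self.r_cut:
                            du_real += (
                                sgn
                                * self.z[moved[a]]
                                * self.z[moved[b]]
                                * erfc(self.alpha * r)
                                / r
                            )
        du_real *= self.l_B

        zm = self.z[moved]
        dS = (zm[:, None] * (self._phases(new_pos) - self._phases(positions[moved]))).sum(axis=0)
        S_new = self._S + dS
        du_rec = (
            2.0 * np.pi * self.l_B / self.volume
            * float(np.sum(self.a_k * (np.abs(S_new) ** 2 - np.abs(self._S) ** 2)))
        )
        return du_real + du_rec, dS

    def apply_delta(self, dS: np.ndarray) -> None:
        self._S = self._S + dS


class EnergyModel:
    """Total and incremental energies of a configuration at temperature T."""

    def __init__(
        self,
        config: Configuration,
        topology: NetworkTopology | None,
        thermo: ThermoState,
        params: ModelParams | None = None,
        ewald_settings: EwaldSettings | None = None,
    ):
        self.config = config
        self.topology = topology
        self.thermo = thermo
        self.params = params or ModelParams()
        self.pos = config.positions  # shared reference, mutated by the sampler
        self.L = config.box_length
        self.z = config.valence.astype(float)
        self.dia = config.diameter
        self.eligible = config.hydrophobic_eligible & (config.valence == 0)
        self.bonds = (
            topology.bonds if topology is not None else np.empty((0, 2), int)
        )
        nbrs = [[] for _ in range(config.n_beads)]
        for i, j in self.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        self.bond_partners = [np.asarray(v, dtype=int) for v in nbrs]

        self.hydro_cut = self.params.r_h + HYDROPHOBIC_TAIL
        charged = np.nonzero(config.valence != 0)[0]
        self.charged_idx = charged
        self._charged_pos_of = -np.ones(config.n_beads, dtype=int)
        self._charged_pos_of[charged] = np.arange(len(charged))
        if len(charged):
            self.ewald = EwaldSummation(
                self.L, config.valence[charged], thermo.l_B, ewald_settings
            )
            self.ewald.initialize(self.pos[charged])
        else:
            self.ewald = None

    # -- helpers -----------------------------------------------------------
    def _min_image(self, d: np.ndarray) -> np.ndarray:
        return d - self.L * np.round(d / self.L)

    def _short_range_pair(self, i: int, pos_i, others: np.ndarray) -> tuple[float, float]:
        """WCA + hydrophobic energy between bead i at pos_i and ``others``."""
        d = self._min_image(self.pos[others] - pos_i)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        dmean = 0.5 * (self.dia[others] + self.dia[i])
        u_wca = 0.0
        mask = r <= _WCA_CUT * dmean
        if mask.any():
            if np.any(r[mask] <= 0):
                raise FloatingPointError("bead overlap at zero distance")
            x6 = (dmean[mask] / r[mask]) ** 6
            u_wca = self.thermo.eps_wca_kt * float(np.sum(x6 * x6 - x6 + 0.25))
        u_h = 0.0
        if self.eligible[i]:
            hmask = self.eligible[others] & (r < self.hydro_cut)
            if hmask.any():
                u_h = float(
                    np.sum(
                        pair_hydrophobic(
                            r[hmask],
                            self.thermo.eps_h_kt,
                            self.params.k_h,
                            self.params.r_h,
                        )
                    )
                )
        return u_wca, u_h

    # -- full energy -------------------------------------------------------
    def total(self) -> EnergyBreakdown:
        n = self.config.n_beads
        eb = EnergyBreakdown()
        idx = np.arange(n)
        for i in range(n - 1):
            others = idx[i + 1:]
            w, h = self._short_range_pair(i, self.pos[i], others)
            eb.wca += w
            eb.hydrophobic += h
        if len(self.bonds):
            d = self._min_image(self.pos[self.bonds[:, 0]] - self.pos[self.bonds[:, 1]])
            r = np.linalg.norm(d, axis=1)
            eb.bond = float(
                np.sum(pair_bond(r, self.thermo.k_bond_kt, self.params.r0))
            )
        if self.ewald is not None:
            eb.electrostatic = self.ewald.total(self.pos[self.charged_idx])
        return eb

    # -- incremental energy ------------------------------------------------
    def delta(
        self, moved: np.ndarray, new_pos: np.ndarray, rigid: bool = False
    ) -> tuple[EnergyBreakdown, np.ndarray | None]:
        """Energy change for moving ``moved`` beads to ``new_pos``.

        Only terms involving the moved beads are recomputed; returns the
        component-wise change plus the Ewald structure-factor update to be
        applied on acceptance.  For ``rigid`` moves intra-set terms are
        skipped (separations unchanged).
        """
        moved = np.atleast_1d(np.asarray(moved, dtype=int))
        new_pos = np.atleast_2d(np.asarray(new_pos, dtype=float))
        in_set = np.zeros(self.config.n_beads, dtype=bool)
        in_set[moved] = True
        others = np.nonzero(~in_set)[0]
        d_eb = EnergyBreakdown()
        for b, i in enumerate(moved):
            w_new, h_new = self._short_range_pair(i, new_pos[b], others)
            w_old, h_old = self._short_range_pair(i, self.pos[i], others)
            d_eb.wca += w_new - w_old
            d_eb.hydrophobic += h_new - h_old
            partners = self.bond_partners[i]
            if len(partners):
                ext = partners[~in_set[partners]]
                if len(ext):
                    r_new = np.linalg.norm(
                        self._min_image(self.pos[ext] - new_pos[b]), axis=1
                    )
                    r_old = np.linalg.norm(
                        self._min_image(self.pos[ext] - self.pos[i]), axis=1
                    )
                    d_eb.bond += float(
                        np.sum(pair_bond(r_new, self.thermo.k_bond_kt, self.params.r0))
                        - np.sum(pair_bond(r_old, self.thermo.k_bond_kt, self.params.r0))
                    )
        if not rigid and len(moved) > 1:
            d_eb = d_eb + self._intra_set_delta(moved, new_pos)
        dS = None
        charged_moved = moved[self.z[moved] != 0.0]
        if self.ewald is not None and len(charged_moved):
            cpos = self._charged_pos_of[charged_moved]
            sel = self.z[moved] != 0.0
            du_e, dS = self.ewald.delta_move(
                self.pos[self.charged_idx], cpos, new_pos[sel], rigid=rigid
            )
            d_eb.electrostatic = du_e
        return d_eb, dS

    def _intra_set_delta(self, moved, new_pos) -> EnergyBreakdown:
        d_eb = EnergyBreakdown()
        m = len(moved)
        for a in range(m - 1):
            for b in range(a + 1, m):
                i, j = moved[a], moved[b]
                for pi, pj, sgn in (
                    (new_pos[a], new_pos[b], +1.0),
                    (self.pos[i], self.pos[j], -1.0),
                ):
                    d = self._min_image(np.asarray(pi) - np.asarray(pj))
                    r = float(np.linalg.norm(d))
                    dmean = 0.5 * (self.dia[i] + self.dia[j])
                    if r <= _WCA_CUT * dmean:
                        x6 = (dmean / r) ** 6
                        d_eb.wca += sgn * self.thermo.eps_wca_kt * (x6 * x6 - x6 + 0.25)
                    if self.eligible[i] and self.eligible[j] and r < self.hydro_cut:
                        d_eb.hydrophobic += sgn * float(
                            pair_hydrophobic(
                                r, self.thermo.eps_h_kt, self.params.k_h, self.params.r_h
                            )
                        )
                    if j in self.bond_partners[i]:
                        d_eb.bond += sgn * float(
                            pair_bond(r, self.thermo.k_bond_kt, self.params.r0)
                        )
        return d_eb

    def apply(self, moved: np.ndarray, new_pos: np.ndarray, dS: np.ndarray | None) -> None:
        moved = np.atleast_1d(np.asarray(moved, dtype=int))
        self.pos[moved] = np.atleast_2d(new_pos)
        if dS is not None and self.ewald is not None:
            self.ewald.apply_delta(dS)

    def resync_ewald(self) -> None:
        """Rebuild structure factors from scratch (after non-incremental moves)."""
        if self.ewald is not None:
            self.ewald.initialize(self.pos[self.charged_idx])
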