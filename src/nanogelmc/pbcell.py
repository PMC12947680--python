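"""Poisson-Boltzmann cell model of a charged nanogel.

One nanogel is represented as a uniformly charged permeable sphere of
radius ``R_NG`` at the centre of a larger electroneutral spherical cell
whose volume equals that of the simulation box.  Mobile species (anions,
cations, nanoparticles) follow Boltzmann statistics in the mean-field
potential; the excluded-volume variant caps local concentrations through a
shared saturation denominator with per-species maxima
``n_i,max = (1 - phi_NG) / d_i^3`` inside the gel (and ``1 / d_i^3``
outside, where only the species' own size limits packing).

Convention: ``psi`` is the dimensionless potential e*psi/k_B*T and the
Poisson equation reads

    psi'' + (2/r) psi' = -4 pi l_B [ rho_bare(r) + sum_i z_i c_i(r) ]

with c_i(r) = n_i0 exp(-z_i psi) / D(r) and
D = 1 + sum_j (n_j0 / n_j,max) exp(-z_j psi) when saturation is enabled.
Boundary conditions: psi(R_cell) = 0 (gauge) and psi'(r -> 0) = 0
(regularity); psi'(R_cell) = 0 then follows from cell electroneutrality
via Gauss' law and is reported as a residual diagnostic.  The boundary
concentrations n_i0 are adjusted by an outer fixed-point loop until each
species' concentration integrates to its prescribed number per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded


@dataclass(frozen=True)
class PBSpecies:
    label: str
    valence: int
    diameter: float   # nm
    count: float      # particles per cell (mean-field: may be non-integer)


@dataclass
class PBCellSpec:
    """Inputs of one cell-model solve.  Lengths in nm, charges in e."""

    R_NG: float
    Z: float                       # bare network charge
    cell_radius: float
    l_B: float
    species: list[PBSpecies]
    phi_NG: float = 0.0
    saturation_enabled: bool = True
    n_nodes: int = 4000

    def __post_init__(self) -> None:
        if not 0.0 < self.R_NG < self.cell_radius:
            raise ValueError("need 0 < R_NG < cell_radius")
        if not 0.0 <= self.phi_NG < 1.0:
            raise ValueError("phi_NG must be in [0, 1)")
        q = self.Z + sum(s.valence * s.count for s in self.species)
        if abs(q) > 1e-9 * max(1.0, abs(self.Z)):
            raise ValueError(f"cell is not electroneutral (residual charge {q:g})")


@dataclass
class PBCellSolution:
    spec: PBCellSpec
    r_grid: np.ndarray
    psi: np.ndarray
    concentrations: dict[str, np.ndarray]   # nm^-3 per node
    boundary_concentrations: dict[str, float]
    converged: bool
    residual: float                          # max relative count error
    edge_field: float = field(default=0.0)   # |psi'(R_cell)|, diagnostic

    def psi_at(self, r: float) -> float:
        return float(np.interp(r, self.r_grid, self.psi))


def n_i_max(phi_NG: float, diameter: float) -> float:
    """Maximum local concentration (1/nm^3): (1 - phi_NG) / d^3."""
    if not 0.0 <= phi_NG < 1.0:
        raise ValueError("phi_NG must be in [0, 1)")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return (1.0 - phi_NG) / diameter**3


def cell_radius_for_box(box_length: float) -> float:
    """Radius of the sphere with the volume of a cubic box."""
    return (3.0 * box_length**3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def polymer_volume_fraction(
    n_network_beads: int, bead_diameter: float, r_ng: float
) -> float:
    """phi_NG estimate: total network bead volume over the gel volume."""
    v_beads = n_network_beads * np.pi / 6.0 * bead_diameter**3
    return float(v_beads / (4.0 / 3.0 * np.pi * r_ng**3))


def _concentration_fields(
    psi: np.ndarray, r: np.ndarray, spec: PBCellSpec, n0: np.ndarray
) -> np.ndarray:
    """Species concentrations (n_species, n_nodes) for a given potential."""
    z = np.array([s.valence for s in spec.species], dtype=float)
    boltz = n0[:, None] * np.exp(-z[:, None] * psi[None, :])
    if spec.saturation_enabled and len(spec.species):
        inside = r < spec.R_NG
        nmax = np.array(
            [n_i_max(spec.phi_NG, s.diameter) for s in spec.species]
        )[:, None] * np.ones_like(r)[None, :]
        nmax_out = np.array([n_i_max(0.0, s.diameter) for s in spec.species])
        nmax[:, ~inside] = nmax_out[:, None]
        denom = 1.0 + np.sum(boltz / nmax, axis=0)
        return boltz / denom[None, :]
    return boltz


def _newton_solve_psi(
    r: np.ndarray,
    rho_of_psi,
    l_B: float,
    psi0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> np.ndarray:
    """Damped Newton iteration for psi'' + (2/r) psi' = -4 pi l_B rho(psi, r).

    Second-order central differences on the uniform grid ``r`` with
    psi'(r[0]) = 0 (mirror node) and psi(r[-1]) = 0.  The Jacobian is
    tridiagonal; the Newton step is damped by halving until the residual
    norm decreases.
    """
    n = r.size
    h = r[1] - r[0]
    psi = psi0.copy()
    psi[-1] = 0.0
    pref = 4.0 * np.pi * l_B

    def residual(p):
        res = np.zeros(n)
        lap_in = (2.0 * p[1] - 2.0 * p[0]) / h**2  # mirror: psi[-1] == psi[1]
        res[0] = lap_in + pref * rho_of_psi(p[0:1], slice(0, 1))[0]
        interior = slice(1, n - 1)
        d2 = (p[2:] - 2.0 * p[1:-1] + p[:-2]) / h**2
        d1 = (p[2:] - p[:-2]) / (2.0 * h)
        res[interior] = d2 + 2.0 / r[1:-1] * d1 + pref * rho_of_psi(p[1:-1], interior)
        res[n - 1] = p[n - 1]
        return res

    def drho_dpsi(p, sl):
        eps = 1e-7 * np.maximum(1.0, np.abs(p))
        return (rho_of_psi(p + eps, sl) - rho_of_psi(p - eps, sl)) / (2.0 * eps)

    res = residual(psi)
    norm = np.linalg.norm(res)
    for _ in range(max_iter):
        if norm < tol * n:
            break
        ab = np.zeros((3, n))
        # row 0: mirror boundary
        ab[1, 0] = -2.0 / h**2 + pref * drho_dpsi(psi[0:1], slice(0, 1))[0]
        ab[0, 1] = 2.0 / h**2  # superdiag entry for column 1
        # interior rows
        ri = r[1:-1]
        ab[0, 2:] = 1.0 / h**2 + 1.0 / (ri * h)          # superdiagonal
        ab[1, 1:-1] = -2.0 / h**2 + pref * drho_dpsi(psi[1:-1], slice(1, n - 1))
        ab[2, :-2] = 1.0 / h**2 - 1.0 / (ri * h)          # subdiagonal
        # last row: Dirichlet
        ab[1, n - 1] = 1.0
        ab[2, n - 2] = 0.0
        step = solve_banded((1, 1), ab, -res)
        t = 1.0
        while t > 1e-6:
            trial = psi + t * step
            res_t = residual(trial)
            norm_t = np.linalg.norm(res_t)
            if norm_t < norm:
                psi, res, norm = trial, res_t, norm_t
                break
            t *= 0.5
        else:
            break  # stalled; return best found
    return psi


def solve(spec: PBCellSpec, count_tol: float = 1e-6, max_outer: int = 400) -> PBCellSolution:
    """Solve the (modified) PB cell model with the number constraints.

    Inner problem: finite-difference damped-Newton solve for psi on a
    uniform radial mesh; outer loop: multiplicative fixed point on the
    boundary concentrations until every species count integrates to its
    target within ``count_tol`` (relative).  The electrostatic coupling is
    ramped up in stages to give Newton a tractable starting point at high
    charge.
    """
    b = spec.cell_radius
    rho_bare_amp = 3.0 * spec.Z / (4.0 * np.pi * spec.R_NG**3)
    z = np.array([s.valence for s in spec.species], dtype=float)
    counts = np.array([s.count for s in spec.species], dtype=float)
    v_cell = 4.0 / 3.0 * np.pi * b**3
    active = counts > 0
    n0 = np.where(active, counts / v_cell, 0.0)

    r = np.linspace(b / spec.n_nodes, b, spec.n_nodes)
    shell = 4.0 * np.pi * r**2
    h = r[1] - r[0]
    # bare-charge step smeared over one grid cell (fraction of the cell
    # inside R_NG); pointwise sampling would make psi first-order in h
    inside_frac = np.clip((spec.R_NG - (r - 0.5 * h)) / h, 0.0, 1.0)
    rho_bare = rho_bare_amp * inside_frac

    def rho_for(n0_cur, scale=1.0):
        def rho(psi, sl):
            out = scale * rho_bare[sl]
            if len(spec.species):
                c = _concentration_fields(psi, r[sl], spec, scale * n0_cur)
                out = out + np.sum(z[:, None] * c, axis=0)
            return out
        return rho

    psi = np.zeros(r.size)
    for scale in (0.05, 0.2, 0.5, 1.0):  # charge ramp (continuation)
        psi = _newton_solve_psi(r, rho_for(n0, scale), spec.l_B, psi)

    residual = 0.0
    converged = True
    if len(spec.species):
        converged = False
        for _ in range(max_outer):
            psi = _newton_solve_psi(r, rho_for(n0), spec.l_B, psi)
            c = _concentration_fields(psi, r, spec, n0)
            integ = np.trapezoid(c * shell, r, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(
                    active & (integ > 0), counts / np.maximum(integ, 1e-300), 1.0
                )
            residual = float(
                np.max(
                    np.abs(
                        np.where(active, integ / np.maximum(counts, 1e-300), 1.0) - 1.0
                    )
                )
            )
            if residual < count_tol:
                converged = True
                break
            n0 = n0 * np.clip(ratio, 0.1, 10.0) ** 0.8

    c = (
        _concentration_fields(psi, r, spec, n0)
        if len(spec.species)
        else np.empty((0, r.size))
    )
    edge_field = abs(psi[-1] - psi[-2]) / (r[-1] - r[-2])
    return PBCellSolution(
        spec=spec,
        r_grid=r,
        psi=psi,
        concentrations={s.label: c[i] for i, s in enumerate(spec.species)},
        boundary_concentrations={s.label: float(n0[i]) for i, s in enumerate(spec.species)},
        converged=converged,
        residual=residual,
        edge_field=float(edge_field),
    )


def absorbed_count(solution: PBCellSolution, species_label: str, r_ng: float | None = None) -> float:
    """Number of a species inside the gel: integral of c(r) 4 pi r^2 dr to R_NG."""
    r_ng = r_ng if r_ng is not None else solution.spec.R_NG
    r = solution.r_grid
    c = solution.concentrations[species_label]
    mask = r <= r_ng
    return float(np.trapezoid(c[mask] * 4.0 * np.pi * r[mask] ** 2, r[mask]))


def net_charge(
    solution: PBCellSolution,
    r_ng: float | None = None,
    external_bare_charge: float = 0.0,
) -> float:
    """Charge within R_NG: Z + sum_i z_i N_i(absorbed) - external bare charge.

    The correction term accounts for charged network groups that lie
    outside the geometric radius in the particle picture but are counted
    inside by the uniformly charged sphere of the cell model.
    """
    total = solution.spec.Z - external_bare_charge
    for s in solution.spec.species:
        total += s.valence * absorbed_count(solution, s.label, r_ng)
    return float(total)


def surface_potential(solution: PBCellSolution, r_ng: float | None = None) -> float:
    """Dimensionless potential interpolated at the gel surface."""
    r_ng = r_ng if r_ng is not None else solution.spec.R_NG
    return solution.psi_at(r_ng)
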