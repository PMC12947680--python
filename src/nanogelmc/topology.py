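"""Nanogel network construction and box population.

The polymer network is built from a diamond lattice of tetrafunctional
cross-linkers: a sphere is drawn around a tetrahedral interstitial site of
the lattice so that exactly the requested number of cross-linkers survive
trimming, and every nearest-neighbour pair of surviving sites is joined by
a straight chain of equally spaced monomeric beads.  With the lattice
spacing tied to the relaxed bond length, the initial network is
stress-free.  Counterions, nanoparticles and the nanoparticles' own
counterions are then inserted at random non-overlapping positions.

Species roles used throughout: ``monomer``, ``crosslinker``, ``anion``,
``cation``, ``nanoparticle``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

ROLE_MONOMER = "monomer"
ROLE_CROSSLINKER = "crosslinker"
ROLE_ANION = "anion"
ROLE_CATION = "cation"
ROLE_NANOPARTICLE = "nanoparticle"

NETWORK_ROLES = (ROLE_MONOMER, ROLE_CROSSLINKER)

# Default bead diameters (nm)
DIAMETER_NETWORK = 0.65
DIAMETER_ION = 0.70
DIAMETER_NANOPARTICLE = 5.00

# nearest-neighbour distance of the diamond lattice, in units of the cubic
# lattice constant
_DIAMOND_NN = np.sqrt(3.0) / 4.0


@dataclass(frozen=True)
class SpeciesSpec:
    """One bead species of the model."""

    label: str
    role: str
    diameter: float      # nm
    valence: int         # elementary charges
    count: int
    hydrophobic_eligible: bool = False

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.hydrophobic_eligible and self.valence != 0:
            raise ValueError("charged species cannot be hydrophobic-eligible")


@dataclass
class NetworkTopology:
    """Connectivity of the polymer network.

    ``chains`` are ordered bead-index sequences including the two terminal
    cross-linkers; each chain therefore has ``len(chain) - 2`` interior
    monomers.
    """

    bead_roles: list[str]
    bonds: np.ndarray                    # (M, 2) int
    chains: list[list[int]]
    crosslinker_ids: np.ndarray          # int
    charged_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_beads(self) -> int:
        return len(self.bead_roles)

    def neighbour_lists(self) -> list[np.ndarray]:
        """Per-bead arrays of bonded partners."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_beads)]
        for i, j in self.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.asarray(v, dtype=int) for v in nbrs]

    def functionality(self) -> np.ndarray:
        """Number of chains meeting at each cross-linker."""
        deg = np.zeros(self.n_beads, dtype=int)
        for i, j in self.bonds:
            deg[i] += 1
            deg[j] += 1
        return deg[self.crosslinker_ids]

    def is_connected(self) -> bool:
        if self.n_beads == 0:
            return True
        adj = self.neighbour_lists()
        seen = np.zeros(self.n_beads, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            i = stack.pop()
            for j in adj[i]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        return bool(seen.all())


@dataclass
class Configuration:
    """Positions and species assignment of every bead in the periodic box.

    Positions are stored unwrapped (the network is kept contiguous so its
    centre of mass is meaningful); every distance computation applies the
    minimum-image convention, so values outside [0, L) are harmless and
    :meth:`wrapped_positions` is available for output.
    """

    box_length: float
    positions: np.ndarray        # (N, 3) nm
    species: list[str]           # label per bead
    roles: list[str]             # role per bead
    valence: np.ndarray          # int per bead
    diameter: np.ndarray         # nm per bead
    hydrophobic_eligible: np.ndarray  # bool per bead

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def total_charge(self) -> int:
        return int(self.valence.sum())

    def role_mask(self, *roles: str) -> np.ndarray:
        rset = set(roles)
        return np.array([r in rset for r in self.roles], dtype=bool)

    @property
    def network_mask(self) -> np.ndarray:
        return self.role_mask(*NETWORK_ROLES)

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.positions, self.box_length)

    def minimum_image(self, delta: np.ndarray) -> np.ndarray:
        L = self.box_length
        return delta - L * np.round(delta / L)

    def distances_from(self, point: np.ndarray, indices=None) -> np.ndarray:
        pos = self.positions if indices is None else self.positions[indices]
        d = self.minimum_image(pos - point)
        return np.linalg.norm(d, axis=1)

    def copy(self) -> "Configuration":
        return Configuration(
            box_length=self.box_length,
            positions=self.positions.copy(),
            species=list(self.species),
            roles=list(self.roles),
            valence=self.valence.copy(),
            diameter=self.diameter.copy(),
            hydrophobic_eligible=self.hydrophobic_eligible.copy(),
        )


class TrimmingError(ValueError):
    """No trimming radius encloses exactly the requested cross-linker count."""


def _diamond_sites(n_cells: int) -> np.ndarray:
    """Diamond-lattice sites of an n_cells^3 block, lattice constant 1."""
    fcc = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    basis = np.array([[0, 0, 0], [0.25, 0.25, 0.25]])
    cells = np.array(list(product(range(n_cells), repeat=3)), dtype=float)
    sites = (cells[:, None, None, :] + fcc[None, :, None, :] + basis[None, None, :, :])
    return sites.reshape(-1, 3)


def trim_crosslinker_sites(n_crosslinkers: int, n_cells: int | None = None) -> np.ndarray:
    """Select exactly ``n_crosslinkers`` diamond sites inside a sphere.

    The sphere is centred on a tetrahedral interstitial position in the
    middle of the lattice block; sites are ranked by distance with
    lexicographic tie-breaking, and the trimming radius is the unique value
    (if any) that separates the requested count from the next shell.
    Returns site coordinates in lattice-constant units, centred on the
    sphere centre.
    """
    if n_crosslinkers < 1:
        raise ValueError("n_crosslinkers must be >= 1")
    if n_crosslinkers == 1:  # degenerate: one isolated bead, no chains
        return np.zeros((1, 3))
    if n_cells is None:
        n_cells = max(4, int(np.ceil((n_crosslinkers / 8.0) ** (1.0 / 3.0))) + 4)
    sites = _diamond_sites(n_cells)
    centre = np.full(3, n_cells // 2 + 0.5)  # tetrahedral hole
    rel = sites - centre
    d = np.linalg.norm(rel, axis=1)
    order = np.lexsort((rel[:, 2], rel[:, 1], rel[:, 0], np.round(d, 9)))
    d_sorted = d[order]
    k = n_crosslinkers
    if k > len(sites):
        raise TrimmingError(f"lattice block too small for {k} sites")
    gap = 1e-9
    if k < len(sites) and d_sorted[k] - d_sorted[k - 1] <= gap:
        achievable = [
            m + 1
            for m in range(min(len(sites) - 1, 4 * k))
            if d_sorted[m + 1] - d_sorted[m] > gap
        ]
        raise TrimmingError(
            f"no trimming radius encloses exactly {k} cross-linkers; "
            f"achievable counts near the centre: {achievable[:20]}"
        )
    return rel[order[:k]]


def _nearest_neighbour_bonds(sites: np.ndarray) -> np.ndarray:
    """Index pairs of diamond nearest neighbours (distance sqrt(3)/4)."""
    n = len(sites)
    pairs = []
    for i in range(n):
        dd = np.linalg.norm(sites[i + 1:] - sites[i], axis=1)
        for j in np.nonzero(np.abs(dd - _DIAMOND_NN) < 1e-8)[0]:
            pairs.append((i, i + 1 + int(j)))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def build_network(
    n_chains: int,
    monomers_per_chain: int,
    n_crosslinkers: int,
    bond_length: float = 0.65,
    box_length: float = 150.0,
    diameter: float = DIAMETER_NETWORK,
) -> tuple[NetworkTopology, Configuration]:
    """Build the diamond-derived nanogel network.

    The lattice constant is chosen so that nearest-neighbour cross-linkers
    sit ``(monomers_per_chain + 1) * bond_length`` apart, i.e. the straight
    connecting chains are at their relaxed bond length.  Raises
    :class:`TrimmingError` if no sphere encloses exactly
    ``n_crosslinkers`` sites, and :class:`ValueError` if the induced chain
    count differs from ``n_chains``.
    """
    if min(n_chains, monomers_per_chain, n_crosslinkers) < 0:
        raise ValueError("counts must be non-negative")
    sites = trim_crosslinker_sites(n_crosslinkers)
    site_bonds = _nearest_neighbour_bonds(sites) if n_crosslinkers > 1 else np.empty((0, 2), int)
    if len(site_bonds) != n_chains:
        raise ValueError(
            f"trimming {n_crosslinkers} cross-linkers induces {len(site_bonds)} "
            f"chains, but {n_chains} were requested"
        )

    a = (monomers_per_chain + 1) * bond_length * 4.0 / np.sqrt(3.0)
    xl_pos = sites * a + box_length / 2.0

    roles: list[str] = [ROLE_CROSSLINKER] * n_crosslinkers
    positions = [xl_pos]
    bonds: list[tuple[int, int]] = []
    chains: list[list[int]] = []
    next_id = n_crosslinkers
    m = monomers_per_chain
    for i, j in site_bonds:
        chain = [int(i)]
        prev = int(i)
        for k in range(1, m + 1):
            frac = k / (m + 1)
            positions.append(xl_pos[i] + frac * (xl_pos[j] - xl_pos[i]))
            roles.append(ROLE_MONOMER)
            bonds.append((prev, next_id))
            chain.append(next_id)
            prev = next_id
            next_id += 1
        bonds.append((prev, int(j)))
        chain.append(int(j))
        chains.append(chain)

    all_pos = np.vstack([xl_pos] + [np.asarray(p).reshape(1, 3) for p in positions[1:]]) \
        if len(positions) > 1 else xl_pos.copy()
    n_beads = len(roles)
    topo = NetworkTopology(
        bead_roles=roles,
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        chains=chains,
        crosslinker_ids=np.arange(n_crosslinkers),
    )
    config = Configuration(
        box_length=box_length,
        positions=all_pos,
        species=list(roles),
        roles=list(roles),
        valence=np.zeros(n_beads, dtype=int),
        diameter=np.full(n_beads, diameter),
        hydrophobic_eligible=np.ones(n_beads, dtype=bool),
    )
    return topo, config


def assign_chain_charges(
    topology: NetworkTopology,
    config: Configuration,
    n_charged_per_chain: int,
) -> NetworkTopology:
    """Give every chain exactly ``n_charged_per_chain`` monomers of +1e.

    Charged monomers are evenly spaced along the chain interior (indices
    floor((j + 1/2) * m / n) for j = 0..n-1); they lose hydrophobic
    eligibility.  Total network charge becomes
    ``n_chains * n_charged_per_chain``.
    """
    if not topology.chains:
        if n_charged_per_chain:
            raise ValueError("network has no chains to charge")
        topology.charged_ids = np.empty(0, dtype=int)
        return topology
    m = len(topology.chains[0]) - 2
    n = n_charged_per_chain
    if not 0 <= n <= m:
        raise ValueError(f"n_charged_per_chain must be in [0, {m}], got {n}")
    charged: list[int] = []
    for chain in topology.chains:
        interior = chain[1:-1]
        for j in range(n):
            charged.append(interior[int((j + 0.5) * m // n)])
    charged_arr = np.array(sorted(charged), dtype=int)
    config.valence[:] = 0
    config.valence[charged_arr] = 1
    config.hydrophobic_eligible[:] = config.network_mask
    config.hydrophobic_eligible[charged_arr] = False
    for i in charged_arr:
        config.species[i] = "charged_monomer"
    topology.charged_ids = charged_arr
    return topology


class InsertionError(RuntimeError):
    pass


def populate_box(
    config: Configuration,
    topology: NetworkTopology,
    n_nanoparticles: int,
    np_valence: int = -5,
    seed: int = 0,
    ion_diameter: float = DIAMETER_ION,
    np_diameter: float = DIAMETER_NANOPARTICLE,
    max_attempts: int = 20000,
) -> Configuration:
    """Add counterions, nanoparticles and their counterions to the box.

    Inserts ``Z`` monovalent anions (neutralising the network),
    ``n_nanoparticles`` nanoparticles of valence ``np_valence`` and
    ``|np_valence| * n_nanoparticles`` monovalent cations, all at uniform
    random positions rejected on overlap (minimum-image centre distance
    below contact) with everything already placed.  Exact electroneutrality
    holds by construction.
    """
    if np_valence >= 0 and n_nanoparticles > 0:
        raise ValueError("nanoparticles are expected to carry negative charge")
    rng = np.random.default_rng(seed)
    Z = int(config.valence.sum())
    to_insert: list[tuple[str, str, int, float, bool]] = []
    to_insert += [(ROLE_ANION, ROLE_ANION, -1, ion_diameter, False)] * Z
    to_insert += [
        (ROLE_NANOPARTICLE, ROLE_NANOPARTICLE, np_valence, np_diameter, False)
    ] * n_nanoparticles
    to_insert += [(ROLE_CATION, ROLE_CATION, +1, ion_diameter, False)] * (
        abs(np_valence) * n_nanoparticles
    )

    out = config.copy()
    pos_list = [out.positions]
    dia_list = [out.diameter]
    L = out.box_length
    for label, role, z, dia, elig in to_insert:
        cur_pos = np.vstack(pos_list)
        cur_dia = np.concatenate(dia_list)
        contact = 0.5 * (cur_dia + dia)
        placed = False
        for _ in range(max_attempts):
            trial = rng.uniform(0.0, L, size=3)
            delta = cur_pos - trial
            delta -= L * np.round(delta / L)
            if np.all(np.einsum("ij,ij->i", delta, delta) >= contact**2):
                pos_list.append(trial.reshape(1, 3))
                dia_list.append(np.array([dia]))
                out.species.append(label)
                out.roles.append(role)
                placed = True
                break
        if not placed:
            raise InsertionError(
                f"could not insert a {label} bead without overlap after "
                f"{max_attempts} attempts"
            )
    n_new = len(to_insert)
    out.positions = np.vstack(pos_list)
    out.diameter = np.concatenate(dia_list)
    out.valence = np.concatenate(
        [out.valence, np.array([t[2] for t in to_insert], dtype=int)]
    )
    out.hydrophobic_eligible = np.concatenate(
        [out.hydrophobic_eligible, np.zeros(n_new, dtype=bool)]
    )
    assert out.total_charge() == 0
    return out
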