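"""Deterministic generators of small reference systems.

Everything here is reproducible bit-for-bit from its arguments (and seed,
where one is used): miniature diamond-derived networks, a rock-salt
crystal for validating the Ewald sum against the Madelung constant, and a
handful of analytic systems (ideal gas, two charges, a harmonic dimer, a
uniform spherical cloud) with known exact properties.
"""

from __future__ import annotations

import numpy as np

from .topology import (
    Configuration,
    NetworkTopology,
    assign_chain_charges,
    build_network,
    populate_box,
    DIAMETER_ION,
)

# Exact cross-linker counts achievable by spherical trimming about the
# tetrahedral-hole centre, with the chain count each induces.
TINY_NETWORK_CHAINS = {4: 0, 10: 12, 22: 24, 30: 36, 42: 60, 66: 100}


def make_tiny_network(
    n_crosslinkers: int = 10,
    monomers_per_chain: int = 3,
    charged_per_chain: int = 1,
    bond_length: float = 0.65,
    box_factor: float = 4.0,
) -> tuple[NetworkTopology, Configuration]:
    """Miniature trimmed-diamond network with hand-checkable counts.

    The default (10 cross-linkers, 12 chains of 3 monomers) is the
    smallest trimmed network that is connected with cross-linker
    functionality in {2, 3}.  The box is ``box_factor`` times the network
    diameter.
    """
    if n_crosslinkers not in TINY_NETWORK_CHAINS:
        raise ValueError(
            f"exactly trimmable counts are {sorted(TINY_NETWORK_CHAINS)}; "
            f"got {n_crosslinkers}"
        )
    n_chains = TINY_NETWORK_CHAINS[n_crosslinkers]
    topo, config = build_network(
        n_chains, monomers_per_chain, n_crosslinkers,
        bond_length=bond_length, box_length=1000.0,
    )
    net = config.positions
    cm = net.mean(axis=0)
    diameter = 2.0 * np.max(np.linalg.norm(net - cm, axis=1)) + bond_length
    L = float(np.ceil(box_factor * diameter))
    config.box_length = L
    config.positions = net - cm + L / 2.0
    assign_chain_charges(topo, config, charged_per_chain)
    return topo, config


def make_madelung_crystal(
    n_unit_cells_per_side: int = 2, spacing: float = 1.0
) -> Configuration:
    """Rock-salt arrangement of +-1 charges filling the periodic box.

    ``spacing`` is the nearest-neighbour distance (nm); each conventional
    cell contributes 8 ions, so the box holds ``8 n^3`` charges and is
    exactly neutral.
    """
    n = n_unit_cells_per_side
    if n < 1:
        raise ValueError("need at least one unit cell")
    side = 2 * n
    grid = np.arange(side)
    i, j, k = np.meshgrid(grid, grid, grid, indexing="ij")
    positions = np.stack([i, j, k], axis=-1).reshape(-1, 3) * spacing
    valence = np.where((i + j + k).reshape(-1) % 2 == 0, 1, -1)
    n_beads = len(valence)
    return Configuration(
        box_length=side * spacing,
        positions=positions.astype(float),
        species=["cation" if v > 0 else "anion" for v in valence],
        roles=["cation" if v > 0 else "anion" for v in valence],
        valence=valence.astype(int),
        diameter=np.full(n_beads, 0.1 * spacing),
        hydrophobic_eligible=np.zeros(n_beads, dtype=bool),
    )


def make_reference_system(kind: str, seed: int = 0, **params) -> Configuration:
    """Analytic reference configurations.

    Kinds: ``ideal_gas`` (n, box), ``two_charge_box`` (separation, box),
    ``harmonic_dimer`` (box), ``uniform_sphere_cloud`` (n, radius, box).
    """
    rng = np.random.default_rng(seed)
    if kind == "ideal_gas":
        n = params.get("n", 50)
        box = params.get("box", 20.0)
        pos = rng.uniform(0, box, size=(n, 3))
        return Configuration(
            box_length=box,
            positions=pos,
            species=["gas"] * n,
            roles=["gas"] * n,
            valence=np.zeros(n, dtype=int),
            diameter=np.zeros(n) + 1e-9,
            hydrophobic_eligible=np.zeros(n, dtype=bool),
        )
    if kind == "two_charge_box":
        sep = params.get("separation", 1.0)
        box = params.get("box", 50.0)
        pos = np.array([[0.0, 0.0, 0.0], [sep, 0.0, 0.0]]) + box / 2.0
        return Configuration(
            box_length=box,
            positions=pos,
            species=["cation", "anion"],
            roles=["cation", "anion"],
            valence=np.array([1, -1]),
            diameter=np.full(2, DIAMETER_ION),
            hydrophobic_eligible=np.zeros(2, dtype=bool),
        )
    if kind == "harmonic_dimer":
        box = params.get("box", 20.0)
        r0 = params.get("r0", 0.65)
        pos = np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]) + box / 2.0
        return Configuration(
            box_length=box,
            positions=pos,
            species=["monomer", "monomer"],
            roles=["monomer", "monomer"],
            valence=np.zeros(2, dtype=int),
            diameter=np.zeros(2) + 1e-9,  # no excluded volume: pure bond
            hydrophobic_eligible=np.zeros(2, dtype=bool),
        )
    if kind == "uniform_sphere_cloud":
        n = params.get("n", 100000)
        radius = params.get("radius", 10.0)
        box = params.get("box", 8.0 * radius)
        # rejection-free sampling: direction x radius^(1/3) scaling
        u = rng.random(n)
        direction = rng.normal(size=(n, 3))
        direction /= np.linalg.norm(direction, axis=1)[:, None]
        pos = direction * radius * u[:, None] ** (1.0 / 3.0) + box / 2.0
        return Configuration(
            box_length=box,
            positions=pos,
            species=["monomer"] * n,
            roles=["monomer"] * n,
            valence=np.zeros(n, dtype=int),
            diameter=np.zeros(n) + 1e-9,
            hydrophobic_eligible=np.zeros(n, dtype=bool),
        )
    raise ValueError(f"unknown reference-system kind: {kind!r}")


def dimer_topology() -> NetworkTopology:
    """Topology of the two-bead harmonic dimer."""
    return NetworkTopology(
        bead_roles=["monomer", "monomer"],
        bonds=np.array([[0, 1]]),
        chains=[[0, 1]],
        crosslinker_ids=np.empty(0, dtype=int),
    )


def make_mini_nanocomposite(
    charged_per_chain: int = 1,
    n_nanoparticles: int = 4,
    np_valence: int = -5,
    np_diameter: float = 2.0,
    monomers_per_chain: int = 3,
    seed: int = 0,
) -> tuple[NetworkTopology, Configuration]:
    """Miniature nanogel (10 cross-linkers) with charged nanoparticles.

    A proportionally scaled analogue of the full nanocomposite: the
    nanoparticle diameter defaults to 2 nm so the nanoparticle-to-gel size
    ratio roughly matches that of the full system, while keeping the
    nanoparticle clearly larger than the 0.7 nm ions.
    """
    topo, config = make_tiny_network(
        charged_per_chain=charged_per_chain,
        monomers_per_chain=monomers_per_chain,
    )
    config = populate_box(
        config, topo, n_nanoparticles, np_valence=np_valence,
        seed=seed, np_diameter=np_diameter,
    )
    return topo, config
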