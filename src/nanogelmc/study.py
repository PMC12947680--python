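"""High-level drivers: build a system, run it, and analyse the trajectory.

`run_system` ties the builder, sampler and observables together for one
(temperature, seed) point and returns the scalar summary the study tables
are made of.  `run_miniature` does the same for the proportionally scaled
miniature systems used for fast, qualitative reproductions of the full
study's trends (collapse on heating, charge-dependent shrinkage,
nanoparticle expulsion); problem sizes there are chosen to keep a run in
the seconds-to-a-minute range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import observables as obs
from .config import RunConfig
from .energy import EwaldSettings
from .fixtures import make_mini_nanocomposite
from .mc import MCSampler, MoveSettings, RunResult, RunSchedule
from .pbcell import (
    PBCellSpec,
    PBSpecies,
    cell_radius_for_box,
    polymer_volume_fraction,
)
from .thermo import ModelParams, ThermoState, celsius_to_kelvin
from .topology import (
    Configuration,
    NetworkTopology,
    ROLE_NANOPARTICLE,
    assign_chain_charges,
    build_network,
    populate_box,
)


@dataclass
class SystemSummary:
    """Scalar observables of one production run."""

    temperature_celsius: float
    seed: int
    r_gyr: float
    r_ng: float
    n_inside: float
    z_net: float
    psi_surface: float
    acceptance: dict[str, float]
    result: RunResult


def build_system(config: RunConfig, seed: int = 0) -> tuple[NetworkTopology, Configuration]:
    """Build and populate the configured system (network + mobile species)."""
    sy = config.system
    topo, conf = build_network(
        sy.n_chains,
        sy.monomers_per_chain,
        sy.n_crosslinkers,
        bond_length=sy.bond_length,
        box_length=sy.box_length,
    )
    assign_chain_charges(topo, conf, sy.charged_per_chain)
    conf = populate_box(
        conf,
        topo,
        sy.n_nanoparticles,
        np_valence=sy.np_valence,
        seed=seed,
        ion_diameter=sy.ion_diameter,
        np_diameter=sy.np_diameter,
    )
    return topo, conf


def analyse_run(
    result: RunResult,
    topo: NetworkTopology,
    thermo: ThermoState,
    temperature_celsius: float,
    seed: int,
) -> SystemSummary:
    config = result.config
    box = config.box_length
    net_mask = config.network_mask
    frames = result.frames or [config.positions.copy()]
    rgyrs = [obs.radius_of_gyration(f[net_mask]) for f in frames]
    r_gyr = float(np.mean(rgyrs))
    r_ng = obs.geometric_radius(r_gyr)
    np_ids = np.nonzero(config.role_mask(ROLE_NANOPARTICLE))[0]
    if len(np_ids):
        n_in = float(
            np.mean(
                [
                    obs.count_inside(
                        f[np_ids],
                        f[net_mask].mean(axis=0),
                        obs.geometric_radius(obs.radius_of_gyration(f[net_mask])),
                        box,
                    )
                    for f in frames
                ]
            )
        )
    else:
        n_in = 0.0
    z_net = obs.net_charge_at(frames, config.valence, net_mask, box)
    psi_s = obs.surface_potential(
        frames, config.valence, net_mask, box, thermo.l_B, r_ng
    )
    return SystemSummary(
        temperature_celsius=temperature_celsius,
        seed=seed,
        r_gyr=r_gyr,
        r_ng=r_ng,
        n_inside=n_in,
        z_net=z_net,
        psi_surface=psi_s,
        acceptance=result.acceptance,
        result=result,
    )


def run_system(
    topo: NetworkTopology,
    conf: Configuration,
    temperature_celsius: float,
    seed: int,
    n_equilibration: int,
    n_production: int,
    sample_interval: int = 2000,
    params: ModelParams | None = None,
    ewald_accuracy: float = 1e-4,
    moves: MoveSettings | None = None,
) -> SystemSummary:
    T = celsius_to_kelvin(temperature_celsius)
    schedule = RunSchedule(
        n_equilibration=n_equilibration,
        n_production=n_production,
        sample_interval=sample_interval,
        seed=seed,
        temperature=T,
    )
    sampler = MCSampler(
        conf.copy(),
        topo,
        schedule,
        settings=moves or MoveSettings(),
        params=params,
        ewald_settings=EwaldSettings(accuracy=ewald_accuracy),
    )
    result = sampler.run()
    return analyse_run(result, topo, sampler.thermo, temperature_celsius, seed)


def run_miniature(
    charged_per_chain: int,
    temperature_celsius: float,
    n_nanoparticles: int = 0,
    seed: int = 0,
    n_equilibration: int = 40_000,
    n_production: int = 20_000,
    np_diameter: float = 2.0,
) -> SystemSummary:
    """One production point of the scaled-down study system."""
    topo, conf = make_mini_nanocomposite(
        charged_per_chain=charged_per_chain,
        n_nanoparticles=n_nanoparticles,
        np_diameter=np_diameter,
        seed=seed,
    )
    return run_system(
        topo,
        conf,
        temperature_celsius,
        seed=seed,
        n_equilibration=n_equilibration,
        n_production=n_production,
    )


def pb_spec_from_system(
    conf: Configuration,
    topo: NetworkTopology,
    r_ng: float,
    temperature_celsius: float,
    saturation_enabled: bool = True,
) -> PBCellSpec:
    """Cell-model spec matched to a particle system and a measured radius.

    The cell volume equals the simulation-box volume, the bare charge and
    species counts are taken from the configuration, and the core polymer
    volume fraction is estimated from the network bead volume inside the
    measured geometric radius.
    """
    thermo = ThermoState.at(celsius_to_kelvin(temperature_celsius))
    net_mask = conf.network_mask
    species = []
    for role in ("anion", "cation", "nanoparticle"):
        ids = np.nonzero(conf.role_mask(role))[0]
        if len(ids):
            species.append(
                PBSpecies(
                    label=role,
                    valence=int(conf.valence[ids[0]]),
                    diameter=float(conf.diameter[ids[0]]),
                    count=float(len(ids)),
                )
            )
    phi = polymer_volume_fraction(
        int(net_mask.sum()), float(conf.diameter[net_mask][0]), r_ng
    )
    return PBCellSpec(
        R_NG=r_ng,
        Z=float(conf.valence[net_mask].sum()),
        cell_radius=cell_radius_for_box(conf.box_length),
        l_B=thermo.l_B,
        species=species,
        phi_NG=min(phi, 0.74),  # cap at close packing for deeply collapsed gels
        saturation_enabled=saturation_enabled,
    )


def external_bare_charge(summary: SystemSummary) -> float:
    """Mean network charge outside the geometric radius (frame-averaged)."""
    config = summary.result.config
    net_mask = config.network_mask
    frames = summary.result.frames or [config.positions]
    out = []
    for f in frames:
        net = f[net_mask]
        cm = net.mean(axis=0)
        r_ng = obs.geometric_radius(obs.radius_of_gyration(net))
        r = np.linalg.norm(net - cm, axis=1)
        out.append(float(config.valence[net_mask][r >= r_ng].sum()))
    return float(np.mean(out))


def strip_external_nanoparticles(
    conf: Configuration, topo: NetworkTopology
) -> tuple[Configuration, int]:
    """Remove nanoparticles outside the geometric radius (with counterions).

    Emulates open-boundary conditions: every nanoparticle whose centre is
    beyond R_NG is deleted together with its |z| nearest cations so the box
    stays exactly neutral.  Returns the reduced configuration and the
    number of nanoparticles removed.
    """
    net_mask = conf.network_mask
    net = conf.positions[net_mask]
    cm = net.mean(axis=0)
    r_ng = obs.geometric_radius(obs.radius_of_gyration(net))
    np_ids = np.nonzero(conf.role_mask(ROLE_NANOPARTICLE))[0]
    r = conf.distances_from(cm, np_ids)
    outside = np_ids[r >= r_ng]
    drop = set(int(i) for i in outside)
    cation_ids = [int(i) for i in np.nonzero(conf.role_mask("cation"))[0]]
    for np_i in outside:
        needed = abs(int(conf.valence[np_i]))
        avail = [c for c in cation_ids if c not in drop]
        d = conf.distances_from(conf.positions[np_i], np.array(avail))
        for c in np.array(avail)[np.argsort(d)[:needed]]:
            drop.add(int(c))
    keep = np.array([i for i in range(conf.n_beads) if i not in drop], dtype=int)
    out = Configuration(
        box_length=conf.box_length,
        positions=conf.positions[keep],
        species=[conf.species[i] for i in keep],
        roles=[conf.roles[i] for i in keep],
        valence=conf.valence[keep],
        diameter=conf.diameter[keep],
        hydrophobic_eligible=conf.hydrophobic_eligible[keep],
    )
    assert out.total_charge() == 0
    return out, len(outside)
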