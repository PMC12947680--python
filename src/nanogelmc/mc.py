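"""Metropolis Monte Carlo sampler.

Move repertoire:

* single-bead displacements for every species, drawn uniformly from a cube
  of per-species half-width ``max_disp``;
* rigid translations of a nanoparticle together with the cations found in
  a spherical shell of thickness twice the cation diameter around it
  (cluster moves), with the symmetric-proposal safeguard that a move is
  rejected outright if the cluster recomputed at the destination differs
  from the one selected at the origin;
* isotropic scaling of the whole network plus the particles inside its
  geometric radius about the network centre of mass (thermalization only),
  accepted with the proposal Jacobian 3 N ln s included in the exponent.

Maximum displacements are adapted multiplicatively toward 50% acceptance
during equilibration and frozen during production.  Identical seed and
inputs give a bit-identical trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import EnergyModel, EwaldSettings, EnergyBreakdown
from .thermo import ThermoState, ModelParams
from .topology import Configuration, NetworkTopology, ROLE_CATION, ROLE_NANOPARTICLE
from . import observables as obs

MAX_DISP_FLOOR = 1e-3  # nm


@dataclass
class MoveSettings:
    max_disp: dict[str, float] = field(default_factory=dict)  # per role, nm
    cluster_shell_thickness: float | None = None  # nm; default 2 x d_cation
    adapt_interval: int = 1000
    adapt_factor: float = 1.05
    cluster_move_period: int | None = None  # single attempts between cluster sweeps
    scale_moves_enabled: bool = True        # acts during equilibration only
    scale_dmax: float = 0.03                # bound on |ln s| per scale attempt
    resync_interval: int = 50000            # moves between Ewald resyncs


@dataclass
class RunSchedule:
    n_equilibration: int
    n_production: int
    sample_interval: int = 1000
    seed: int = 0
    temperature: float = 293.15  # K

    def __post_init__(self) -> None:
        if min(self.n_equilibration, self.n_production, self.sample_interval) < 0:
            raise ValueError("schedule counts must be non-negative")


@dataclass
class RunResult:
    config: Configuration
    frames: list[np.ndarray]
    series: pd.DataFrame
    acceptance: dict[str, float]
    max_disp: dict[str, float]
    energy: EnergyBreakdown


def metropolis_accept(delta_u: float, rng_draw: float) -> bool:
    """Metropolis rule: accept iff draw < min(1, exp(-delta_u))."""
    if delta_u <= 0.0:
        return True
    return rng_draw < math.exp(-delta_u)


def select_cluster(config: Configuration, np_index: int) -> np.ndarray:
    """Nanoparticle plus the cations in its surrounding spherical layer.

    The layer spans centre distances [(d_NP + d_cat)/2,
    (d_NP + d_cat)/2 + 2 d_cat]: contact to contact-plus-twice-the-cation-
    diameter.  Returns bead indices, nanoparticle first.
    """
    if config.roles[np_index] != ROLE_NANOPARTICLE:
        raise ValueError(f"bead {np_index} is not a nanoparticle")
    cation_ids = np.nonzero(config.role_mask(ROLE_CATION))[0]
    if len(cation_ids) == 0:
        return np.array([np_index], dtype=int)
    d_np = config.diameter[np_index]
    d_cat = config.diameter[cation_ids[0]]
    inner = 0.5 * (d_np + d_cat)
    outer = inner + 2.0 * d_cat
    r = config.distances_from(config.positions[np_index], cation_ids)
    members = cation_ids[(r >= inner) & (r <= outer)]
    return np.concatenate(([np_index], members))


class MCSampler:
    """Canonical-ensemble Metropolis sampler for a built configuration."""

    def __init__(
        self,
        config: Configuration,
        topology: NetworkTopology,
        schedule: RunSchedule,
        settings: MoveSettings | None = None,
        params: ModelParams | None = None,
        ewald_settings: EwaldSettings | None = None,
    ):
        if config.total_charge() != 0:
            raise ValueError("configuration must be electroneutral")
        self.config = config
        self.topology = topology
        self.schedule = schedule
        self.settings = settings or MoveSettings()
        self.params = params or ModelParams()
        self.thermo = ThermoState.at(schedule.temperature, self.params)
        self.energy = EnergyModel(
            config, topology, self.thermo, self.params, ewald_settings
        )
        self.rng = np.random.default_rng(schedule.seed)

        roles = np.array(config.roles)
        self.roles = roles
        self.np_ids = np.nonzero(roles == ROLE_NANOPARTICLE)[0]
        self.network_ids = np.nonzero(config.network_mask)[0]
        self.mobile = np.arange(config.n_beads)

        disp = dict(self.settings.max_disp)
        for role in np.unique(roles):
            disp.setdefault(role, max(float(np.mean(config.diameter[roles == role])), 0.1))
        disp.setdefault("cluster", 1.0)
        disp.setdefault("scale", self.settings.scale_dmax)
        self.max_disp = disp
        self._attempts = {k: 0 for k in disp}
        self._accepts = {k: 0 for k in disp}
        self._attempts_tot = {k: 0 for k in disp}
        self._accepts_tot = {k: 0 for k in disp}

        if self.settings.cluster_shell_thickness is None:
            cat = np.nonzero(roles == ROLE_CATION)[0]
            self.settings.cluster_shell_thickness = (
                2.0 * float(config.diameter[cat[0]]) if len(cat) else 1.4
            )
        self.running = self.energy.total()
        self._since_resync = 0

    # -- individual move types --------------------------------------------
    def _single_move(self, i: int) -> None:
        role = self.roles[i]
        dmax = self.max_disp[role]
        step = self.rng.uniform(-dmax, dmax, size=3)
        new_pos = self.config.positions[i] + step
        d_eb, dS = self.energy.delta(i, new_pos)
        self._attempts[role] += 1
        if metropolis_accept(d_eb.total, self.rng.random()):
            self.energy.apply(i, new_pos, dS)
            self.running = self.running + d_eb
            self._accepts[role] += 1

    def _cluster_move(self, np_index: int) -> None:
        members = select_cluster(self.config, np_index)
        dmax = self.max_disp["cluster"]
        step = self.rng.uniform(-dmax, dmax, size=3)
        draw = self.rng.random()  # drawn unconditionally: keeps the stream aligned
        new_pos = self.config.positions[members] + step
        self._attempts["cluster"] += 1
        # detailed balance: the reverse move must select the same cluster
        trial = self.config.copy()
        trial.positions[members] = new_pos
        if not np.array_equal(np.sort(select_cluster(trial, np_index)), np.sort(members)):
            return
        d_eb, dS = self.energy.delta(members, new_pos, rigid=True)
        if metropolis_accept(d_eb.total, draw):
            self.energy.apply(members, new_pos, dS)
            self.running = self.running + d_eb
            self._accepts["cluster"] += 1

    def _scale_move(self) -> None:
        """Isotropic breathing of the network and its interior particles."""
        delta = self.rng.uniform(-self.max_disp["scale"], self.max_disp["scale"])
        s = math.exp(delta)
        pos = self.config.positions
        cm = pos[self.network_ids].mean(axis=0)
        rgyr = obs.radius_of_gyration(pos[self.network_ids])
        r_ng = obs.geometric_radius(rgyr)
        inside = self.config.distances_from(cm) < r_ng
        inside[self.network_ids] = True
        moved = np.nonzero(inside)[0]
        new_pos = cm + s * (pos[moved] - cm)
        self._attempts["scale"] += 1
        old_total = self.running
        old_positions = pos[moved].copy()
        pos[moved] = new_pos
        self.energy.resync_ewald()
        new_total = self.energy.total()
        d_u = new_total.total - old_total.total
        jacobian = 3.0 * len(moved) * delta
        if metropolis_accept(d_u - jacobian, self.rng.random()):
            self.running = new_total
            self._accepts["scale"] += 1
        else:
            pos[moved] = old_positions
            self.energy.resync_ewald()

    # -- adaptation --------------------------------------------------------
    def _adapt(self) -> None:
        f = self.settings.adapt_factor
        hi = self.config.box_length / 4.0
        for key in self.max_disp:
            att = self._attempts[key]
            if att == 0:
                continue
            rate = self._accepts[key] / att
            if rate > 0.5:
                self.max_disp[key] *= f
            elif rate < 0.5:
                self.max_disp[key] /= f
            if key != "scale":
                self.max_disp[key] = min(max(self.max_disp[key], MAX_DISP_FLOOR), hi)
            else:
                self.max_disp[key] = min(max(self.max_disp[key], 1e-4), 0.3)
            self._attempts_tot[key] += self._attempts[key]
            self._accepts_tot[key] += self._accepts[key]
            self._attempts[key] = 0
            self._accepts[key] = 0

    # -- main loop ---------------------------------------------------------
    def run(self, record_frames: bool = True) -> RunResult:
        sched = self.schedule
        n_beads = self.config.n_beads
        cluster_period = self.settings.cluster_move_period or n_beads
        frames: list[np.ndarray] = []
        rows: list[dict] = []
        net = self.network_ids

        def sample_row(step: int, phase: str) -> dict:
            pos_net = self.config.positions[net]
            rgyr = obs.radius_of_gyration(pos_net)
            r_ng = obs.geometric_radius(rgyr)
            row = {
                "step": step,
                "phase": phase,
                "T": sched.temperature,
                "R_gyr": rgyr,
                "R_NG": r_ng,
                "wca": self.running.wca,
                "bond": self.running.bond,
                "hydrophobic": self.running.hydrophobic,
                "electrostatic": self.running.electrostatic,
                "total": self.running.total,
            }
            if len(self.np_ids):
                cm = pos_net.mean(axis=0)
                r = self.config.distances_from(cm, self.np_ids)
                row["N_inside"] = int(np.sum(r < r_ng))
            return row

        total_steps = sched.n_equilibration + sched.n_production
        for step in range(total_steps):
            equilibrating = step < sched.n_equilibration
            i = int(self.mobile[self.rng.integers(len(self.mobile))])
            self._single_move(i)
            if (step + 1) % cluster_period == 0:
                for np_i in self.np_ids:
                    self._cluster_move(int(np_i))
                if equilibrating and self.settings.scale_moves_enabled and len(net):
                    self._scale_move()
            if equilibrating and (step + 1) % self.settings.adapt_interval == 0:
                self._adapt()
            self._since_resync += 1
            if self._since_resync >= self.settings.resync_interval:
                self.energy.resync_ewald()
                self.running = self.energy.total()
                self._since_resync = 0
            if sched.sample_interval and (step + 1) % sched.sample_interval == 0:
                phase = "equil" if equilibrating else "prod"
                rows.append(sample_row(step + 1, phase))
                if record_frames and not equilibrating:
                    frames.append(self.config.positions.copy())

        for key in self.max_disp:
            self._attempts_tot[key] += self._attempts[key]
            self._accepts_tot[key] += self._accepts[key]
        acceptance = {
            k: (self._accepts_tot[k] / self._attempts_tot[k])
            for k in self._attempts_tot
            if self._attempts_tot[k] > 0
        }
        series = pd.DataFrame(rows)
        return RunResult(
            config=self.config,
            frames=frames,
            series=series,
            acceptance=acceptance,
            max_disp=dict(self.max_disp),
            energy=self.running,
        )
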