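"""Metropolis rule, cluster selection, adaptation and sampler behaviour."""

import math

import numpy as np
import pytest

from nanogelmc.fixtures import (
    dimer_topology,
    make_mini_nanocomposite,
    make_reference_system,
)
from nanogelmc.mc import (
    MCSampler,
    MoveSettings,
    RunSchedule,
    metropolis_accept,
    select_cluster,
)
from nanogelmc.thermo import ThermoState
from nanogelmc.topology import NetworkTopology


class TestMetropolisRule:
    def test_downhill_and_flat_always_accepted(self):
        assert metropolis_accept(-1.0, 0.999999)
        assert metropolis_accept(0.0, 0.999999)

    def test_uphill_acceptance_frequency_matches_boltzmann(self):
        rng = np.random.default_rng(0)
        draws = rng.random(100_000)
        rate = np.mean([metropolis_accept(1.0, d) for d in draws])
        assert rate == pytest.approx(math.exp(-1.0), abs=0.005)

    def test_three_state_chain_samples_boltzmann(self):
        # discrete toy system: states 0,1,2 with u = 0,1,2 kT; symmetric
        # nearest-neighbour proposals with reflecting ends handled by
        # proposing and rejecting out-of-range states.
        u = np.array([0.0, 1.0, 2.0])
        rng = np.random.default_rng(1)
        state, counts = 0, np.zeros(3)
        for _ in range(200_000):
            prop = state + (1 if rng.random() < 0.5 else -1)
            if 0 <= prop <= 2 and metropolis_accept(u[prop] - u[state], rng.random()):
                state = prop
            counts[state] += 1
        p = counts / counts.sum()
        boltz = np.exp(-u) / np.exp(-u).sum()
        np.testing.assert_allclose(p, boltz, atol=0.01)


class TestClusterSelection:
    @pytest.fixture()
    def composite(self):
        return make_mini_nanocomposite(charged_per_chain=1, n_nanoparticles=2, seed=9)

    def test_layer_geometry(self, composite):
        topo, conf = composite
        np_idx = int(np.nonzero(conf.role_mask("nanoparticle"))[0][0])
        cat = int(np.nonzero(conf.role_mask("cation"))[0][0])
        d_np, d_cat = conf.diameter[np_idx], conf.diameter[cat]
        inner = 0.5 * (d_np + d_cat)
        # included: inside the layer [inner, inner + 2 d_cat]
        conf.positions[cat] = conf.positions[np_idx] + [inner + d_cat, 0, 0]
        assert cat in select_cluster(conf, np_idx)
        # excluded: beyond the layer
        conf.positions[cat] = conf.positions[np_idx] + [inner + 2 * d_cat + 0.1, 0, 0]
        assert cat not in select_cluster(conf, np_idx)

    def test_full_size_layer_bounds(self, composite):
        # 5 nm nanoparticle, 0.7 nm cation: layer spans [2.85, 4.25] nm
        topo, conf = composite
        np_idx = int(np.nonzero(conf.role_mask("nanoparticle"))[0][0])
        cat = int(np.nonzero(conf.role_mask("cation"))[0][0])
        conf.diameter[np_idx], conf.diameter[cat] = 5.0, 0.7
        conf.positions[cat] = conf.positions[np_idx] + [3.0, 0, 0]
        assert cat in select_cluster(conf, np_idx)
        conf.positions[cat] = conf.positions[np_idx] + [5.0, 0, 0]
        assert cat not in select_cluster(conf, np_idx)

    def test_isolated_nanoparticle_gives_singleton(self, composite):
        topo, conf = composite
        np_idx = int(np.nonzero(conf.role_mask("nanoparticle"))[0][0])
        cations = np.nonzero(conf.role_mask("cation"))[0]
        conf.positions[cations] = conf.positions[np_idx] + 20.0
        assert list(select_cluster(conf, np_idx)) == [np_idx]

    def test_rejects_non_nanoparticle(self, composite):
        topo, conf = composite
        with pytest.raises(ValueError):
            select_cluster(conf, 0)


def _ideal_gas_sampler(n_steps, seed=0):
    conf = make_reference_system("ideal_gas", n=30, box=20.0, seed=2)
    topo = NetworkTopology(
        bead_roles=list(conf.roles), bonds=np.empty((0, 2), int), chains=[],
        crosslinker_ids=np.empty(0, dtype=int),
    )
    sched = RunSchedule(n_equilibration=0, n_production=n_steps, sample_interval=0, seed=seed)
    return MCSampler(conf, topo, sched, settings=MoveSettings(scale_moves_enabled=False))


class TestSampler:
    def test_ideal_gas_accepts_everything(self):
        res = _ideal_gas_sampler(2000).run()
        assert res.acceptance["gas"] == 1.0

    def test_zero_step_schedule_is_identity(self):
        topo, conf = make_mini_nanocomposite(charged_per_chain=1, n_nanoparticles=0, seed=2)
        before = conf.positions.copy()
        sched = RunSchedule(0, 0, sample_interval=0, seed=0)
        res = MCSampler(conf.copy(), topo, sched).run()
        np.testing.assert_array_equal(res.config.positions, before)

    def test_same_seed_bitwise_identical_trajectories(self):
        results = []
        for _ in range(2):
            topo, conf = make_mini_nanocomposite(charged_per_chain=1, n_nanoparticles=2, seed=4)
            sched = RunSchedule(2000, 3000, sample_interval=500, seed=11, temperature=310.0)
            results.append(MCSampler(conf, topo, sched).run())
        for f1, f2 in zip(results[0].frames, results[1].frames):
            np.testing.assert_array_equal(f1, f2)

    def test_species_counts_conserved(self):
        topo, conf = make_mini_nanocomposite(charged_per_chain=1, n_nanoparticles=2, seed=4)
        labels_before = sorted(conf.species)
        sched = RunSchedule(1000, 1000, sample_interval=0, seed=3)
        res = MCSampler(conf, topo, sched).run()
        assert sorted(res.config.species) == labels_before
        assert res.config.total_charge() == 0

    def test_running_energy_matches_full_recompute(self):
        topo, conf = make_mini_nanocomposite(charged_per_chain=1, n_nanoparticles=2, seed=8)
        sched = RunSchedule(5000, 5000, sample_interval=0, seed=5, temperature=310.0)
        sampler = MCSampler(conf, topo, sched, settings=MoveSettings(resync_interval=10**9))
        res = sampler.run()
        sampler.energy.resync_ewald()
        fresh = sampler.energy.total()
        assert res.energy.total == pytest.approx(fresh.total, rel=1e-8, abs=1e-8)

    def test_harmonic_dimer_bond_distribution_matches_quadrature(self):
        conf = make_reference_system("harmonic_dimer", box=20.0)
        sched = RunSchedule(5_000, 150_000, sample_interval=15, seed=21, temperature=298.15)
        sampler = MCSampler(
            conf, dimer_topology(), sched, settings=MoveSettings(scale_moves_enabled=False)
        )
        res = sampler.run()
        rs = np.array(
            [np.linalg.norm(f[0] - f[1]) for f in res.frames]
        )
        k = sampler.thermo.k_bond_kt
        r0 = sampler.params.r0
        grid = np.linspace(1e-4, 2.0, 4000)
        w = grid**2 * np.exp(-0.5 * k * (grid - r0) ** 2)
        mean_exact = np.trapezoid(grid * w, grid) / np.trapezoid(w, grid)
        sem = rs.std() / np.sqrt(len(rs) / 20.0)  # generous correlation allowance
        assert abs(rs.mean() - mean_exact) < 3.0 * max(sem, 1e-4)


class TestAdaptation:
    def _sampler(self):
        return _ideal_gas_sampler(0)

    def test_sustained_acceptance_grows_step_to_clamp(self):
        s = self._sampler()
        for _ in range(400):
            s._attempts["gas"] = 100
            s._accepts["gas"] = 100
            s._adapt()
        assert s.max_disp["gas"] == pytest.approx(s.config.box_length / 4.0)

    def test_sustained_rejection_shrinks_step_to_floor(self):
        s = self._sampler()
        for _ in range(600):
            s._attempts["gas"] = 100
            s._accepts["gas"] = 0
            s._adapt()
        assert s.max_disp["gas"] == pytest.approx(1e-3)

    def test_half_acceptance_is_stationary(self):
        s = self._sampler()
        before = s.max_disp["gas"]
        s._attempts["gas"] = 100
        s._accepts["gas"] = 50
        s._adapt()
        assert s.max_disp["gas"] == before

    def test_acceptance_rates_approach_target_in_real_run(self):
        topo, conf = make_mini_nanocomposite(charged_per_chain=1, n_nanoparticles=0, seed=5)
        sched = RunSchedule(20_000, 5_000, sample_interval=0, seed=6, temperature=310.0)
        res = MCSampler(
            conf, topo, sched, settings=MoveSettings(adapt_interval=500)
        ).run()
        # dense network species are tunable to ~50%
        assert 0.25 < res.acceptance["monomer"] < 0.75
        # dilute ions accept almost everything, so their step keeps growing
        # toward the clamp instead of ever reaching the target rate
        assert res.acceptance["anion"] > 0.75
        assert res.max_disp["anion"] > 2.0
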