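"""Pair potentials, Ewald summation, and incremental energy bookkeeping."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanogelmc.energy import (
    EnergyModel,
    EwaldSettings,
    EwaldSummation,
    pair_bond,
    pair_coulomb,
    pair_hydrophobic,
    pair_wca,
)
from nanogelmc.fixtures import (
    make_madelung_crystal,
    make_mini_nanocomposite,
    make_reference_system,
)
from nanogelmc.thermo import ModelParams, ThermoState, bjerrum_length

MADELUNG_NACL = 1.747565  # rock-salt lattice constant (nearest-neighbour units)


class TestPairPotentials:
    def test_wca_zero_at_cutoff_and_quarter_at_contact(self):
        d = 0.65
        assert pair_wca(2 ** (1 / 6) * d, d, d, eps=1.0) == pytest.approx(0.0, abs=1e-15)
        assert pair_wca(d, d, d, eps=1.0) == pytest.approx(0.25)

    def test_wca_at_ninety_percent_contact(self):
        val = (1 / 0.9) ** 12 - (1 / 0.9) ** 6 + 0.25
        assert pair_wca(0.9 * 0.65, 0.65, 0.65, eps=1.0) == pytest.approx(val)
        assert val == pytest.approx(1.909, abs=2e-3)

    def test_wca_uses_mean_diameter_and_rejects_overlap(self):
        # d = (5.0 + 0.7)/2 = 2.85
        assert pair_wca(2.85, 5.0, 0.7, eps=2.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            pair_wca(0.0, 1.0, 1.0)

    @given(st.floats(min_value=0.3, max_value=3.0))
    @settings(max_examples=50, deadline=None)
    def test_wca_continuous_and_repulsive(self, d):
        rc = 2 ** (1 / 6) * d
        assert pair_wca(rc * (1 - 1e-9), d, d) < 1e-6
        rs = np.linspace(0.55 * d, rc, 200)
        u = pair_wca(rs, d, d)
        assert np.all(np.diff(u) <= 1e-12)  # monotone repulsive
        assert np.all(u >= -1e-15)

    def test_bond_reference_values(self):
        # 0.5 * 0.40 N/m * (0.1 nm)^2 = 2.0e-21 J, evaluated in joules
        assert pair_bond(0.75, k_bond=0.40e-18, r0=0.65) == pytest.approx(2.0e-21)
        assert pair_bond(0.65, 0.40e-18, 0.65) == 0.0
        assert pair_bond(0.65 + 0.07, 1.0, 0.65) == pytest.approx(
            pair_bond(0.65 - 0.07, 1.0, 0.65)
        )

    def test_hydrophobic_well_shape(self):
        p = ModelParams()
        assert pair_hydrophobic(p.r_h, 1.0, p.k_h, p.r_h) == pytest.approx(-0.5)
        assert pair_hydrophobic(1e-9, 1.0, p.k_h, p.r_h) == pytest.approx(-1.0, rel=1e-6)
        # tail is numerically dead beyond r_h + 1.5 nm
        assert abs(pair_hydrophobic(p.r_h + 1.5, 1.0, p.k_h, p.r_h)) < 1e-6

    def test_coulomb_values_and_scaling(self):
        lB = bjerrum_length(298.15)
        assert pair_coulomb(1.0, 1, 1, lB) == pytest.approx(0.715, abs=1e-3)
        assert pair_coulomb(1.0, 1, -1, lB) == -pair_coulomb(1.0, 1, 1, lB)
        assert pair_coulomb(2.0, 1, 1, lB) == pytest.approx(pair_coulomb(1.0, 1, 1, lB) / 2)
        with pytest.raises(ValueError):
            pair_coulomb(0.0, 1, 1, lB)


class TestEwald:
    def test_madelung_constant(self):
        conf = make_madelung_crystal(2, spacing=1.0)
        ew = EwaldSummation(
            conf.box_length, conf.valence, l_B=1.0, settings=EwaldSettings(accuracy=1e-6)
        )
        per_pair = ew.total(conf.positions) / (conf.n_beads / 2)
        assert per_pair == pytest.approx(-MADELUNG_NACL, rel=1e-4)

    def test_two_charges_in_large_box_match_direct_coulomb(self):
        conf = make_reference_system("two_charge_box", separation=1.0, box=60.0)
        lB = bjerrum_length(298.15)
        ew = EwaldSummation(
            conf.box_length, conf.valence, lB, EwaldSettings(accuracy=1e-5)
        )
        assert ew.total(conf.positions) == pytest.approx(-lB, rel=1e-2)

    def test_random_neutral_config_matches_direct_image_sum(self, rng):
        # spherically truncated direct sum converges to vacuum boundary
        # conditions; tinfoil Ewald differs by the dipole term 2 pi M^2/(3V)
        n, box, lB = 20, 6.0, 1.0
        pos = rng.uniform(0, box, (n, 3))
        z = np.array([1.0, -1.0] * (n // 2))
        ew = EwaldSummation(box, z, lB, EwaldSettings(accuracy=1e-7))
        u_tinfoil = ew.total(pos)
        M = (z[:, None] * pos).sum(axis=0)
        dipole = 2 * np.pi * lB * (M @ M) / (3 * box**3)
        nmax = 8
        shifts = np.array(
            [
                s
                for s in product(range(-nmax, nmax + 1), repeat=3)
                if s[0] ** 2 + s[1] ** 2 + s[2] ** 2 <= nmax**2
            ],
            dtype=float,
        ) * box
        u_direct = 0.0
        for i in range(n):
            d = pos[None, :, :] + shifts[:, None, :] - pos[i]
            r = np.linalg.norm(d, axis=2)
            mask = r > 1e-12
            u_direct += 0.5 * lB * z[i] * np.sum((z[None, :] / np.where(mask, r, np.inf)) * mask)
        assert u_tinfoil + dipole == pytest.approx(u_direct, rel=1e-3)

    def test_parameter_convergence_self_consistency(self, rng):
        n, box = 16, 8.0
        pos = rng.uniform(0, box, (n, 3))
        z = np.array([1.0, -1.0] * (n // 2))
        coarse = EwaldSummation(box, z, 1.0, EwaldSettings(accuracy=1e-4))
        fine = EwaldSummation(
            box, z, 1.0,
            EwaldSettings(accuracy=1e-8, k_max=2 * coarse.settings.k_max),
        )
        u1, u2 = coarse.total(pos), fine.total(pos)
        assert abs(u1 - u2) / abs(u2) < 1e-4

    def test_requires_electroneutrality(self):
        with pytest.raises(ValueError, match="electroneutral"):
            EwaldSummation(10.0, np.array([1, 1]), 1.0)

    def test_rcut_cannot_exceed_half_box(self):
        with pytest.raises(ValueError, match="half the box"):
            EwaldSettings(r_cut=6.0).resolved(10.0)


@pytest.fixture(scope="module")
def mini_energy_model():
    topo, conf = make_mini_nanocomposite(charged_per_chain=1, n_nanoparticles=4, seed=3)
    return EnergyModel(conf, topo, ThermoState.at(293.15))


class TestEnergyModel:
    def test_breakdown_totals_add_up(self, mini_energy_model):
        eb = mini_energy_model.total()
        assert eb.total == pytest.approx(
            eb.wca + eb.bond + eb.hydrophobic + eb.electrostatic
        )

    def test_null_move_has_zero_delta(self, mini_energy_model):
        em = mini_energy_model
        d, _ = em.delta(5, em.pos[5].copy())
        assert d.total == pytest.approx(0.0, abs=1e-12)

    def test_incremental_single_move_matches_full_recompute(self):
        topo, conf = make_mini_nanocomposite(charged_per_chain=1, n_nanoparticles=2, seed=5)
        em = EnergyModel(conf, topo, ThermoState.at(310.0))
        rng = np.random.default_rng(2)
        before = em.total()
        for _ in range(12):
            i = int(rng.integers(conf.n_beads))
            new = em.pos[i] + rng.uniform(-0.4, 0.4, 3)
            d, dS = em.delta(i, new)
            em.apply(i, new, dS)
            em.resync_ewald()
            after = em.total()
            assert d.total == pytest.approx(
                after.total - before.total, rel=1e-10, abs=1e-10
            )
            before = after

    def test_incremental_cluster_move_matches_full_recompute(self):
        topo, conf = make_mini_nanocomposite(charged_per_chain=1, n_nanoparticles=4, seed=4)
        em = EnergyModel(conf, topo, ThermoState.at(293.15))
        from nanogelmc.mc import select_cluster

        np_idx = int(np.nonzero(conf.role_mask("nanoparticle"))[0][0])
        cations = np.nonzero(conf.role_mask("cation"))[0][:3]
        # park three cations in the shell so the cluster is non-trivial
        for k, c in enumerate(cations):
            offset = np.zeros(3)
            offset[k] = 0.5 * (conf.diameter[np_idx] + conf.diameter[c]) + 0.5
            em.pos[c] = em.pos[np_idx] + offset
        em.resync_ewald()
        members = select_cluster(conf, np_idx)
        assert len(members) >= 4
        before = em.total()
        step = np.array([0.8, -0.4, 0.3])
        d, dS = em.delta(members, em.pos[members] + step, rigid=True)
        em.apply(members, em.pos[members] + step, dS)
        em.resync_ewald()
        after = em.total()
        assert d.total == pytest.approx(after.total - before.total, rel=1e-10, abs=1e-10)

    def test_global_translation_invariance(self):
        topo, conf = make_mini_nanocomposite(charged_per_chain=1, n_nanoparticles=2, seed=6)
        em = EnergyModel(conf, topo, ThermoState.at(293.15))
        u0 = em.total().total
        conf.positions += np.array([3.21, -7.65, 11.1])
        em.resync_ewald()
        u1 = em.total().total
        assert u1 == pytest.approx(u0, rel=1e-9)

    def test_hydrophobic_inoperative_for_charged_beads(self):
        topo, conf = make_mini_nanocomposite(charged_per_chain=3, n_nanoparticles=0, seed=1)
        em = EnergyModel(conf, topo, ThermoState.at(337.15))
        # with every monomer charged, only crosslinker pairs may attract
        assert not em.eligible[conf.valence != 0].any()
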