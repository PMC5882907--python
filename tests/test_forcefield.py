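import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import clutchpmf as cp
from clutchpmf.forcefield import (BondOverstretchError, DivergentPairError,
                                  system_energy_bruteforce, system_energy_forces)
from clutchpmf.params import CORE, DNA
from clutchpmf.topology import CollapseRestraint


class TestPairEnergy:
    def test_value_at_contact_shift(self, ff):
        # r - r0 = sigma gives 4eps(1-1)+eps = eps for every species pair
        for pair, r in [((DNA, DNA), 2.0), ((CORE, DNA), 4.5), ((CORE, CORE), 7.0)]:
            p = cp.pair_interaction(ff, *pair)
            assert cp.pair_energy(r, p) == pytest.approx(1.0)

    def test_zero_at_cutoff_and_beyond(self, ff):
        p = cp.pair_interaction(ff, DNA, DNA)
        assert cp.pair_energy(ff.rc, p) == 0.0
        assert cp.pair_energy(10.0, p) == 0.0
        assert cp.pair_force(ff.rc * 1.0001, p) == 0.0

    def test_divergence_flagged(self, ff):
        p = cp.pair_interaction(ff, CORE, CORE)
        with pytest.raises(DivergentPairError):
            cp.pair_energy(5.0, p)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.02, max_value=6.0))
    def test_nonnegative_and_continuous(self, rr):
        ff = cp.ForceFieldParams()
        p = cp.pair_interaction(ff, DNA, DNA)
        u = cp.pair_energy(rr, p)
        assert u >= 0.0
        # continuity at the cutoff: energy below ~eps near rc
        if abs(rr - ff.rc) < 1e-3:
            assert u < 1e-2


class TestBondedTerms:
    def test_fene_examples(self, ff):
        assert cp.fene_energy(0.0, ff) == 0.0
        # -1/2 * 30 * 1.5^2 * ln(1 - 0.25) in reduced units
        assert cp.fene_energy(0.75 * ff.sigma, ff) == pytest.approx(9.709, abs=1e-3)
        with pytest.raises(BondOverstretchError):
            cp.fene_energy(1.5 * ff.sigma, ff)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=2.9), st.floats(min_value=1e-4, max_value=0.09))
    def test_fene_strictly_increasing(self, r, dr):
        ff = cp.ForceFieldParams()
        if r + dr < ff.r_b:
            assert cp.fene_energy(r + dr, ff) > cp.fene_energy(r, ff) or r == 0.0

    def test_angle_examples(self, ff):
        assert cp.angle_energy(0.0, ff) == 0.0
        assert cp.angle_energy(0.2, ff) == pytest.approx(0.5)
        assert cp.angle_energy(np.pi / 2, ff) == pytest.approx(30.84, abs=0.01)


def _random_test_system(seed):
    """Small random-ish system exercising every force-field term."""
    rng = np.random.default_rng(seed)
    topo = cp.make_fixture("mini_clutch_n2", seed=seed)
    topo.collapse.append(CollapseRestraint(topo.core_indices(0), 4.0, 1.25))
    coords = topo.coords + rng.normal(scale=0.05, size=topo.coords.shape)
    return topo, coords


class TestSystemEnergyForces:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_forces_match_numerical_gradient(self, seed):
        topo, coords = _random_test_system(seed)
        _, forces = system_energy_forces(topo, coords)
        rng = np.random.default_rng(seed + 100)
        h = 1e-6
        for _ in range(12):
            i = rng.integers(topo.n_beads)
            d = rng.integers(3)
            cp_ = coords.copy()
            cp_[i, d] += h
            ep, _ = system_energy_forces(topo, cp_)
            cp_[i, d] -= 2 * h
            em, _ = system_energy_forces(topo, cp_)
            num = -(ep.total - em.total) / (2 * h)
            assert num == pytest.approx(forces[i, d], rel=1e-5, abs=1e-5)

    def test_pair_forces_sum_to_zero(self):
        topo, coords = _random_test_system(3)
        _, forces = system_energy_forces(topo, coords)
        assert np.abs(forces.sum(axis=0)).max() < 1e-9

    def test_celllist_matches_bruteforce(self):
        # dense periodic system exercising the cell path
        topo = cp.Topology.empty()
        topo.box = 40.0
        topo = cp.place_crowders(topo, cp.CrowdingCondition(0.25), seed=5)
        # shrink slightly so pair energies are non-trivial
        topo.coords *= 0.97
        report, _ = system_energy_forces(topo)
        brute = system_energy_bruteforce(topo)
        assert report.pair == pytest.approx(brute, rel=1e-10)

    def test_energy_invariant_under_rigid_motion(self):
        topo, coords = _random_test_system(4)
        e0, _ = system_energy_forces(topo, coords)
        rng = np.random.default_rng(8)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        q0, q1, q2, q3 = q
        rot = np.array([
            [1 - 2 * (q2**2 + q3**2), 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), 1 - 2 * (q1**2 + q3**2), 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), 1 - 2 * (q1**2 + q2**2)]])
        moved = coords @ rot.T + np.array([3.0, -7.0, 11.0])
        e1, _ = system_energy_forces(topo, moved)
        assert e1.total == pytest.approx(e0.total, rel=1e-9)

    def test_report_total_is_sum(self):
        topo, coords = _random_test_system(5)
        report, _ = system_energy_forces(topo, coords)
        assert report.total == pytest.approx(
            report.pair + report.fene + report.angle + report.restraint)

    def test_divergent_configuration_reported_infinite(self, ff):
        topo = cp.make_fixture("single_core_pair")
        coords = topo.coords.copy()
        coords[1] = coords[0] + np.array([4.9, 0, 0])  # inside core-core r0
        report, forces = system_energy_forces(topo, coords)
        assert np.isinf(report.pair)
        assert np.all(np.isnan(forces))


class TestInterGroupEnergy:
    def test_far_apart_is_zero(self, ff):
        a = cp.make_fixture("mini_clutch_n2")
        e = cp.inter_group_energy(a.coords, a.species, a.coords, a.species, 100.0)
        assert e == 0.0

    def test_single_pair_reduction(self, ff):
        core = np.zeros((1, 3))
        sp = np.array([CORE], np.int8)
        p = cp.pair_interaction(ff, CORE, CORE)
        e = cp.inter_group_energy(core, sp, core, sp, 7.2)
        assert e == pytest.approx(cp.pair_energy(7.2, p))

    def test_matches_naive_double_loop(self, ff):
        rng = np.random.default_rng(11)
        na, nb = 40, 35
        ca = rng.random((na, 3)) * 10
        cb = rng.random((nb, 3)) * 10
        spa = rng.integers(0, 2, na).astype(np.int8)
        spb = rng.integers(0, 2, nb).astype(np.int8)
        shift = 9.0
        r0m = ff.r0_matrix()
        expect = 0.0
        for i in range(na):
            for j in range(nb):
                d = ca[i] - cb[j] - np.array([shift, 0, 0])
                r = np.linalg.norm(d)
                rr = r - r0m[spa[i], spb[j]]
                if rr <= 0:
                    expect = np.inf
                    break
                if rr < ff.rc:
                    s6 = (ff.sigma / rr) ** 6
                    expect += 4 * (s6 * s6 - s6) + 1
            if np.isinf(expect):
                break
        got = cp.inter_group_energy(ca, spa, cb, spb, shift)
        if np.isinf(expect):
            assert np.isinf(got)
        else:
            assert got == pytest.approx(expect, rel=1e-12)

    def test_overlap_gives_infinity(self, ff):
        core = np.zeros((1, 3))
        sp = np.array([CORE], np.int8)
        assert np.isinf(cp.inter_group_energy(core, sp, core, sp, 3.0))
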