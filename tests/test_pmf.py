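import numpy as np
import pytest

import clutchpmf as cp
from clutchpmf.dynamics import ConformerLibrary, ConstraintRecord
from clutchpmf.params import CORE
from clutchpmf.pmf import ForceTable


def _single_core_library(n_conf=1):
    return ConformerLibrary(frames=np.zeros((n_conf, 1, 3)),
                            species=np.array([CORE], np.int8),
                            meta={"phi_c": 0.0})


def _record(xi, value, n=1000, rng=None):
    """Synthetic constraint record with the given mean."""
    rng = rng or np.random.default_rng(0)
    return ConstraintRecord(xi=xi, samples=value + 1e-12 * rng.random(n))


class TestInsertionEstimator:
    def test_single_core_pair_reduces_to_pair_energy(self, ff):
        """One-bead 'clutches' need no orientational average: the PMF is
        the bare core-core WCA curve, exactly."""
        lib = _single_core_library()
        p = cp.pair_interaction(ff, CORE, CORE)
        grid = np.array([6.8, 7.0, 7.1, 8.0, 10.0])
        curve = cp.pmf_insertion(lib, lib, grid, n_pairs=10, seed=1)
        for x, f in zip(curve.xi, curve.f):
            assert f == pytest.approx(cp.pair_energy(x, p), abs=1e-10)
        assert curve.f[-1] == 0.0  # anchored at the reference

    def test_matches_bruteforce_reference(self, ff):
        """Insertion average equals an independent naive-loop estimate on
        a frozen mini-clutch library (no rotations, so the sample set is
        deterministic)."""
        topo = cp.make_fixture("mini_clutch_n2")
        lib = ConformerLibrary(
            frames=(topo.coords - topo.coords[topo.core_indices(0)].mean(0))[None],
            species=topo.species, meta={})
        grid = np.array([14.0, 18.0, 25.0])
        curve = cp.pmf_insertion(lib, lib, grid, n_pairs=7, seed=3, rotate=False)
        # naive reference: same single conformer pair at each distance
        for x, f in zip(curve.xi[:-1], curve.f[:-1]):
            u = cp.inter_group_energy(lib.frames[0], lib.species,
                                      lib.frames[0], lib.species, float(x))
            expect = -np.log(np.exp(-u))  # single deterministic sample
            assert f == pytest.approx(expect, abs=1e-9)

    def test_overlap_contributes_zero(self, ff):
        lib = _single_core_library()
        grid = np.array([4.0, 10.0])  # 4.0 nm is inside the divergence zone
        curve = cp.pmf_insertion(lib, lib, grid, n_pairs=50, seed=2)
        assert np.isinf(curve.f[0])
        assert curve.meta["overlap_flag"]

    def test_validation(self):
        lib = _single_core_library()
        with pytest.raises(ValueError):
            cp.pmf_insertion(lib, lib, np.array([5.0, 6.0]), n_pairs=0, seed=1)
        empty = ConformerLibrary(frames=np.zeros((0, 1, 3)),
                                 species=np.array([CORE], np.int8))
        with pytest.raises(ValueError):
            cp.pmf_insertion(empty, lib, np.array([5.0, 6.0]), n_pairs=5, seed=1)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(scale=2.0, size=(6, 8, 3))
        lib = ConformerLibrary(frames=frames, species=np.zeros(8, np.int8))
        grid = np.array([4.0, 6.0, 12.0])
        a = cp.pmf_insertion(lib, lib, grid, n_pairs=500, seed=42)
        b = cp.pmf_insertion(lib, lib, grid, n_pairs=500, seed=42)
        assert np.array_equal(a.f, b.f)


class TestConstraintEstimator:
    def test_zero_forces_leave_pure_jacobian_term(self):
        """With <f_c> = 0 everywhere the integral is 2 kBT ln(xi/xi_ref)."""
        grid = np.arange(29.0, 45.1, 1.0)
        table = ForceTable([_record(x, 0.0) for x in grid])
        curve = cp.pmf_constraint(table)
        expect = 2.0 * np.log(29.0 / 45.0)
        k = int(np.nonzero(curve.xi == 29.0)[0][0])
        # trapezoid of 2/s on a 1-nm grid is within 1e-3 of the log
        assert curve.f[k] == pytest.approx(expect, abs=2e-3)
        assert expect == pytest.approx(-0.879, abs=1e-3)

    def test_analytic_two_core_table_recovers_pair_energy(self, ff):
        """A force table built from the analytic dU/dxi - 2kBT/xi recovers
        the WCA pair potential up to trapezoid discretisation error."""
        p = cp.pair_interaction(ff, CORE, CORE)
        grid = np.arange(6.9, 7.81, 0.05)
        table = ForceTable([
            _record(x, -cp.pair_force(x, p) - 2.0 / x) for x in grid])
        curve = cp.pmf_constraint(table)
        # reference: trapezoid applied to the same analytic integrand
        integrand = np.array([-cp.pair_force(x, p) for x in grid])
        expect = np.zeros(len(grid))
        for k in range(len(grid) - 2, -1, -1):
            h = grid[k + 1] - grid[k]
            expect[k] = expect[k + 1] - 0.5 * h * (integrand[k] + integrand[k + 1])
        assert np.allclose(curve.f, expect, atol=1e-9)
        # and the trapezoid itself is close to the true energy
        assert curve.f[0] == pytest.approx(
            cp.pair_energy(grid[0], p) - cp.pair_energy(grid[-1], p), abs=0.08)

    def test_single_point_grid(self):
        curve = cp.pmf_constraint(ForceTable([_record(30.0, 1.0)]))
        assert len(curve) == 1
        assert curve.f[0] == 0.0

    def test_duplicate_grid_rejected(self):
        with pytest.raises(ValueError):
            ForceTable([_record(30.0, 1.0), _record(30.0, 2.0)])

    def test_nonfinite_stats_rejected(self):
        rec = ConstraintRecord(xi=30.0, samples=np.full(100, np.nan))
        with pytest.raises(ValueError):
            cp.pmf_constraint(ForceTable([rec, _record(31.0, 0.0)]))


class TestDecomposition:
    def test_identity_exact_and_se_quadrature(self, ff):
        lib = _single_core_library()
        grid = np.array([6.9, 7.1, 7.5, 9.0])
        f_t = cp.pmf_insertion(lib, lib, grid, n_pairs=20, seed=4)
        f_nuc, f_crd = cp.decompose(f_t, lib, lib, n_pairs=20, seed=5)
        assert np.allclose(f_t.f, f_nuc.f + f_crd.f)
        assert np.allclose(f_crd.se, np.sqrt(f_t.se**2 + f_nuc.se**2))

    def test_grid_mismatch_rejected(self, ff):
        lib = _single_core_library()
        f_t = cp.pmf_insertion(lib, lib, np.array([7.0, 9.0]), n_pairs=5, seed=1)
        with pytest.raises(ValueError):
            cp.decompose(f_t, lib, lib, n_pairs=5, seed=1,
                         xi_grid=np.array([7.5, 9.5]))


class TestFeatures:
    def test_hard_sphere_vanish_at_contact(self):
        xi = np.arange(5.0, 12.1, 0.5)
        f = np.where(xi < 7.0, np.inf, 0.0)
        f[xi == 7.0] = 5.0  # steep wall at contact
        curve = cp.PMFCurve(xi=xi, f=f - f[-1], se=np.zeros_like(xi), xi_ref=12.0)
        feat = cp.pmf_features(curve, vanish_threshold=0.1)
        assert feat.vanish_distance == pytest.approx(7.0, abs=0.5)

    def test_flat_curve_has_null_features(self):
        xi = np.arange(5.0, 10.0)
        curve = cp.PMFCurve(xi=xi, f=np.zeros_like(xi), se=np.zeros_like(xi),
                            xi_ref=9.0)
        feat = cp.pmf_features(curve)
        assert feat.vanish_distance is None
        assert feat.min_value is None

    def test_well_and_bump(self):
        xi = np.arange(0.0, 10.0)
        f = np.array([8.0, 3.0, 1.0, -0.5, -0.2, 0.3, 0.1, 0.0, 0.0, 0.0])
        curve = cp.PMFCurve(xi=xi, f=f, se=np.zeros_like(f), xi_ref=9.0)
        feat = cp.pmf_features(curve, vanish_threshold=0.1)
        assert feat.min_value == -0.5
        assert feat.min_location == 3.0
        assert feat.bump_height == 0.3
        # outermost crossing of 0.1 scanned inward: between xi=6 (0.1) and 5
        assert 5.0 <= feat.vanish_distance <= 6.5


class TestPMFCurveIO:
    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        xi = np.arange(20.0, 30.0)
        curve = cp.PMFCurve(xi=xi, f=rng.normal(size=10),
                            se=np.abs(rng.normal(size=10)), xi_ref=29.0,
                            meta={"estimator": "insertion"})
        path = tmp_path / "pmf.tsv"
        curve.to_tsv(path)
        back = cp.PMFCurve.from_tsv(path)
        assert np.allclose(back.xi, curve.xi)
        assert np.allclose(back.f, curve.f, atol=1e-6)
        assert back.xi_ref == 29.0
        assert back.meta["estimator"] == "insertion"

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            cp.PMFCurve(xi=np.array([5.0, 4.0]), f=np.zeros(2),
                        se=np.zeros(2), xi_ref=5.0)
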