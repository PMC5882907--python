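import numpy as np
import pytest

import clutchpmf as cp
from clutchpmf.builders import BuildError, PackingError
from clutchpmf.forcefield import system_energy_forces
from clutchpmf.params import CORE, CROWDER, DNA


def _min_shifted_gap(topo, ff):
    """Smallest r - r0 over all pairs (minimum image)."""
    c = topo.coords
    sp = topo.species
    d = c[:, None, :] - c[None, :, :]
    if topo.box is not None:
        d -= topo.box * np.rint(d / topo.box)
    r = np.sqrt((d**2).sum(-1))
    rr = r - ff.r0_matrix()[sp[:, None], sp[None, :]]
    iu = np.triu_indices(len(c), k=1)
    return rr[iu].min()


class TestDnaChain:
    @pytest.mark.parametrize("n,bonds,angles", [(2, 1, 0), (100, 99, 98)])
    def test_counts(self, n, bonds, angles):
        topo = cp.build_dna_chain(n)
        assert (topo.n_beads, len(topo.bonds), len(topo.angles)) == (n, bonds, angles)

    def test_rejects_short_chain(self):
        with pytest.raises(BuildError):
            cp.build_dna_chain(1)

    def test_bond_geometry_and_validity(self, ff):
        topo = cp.build_dna_chain(575)
        blen = np.linalg.norm(np.diff(topo.coords, axis=0), axis=1)
        assert np.allclose(blen, ff.sigma)
        assert _min_shifted_gap(topo, ff) > 0


class TestNucleosomeChain:
    @pytest.mark.parametrize("n,dna,cores", [(1, 24, 1), (2, 53, 2),
                                             (11, 314, 11), (20, 575, 20)])
    def test_bead_counts(self, n, dna, cores):
        spec = cp.ClutchSpec(n_nucleosomes=n, label="x")
        topo = cp.build_nucleosome_chain(spec)
        assert (topo.species == DNA).sum() == dna
        assert (topo.species == CORE).sum() == cores
        assert len(topo.bonds) == dna - 1
        assert len(topo.angles) == dna - 2

    def test_wrap_restraints(self, ff):
        spec = cp.ClutchSpec(n_nucleosomes=1, label="x")
        topo = cp.build_nucleosome_chain(spec)
        wraps = [k for k in topo.hr_kind if k == "wrap"]
        loops = [k for k in topo.hr_kind if k == "loop-parallel"]
        assert len(wraps) == 24
        assert len(loops) == 24 - 14
        # every wrapped bead belongs to exactly one wrap restraint
        wrap_rows = topo.hr_idx[:24]
        assert sorted(wrap_rows[:, 0]) == list(range(24))
        assert set(wrap_rows[:, 1]) == {24}
        assert np.all(topo.hr_k == ff.k_wrap_nm)

    def test_initial_configuration_valid(self, ff):
        topo = cp.build_nucleosome_chain(cp.heterochromatin_spec())
        assert _min_shifted_gap(topo, ff) > 0
        report, _ = system_energy_forces(topo)
        assert np.isfinite(report.total)

    def test_build_reproducible(self):
        spec = cp.euchromatin_spec()
        a = cp.build_nucleosome_chain(spec, seed=4)
        b = cp.build_nucleosome_chain(spec, seed=4)
        assert np.array_equal(a.coords, b.coords)


class TestCollapse:
    def test_weak_pull_leaves_clutch_open(self):
        """In the vanishing-stiffness limit the chain is not collapsed."""
        spec = cp.ClutchSpec(n_nucleosomes=4, label="mini")
        chain = cp.build_nucleosome_chain(spec)
        topo = cp.collapse_clutch(chain, spec, calibrate=False, k_collapse=1e-4,
                                  sim=cp.SimulationParams(n_steps=10_000, seed=2))
        lib = cp.sample_conformers(
            topo, cp.SimulationParams(n_steps=1, equilibration=5_000, seed=3),
            n_conformers=20, stride=200, check_decorrelation=False)
        prof = cp.radial_profile(lib, species=None)
        # a free 4-nucleosome chain spans far beyond the 15 nm target
        assert cp.clutch_extent(prof) > 15.0

    def test_stronger_pull_compacts_more(self):
        spec = cp.ClutchSpec(n_nucleosomes=4, label="mini")
        extents = []
        for k in (0.05, 2.0):
            chain = cp.build_nucleosome_chain(spec)
            topo = cp.collapse_clutch(chain, spec, calibrate=False, k_collapse=k,
                                      sim=cp.SimulationParams(n_steps=10_000, seed=5))
            lib = cp.sample_conformers(
                topo, cp.SimulationParams(n_steps=1, equilibration=8_000, seed=6),
                n_conformers=30, stride=200, check_decorrelation=False)
            extents.append(cp.clutch_extent(cp.radial_profile(lib, species=None)))
        assert extents[1] < extents[0]

    def test_rejects_double_collapse(self, het_clutch):
        with pytest.raises(BuildError):
            cp.collapse_clutch(het_clutch, cp.heterochromatin_spec())


class TestCrowders:
    def test_phi_zero_is_noop(self, ff):
        topo = cp.make_fixture("single_core_pair")
        topo.box = 30.0
        out = cp.place_crowders(topo, cp.CrowdingCondition(0.0), seed=1)
        assert out.n_beads == topo.n_beads

    def test_dense_bath_placement(self, ff):
        topo = cp.Topology.empty()
        topo.box = 45.0
        cond = cp.CrowdingCondition(0.3)
        out = cp.place_crowders(topo, cond, seed=7)
        assert (out.species == CROWDER).sum() == cond.n_crowders(45.0)
        # hard criterion: no crowder pair inside its divergence distance
        # (2.5 sigma); builder leaves extra clearance on top
        assert _min_shifted_gap(out, ff) > 0.9 * ff.sigma

    def test_overfull_box_raises(self):
        topo = cp.Topology.empty()
        topo.box = 7.0
        with pytest.raises(PackingError):
            cp.place_crowders(topo, cp.CrowdingCondition(0.3), seed=1)

    def test_requires_box(self):
        topo = cp.make_fixture("single_core_pair")
        with pytest.raises(BuildError):
            cp.place_crowders(topo, cp.CrowdingCondition(0.1), seed=1)

    def test_seed_determinism(self):
        topo = cp.Topology.empty()
        topo.box = 40.0
        a = cp.place_crowders(topo, cp.CrowdingCondition(0.2), seed=9)
        b = cp.place_crowders(topo, cp.CrowdingCondition(0.2), seed=9)
        assert np.array_equal(a.coords, b.coords)


class TestPairAssembly:
    def test_centroid_distance_set(self, ff):
        a = cp.make_fixture("mini_clutch_n2")
        pair = cp.build_pair_topology(a, a, xi=25.0, box=None, seed=3)
        ca = pair.coords[pair.core_indices(0)].mean(0)
        cb = pair.coords[pair.core_indices(1)].mean(0)
        assert np.linalg.norm(cb - ca) == pytest.approx(25.0, abs=1e-9)
        report, _ = system_energy_forces(pair)
        assert np.isfinite(report.total)


class TestTopologyIO:
    def test_hdf5_roundtrip(self, tmp_path, ff):
        topo = cp.build_nucleosome_chain(cp.ClutchSpec(n_nucleosomes=2, label="m"))
        topo.box = 50.0
        from clutchpmf.topology import CollapseRestraint
        topo.collapse.append(
            CollapseRestraint(topo.core_indices(0), 3.0, 1.5))
        path = tmp_path / "topo.h5"
        topo.save(path)
        back = cp.Topology.load(path)
        assert np.array_equal(back.coords, topo.coords)
        assert np.array_equal(back.hr_idx, topo.hr_idx)
        assert back.box == 50.0
        assert back.collapse[0].r_t == 3.0
        assert back.hr_kind == topo.hr_kind

    def test_xyz_export(self, tmp_path):
        topo = cp.make_fixture("single_core_pair")
        path = tmp_path / "snap.xyz"
        topo.write_xyz(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[2].startswith("COR")


class TestWLCDraws:
    def test_angle_statistics_match_boltzmann(self, ff):
        """wlc_coords draws bending angles from sin(theta)exp(-k theta^2/2)."""
        from scipy import integrate
        from clutchpmf.builders import wlc_coords
        rng = np.random.default_rng(8)
        cts = []
        for _ in range(300):
            x = wlc_coords(50, ff.k_angle, 1.94, rng)
            b = np.diff(x, axis=0)
            u = b / np.linalg.norm(b, axis=1, keepdims=True)
            cts.append((u[:-1] * u[1:]).sum(1))
        ct = np.concatenate(cts)
        k = ff.k_angle
        num = integrate.quad(lambda t: np.cos(t) * np.sin(t) * np.exp(-0.5 * k * t * t), 0, np.pi)[0]
        den = integrate.quad(lambda t: np.sin(t) * np.exp(-0.5 * k * t * t), 0, np.pi)[0]
        assert ct.mean() == pytest.approx(num / den, abs=3 * ct.std() / np.sqrt(len(ct) / 2))
        # bond lengths are exactly the requested value
        assert np.allclose(np.linalg.norm(np.diff(wlc_coords(20, k, 1.94, rng), axis=0), axis=1), 1.94)

    def test_wlc_chain_build_is_overlap_free(self, ff):
        topo = cp.build_dna_chain(100, seed=3, init="wlc")
        assert _min_shifted_gap(topo, ff) > 0
        with pytest.raises(BuildError):
            cp.build_dna_chain(100, init="bogus")
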