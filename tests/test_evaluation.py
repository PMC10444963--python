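import numpy as np
import pytest

from emgan3d.density_io import DensityMap
from emgan3d.evaluation import (
    RSCCProfile,
    UndefinedCorrelationError,
    cross_correlation,
    cubewise_improvement,
    improvement_report,
    rscc_per_residue,
)
from emgan3d.map_simulation import Atom, AtomModel, SimulationConfig, simulate_map
from emgan3d.synthetic_fixtures import make_toy_structure


def brute_pearson(a, b):
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


class TestCrossCorrelation:
    def test_identical_is_one(self, rng):
        a = rng.random((4, 4, 4))
        assert cross_correlation(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_negation_is_minus_one(self, rng):
        a = rng.random((4, 4, 4))
        assert cross_correlation(a, -a) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        a = rng.random((3, 3, 3))
        b = rng.random((3, 3, 3))
        assert cross_correlation(a, b) == pytest.approx(brute_pearson(a, b), abs=1e-12)
        about_zero = float(
            (a * b).sum() / (np.linalg.norm(a.ravel()) * np.linalg.norm(b.ravel()))
        )
        assert cross_correlation(a, b, about_mean=False) == pytest.approx(
            about_zero, abs=1e-12
        )

    def test_symmetry_and_invariance(self, rng):
        a = rng.random((4, 4, 4))
        b = rng.random((4, 4, 4))
        cc = cross_correlation(a, b)
        assert cross_correlation(b, a) == pytest.approx(cc, abs=1e-12)
        assert cross_correlation(3.0 * a, b) == pytest.approx(cc, abs=1e-12)
        assert cross_correlation(a + 5.0, b) == pytest.approx(cc, abs=1e-12)
        assert -1.0 <= cc <= 1.0

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            cross_correlation(np.ones((3, 3, 3)), np.random.rand(3, 3, 3))

    def test_zero_norm_about_zero_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            cross_correlation(
                np.zeros((3, 3, 3)), np.ones((3, 3, 3)), about_mean=False
            )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cross_correlation(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestCubewiseImprovement:
    def _triple(self, rng, shape=(33, 33, 33)):
        exp = DensityMap(rng.random(shape, dtype=np.float32))
        mod = DensityMap(rng.random(shape, dtype=np.float32))
        sim = DensityMap(rng.random(shape, dtype=np.float32))
        return exp, mod, sim

    def test_mod_equals_sim(self, rng):
        exp, _, sim = self._triple(rng)
        frac, cc_exp, cc_mod = cubewise_improvement(exp, sim, sim)
        assert frac == 1.0
        assert cc_mod == pytest.approx(1.0, abs=1e-9)

    def test_mod_equals_exp_ties(self, rng):
        exp, _, sim = self._triple(rng)
        frac, cc_exp, cc_mod = cubewise_improvement(exp, exp, sim)
        assert frac == 1.0  # exact ties count as improved-or-equal
        assert cc_mod == pytest.approx(cc_exp, abs=1e-12)

    def test_matches_brute_force(self, rng):
        from emgan3d.cube_pipeline import extract_cubes

        exp, mod, sim = self._triple(rng)
        frac, cc_exp_mean, cc_mod_mean = cubewise_improvement(exp, mod, sim)
        _, ecs = extract_cubes(exp)
        _, mcs = extract_cubes(mod)
        _, scs = extract_cubes(sim)
        n = imp = 0
        s_exp = s_mod = 0.0
        for ec, mc, sc in zip(ecs, mcs, scs):
            if not (ec.any() and sc.any()):
                continue
            ce = brute_pearson(ec, sc)
            cm = brute_pearson(mc, sc)
            n += 1
            s_exp += ce
            s_mod += cm
            imp += cm >= ce
        assert frac == pytest.approx(imp / n, abs=1e-12)
        assert cc_exp_mean == pytest.approx(s_exp / n, abs=1e-9)
        assert cc_mod_mean == pytest.approx(s_mod / n, abs=1e-9)

    def test_frame_mismatch(self, rng):
        exp, mod, sim = self._triple(rng)
        bad = DensityMap(rng.random((30, 33, 33), dtype=np.float32))
        with pytest.raises(ValueError, match="frame"):
            cubewise_improvement(exp, bad, sim)


class TestRSCC:
    @pytest.fixture(scope="module")
    def model(self):
        return make_toy_structure("helix", 8, seed=3)

    @pytest.fixture(scope="module")
    def cfg(self):
        return SimulationConfig(resolution=3.0)

    def test_self_consistency(self, model, cfg):
        m = simulate_map(model, cfg)
        profile = rscc_per_residue(m, model, cfg)
        assert len(profile.entries) == 8
        for entry in profile.entries:
            assert entry.rscc == pytest.approx(1.0, abs=1e-9)

    def test_noise_lowers_mean(self, model, cfg):
        m = simulate_map(model, cfg)
        noisy = DensityMap(
            m.data + np.random.default_rng(0).normal(0, 0.3, m.shape).astype(np.float32),
            m.origin,
            m.voxel_size,
        )
        clean = rscc_per_residue(m, model, cfg).mean_rscc
        degraded = rscc_per_residue(noisy, model, cfg).mean_rscc
        assert degraded < clean

    def test_two_residue_matches_brute_force(self):
        model = AtomModel(
            [
                Atom("C", "A", 1, "ALA", (3.0, 3.0, 3.0), name="CA"),
                Atom("C", "A", 2, "ALA", (5.0, 4.0, 3.0), name="CA"),
            ]
        )
        cfg = SimulationConfig(resolution=2.5, padding=2.0)
        ref = simulate_map(model, cfg)
        rng = np.random.default_rng(5)
        m = DensityMap(
            np.clip(ref.data + rng.normal(0, 0.1, ref.shape), 0, None).astype(np.float32),
            ref.origin,
            ref.voxel_size,
        )
        profile = rscc_per_residue(m, model, cfg, mask_radius=2.5)
        # brute-force masked correlation per residue
        nz, ny, nx = m.shape
        for entry, atom in zip(profile.entries, model.atoms):
            sel_map, sel_ref = [], []
            count = 0
            for iz in range(nz):
                for iy in range(ny):
                    for ix in range(nx):
                        p = m.origin + np.array([ix, iy, iz]) * m.voxel_size
                        if np.linalg.norm(p - np.array(atom.position)) <= 2.5:
                            sel_map.append(m.data[iz, iy, ix])
                            sel_ref.append(ref.data[iz, iy, ix])
                            count += 1
            assert entry.n_voxels == count
            assert entry.rscc == pytest.approx(
                brute_pearson(np.array(sel_map), np.array(sel_ref)), abs=1e-6
            )

    def test_outside_atoms_skipped(self, model, cfg):
        m = simulate_map(model, cfg)
        far = AtomModel(
            model.atoms
            + [Atom("C", "B", 1, "ALA", (500.0, 500.0, 500.0), name="CA")]
        )
        profile = rscc_per_residue(m, far, cfg, reference=simulate_map(model, cfg, grid=m))
        assert len(profile.entries) == 8  # the far residue is skipped

    def test_tsv_output(self, tmp_path, model, cfg):
        m = simulate_map(model, cfg)
        profile = rscc_per_residue(m, model, cfg)
        out = tmp_path / "rscc.tsv"
        profile.write_tsv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["chain", "resi", "resname", "rscc", "n_voxels"]
        assert len(lines) == 9


class TestImprovementReport:
    def _profile(self, values):
        from emgan3d.evaluation import RSCCEntry

        return RSCCProfile(
            [RSCCEntry("A", i + 1, "ALA", v, 10) for i, v in enumerate(values)]
        )

    def test_identical_profiles(self):
        a = self._profile([0.5, 0.6, 0.7])
        rep = improvement_report(a, a)
        assert rep["fraction_improved"] == 1.0
        assert rep["mean_delta"] == 0.0

    def test_uniform_improvement(self):
        a = self._profile([0.5, 0.6, 0.7])
        b = self._profile([0.6, 0.7, 0.8])
        rep = improvement_report(a, b)
        assert rep["fraction_improved"] == 1.0
        assert rep["mean_delta"] == pytest.approx(0.1)
        assert rep["mean_before"] == pytest.approx(0.6)
        assert rep["mean_after"] == pytest.approx(0.7)

    def test_order_independent(self):
        a = self._profile([0.5, 0.6, 0.7])
        b = self._profile([0.4, 0.8, 0.9])
        shuffled = RSCCProfile(list(reversed(b.entries)))
        assert improvement_report(a, b) == improvement_report(a, shuffled)

    def test_key_mismatch_raises(self):
        a = self._profile([0.5, 0.6])
        b = self._profile([0.5, 0.6, 0.7])
        with pytest.raises(ValueError, match="residue keys"):
            improvement_report(a, b)
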