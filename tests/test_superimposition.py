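import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import craniomorph as cm
from craniomorph.superimposition import (
    DegenerateConfigurationError,
    align_pair,
    center,
    centroid_size,
    reflect_relabel,
)


def _random_rigid(rng, config, scale=None):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(size=3) * 10
    s = scale if scale is not None else rng.uniform(0.5, 2.0)
    return s * config @ R.T + t


class TestAlignPair:
    def test_identical_configurations(self, rng):
        X = rng.normal(size=(7, 3))
        R, s, d = align_pair(X, X)
        assert d == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_rotated_and_scaled_source_recovered(self, rng):
        X = center(rng.normal(size=(6, 3)))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        src = 2.0 * X @ Rz.T
        R, s, d = align_pair(src, X, allow_scaling=True)
        assert d == pytest.approx(0.0, abs=1e-10)
        assert s == pytest.approx(0.5, rel=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_rotation_is_always_proper(self, rng):
        # a reflected copy must NOT be matched by an improper rotation
        X = center(rng.normal(size=(8, 3)))
        mirrored = X * np.array([-1.0, 1.0, 1.0])
        R, _, d = align_pair(mirrored, X)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert d > 0.1

    def test_distance_matches_grid_search_oracle(self, rng):
        """Optimal distance equals a brute-force minimum over a dense
        grid of rotations (Euler-angle parameterization)."""
        src = center(rng.normal(size=(5, 3)))
        tgt = center(rng.normal(size=(5, 3)))
        _, _, d = align_pair(src, tgt)
        grid = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        half = np.linspace(0, np.pi, 36)
        angles = np.stack(
            np.meshgrid(grid, half, grid, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        mats = Rotation.from_euler("zyz", angles).as_matrix()
        rotated = np.einsum("kij,lj->kli", mats, src)
        best = np.sqrt(((rotated - tgt) ** 2).sum(axis=(1, 2)).min())
        assert d <= best + 1e-9
        assert d == pytest.approx(best, abs=0.05 * best)

    def test_degenerate_configuration_raises(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(DegenerateConfigurationError):
            align_pair(line, line)


class TestPlainGPA:
    def test_rigid_copies_collapse_to_consensus(self, rng):
        X = center(rng.normal(size=(9, 3)))
        data = np.array([_random_rigid(rng, X) for _ in range(6)])
        fit = cm.gpa(data)
        assert fit.converged
        for a in fit.aligned:
            for b in fit.aligned:
                assert np.sqrt(((a - b) ** 2).sum()) < 1e-8
        _, _, d = align_pair(fit.consensus, X / centroid_size(X), allow_scaling=True)
        assert d < 1e-8

    def test_two_specimen_consensus_is_equidistant(self, rng):
        tri1 = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        tri2 = np.array([[0.0, 0, 0], [2, 0, 0], [0.4, 1.6, 0]])
        fit = cm.gpa(np.array([tri1, tri2]))
        d1 = np.sqrt(((fit.aligned[0] - fit.consensus) ** 2).sum())
        d2 = np.sqrt(((fit.aligned[1] - fit.consensus) ** 2).sum())
        assert d1 == pytest.approx(d2, rel=1e-6)

    def test_residuals_sum_to_zero_at_convergence(self, rng):
        data = rng.normal(size=(8, 6, 3)) + 5.0
        fit = cm.gpa(data)
        resid = (fit.aligned - fit.consensus).sum(axis=0)
        np.testing.assert_allclose(resid, 0.0, atol=1e-8)

    def test_procrustes_distances_invariant_to_rigid_motion(self, rng):
        data = rng.normal(size=(5, 7, 3))
        fit1 = cm.gpa(data)
        jittered = np.array([_random_rigid(rng, c) for c in data])
        fit2 = cm.gpa(jittered)

        def pdists(fit):
            n = fit.n_specimens
            return np.array(
                [
                    np.sqrt(((fit.aligned[i] - fit.aligned[j]) ** 2).sum())
                    for i in range(n)
                    for j in range(i + 1, n)
                ]
            )

        np.testing.assert_allclose(pdists(fit1), pdists(fit2), atol=1e-8)


class TestObjectSymmetryGPA:
    def test_mirror_symmetric_input_has_zero_asymmetry(self, sym31):
        template, sym, _ = cm.make_template("cranial31")
        rng = np.random.default_rng(7)
        data = np.array([_random_rigid(rng, template) for _ in range(4)])
        fit = cm.gpa_object_symmetry(
            cm.LandmarkDataset(data, [f"s{i}" for i in range(4)],
                               ["other"] * 4, [1] * 4),
            sym,
        )
        assert np.abs(fit.asymmetric).max() < 1e-10

    def test_symmetric_component_invariant_under_reflect_relabel(self, small_fit, sym31):
        sym_again = reflect_relabel(small_fit.symmetric, sym31)
        np.testing.assert_allclose(sym_again, small_fit.symmetric, atol=1e-9)

    def test_decomposition_reconstructs_aligned_to_machine_precision(self, small_fit):
        np.testing.assert_allclose(
            small_fit.symmetric + small_fit.asymmetric,
            small_fit.aligned,
            atol=1e-15,
            rtol=0,
        )

    def test_asymmetry_grows_with_fluctuating_asymmetry_variance(self, sym31):
        msds = []
        for fa in (0.01, 0.1, 1.0):
            spec = cm.SyntheticSpec(
                n_per_group={"non-deformed": 40},
                fa_variance=fa, da_scale=0.0, measurement_error_sd=0.0,
                seed=99,
            )
            fit = cm.gpa_object_symmetry(cm.simulate_dataset(spec), sym31)
            msds.append((fit.asymmetric**2).mean())
        assert msds[0] < msds[1] < msds[2]


class TestErrorAnova:
    def test_identical_replicates_give_perfect_repeatability(self, sym31):
        spec = cm.SyntheticSpec(
            n_per_group={"non-deformed": 12}, n_replicates=2,
            measurement_error_sd=0.0, seed=3,
        )
        res = cm.procrustes_anova_error(cm.simulate_dataset(spec), sym31)
        assert res.ms_error == pytest.approx(0.0, abs=1e-20)
        assert res.repeatability == 1.0

    def test_no_individual_variation_gives_near_zero_repeatability(self, sym31):
        spec = cm.SyntheticSpec(
            n_per_group={"non-deformed": 60}, n_replicates=2,
            integration_strength=0.0,
            within_module_variance={"viscerocranium": 0.0, "neurocranium": 0.0},
            fa_variance=0.0, residual_sd=0.0, ap_compression=0.0,
            oblique_shear=0.0, measurement_error_sd=0.5, seed=4,
        )
        res = cm.procrustes_anova_error(cm.simulate_dataset(spec), sym31)
        # expected MS_individual == MS_error; estimate is clipped at 0
        assert res.repeatability < 0.15

    def test_incomplete_specimens_are_excluded(self, sym31):
        spec = cm.SyntheticSpec(
            n_per_group={"non-deformed": 10}, n_replicates=2, seed=5
        )
        ds = cm.simulate_dataset(spec)
        keep = np.ones(ds.n_records, dtype=bool)
        keep[1] = False  # drop one replicate of one specimen
        res = cm.procrustes_anova_error(ds.subset(keep), sym31)
        assert res.n_excluded == 1
        assert res.n_specimens == 9

    def test_single_replicate_dataset_rejected(self, small_dataset, sym31):
        with pytest.raises(ValueError, match="replicates"):
            cm.procrustes_anova_error(small_dataset, sym31)
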