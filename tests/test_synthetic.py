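import numpy as np
import pytest

import craniomorph as cm
from craniomorph.superimposition import centroid_size, reflect_relabel
from craniomorph.synthetic import default_da_shift


class TestTemplates:
    def test_cranial_template_counts(self):
        template, sym, part = cm.make_template("cranial31")
        assert template.shape == (31, 3)
        assert len(sym.pairs) == 10
        assert len(sym.midline) == 11
        assert len(part.indices("viscerocranium")) == 9
        assert len(part.indices("neurocranium")) == 22

    def test_cranial_template_is_mirror_symmetric(self):
        template, sym, _ = cm.make_template("cranial31")
        np.testing.assert_array_equal(reflect_relabel(template, sym), template)

    def test_template_has_zero_asymmetric_component(self, sym31):
        template, _, _ = cm.make_template("cranial31")
        rng = np.random.default_rng(0)
        data = np.array([template + 0 for _ in range(3)])
        # random rigid motions applied to copies of the template
        from scipy.spatial.transform import Rotation

        for i in range(3):
            R = Rotation.random(rng=rng).as_matrix()
            data[i] = template @ R.T + rng.normal(size=3)
        ds = cm.LandmarkDataset(data, ["a", "b", "c"], ["other"] * 3, [1] * 3)
        fit = cm.gpa_object_symmetry(ds, sym31)
        assert np.abs(fit.asymmetric).max() < 1e-10

    def test_toy_schema_validates(self):
        template, sym, part = cm.make_template("toy")
        ds = cm.LandmarkDataset(template[None], ["t"], ["other"], [1])
        assert cm.validate_dataset(ds, sym, part) == []

    def test_unknown_schema_rejected(self):
        with pytest.raises(ValueError):
            cm.make_template("dodo")


class TestSimulateDataset:
    def test_zero_variance_gives_exact_template_copies(self):
        template, _, _ = cm.make_template("cranial31")
        spec = cm.SyntheticSpec(
            n_per_group={"non-deformed": 5},
            integration_strength=0.0,
            within_module_variance={"viscerocranium": 0.0, "neurocranium": 0.0},
            fa_variance=0.0, residual_sd=0.0, measurement_error_sd=0.0,
            ap_compression=0.0, oblique_shear=0.0, seed=0,
        )
        ds = cm.simulate_dataset(spec)
        assert ds.n_records == 5
        for rec in ds.coords:
            np.testing.assert_array_equal(rec, template)

    def test_seed_determinism(self):
        spec = cm.SyntheticSpec(n_per_group={"non-deformed": 8}, seed=42)
        d1 = cm.simulate_dataset(spec)
        d2 = cm.simulate_dataset(spec)
        np.testing.assert_array_equal(d1.coords, d2.coords)
        assert d1.specimen_ids == d2.specimen_ids

    def test_no_asymmetry_terms_leave_only_noise_scale_asymmetry(self, sym31):
        me = 0.05
        spec = cm.SyntheticSpec(
            n_per_group={"non-deformed": 25}, fa_variance=0.0, da_scale=0.0,
            fa_integration_strength=0.0, fa_module_variance=0.0,
            measurement_error_sd=me, seed=9,
        )
        ds = cm.simulate_dataset(spec)
        fit = cm.gpa_object_symmetry(ds, sym31)
        # asymmetric deviations live on the measurement-noise scale:
        # compare RMS asymmetry (in raw units) with the noise sd
        rms = np.sqrt((fit.asymmetric**2).mean()) * fit.centroid_sizes.mean()
        assert rms < 2 * me

    def test_ap_compression_preserves_centroid_size(self):
        template, _, _ = cm.make_template("cranial31")
        spec = cm.SyntheticSpec(
            n_per_group={"antero-posterior": 3}, integration_strength=0.0,
            within_module_variance={"viscerocranium": 0.0, "neurocranium": 0.0},
            fa_variance=0.0, residual_sd=0.0, measurement_error_sd=0.0,
            ap_compression=0.15, deformation_sd_frac=0.0, seed=1,
        )
        ds = cm.simulate_dataset(spec)
        for rec in ds.coords:
            assert centroid_size(rec) == pytest.approx(
                centroid_size(template), rel=1e-10
            )
            assert not np.allclose(rec, template)

    def test_groups_and_replicates_structure(self):
        spec = cm.SyntheticSpec(
            n_per_group={"antero-posterior": 3, "oblique": 2},
            n_replicates=2, seed=0,
        )
        ds = cm.simulate_dataset(spec)
        assert ds.n_records == 10
        assert sorted(set(ds.groups)) == ["antero-posterior", "oblique"]
        assert sorted(set(ds.replicates)) == [1, 2]
        assert cm.validate_dataset(ds, cm.cranial31_symmetry(),
                                   cm.cranial31_partition()) == []

    def test_invalid_spec_lists_offending_fields(self):
        spec = cm.SyntheticSpec(fa_variance=-1.0, n_replicates=0)
        with pytest.raises(ValueError) as err:
            cm.simulate_dataset(spec)
        assert "fa_variance" in str(err.value)
        assert "n_replicates" in str(err.value)

    def test_integration_strength_lowers_modularity_signal(self, part31, sym31):
        """Sample CR is lower (more modular) without a cross-module factor
        than with even a weak one, on paired seeds."""
        wins = 0
        for rep in range(20):
            crs = []
            for s in (0.0, 0.01):
                spec = cm.SyntheticSpec(
                    n_per_group={"non-deformed": 300}, integration_strength=s,
                    within_module_variance={"viscerocranium": 0.05,
                                            "neurocranium": 0.05},
                    fa_variance=0.01, residual_sd=0.02,
                    measurement_error_sd=0.0, ap_compression=0.0,
                    oblique_shear=0.0, seed=rep,
                )
                fit = cm.gpa_object_symmetry(cm.simulate_dataset(spec), sym31)
                crs.append(
                    cm.covariance_ratio(fit.component_matrix("symmetric"), part31)
                )
            wins += crs[0] < crs[1]
        assert wins >= 18

    def test_ap_compression_separates_groups_along_pc1(self, sym31):
        """Antero-posterior flattening shifts group means along PC1 well
        beyond the within-group spread when deformation dominates."""
        spec = cm.SyntheticSpec(
            n_per_group={"antero-posterior": 150, "non-deformed": 150},
            ap_compression=0.15, integration_strength=4.0,
            within_module_variance={"viscerocranium": 1.0, "neurocranium": 1.0},
            deformation_sd_frac=0.2, seed=11,
        )
        ds = cm.simulate_dataset(spec)
        fit = cm.gpa_object_symmetry(ds, sym31)
        res = cm.pca(fit.component_matrix("symmetric"))
        g = np.asarray(ds.groups)
        s1 = res.scores[:, 0]
        means = [s1[g == grp].mean() for grp in np.unique(g)]
        sds = [s1[g == grp].std() for grp in np.unique(g)]
        assert abs(means[0] - means[1]) > 3 * np.mean(sds)

    def test_da_shift_is_purely_antisymmetric(self, sym31):
        template, sym, _ = cm.make_template("cranial31")
        da = default_da_shift(template, sym, scale=2.0)
        np.testing.assert_allclose(reflect_relabel(da, sym), -da, atol=1e-12)
        assert np.linalg.norm(da) == pytest.approx(2.0)


class TestSpecPlumbing:
    def test_yaml_round_trip(self, tmp_path):
        spec = cm.SyntheticSpec(seed=5, fa_variance=0.3)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert cm.SyntheticSpec.from_yaml(path) == spec

    def test_reference_cohort_preset_loads(self):
        spec = cm.reference_cohort_spec(seed=3)
        assert spec.n_per_group == {
            "antero-posterior": 74, "non-deformed": 118, "oblique": 77,
        }
        assert spec.seed == 3
        assert spec.validate() == []

    def test_target_integration_parameterization(self):
        spec = cm.SyntheticSpec.with_target_integration(0.8, within=2.0)
        s = spec.integration_strength
        v = spec.within_module_variance["neurocranium"]
        assert s / (s + v) == pytest.approx(0.8)
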