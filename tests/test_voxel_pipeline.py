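"""Pipeline stages: masking, scaling, per-voxel fits, selection, maps."""

import numpy as np
import pandas as pd
import pytest

from voxelsem import sem_core as sc
from voxelsem import voxel_pipeline as vp
from voxelsem.aging_models import MODEL_CODES, ModelKind, make_aging_model
from voxelsem.sem_core import FitStatus, SemFitResult, build_covariance

from conftest import make_region_dataset


class TestSkeletonMask:
    def test_all_above_threshold_gives_full_mask(self):
        fa = np.full((3, 3, 2, 5), 0.5)
        skel = vp.skeleton_mask(fa)
        assert skel.mask.all() and skel.n_voxels == 18

    def test_single_low_subject_excludes_voxel(self):
        fa = np.full((2, 2, 1, 4), 0.5)
        fa[0, 0, 0, 2] = 0.15
        skel = vp.skeleton_mask(fa)
        assert not skel.mask[0, 0, 0]
        assert skel.mask.sum() == 3

    def test_exactly_threshold_is_excluded(self):
        fa = np.full((1, 1, 1, 3), 0.2)
        skel = vp.skeleton_mask(fa)
        assert skel.n_voxels == 0

    def test_empty_mask_warns_not_raises(self):
        with pytest.warns(UserWarning, match="empty"):
            vp.skeleton_mask(np.zeros((2, 2, 2, 3)))


class TestPrepareVoxel:
    def _cohort(self, n):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "age": np.linspace(20, 80, n),
            "rt_verbal": rng.uniform(500, 900, n),
            "rt_visuospatial": rng.uniform(500, 900, n),
        })

    def test_minmax_endpoints_after_sign_flip(self):
        cohort = self._cohort(2)
        fa = np.array([0.8, 0.2])     # negFA = [-0.8, -0.2] -> [0, 10]
        md = np.array([0.7, 0.9])
        data, names = vp.prepare_voxel(fa, md, cohort)
        col = data[:, names.index("neg_fa")]
        np.testing.assert_allclose(col, [0.0, 10.0])
        assert data.min() >= 0.0 and data.max() <= 10.0

    def test_declining_fa_becomes_positive_age_association(self):
        cohort = self._cohort(30)
        age = cohort["age"].to_numpy()
        fa = 0.8 - 0.004 * age        # raw FA declines with age
        md = np.full(30, 0.8) + 0.001 * age
        data, names = vp.prepare_voxel(fa, md, cohort)
        r = np.corrcoef(data[:, names.index("age")],
                        data[:, names.index("neg_fa")])[0, 1]
        assert r > 0.99

    def test_constant_column_marks_voxel_unfittable(self):
        cohort = self._cohort(10)
        with pytest.raises(sc.DegenerateInputError, match="neg_fa"):
            vp.prepare_voxel(np.full(10, 0.5), np.linspace(0.7, 0.9, 10), cohort)

    def test_chi_square_identical_across_well_conditioned_scalings(self):
        """The 0-10 min-max convention is one of many valid scalings: the
        chi-square is the same under per-column standardisation."""
        cohort, _, _, vols = make_region_dataset(
            ModelKind.COGNITIVE_MEDIATION, shape=(1, 1, 1), seed=13)
        data, names = vp.prepare_voxel(vols.fa[0, 0, 0], vols.md[0, 0, 0],
                                       cohort)
        raw = np.column_stack([
            cohort["age"], cohort["rt_verbal"], cohort["rt_visuospatial"],
            -vols.fa[0, 0, 0], vols.md[0, 0, 0],
        ])
        zscored = (raw - raw.mean(axis=0)) / raw.std(axis=0)
        spec = make_aging_model(ModelKind.COGNITIVE_MEDIATION)
        f_minmax = sc.fit_sem(spec, build_covariance(data, names))
        f_z = sc.fit_sem(spec, build_covariance(zscored, names))
        assert f_minmax.chi_square == pytest.approx(f_z.chi_square, abs=1e-4)


class TestFitVoxel:
    def test_all_models_fitted_on_shared_covariance(self):
        cohort, _, _, vols = make_region_dataset(
            ModelKind.INDEPENDENT_FACTOR, shape=(1, 1, 1), seed=14)
        data, names = vp.prepare_voxel(vols.fa[0, 0, 0], vols.md[0, 0, 0],
                                       cohort)
        specs = {k: make_aging_model(k) for k in MODEL_CODES}
        fits = vp.fit_voxel(data, specs, names)
        assert set(fits) == set(specs)
        assert all(f.n_subjects == 88 for f in fits.values())

    def test_singular_voxel_yields_all_red(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=88)
        data = np.column_stack([base, base, base, base, base])  # rank 1
        specs = {k: make_aging_model(k) for k in MODEL_CODES}
        fits = vp.fit_voxel(data, specs,
                            list(specs[ModelKind.INDEPENDENT_FACTOR].observed))
        assert all(f.status is FitStatus.RED for f in fits.values())
        assert all(np.isinf(f.aic) for f in fits.values())

    def test_population_covariance_voxel_fits_exactly(self):
        """A voxel whose sample covariance equals the independent-factor
        population covariance yields a near-zero chi-square."""
        spec = make_aging_model(ModelKind.INDEPENDENT_FACTOR)
        true = dict(l_rt_visuospatial=0.9, l_md=1.0, e_rt_verbal=1.2,
                    e_rt_visuospatial=1.0, e_neg_fa=0.8, e_md=0.9,
                    v_age=6.0, v_beh=1.5, v_wmi=1.0,
                    age_to_beh=0.5, age_to_wmi=0.3)
        sigma = sc.implied_covariance(
            spec, np.array([true[p] for p in spec.param_ids]))
        rng = np.random.default_rng(2)
        z = rng.standard_normal((88, 5))
        z -= z.mean(axis=0)
        # rotate the sample so its covariance is exactly sigma
        s_z = np.cov(z, rowvar=False)
        z = z @ np.linalg.inv(np.linalg.cholesky(s_z).T)
        data = z @ np.linalg.cholesky(sigma).T
        fits = vp.fit_voxel(data, {"m": spec}, list(spec.observed))
        assert fits["m"].chi_square < 1e-6


def _result(kind, aic, p=0.5, status=FitStatus.GREEN, corr=0.3, df=4):
    spec = make_aging_model(kind)
    return SemFitResult(spec=spec, theta_hat=np.zeros(spec.n_free), f_ml=0.0,
                        chi_square=aic + 2 * df, df=df, p_value=p, aic=aic,
                        status=status, latent_corr={("beh", "wmi"): corr},
                        n_subjects=88)


class TestSelectModel:
    def test_no_eligible_fit_gives_zero(self):
        fits = {
            ModelKind.INDEPENDENT_FACTOR: _result(
                ModelKind.INDEPENDENT_FACTOR, -5, p=0.01),
            ModelKind.COGNITIVE_MEDIATION: _result(
                ModelKind.COGNITIVE_MEDIATION, -9, status=FitStatus.RED),
            ModelKind.BRAIN_MEDIATION: _result(
                ModelKind.BRAIN_MEDIATION, -9, corr=1.2),
            ModelKind.COMMON_FACTOR: _result(
                ModelKind.COMMON_FACTOR, -9, status=FitStatus.BLUE),
        }
        code, diag = vp.select_model(fits)
        assert code == 0
        assert diag["eligible"] == []
        assert diag["n_red"] == 1 and diag["n_blue"] == 1

    def test_single_eligible_model_wins_regardless_of_aic(self):
        fits = {
            ModelKind.INDEPENDENT_FACTOR: _result(
                ModelKind.INDEPENDENT_FACTOR, +10),
            ModelKind.COGNITIVE_MEDIATION: _result(
                ModelKind.COGNITIVE_MEDIATION, -20, p=0.02),
        }
        code, _ = vp.select_model(fits)
        assert code == MODEL_CODES[ModelKind.INDEPENDENT_FACTOR]

    def test_exact_tie_goes_to_larger_df_then_fixed_order(self):
        fits = {
            ModelKind.COMMON_FACTOR: _result(ModelKind.COMMON_FACTOR, -4, df=3),
            ModelKind.COGNITIVE_MEDIATION: _result(
                ModelKind.COGNITIVE_MEDIATION, -4, df=4),
        }
        code, diag = vp.select_model(fits)
        assert code == MODEL_CODES[ModelKind.COGNITIVE_MEDIATION]
        assert diag["tie_broken_against"] == ["common"]
        # equal df as well: fixed preference order decides
        fits = {
            ModelKind.COGNITIVE_MEDIATION: _result(
                ModelKind.COGNITIVE_MEDIATION, -4),
            ModelKind.INDEPENDENT_FACTOR: _result(
                ModelKind.INDEPENDENT_FACTOR, -4),
        }
        code, _ = vp.select_model(fits)
        assert code == MODEL_CODES[ModelKind.INDEPENDENT_FACTOR]

    def test_boundary_p_and_corr_are_ineligible_and_eligible(self):
        """p must strictly exceed the threshold; |corr| = 1 is still kept."""
        at_p = {ModelKind.INDEPENDENT_FACTOR: _result(
            ModelKind.INDEPENDENT_FACTOR, -4, p=0.05)}
        assert vp.select_model(at_p)[0] == 0
        at_corr = {ModelKind.INDEPENDENT_FACTOR: _result(
            ModelKind.INDEPENDENT_FACTOR, -4, corr=1.0)}
        assert vp.select_model(at_corr)[0] == MODEL_CODES[
            ModelKind.INDEPENDENT_FACTOR]


class TestClusterThreshold:
    def test_299_removed_300_kept_at_300mm3(self):
        vol = np.zeros((350, 1, 1), dtype=np.int16)
        vol[:299, 0, 0] = 1
        assert vp.cluster_threshold(vol, 300.0).sum() == 0
        vol[:300, 0, 0] = 1
        out = vp.cluster_threshold(vol, 300.0)
        assert out.sum() == 300

    def test_threshold_of_one_voxel_volume_is_identity(self):
        rng = np.random.default_rng(4)
        vol = rng.integers(0, 3, size=(6, 6, 6)).astype(np.int16)
        np.testing.assert_array_equal(vp.cluster_threshold(vol, 1.0), vol)

    def test_diagonal_voxels_one_component_under_26_two_under_6(self):
        vol = np.zeros((2, 2, 2), dtype=np.int16)
        vol[0, 0, 0] = vol[1, 1, 1] = 1   # touch only at a corner
        kept26 = vp.cluster_threshold(vol, 2.0, connectivity=26)
        assert kept26.sum() == 2          # one 2-voxel component survives
        kept6 = vp.cluster_threshold(vol, 2.0, connectivity=6)
        assert kept6.sum() == 0           # two 1-voxel components die

    def test_labels_clustered_separately(self):
        vol = np.zeros((4, 1, 1), dtype=np.int16)
        vol[:2, 0, 0] = 1
        vol[2:, 0, 0] = 2                 # adjacent but different labels
        out = vp.cluster_threshold(vol, 3.0)
        assert out.sum() == 0             # each label's component has size 2

    def test_voxel_volume_scales_threshold(self):
        vol = np.zeros((5, 1, 1), dtype=np.int16)
        vol[:2, 0, 0] = 1
        assert vp.cluster_threshold(vol, 16.0, voxel_volume=8.0).sum() == 2
        assert vp.cluster_threshold(vol, 17.0, voxel_volume=8.0).sum() == 0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            vp.cluster_threshold(np.zeros((2, 2, 2)), 0.0)
        with pytest.raises(ValueError):
            vp.cluster_threshold(np.zeros((2, 2, 2)), 10.0, connectivity=4)


class TestOverlap:
    def _skel(self, shape, n_true):
        mask = np.zeros(shape, dtype=bool)
        mask.ravel()[:n_true] = True
        return vp.SkeletonMask(mask=mask, threshold=0.2)

    def test_direct_formula(self):
        skel = self._skel((10, 10, 1), 100)
        sel = np.zeros((10, 10, 1), dtype=np.int16)
        sel.ravel()[:16] = 2
        assert vp.overlap_statistic(sel, skel, 2) == 16.0

    def test_full_detection_is_100(self):
        skel = self._skel((5, 5, 1), 25)
        sel = np.full((5, 5, 1), 3, dtype=np.int16)
        assert vp.overlap_statistic(sel, skel, 3) == 100.0

    def test_table_partitions_skeleton(self):
        rng = np.random.default_rng(9)
        skel = self._skel((8, 8, 2), 100)
        sel = np.where(skel.mask, rng.integers(0, 5, size=(8, 8, 2)), 0)
        table = vp.overlap_table(sel.astype(np.int16), skel)
        assert table["overlap_pct"].sum() == pytest.approx(100.0)

    def test_empty_skeleton_is_an_error(self):
        skel = self._skel((2, 2, 1), 0)
        with pytest.raises(ValueError, match="empty skeleton"):
            vp.overlap_statistic(np.zeros((2, 2, 1), dtype=int), skel, 1)


class TestConjunction:
    def test_disjoint_and_superset(self):
        sel = np.zeros((4, 4, 1), dtype=np.int16)
        sel[:2] = 2
        labels = np.zeros((4, 4, 1), dtype=np.int16)
        labels[3:] = 7                    # disjoint from the map
        out = vp.conjunction_with_labels(sel, labels, 2)
        assert out.loc[0, "n_voxels"] == 0
        labels[:] = 7                     # superset
        out = vp.conjunction_with_labels(sel, labels, 2)
        assert out.loc[0, "n_voxels"] == 8

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(12)
        sel = rng.integers(0, 3, size=(6, 6, 3)).astype(np.int16)
        labels = rng.integers(0, 5, size=(6, 6, 3)).astype(np.int16)
        out = vp.conjunction_with_labels(sel, labels, 2).set_index("label")
        for lab in np.unique(labels[labels != 0]):
            count = sum(
                1
                for i in range(6) for j in range(6) for k in range(3)
                if sel[i, j, k] == 2 and labels[i, j, k] == lab
            )
            assert out.loc[lab, "n_voxels"] == count
        assert out["n_voxels"].is_monotonic_decreasing

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            vp.conjunction_with_labels(np.zeros((2, 2, 1), dtype=int),
                                       np.zeros((3, 2, 1), dtype=int), 1)


class TestFaMdCorrelation:
    def test_md_equal_negfa_gives_unit_correlation(self):
        rng = np.random.default_rng(3)
        fa = rng.uniform(0.3, 0.8, size=(3, 3, 1, 20))
        md = -fa
        skel = vp.SkeletonMask(mask=np.ones((3, 3, 1), dtype=bool), threshold=0.2)
        r, median, counts, edges = vp.fa_md_correlation_map(fa, md, skel)
        np.testing.assert_allclose(r, 1.0)
        assert median == pytest.approx(1.0)

    def test_independent_noise_has_null_median(self):
        rng = np.random.default_rng(7)
        fa = rng.uniform(0.3, 0.8, size=(10, 10, 1, 1000))
        md = rng.uniform(0.6, 1.0, size=(10, 10, 1, 1000))
        skel = vp.SkeletonMask(mask=np.ones((10, 10, 1), dtype=bool),
                               threshold=0.2)
        _, median, _, _ = vp.fa_md_correlation_map(fa, md, skel)
        assert abs(median) < 0.02

    def test_outside_skeleton_is_nan_and_histogram_counts_match(self):
        rng = np.random.default_rng(8)
        fa = rng.uniform(0.3, 0.8, size=(4, 4, 1, 30))
        md = rng.uniform(0.6, 1.0, size=(4, 4, 1, 30))
        mask = np.zeros((4, 4, 1), dtype=bool)
        mask[:2] = True
        skel = vp.SkeletonMask(mask=mask, threshold=0.2)
        r, _, counts, _ = vp.fa_md_correlation_map(fa, md, skel)
        assert np.isnan(r[~mask]).all()
        assert counts.sum() == mask.sum()


class TestRunSelectionSmall:
    def test_selection_respects_skeleton_and_filters(self):
        cohort, _, truth, vols = make_region_dataset(
            ModelKind.INDEPENDENT_FACTOR, shape=(2, 2, 1), seed=21)
        # carve one voxel out of the skeleton for one subject
        vols.fa[0, 0, 0, 3] = 0.1
        sel = vp.run_selection(vols, cohort)
        assert sel.selected[0, 0, 0] == 0
        assert not sel.skeleton.mask[0, 0, 0]
        nz = sel.selected != 0
        assert nz.any()
        assert (sel.p_value[nz] > 0.05).all()
        assert (sel.latent_corr[nz] <= 1.0).all()
        assert (sel.status[nz] == 1).all()

    def test_cohort_volume_mismatch_rejected(self):
        cohort, _, _, vols = make_region_dataset(
            ModelKind.INDEPENDENT_FACTOR, shape=(1, 1, 1), seed=22)
        with pytest.raises(ValueError, match="frames"):
            vp.run_selection(vols, cohort.iloc[:-1])


class TestThreeIndicatorVariant:
    def test_selection_and_pathmap_with_stroop_indicator(self):
        """The broader three-RT behavioral construct drives the same pipeline:
        cognitive-mediation truth is still recovered and the BEH->WMI path
        test fires in a region with a true effect."""
        cohort, _, truth, vols = make_region_dataset(
            ModelKind.COGNITIVE_MEDIATION, shape=(2, 2, 1), seed=55,
            tasks=("verbal", "spatial", "stroop"))
        sel = vp.run_selection(vols, cohort, n_indicators=3)
        assert sel.n_indicators == 3
        code = MODEL_CODES[ModelKind.COGNITIVE_MEDIATION]
        assert (sel.selected == code).mean() >= 0.5
        delta, _ = vp.path_significance_map(vols, cohort, "beh-wm",
                                            n_indicators=3)
        assert (delta > 0).all()


class TestPathSignificanceMap:
    def test_consistency_with_chi_square_difference(self):
        cohort, _, truth, vols = make_region_dataset(
            ModelKind.INDEPENDENT_FACTOR, shape=(2, 2, 1), seed=23)
        delta, skel = vp.path_significance_map(vols, cohort, "age-wm")
        assert delta.shape == skel.mask.shape
        assert (delta >= 0).all()
        # the independent region has a true age->WMI path: strong signal
        assert (delta > sc.critical_value(0.01, 1)).mean() > 0.5
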