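"""Imputation, exclusion flagging, replicate averaging, PCA screen, log2."""

import numpy as np
import pandas as pd
import pytest

from metabocurate.curation import (
    MISSING_BMI,
    NON_FASTING,
    PCA_OUTLIER,
    OutlierParams,
    average_blinded_replicates,
    detect_pca_outliers,
    flag_sample_exclusions,
    impute_below_lod,
    log2_transform,
)
from metabocurate.datamodel import MeasurementFlag, WellRole

from conftest import build_matrix, gaussian_cohort_matrix


class TestImputation:
    def test_imputed_value_is_half_lod(self):
        m = build_matrix([[np.nan]], ["CA"], flags=[["BELOW_LOD"]],
                         lods={"CA": {"plate01": 0.04}})
        out = impute_below_lod(m)
        assert out.values.at["S1", "CA"] == pytest.approx(0.02)
        assert out.flags.at["S1", "CA"] == MeasurementFlag.BELOW_LOD.value

    def test_no_censored_cells_is_a_no_op(self):
        m = build_matrix([[1.0, 2.0], [3.0, 4.0]], ["CA", "GCA"])
        out = impute_below_lod(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_exactly_the_censored_cells_change(self):
        vals = [[np.nan, 1.0], [2.0, np.nan], [np.nan, 3.0]]
        flags = [["BELOW_LOD", "VALID"], ["VALID", "BELOW_LOD"], ["BELOW_LOD", "VALID"]]
        lods = {"CA": {"p1": 0.2, "p2": 0.4}, "GCA": {"p1": 0.1, "p2": 0.3}}
        m = build_matrix(vals, ["CA", "GCA"], plate_ids=["p1", "p2", "p2"],
                         flags=flags, lods=lods)
        out = impute_below_lod(m)
        changed = (out.values != m.values) & out.values.notna() & m.values.isna()
        assert int(changed.to_numpy().sum()) == 3
        assert out.values.at["S1", "CA"] == pytest.approx(0.1)   # p1 LOD 0.2 / 2
        assert out.values.at["S2", "GCA"] == pytest.approx(0.15)  # p2 LOD 0.3 / 2
        assert out.values.at["S3", "CA"] == pytest.approx(0.2)   # p2 LOD 0.4 / 2

    def test_missing_lod_is_an_error_listing_cells(self):
        m = build_matrix([[np.nan]], ["CA"], flags=[["BELOW_LOD"]])
        with pytest.raises(ValueError, match="no LOD.*CA"):
            impute_below_lod(m)

    def test_below_lloq_values_retained_as_reported(self):
        m = build_matrix([[0.07]], ["CA"], flags=[["BELOW_LLOQ"]],
                         lods={"CA": {"plate01": 0.04}})
        out = impute_below_lod(m)
        assert out.values.at["S1", "CA"] == pytest.approx(0.07)


class TestExclusionFlags:
    def test_non_fasting_flagged_but_row_kept(self):
        m = build_matrix([[1.0], [2.0]], ["CA"], is_fasting=[False, True])
        rep = flag_sample_exclusions(m.samples)
        assert rep.at["S1", NON_FASTING] and rep.at["S1", "excluded"]
        assert rep.at["S1", "flagged_at_level"] == 4
        assert "S1" in m.sample_ids  # flagging does not remove the row

    def test_complete_metadata_gives_empty_report(self):
        m = build_matrix([[1.0], [2.0]], ["CA"])
        rep = flag_sample_exclusions(m.samples)
        assert not rep["excluded"].any()

    def test_multiple_reasons_counted_once(self):
        m = build_matrix([[1.0]], ["CA"], is_fasting=[False], has_bmi=[False])
        rep = flag_sample_exclusions(m.samples)
        assert rep.at["S1", NON_FASTING] and rep.at["S1", MISSING_BMI]
        assert rep["excluded"].sum() == 1
        assert rep.at["S1", "reasons"] == f"{NON_FASTING};{MISSING_BMI}"

    def test_toggles_disable_checks(self):
        m = build_matrix([[1.0]], ["CA"], has_bmi=[False], has_medication_record=[False])
        rep = flag_sample_exclusions(m.samples, check_bmi=False, check_medication=False)
        assert not rep["excluded"].any()

    def test_only_cohort_rows_considered(self):
        m = build_matrix([[1.0], [2.0]], ["CA"], roles=[WellRole.NIST.value,
                                                        WellRole.COHORT.value])
        rep = flag_sample_exclusions(m.samples)
        assert list(rep.index) == ["S2"]


class TestReplicateAveraging:
    def test_singleton_rows_pass_through(self):
        m = build_matrix([[1.5], [2.5]], ["CA"])
        out = average_blinded_replicates(m)
        assert list(out.values["CA"]) == [1.5, 2.5]
        assert list(out.values.index) == ["SUB1", "SUB2"]

    def test_duplicate_and_triplicate_means(self):
        m = build_matrix(
            [[4.0], [6.0], [2.0], [3.0], [10.0]],
            ["CA"],
            replicate_groups=["G1", "G1", "G2", "G2", "G2"],
            subject_ids=["A", "A", "B", "B", "B"],
        )
        out = average_blinded_replicates(m)
        assert out.values.at["A", "CA"] == pytest.approx(5.0)
        assert out.values.at["B", "CA"] == pytest.approx(5.0)

    def test_group_spanning_subjects_is_an_error(self):
        m = build_matrix([[1.0], [2.0]], ["CA"], replicate_groups=["G1", "G1"],
                         subject_ids=["A", "B"])
        with pytest.raises(ValueError, match="spans subjects"):
            average_blinded_replicates(m)

    def test_unimputed_values_rejected(self):
        m = build_matrix([[np.nan]], ["CA"], flags=[["BELOW_LOD"]])
        with pytest.raises(ValueError, match="impute"):
            average_blinded_replicates(m)


class TestPCAOutliers:
    def test_identical_subjects_no_outliers(self):
        X = np.ones((10, 3))
        rep = detect_pca_outliers(gaussian_cohort_matrix(X))
        assert not rep[PCA_OUTLIER].any()

    def test_displaced_subject_flagged_eigendecomposition_oracle(self):
        """A 12-SD spike is found, matching a direct covariance eigen oracle."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((500, 15))
            X[7, 0] = 12.0
            rep = detect_pca_outliers(gaussian_cohort_matrix(X))
            assert set(rep.index[rep[PCA_OUTLIER]]) == {"S8"}

            # oracle: eigendecompose the standardized covariance directly
            Xs = (X - X.mean(0)) / X.std(0, ddof=1)
            w, v = np.linalg.eigh(np.cov(Xs.T))
            order = np.argsort(w)[::-1]
            w, v = w[order], v[:, order]
            scores = Xs @ v
            k = int(np.searchsorted(np.cumsum(w / w.sum()), 0.90, side="right")) + 1
            z = (scores[:, :k] - scores[:, :k].mean(0)) / scores[:, :k].std(0, ddof=1)
            d = np.sqrt((z**2).sum(axis=1))
            assert set(np.nonzero(d > 7.0)[0]) == {7}
            assert rep["distance"].to_numpy() == pytest.approx(d, rel=1e-8)

    def test_clean_gaussian_cohorts_produce_no_flags(self):
        for seed in range(20):
            X = np.random.default_rng(seed).standard_normal((500, 15))
            rep = detect_pca_outliers(gaussian_cohort_matrix(X))
            assert not rep[PCA_OUTLIER].any()

    def test_flags_invariant_to_analyte_rescaling(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 10))
        X[5] += 15.0
        m1 = gaussian_cohort_matrix(X)
        m2 = gaussian_cohort_matrix(X * rng.uniform(0.1, 50.0, size=10))
        r1, r2 = detect_pca_outliers(m1), detect_pca_outliers(m2)
        assert r1[PCA_OUTLIER].tolist() == r2[PCA_OUTLIER].tolist()
        assert r1["distance"].to_numpy() == pytest.approx(r2["distance"].to_numpy())

    def test_per_component_mode_uses_max_z(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 8))
        rep = detect_pca_outliers(gaussian_cohort_matrix(X),
                                  OutlierParams(method="per_component"))
        assert rep["distance"].to_numpy() == pytest.approx(rep["max_abs_z"].to_numpy())

    def test_cumulative_variance_selection_minimum_one(self):
        X = np.random.default_rng(0).standard_normal((50, 4))
        rep = detect_pca_outliers(gaussian_cohort_matrix(X),
                                  OutlierParams(cum_var_threshold=1e-9))
        assert not rep[PCA_OUTLIER].any()  # one PC selected, nothing extreme

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError, match=">= 3 rows"):
            detect_pca_outliers(gaussian_cohort_matrix(np.ones((2, 5))))


class TestLog2:
    def test_reference_values(self):
        m = build_matrix([[1.0, 2.0, 0.02]], ["A", "B", "C"])
        out = log2_transform(m)
        assert out.values.at["S1", "A"] == 0.0
        assert out.values.at["S1", "B"] == 1.0
        assert out.values.at["S1", "C"] == pytest.approx(-5.6439, abs=1e-4)

    def test_non_positive_values_rejected_with_cell_names(self):
        m = build_matrix([[1.0, -2.0]], ["A", "B"])
        with pytest.raises(ValueError, match="S1.*B"):
            log2_transform(m)
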