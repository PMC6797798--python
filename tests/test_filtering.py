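"""Replicate CV, one-way ICC (vs independent oracles), censoring filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabocurate.datamodel import MeasurementFlag, WellRole
from metabocurate.filtering import (
    FilterThresholds,
    apply_analyte_filters,
    compute_lod_fraction,
    compute_replicate_cv,
    compute_replicate_icc,
    oneway_icc,
)

from conftest import build_matrix

C = WellRole.COHORT.value


def replicate_matrix(groups_per_analyte, analyte="CA"):
    """Build a matrix whose rows are replicate groups of one analyte."""
    vals, gids, subs = [], [], []
    for gi, g in enumerate(groups_per_analyte):
        for v in g:
            vals.append([v])
            gids.append(f"G{gi}")
            subs.append(f"SUB{gi}")
    return build_matrix(vals, [analyte], replicate_groups=gids, subject_ids=subs)


def icc_sums_of_squares_oracle(groups):
    """Brute-force one-way ICC via explicit elementwise sums of squares."""
    groups = [list(g) for g in groups if len(g) >= 2]
    g = len(groups)
    allv = [v for grp in groups for v in grp]
    n = len(allv)
    grand = sum(allv) / n
    ssb = sum(len(grp) * (sum(grp) / len(grp) - grand) ** 2 for grp in groups)
    ssw = sum((v - sum(grp) / len(grp)) ** 2 for grp in groups for v in grp)
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    k0 = (n - sum(len(grp) ** 2 for grp in groups) / n) / (g - 1)
    return (msb - msw) / (msb + (k0 - 1) * msw)


class TestReplicateCV:
    def test_identical_duplicates_have_zero_cv(self):
        m = replicate_matrix([(10.0, 10.0)])
        assert compute_replicate_cv(m)["CA"] == 0.0

    def test_hand_arithmetic_oracle(self):
        m = replicate_matrix([(90.0, 110.0)])
        assert compute_replicate_cv(m)["CA"] == pytest.approx(np.sqrt(200) / 100)

    def test_mean_aggregation_of_group_cvs(self):
        # group CVs 10% and 30% -> mean 20%
        g1 = (100 * (1 - 0.1 / np.sqrt(2)), 100 * (1 + 0.1 / np.sqrt(2)))
        g2 = (100 * (1 - 0.3 / np.sqrt(2)), 100 * (1 + 0.3 / np.sqrt(2)))
        m = replicate_matrix([g1, g2])
        assert compute_replicate_cv(m)["CA"] == pytest.approx(0.2)
        assert compute_replicate_cv(m, "median")["CA"] == pytest.approx(0.2)
        assert compute_replicate_cv(m, "rms")["CA"] == pytest.approx(
            np.sqrt((0.01 + 0.09) / 2)
        )

    def test_groups_without_two_valid_values_skipped(self):
        m = replicate_matrix([(90.0, 110.0), (5.0,)])
        assert compute_replicate_cv(m)["CA"] == pytest.approx(np.sqrt(200) / 100)

    def test_no_usable_group_gives_nan(self):
        m = build_matrix([[1.0], [2.0]], ["CA"])  # no replicate groups at all
        assert np.isnan(compute_replicate_cv(m)["CA"])

    def test_censored_members_do_not_enter_cv(self):
        m = replicate_matrix([(90.0, 110.0), (1.0, 1.0)])
        m.flags.loc[["S3", "S4"], "CA"] = MeasurementFlag.BELOW_LOD.value
        m.values.loc[["S3", "S4"], "CA"] = np.nan
        assert compute_replicate_cv(m)["CA"] == pytest.approx(np.sqrt(200) / 100)


class TestICC:
    def test_identical_replicates_distinct_groups_gives_one(self):
        m = replicate_matrix([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert compute_replicate_icc(m)["CA"] == pytest.approx(1.0)

    def test_hand_anova_boundary_design(self):
        """(0,2),(2,4),(4,6): MSB=8, MSW=2 -> ICC = 0.6 exactly, failing > 0.6."""
        assert oneway_icc([(0, 2), (2, 4), (4, 6)]) == 0.6
        m = replicate_matrix([(0.0, 2.0), (2.0, 4.0), (4.0, 6.0)])
        icc = compute_replicate_icc(m)["CA"]
        assert icc == 0.6
        assert not icc > FilterThresholds().icc_min

    def test_degenerate_all_identical_gives_nan(self):
        assert np.isnan(oneway_icc([(5.0, 5.0), (5.0, 5.0)]))

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_sums_of_squares_oracle_on_random_designs(self, k):
        rng = np.random.default_rng(42 + k)
        for _ in range(100):
            g = rng.integers(3, 21)
            groups = [rng.normal(rng.normal(0, 2), 1, size=k).tolist() for _ in range(g)]
            assert oneway_icc(groups) == pytest.approx(
                icc_sums_of_squares_oracle(groups), abs=1e-12
            )

    def test_matches_balanced_f_statistic_identity(self):
        """Balanced one-way ICC equals (F-1)/(F+k-1) with F from ANOVA."""
        rng = np.random.default_rng(5)
        groups = [rng.normal(rng.normal(0, 1), 0.5, size=3) for _ in range(10)]
        F = stats.f_oneway(*groups).statistic
        assert oneway_icc(groups) == pytest.approx((F - 1) / (F + 3 - 1), rel=1e-10)

    def test_matches_pingouin_icc1(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        groups = [rng.normal(rng.normal(0, 2), 1, size=2) for _ in range(12)]
        long = pd.DataFrame(
            [(f"t{i}", j, v) for i, g in enumerate(groups) for j, v in enumerate(g)],
            columns=["target", "rater", "value"],
        )
        ref = pingouin.intraclass_corr(long, targets="target", raters="rater",
                                       ratings="value")
        icc1 = float(ref["ICC"].iloc[0])  # first row: one-way single-rater ICC(1,1)
        assert oneway_icc(groups) == pytest.approx(icc1, abs=1e-6)

    def test_zero_between_subject_variance_centers_on_zero(self):
        """With no subject signal the ICC estimate is unbiased around 0."""
        rng = np.random.default_rng(0)
        iccs = []
        for _ in range(40):
            groups = [rng.normal(0, 1, size=2) for _ in range(220)]
            iccs.append(oneway_icc(groups))
        assert abs(np.mean(iccs)) < 0.05

    def test_unbalanced_design_uses_corrected_group_size(self):
        groups = [(0.0, 2.0), (2.0, 4.0, 6.0), (4.0, 6.0)]
        assert oneway_icc(groups) == pytest.approx(icc_sums_of_squares_oracle(groups))

    def test_half_lod_policy_recovers_censored_groups(self):
        m = replicate_matrix([(0.5, 0.7), (1.0, 1.2), (np.nan, 0.06)])
        m.flags.loc["S5", "CA"] = MeasurementFlag.BELOW_LOD.value
        m.analytes[0] = type(m.analytes[0])("CA", lod={"plate01": 0.1})
        icc_half = compute_replicate_icc(m, "half_lod")["CA"]
        icc_excl = compute_replicate_icc(m, "exclude_group")["CA"]
        assert icc_half == pytest.approx(oneway_icc([(0.5, 0.7), (1.0, 1.2), (0.05, 0.06)]))
        assert icc_excl == pytest.approx(oneway_icc([(0.5, 0.7), (1.0, 1.2)]))


class TestLodFraction:
    def test_no_censoring_gives_zero(self):
        m = build_matrix([[1.0], [2.0]], ["CA"])
        assert compute_lod_fraction(m)["CA"] == 0.0

    @pytest.mark.parametrize("n_censored,passes", [(4, True), (5, False)])
    def test_boundary_at_forty_percent(self, n_censored, passes):
        vals = [[np.nan if i < n_censored else 1.0] for i in range(10)]
        flags = [["BELOW_LOD" if i < n_censored else "VALID"] for i in range(10)]
        m = build_matrix(vals, ["CA"], flags=flags)
        frac = compute_lod_fraction(m)["CA"]
        assert frac == pytest.approx(n_censored / 10)
        assert bool(frac <= FilterThresholds().lod_frac_max) is passes

    def test_qc_wells_excluded_from_denominator(self):
        vals = [[np.nan], [1.0], [np.nan]]
        flags = [["BELOW_LOD"], ["VALID"], ["BELOW_LOD"]]
        m = build_matrix(vals, ["CA"], flags=flags,
                         roles=[C, C, WellRole.NIST.value])
        assert compute_lod_fraction(m)["CA"] == pytest.approx(0.5)


class TestApplyFilters:
    def test_planted_failures_removed_clean_retained(self, seed17_dataset):
        from metabocurate.scaling import apply_scale_factors, compute_scale_factors

        m, _, truth = seed17_dataset
        m2 = apply_scale_factors(m, compute_scale_factors(m))
        m3, report = apply_analyte_filters(m2)
        clean = set(truth.clean_analytes(m.analyte_ids))
        # every clean analyte is retained; planted censoring/ICC failures removed
        assert clean <= set(m3.analyte_ids)
        for a, mode in truth.bad_analyte_labels.items():
            if mode in ("HIGH_CENSORING", "LOW_ICC"):
                assert a not in m3.analyte_ids, (a, mode)
        assert report.loc[~report.retained, "failure_reasons"].str.len().gt(0).all()

    def test_vacuous_thresholds_retain_everything(self, default_dataset):
        # a defect-free cohort: every analyte has usable replicate groups
        m, _, _ = default_dataset
        thr = FilterThresholds(cv_max=np.inf, icc_min=-0.999, lod_frac_max=1.0)
        m3, report = apply_analyte_filters(m, thr)
        assert m3.analyte_ids == m.analyte_ids
        assert report.retained.all()

    def test_column_order_preserved_and_report_partitions(self, seed17_dataset):
        m, _, _ = seed17_dataset
        m3, report = apply_analyte_filters(m)
        assert [a for a in m.analyte_ids if a in set(m3.analyte_ids)] == m3.analyte_ids
        assert sorted(report.index) == sorted(m.analyte_ids)
        assert set(report.index[report.retained]) == set(m3.analyte_ids)

    def test_shuffled_columns_give_identical_statistics(self, seed17_dataset):
        m, _, _ = seed17_dataset
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(m.analyte_ids))
        shuffled = m.subset_analytes(m.analyte_ids)
        shuffled.values = shuffled.values[perm]
        shuffled.flags = shuffled.flags[perm]
        shuffled.analytes = sorted(shuffled.analytes, key=lambda a: perm.index(a.analyte_id))
        _, r1 = apply_analyte_filters(m)
        _, r2 = apply_analyte_filters(shuffled)
        pd.testing.assert_frame_equal(r1.sort_index(), r2.sort_index())

    def test_cv_and_icc_scale_invariant(self):
        m = replicate_matrix([(90.0, 110.0), (50.0, 60.0), (20.0, 24.0)])
        cv1, icc1 = compute_replicate_cv(m)["CA"], compute_replicate_icc(m)["CA"]
        m.values = m.values * 37.5
        assert compute_replicate_cv(m)["CA"] == pytest.approx(cv1)
        assert compute_replicate_icc(m)["CA"] == pytest.approx(icc1)

    def test_analyte_without_replicates_fails_with_reason(self):
        m = build_matrix([[1.0], [2.0]], ["CA"])
        _, report = apply_analyte_filters(m)
        assert not report.at["CA", "retained"]
        assert "NO_REPLICATES" in report.at["CA", "failure_reasons"]
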