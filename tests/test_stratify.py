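"""Classification bands, category assignment and cohort summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgstrat import (assess_blockade, assign_category, background_correct_ig,
                     classify_achr_fold, classify_igg_binding,
                     classify_mac_fold, cohort_summary, fold_change,
                     generate_cohort_tables, load_reference_cohort,
                     patient_readouts, spearman_correlation)
from mgstrat.stratify import class_rank


class TestElementary:
    @pytest.mark.parametrize("a,b,expected", [(70, 5, 65.0), (10, 10, 0.0), (5, 12, 0.0)])
    def test_background_correction(self, a, b, expected):
        assert background_correct_ig(a, b) == pytest.approx(expected)

    def test_background_correction_propagates_missing(self):
        assert math.isnan(background_correct_ig(float("nan"), 5))

    def test_background_correction_range_checked(self):
        with pytest.raises(ValueError):
            background_correct_ig(120, 5)

    @pytest.mark.parametrize("t,n,expected", [(30, 30, 1.0), (30, 60, 0.5), (0, 60, 0.0)])
    def test_fold_change(self, t, n, expected):
        assert fold_change(t, n) == pytest.approx(expected)

    def test_fold_change_requires_positive_control(self):
        with pytest.raises(ValueError, match="control"):
            fold_change(10, 0)


class TestClassBands:
    @pytest.mark.parametrize("fc,expected", [
        (1.5, "-"), (1.0, "-"), (0.9, "-"), (0.8, "-"),
        (0.7, "+"), (0.6, "+"),
        (0.55, "++"), (0.45, "++"), (0.3, "++"), (0.2, "++"),
    ])
    def test_achr_bands(self, fc, expected):
        assert classify_achr_fold(fc) == expected

    @pytest.mark.parametrize("fc,expected", [
        (0.9, "-"), (1.0, "-"), (1.1, "-"), (1.3, "-"),
        (1.5, "+"), (1.8, "+"),
        (2.0, "++"), (2.3, "++"),
        (3.0, "+++"), (3.5, "+++"), (4.0, "+++"),
    ])
    def test_mac_bands(self, fc, expected):
        assert classify_mac_fold(fc) == expected

    @pytest.mark.parametrize("pct,expected", [
        (0, "-"), (10, "-"), (14.9, "-"),
        (15, "+"), (39.9, "+"),
        (40, "++"), (50, "++"), (64.9, "++"),
        (65, "+++"), (70, "+++"), (100, "+++"),
    ])
    def test_igg_bands(self, pct, expected):
        assert classify_igg_binding(pct) == expected

    def test_fold_of_one_is_negative_on_both_scales(self):
        assert classify_achr_fold(1.0) == "-"
        assert classify_mac_fold(1.0) == "-"

    @pytest.mark.parametrize("classify", [classify_achr_fold, classify_mac_fold])
    def test_nonpositive_fold_rejected(self, classify):
        for bad in (0.0, -0.5, float("nan")):
            with pytest.raises(ValueError):
                classify(bad)

    def test_out_of_range_percentage_rejected(self):
        with pytest.raises(ValueError):
            classify_igg_binding(101)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.01, 5), st.floats(0.01, 5))
    def test_achr_classifier_monotone_nonincreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert class_rank(classify_achr_fold(lo)) >= class_rank(classify_achr_fold(hi))

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.01, 5), st.floats(0.01, 5))
    def test_mac_classifier_monotone_nondecreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert class_rank(classify_mac_fold(lo)) <= class_rank(classify_mac_fold(hi))

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 100), st.floats(0, 100))
    def test_igg_classifier_monotone_nondecreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert class_rank(classify_igg_binding(lo)) <= class_rank(classify_igg_binding(hi))


class TestBlockadeAndCategory:
    def test_full_blockade(self):
        assert assess_blockade(0.5, 0.95, 0.5) == "yes"

    def test_no_loss_means_not_applicable(self):
        assert assess_blockade(0.9, 0.95, 0.9) == "na"

    def test_partial_blockade(self):
        assert assess_blockade(0.45, 0.7, 0.45) == "yes_partial"

    def test_unblocked_loss(self):
        assert assess_blockade(0.5, 0.5, 0.5) == "no"

    def test_missing_arm_warns_na(self):
        with pytest.warns(UserWarning, match="missing treatment arm"):
            assert assess_blockade(0.5, float("nan"), 0.5) == "na"

    @pytest.mark.parametrize("achr,blockade,mac,igg,expected", [
        ("++", "yes", "++", "+++", 1),
        ("-", "na", "-", "++", 3),
        ("-", "na", "+", "-", 4),
    ])
    def test_published_row_patterns(self, achr, blockade, mac, igg, expected):
        assert assign_category(achr, blockade, mac, igg) == expected

    def test_assignment_is_total(self):
        for achr in ("-", "+", "++"):
            for blockade in ("yes", "yes_partial", "no", "na"):
                for mac in ("-", "+", "++", "+++"):
                    for igg in ("-", "+", "++", "+++"):
                        assert assign_category(achr, blockade, mac, igg) in (1, 2, 3, 4)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            assign_category("+/-", "yes", "-", "-")


class TestReferenceCohort:
    def test_every_patient_row_reproduces_its_printed_category(self):
        ref = load_reference_cohort()
        assert len(ref) == 19
        assigned = [assign_category(r.achr_class, r.blockade, r.mac_class, r.igg_class)
                    for r in ref.itertuples()]
        assert assigned == ref.category.tolist()

    def test_control_row_carries_no_category(self):
        full = load_reference_cohort(include_control=True)
        assert len(full) == 20
        assert full.category.isna().sum() == 1

    def test_cohort_summary_of_reference_table(self):
        ref = load_reference_cohort()
        s = cohort_summary(ref)
        assert s["counts"] == {1: 9, 2: 3, 3: 1, 4: 6}
        assert s["complement_dependent_n"] == 12
        assert s["complement_dependent_pct"] == 63

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_summary(pd.DataFrame({"category": []}))

    def test_all_category4_cohort_has_zero_complement_fraction(self):
        s = cohort_summary(pd.DataFrame({"category": [4]}))
        assert s["complement_dependent_fraction"] == 0.0


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.rho == pytest.approx(1.0)
        r2 = spearman_correlation([1, 2, 3, 4, 5], [-1, -2, -3, -4, -5])
        assert r2.rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        x, y = rng.normal(size=n), rng.normal(size=n)
        r = spearman_correlation(x, y)
        # independent oracle: rank both vectors, then Pearson on the ranks
        rx = np.argsort(np.argsort(x)).astype(float)
        ry = np.argsort(np.argsort(y)).astype(float)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert r.rho == pytest.approx(oracle, abs=1e-12)
        assert r.ci_low <= r.rho <= r.ci_high
        assert -1 <= r.ci_low <= r.ci_high <= 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            spearman_correlation([1, 2, 3], [1, 2, 3])

    def test_constant_vector_reported_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            r = spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r.rho)


class TestPatientReadouts:
    def test_archetype_cohort_round_trip(self):
        wells = generate_cohort_tables({"cat1": 2, "cat2": 1, "cat3": 1, "cat4": 2}, seed=2)
        out = patient_readouts(wells.drop(columns=["true_category"]))
        truth = wells[["patient_id", "true_category"]].drop_duplicates()
        merged = out.merge(truth, on="patient_id")
        assert (merged.category == merged.true_category).all()
        assert set(merged.loc[merged.category == 1, "blockade"]) <= {"yes", "yes_partial"}

    def test_missing_nhs_control_is_an_error(self):
        wells = generate_cohort_tables({"cat1": 1}, seed=0)
        broken = wells[wells.arm != "NHS_only"].drop(columns=["true_category"])
        with pytest.raises(ValueError, match="NHS_only"):
            patient_readouts(broken)

    def test_unknown_arm_rejected(self):
        wells = generate_cohort_tables({"cat1": 1}, seed=0).drop(columns=["true_category"])
        wells.loc[wells.index[0], "arm"] = "mystery"
        with pytest.raises(ValueError, match="unknown treatment arms"):
            patient_readouts(wells)
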