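"""Spot detection, per-cell sums and positivity calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mgstrat import (SimulationConfig, call_positive, detect_nuclei,
                     detect_spots, generate_field, mac_within_achr_pos,
                     per_cell_spot_sum, percent_positive, segment_cells)


def _seg_label_per_truth_cell(truth, cells):
    t = truth.cells
    labels = cells.cell_labels[t.nucleus_row.round().astype(int),
                               t.nucleus_col.round().astype(int)]
    return dict(zip(t.cell_id, labels))


class TestDetectSpots:
    def test_per_cell_count_recovered_on_noiseless_field(self, segmented_noiseless):
        field, truth, cells = segmented_noiseless
        spots = detect_spots(field, cells, "achr")
        detected = spots.groupby("cell_id").size()
        label_of = _seg_label_per_truth_cell(truth, cells)
        t = truth.cells
        det = np.array([detected.get(label_of[c], 0) for c in t.cell_id])
        assert (det == t.true_achr_spot_count.to_numpy()).mean() >= 0.95

    def test_diffuse_unclustered_signal_yields_no_spots(self, cat1):
        cfg = SimulationConfig(seed=8, image_size=256, n_cells_per_field=30,
                               rapsyn=False, read_noise_sd=0.0, shot_noise=False)
        field, _ = generate_field(cfg, cat1, "NHS_only")
        cells = segment_cells(field, detect_nuclei(field))
        assert len(detect_spots(field, cells, "achr")) == 0

    def test_blank_channel_yields_empty_table(self, segmented_noiseless, cat1):
        cfg = SimulationConfig(seed=9, image_size=256, n_cells_per_field=30,
                               read_noise_sd=0.0, shot_noise=False)
        field, _ = generate_field(cfg, cat1, "medium_only")  # no serum: no MAC
        cells = segment_cells(field, detect_nuclei(field))
        spots = detect_spots(field, cells, "marker")
        assert len(spots) == 0

    def test_unknown_channel_role_rejected(self, segmented_noiseless):
        field, _, cells = segmented_noiseless
        with pytest.raises(ValueError, match="channel role"):
            detect_spots(field, cells, "gfp")

    def test_recovered_sums_track_ground_truth(self, cat1):
        cfg = SimulationConfig(seed=31, image_size=512, n_cells_per_field=120,
                               read_noise_sd=0.0, shot_noise=False)
        field, truth = generate_field(cfg, cat1, "NHS_only")
        cells = segment_cells(field, detect_nuclei(field))
        sums = per_cell_spot_sum(detect_spots(field, cells, "achr"), cells)
        label_of = _seg_label_per_truth_cell(truth, cells)
        by_label = sums.set_index("cell_id")["spot_sum"]
        rec = np.array([by_label.get(label_of[c], 0.0) for c in truth.cells.cell_id])
        rho = spearmanr(rec, truth.cells.true_achr_spot_sum).statistic
        assert rho >= 0.99


class TestPerCellSums:
    def test_summation_and_spotless_cells(self, toy_cells):
        spots = pd.DataFrame({"cell_id": [1, 1, 1, 3], "channel": "achr",
                              "intensity": [10.0, 20.0, 5.0, 7.0]})
        out = per_cell_spot_sum(spots, toy_cells)
        assert out.spot_sum.tolist() == [35.0, 0.0, 7.0]

    def test_partition_conservation(self, toy_cells):
        rng = np.random.default_rng(0)
        spots = pd.DataFrame({"cell_id": rng.integers(1, 4, 50), "channel": "achr",
                              "intensity": rng.uniform(1, 10, 50)})
        out = per_cell_spot_sum(spots, toy_cells)
        assert out.spot_sum.sum() == pytest.approx(spots.intensity.sum())

    def test_unknown_cell_id_rejected(self, toy_cells):
        spots = pd.DataFrame({"cell_id": [4], "channel": "achr", "intensity": [1.0]})
        with pytest.raises(ValueError, match="cell ids"):
            per_cell_spot_sum(spots, toy_cells)


class TestPositivityCalls:
    def test_fixed_threshold(self):
        assert call_positive([0, 10, 100], 50).tolist() == [False, False, True]

    def test_zero_threshold_marks_any_spot_positive(self):
        assert call_positive([0.0, 0.5, 3.0], 0).tolist() == [False, True, True]

    def test_untransfected_field_has_no_positives_at_auto_threshold(self, cat1):
        cfg = SimulationConfig(seed=12, image_size=256, n_cells_per_field=30,
                               transfection_fraction=0.0,
                               read_noise_sd=0.0, shot_noise=False)
        field, _ = generate_field(cfg, cat1, "NHS_only")
        cells = segment_cells(field, detect_nuclei(field))
        sums = per_cell_spot_sum(detect_spots(field, cells, "achr"), cells)["spot_sum"]
        assert call_positive(sums, "otsu").sum() == 0

    def test_auto_threshold_separates_transfected_cells(self, segmented_noiseless):
        field, truth, cells = segmented_noiseless
        sums = per_cell_spot_sum(detect_spots(field, cells, "achr"), cells)["spot_sum"]
        calls = call_positive(sums, "otsu")
        label_of = _seg_label_per_truth_cell(truth, cells)
        t = truth.cells
        called = np.array([calls[label_of[c] - 1] for c in t.cell_id])
        assert (called == t.transfected.to_numpy()).mean() >= 0.95

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError, match="threshold rule"):
            call_positive([1.0], "median")

    def test_threshold_monotonicity_of_percent_positive(self):
        rng = np.random.default_rng(1)
        sums = rng.uniform(0, 100, 200)
        pcts = [percent_positive(call_positive(sums, thr)) for thr in (80, 40, 10, 0)]
        assert all(a <= b for a, b in zip(pcts, pcts[1:]))


class TestPercentages:
    @pytest.mark.parametrize("calls,expected", [
        ([True] * 30 + [False] * 90, 25.0),
        ([False] * 7, 0.0),
        ([True] * 5, 100.0),
    ])
    def test_percent_positive(self, calls, expected):
        assert percent_positive(calls) == pytest.approx(expected)

    def test_percent_positive_of_no_cells_is_missing(self):
        with pytest.warns(UserWarning, match="no cells"):
            assert np.isnan(percent_positive([]))

    @pytest.mark.parametrize("achr,mac,expected", [
        ([True] * 10, [True] * 5 + [False] * 5, 50.0),
        ([True] * 4 + [False] * 2, [False] * 6, 0.0),
        ([True] * 3, [True] * 3, 100.0),
    ])
    def test_mac_within_achr_pos(self, achr, mac, expected):
        assert mac_within_achr_pos(achr, mac) == pytest.approx(expected)

    def test_mac_within_achr_pos_undefined_without_achr_positives(self):
        with pytest.warns(UserWarning, match="no AChR-positive"):
            assert np.isnan(mac_within_achr_pos([False, False], [True, False]))

    def test_double_positive_bounded_by_single_positives(self, segmented_noiseless, cat1):
        cfg = SimulationConfig(seed=13, image_size=256, n_cells_per_field=40,
                               read_noise_sd=0.0, shot_noise=False)
        field, _ = generate_field(cfg, cat1, "plasma_NHS")
        cells = segment_cells(field, detect_nuclei(field))
        achr = call_positive(per_cell_spot_sum(
            detect_spots(field, cells, "achr"), cells)["spot_sum"], "otsu")
        mac = call_positive(per_cell_spot_sum(
            detect_spots(field, cells, "marker"), cells)["spot_sum"], 1.0)
        both = (achr & mac).sum()
        assert both <= min(achr.sum(), mac.sum())
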