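"""Matching, accuracy, RMSE, and size-confusion metrics."""
import itertools
import math

import numpy as np
import pytest

from goldpick.evaluation import (
    accuracy,
    center_rmse,
    default_match_radius,
    match_detections,
    size_confusion,
    write_report,
)
from goldpick.extraction import ExtractionParams, extract_particles
from goldpick.synthetic import SceneSpec, render_scene


def brute_force_min_cost(truth, dets, max_dist):
    """Best one-to-one assignment by enumerating all permutations."""
    n, m = len(truth), len(dets)
    best = (0, math.inf)  # (-matches, total distance)
    if n <= m:
        injections = (zip(range(n), perm) for perm in itertools.permutations(range(m), n))
    else:
        injections = (zip(perm, range(m)) for perm in itertools.permutations(range(n), m))
    for pairing in injections:
        matches, total = 0, 0.0
        for ti, di in pairing:
            d = math.dist(truth[ti], dets[di])
            if d <= max_dist:
                matches += 1
                total += d
        best = min(best, (-matches, total))
    return -best[0], best[1]


class TestMatchDetections:
    def test_identical_points_all_matched_at_zero(self):
        pts = [(3.0, 4.0), (10.0, 2.0), (7.5, 9.0)]
        m = match_detections(pts, pts, 5.0)
        assert len(m.pairs) == 3
        assert all(d == 0.0 for _, _, d in m.pairs)
        assert m.unmatched_truth == () and m.unmatched_detections == ()

    def test_empty_detections_all_truth_unmatched(self):
        m = match_detections([(1.0, 1.0), (2.0, 2.0)], [], 5.0)
        assert m.pairs == () and m.unmatched_truth == (0, 1)

    def test_crossing_configuration_matches_permutation_oracle(self):
        truth = [(0.0, 0.0), (4.0, 0.0), (2.0, 3.0)]
        dets = [(3.5, 0.5), (0.5, 0.5), (2.0, 2.0)]
        m = match_detections(truth, dets, 5.0)
        n_matches, total = brute_force_min_cost(truth, dets, 5.0)
        assert len(m.pairs) == n_matches
        assert sum(d for *_, d in m.pairs) == pytest.approx(total)

    def test_random_instances_match_permutation_oracle(self, rng):
        for _ in range(25):
            truth = [tuple(p) for p in rng.uniform(0, 20, size=(4, 2))]
            dets = [tuple(p) for p in rng.uniform(0, 20, size=(rng.integers(1, 6), 2))]
            m = match_detections(truth, dets, 6.0)
            n_matches, total = brute_force_min_cost(truth, dets, 6.0)
            assert len(m.pairs) == n_matches
            assert sum(d for *_, d in m.pairs) <= total + 1e-9

    def test_matches_respect_radius(self):
        m = match_detections([(0.0, 0.0)], [(10.0, 0.0)], 5.0)
        assert m.pairs == () and m.unmatched_detections == (0,)

    def test_roi_excludes_points_before_matching(self):
        roi = np.zeros((20, 20), bool)
        roi[:, :10] = True  # left half only
        truth = [(2.0, 5.0), (15.0, 5.0)]
        dets = [(2.0, 5.0), (15.0, 5.0)]
        m = match_detections(truth, dets, 5.0, roi=roi)
        assert len(m.pairs) == 1
        assert m.n_truth == 1  # out-of-ROI truth not counted at all

    def test_default_match_radius(self):
        assert default_match_radius(12.0, 1.11) == pytest.approx(2 * 12.0 / 1.11)
        assert default_match_radius(1.0, 1.0) == 5.0


class TestAccuracy:
    def test_perfect_detection(self):
        pts = [(1.0, 1.0)]
        assert accuracy(match_detections(pts, pts, 5.0)) == 1.0

    def test_half_of_612_truth_matched_gives_half(self):
        truth = [(float(10 * i), 0.0) for i in range(612)]
        dets = truth[:306]
        m = match_detections(truth, dets, 5.0)
        assert accuracy(m) == 0.5

    def test_false_positives_do_not_change_accuracy(self):
        truth = [(0.0, 0.0), (10.0, 0.0)]
        base = accuracy(match_detections(truth, truth, 5.0))
        with_fp = accuracy(match_detections(truth, truth + [(50.0, 50.0)], 5.0))
        assert base == with_fp == 1.0

    def test_removing_one_detection_costs_one_over_n(self):
        truth = [(float(10 * i), 0.0) for i in range(8)]
        full = accuracy(match_detections(truth, truth, 5.0))
        drop = accuracy(match_detections(truth, truth[:-1], 5.0))
        assert full - drop == pytest.approx(1 / 8)

    def test_zero_truth_is_an_error(self):
        with pytest.raises(ValueError):
            accuracy(match_detections([], [(1.0, 1.0)], 5.0))


class TestCenterRmse:
    def test_zero_distances(self):
        pts = [(1.0, 2.0), (3.0, 4.0)]
        assert center_rmse(match_detections(pts, pts, 5.0)) == 0.0

    def test_distances_3_and_4(self):
        truth = [(0.0, 0.0), (20.0, 0.0)]
        dets = [(3.0, 0.0), (20.0, 4.0)]
        m = match_detections(truth, dets, 5.0)
        assert center_rmse(m) == pytest.approx(math.sqrt(12.5))

    def test_rigid_shift_gives_shift_magnitude(self):
        truth = [(float(i * 10), 5.0) for i in range(6)]
        dets = [(x + 1.0, y) for x, y in truth]
        assert center_rmse(match_detections(truth, dets, 5.0)) == pytest.approx(1.0)

    def test_rmse_dominates_mean_distance(self, rng):
        for _ in range(10):
            truth = [tuple(p) for p in rng.uniform(0, 50, size=(6, 2))]
            dets = [
                (x + rng.normal(0, 1), y + rng.normal(0, 1)) for x, y in truth
            ]
            m = match_detections(truth, dets, 8.0)
            mean_d = np.mean([d for *_, d in m.pairs])
            assert center_rmse(m) >= mean_d - 1e-12

    def test_per_group_breakdown(self):
        truth = [(0.0, 0.0), (20.0, 0.0)]
        dets = [(3.0, 0.0), (20.0, 4.0)]
        m = match_detections(truth, dets, 5.0)
        overall, per_group = center_rmse(m, detection_groups=[0, 1])
        assert per_group[0] == pytest.approx(3.0)
        assert per_group[1] == pytest.approx(4.0)

    def test_no_matches_is_an_error(self):
        with pytest.raises(ValueError):
            center_rmse(match_detections([(0.0, 0.0)], [], 5.0))


class TestSizeConfusion:
    def test_perfect_two_size_recovery_is_diagonal(self):
        truth = [(0.0, 0.0), (20.0, 0.0), (40.0, 0.0)]
        diams = [6.0, 6.0, 12.0]
        m = match_detections(truth, truth, 5.0)
        table, recall = size_confusion(m, diams, [0, 0, 1])
        assert table.loc[6.0, 0] == 2 and table.loc[12.0, 1] == 1
        assert table.values.sum() == 3
        assert recall == {6.0: 1.0, 12.0: 1.0}

    def test_all_small_mislabelled_large(self):
        truth = [(0.0, 0.0), (20.0, 0.0)]
        m = match_detections(truth, truth, 5.0)
        table, recall = size_confusion(m, [6.0, 6.0], [1, 1])
        assert table.loc[6.0, 1] == 2
        assert recall[6.0] == 0.0

    def test_simulated_scene_through_extraction_is_diagonal(self):
        spec = SceneSpec(height_px=256, width_px=256, counts_per_diameter=(4, 4))
        pair = render_scene(spec, seed=33)
        recs = extract_particles(pair.target_mask, ExtractionParams())
        m = match_detections(pair.truth, recs, 5.0)
        diams = [t.diameter_nm for t in pair.truth]
        table, recall = size_confusion(m, diams, [r.group for r in recs])
        assert table.loc[6.0, 0] == 4 and table.loc[12.0, 1] == 4
        assert table.loc[6.0, 1] == 0 and table.loc[12.0, 0] == 0
        assert all(r == 1.0 for r in recall.values())


def test_write_report_contains_key_metrics(tmp_path):
    truth = [(0.0, 0.0), (20.0, 0.0)]
    m = match_detections(truth, [(0.5, 0.0)], 5.0)
    text = write_report(tmp_path / "report.txt", m, [6.0, 12.0], [0])
    assert "accuracy" in text and "0.5" in text
    assert (tmp_path / "report.txt").read_text() == text
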