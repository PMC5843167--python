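"""Detection evaluation protocol: matching, PR curves, interpolated AP."""

import numpy as np
import pytest

from chirpnet.evaluation import (
    evaluate_single_point,
    match_detections,
    pr_curve,
    precision,
    recall,
    recall_at_precision,
    single_point_ap,
    PRCurve,
)
from chirpnet.postprocess import DetectionEvent


def ev(time, prob=1.0, sid=""):
    return DetectionEvent(time=time, probability=prob, source_id=sid)


# -- independent oracle -------------------------------------------------------

def _oracle_greedy_match(events, gt, tol):
    """Re-implementation of greedy matching used to cross-check pr_curve."""
    order = sorted(range(len(events)), key=lambda i: (-events[i].probability, events[i].time))
    taken = [False] * len(gt)
    tp = set()
    for i in order:
        best, best_d = None, tol + 1e-9  # boundary inclusive under round-off
        for j, g in enumerate(gt):
            d = abs(events[i].time - g)
            if not taken[j] and d <= best_d:
                best, best_d = j, d
        if best is not None:
            taken[best] = True
            tp.add(i)
    return tp


def _oracle_ap(events, gt, tol):
    """Brute-force AP: re-match at every distinct threshold, then integrate
    the max-to-the-right precision envelope over recall."""
    thresholds = sorted({e.probability for e in events}, reverse=True)
    points = []
    for thr in thresholds:
        sub = [e for e in events if e.probability >= thr]
        tp = len(_oracle_greedy_match(sub, gt, tol))
        fp = len(sub) - tp
        points.append((tp / (tp + fp), tp / len(gt)))
    ap = 0.0
    prev_r = 0.0
    for k, (p, r) in enumerate(points):
        env = max(pp for pp, _ in points[k:])
        ap += (r - prev_r) * env
        prev_r = r
    return ap


class TestMatchDetections:
    def test_two_hits_one_miss(self):
        events = [ev(0.102, 0.9), ev(0.290, 0.8), ev(0.600, 0.4)]
        m = match_detections(events, [0.100, 0.300])
        assert (m.n_tp, m.n_fp, m.n_fn) == (2, 1, 0)

    def test_no_events_all_false_negatives(self):
        m = match_detections([], [0.1, 0.2, 0.3])
        assert (m.n_tp, m.n_fp, m.n_fn) == (0, 0, 3)

    def test_tolerance_boundary_excludes_11ms(self):
        m = match_detections([ev(0.111, 0.9)], [0.100])
        assert (m.n_tp, m.n_fp, m.n_fn) == (0, 1, 1)

    def test_tolerance_boundary_includes_10ms(self):
        m = match_detections([ev(0.110, 0.9)], [0.100])
        assert m.n_tp == 1

    def test_each_ground_truth_consumed_once(self):
        events = [ev(0.100, 0.9), ev(0.101, 0.8)]
        m = match_detections(events, [0.100])
        assert (m.n_tp, m.n_fp) == (1, 1)

    def test_higher_probability_claims_nearest_first(self):
        events = [ev(0.105, 0.9), ev(0.098, 0.5)]
        m = match_detections(events, [0.104, 0.097])
        assert dict(m.pairs) == {0: 0, 1: 1}

    def test_shift_invariance(self):
        events = [ev(0.102, 0.9), ev(0.290, 0.8), ev(0.600, 0.4)]
        gt = [0.100, 0.300]
        base = match_detections(events, gt)
        shifted = match_detections(
            [ev(e.time + 5.0, e.probability) for e in events], [g + 5.0 for g in gt]
        )
        assert base.pairs == shifted.pairs

    def test_optimal_matching_never_fewer_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            gt = np.sort(rng.uniform(0, 1, rng.integers(1, 8)))
            events = [ev(t, p) for t, p in zip(rng.uniform(0, 1, 10), rng.random(10))]
            g = match_detections(events, gt, method="greedy")
            o = match_detections(events, gt, method="optimal")
            assert o.n_tp >= g.n_tp


class TestPrecisionRecall:
    def test_precision_formula(self):
        events = [ev(0.102, 0.9), ev(0.290, 0.8), ev(0.600, 0.4)]
        m = match_detections(events, [0.100, 0.300])
        assert precision(m) == pytest.approx(2 / 3)

    def test_all_true_positives(self):
        m = match_detections([ev(0.1), ev(0.3)], [0.1, 0.3])
        assert precision(m) == 1.0

    def test_no_true_positives(self):
        m = match_detections([ev(0.5), ev(0.6), ev(0.7)], [0.1])
        assert precision(m) == 0.0

    def test_zero_detections_precision_convention(self):
        assert precision(match_detections([], [0.1])) == 1.0

    def test_recall_undefined_without_ground_truth(self):
        with pytest.raises(ValueError):
            recall(match_detections([ev(0.1)], []))


class TestPrCurve:
    def test_perfect_detector(self):
        gt = [0.1, 0.3, 0.5]
        events = [ev(t, p) for t, p in zip(gt, [0.9, 0.8, 0.7])]
        curve = pr_curve(events, gt)
        assert curve.average_precision == pytest.approx(1.0)
        assert curve.recall_at_p95 == pytest.approx(1.0)

    def test_never_reaching_p95_scores_zero(self):
        # every threshold mixes one TP with at least one FP: max precision 0.5
        events = [ev(0.1, 0.9), ev(0.9, 0.9)]
        curve = pr_curve(events, [0.1])
        assert curve.precision.max() <= 0.5
        assert curve.recall_at_p95 == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_ap_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_gt = int(rng.integers(1, 8))
        n_ev = int(rng.integers(1, 20))
        gt = list(np.sort(rng.uniform(0, 1.0, n_gt)))
        events = [
            ev(float(t), float(np.round(p, 2)))
            for t, p in zip(rng.uniform(0, 1.0, n_ev), rng.random(n_ev))
        ]
        curve = pr_curve(events, gt)
        assert curve.average_precision == pytest.approx(_oracle_ap(events, gt, 0.010))

    def test_five_call_toy_fixture(self):
        gt = [0.10, 0.20, 0.30, 0.40, 0.50]
        events = [
            ev(0.101, 0.95), ev(0.201, 0.90), ev(0.305, 0.85),
            ev(0.70, 0.80), ev(0.401, 0.75), ev(0.80, 0.40),
        ]
        curve = pr_curve(events, gt)
        assert curve.average_precision == pytest.approx(_oracle_ap(events, gt, 0.010))
        # hand check: 3 TPs then a FP, a TP, a FP; envelope = [1,1,1,4/5,4/5,4/6]
        assert curve.average_precision == pytest.approx(
            3 / 5 * 1.0 + 1 / 5 * 4 / 5
        )

    def test_recall_nondecreasing_with_threshold(self):
        rng = np.random.default_rng(3)
        gt = list(rng.uniform(0, 1, 5))
        events = [ev(t, p) for t, p in zip(rng.uniform(0, 1, 30), rng.random(30))]
        curve = pr_curve(events, gt)
        assert np.all(np.diff(curve.recall) >= 0)

    def test_low_probability_false_positive_cannot_raise_ap(self):
        gt = [0.1, 0.3]
        events = [ev(0.1, 0.9), ev(0.3, 0.8)]
        base = pr_curve(events, gt).average_precision
        worse = pr_curve(events + [ev(0.9, 0.1)], gt).average_precision
        assert worse <= base

    def test_added_true_positive_cannot_lower_ap(self):
        gt = [0.1, 0.3, 0.5]
        events = [ev(0.1, 0.9), ev(0.8, 0.5)]
        base = pr_curve(events, gt).average_precision
        better = pr_curve(events + [ev(0.3, 0.7)], gt).average_precision
        assert better >= base

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([ev(0.1, 0.5)], [])

    def test_per_clip_matching_with_mapping(self):
        events = [ev(0.10, 0.9, "a"), ev(0.10, 0.8, "b")]
        gt = {"a": [0.10], "b": []}
        curve = pr_curve(events, gt)
        # the clip-b event cannot claim clip-a ground truth
        assert curve.precision[-1] == pytest.approx(0.5)
        assert curve.recall[-1] == pytest.approx(1.0)


class TestRecallAtPrecision:
    def _curve(self, pairs):
        p = np.array([x for x, _ in pairs])
        r = np.array([y for _, y in pairs])
        return PRCurve(np.linspace(1, 0, len(pairs)), p, r, 0.0, 0.0)

    def test_point_above_threshold_counts(self):
        assert recall_at_precision(self._curve([(1.0, 0.8), (0.5, 0.9)])) >= 0.8

    def test_all_below_gives_zero(self):
        assert recall_at_precision(self._curve([(0.9, 0.5), (0.7, 0.9)])) == 0.0

    def test_boundary_inclusive(self):
        assert recall_at_precision(self._curve([(0.95, 0.5)])) == pytest.approx(0.5)


class TestSinglePoint:
    def test_empty_output_convention(self):
        assert evaluate_single_point([], [0.1]) == (1.0, 0.0)

    def test_perfect_output(self):
        assert evaluate_single_point([ev(0.1), ev(0.3)], [0.1, 0.3]) == (1.0, 1.0)

    def test_point_via_match_oracle(self):
        events = [ev(0.10), ev(0.52), ev(0.90)]
        gt = [0.10, 0.50, 0.70]
        p, r = evaluate_single_point(events, gt)
        tp = len(_oracle_greedy_match(events, gt, 0.010))
        assert p == pytest.approx(tp / len(events))
        assert r == pytest.approx(tp / len(gt))

    def test_single_point_ap_is_product(self):
        assert single_point_ap(0.4, 0.5) == pytest.approx(0.2)
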