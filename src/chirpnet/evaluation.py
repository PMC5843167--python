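"""Detection evaluation: tolerance matching, PR curves, interpolated AP.

A detection counts as a true positive if it lies within a tolerance
(default 10 ms) of an annotated call start; each annotation can be claimed
by at most one detection and vice versa.  Sweeping the probability
threshold from one to zero traces a precision-recall curve, summarised by
the interpolated average precision (area under the max-to-the-right
precision envelope) and by the recall at 0.95 precision — zero when no
threshold reaches that precision.

Matching processes detections in descending probability (ties by earlier
time), each claiming the nearest unconsumed annotation within tolerance.
Because the matches of high-probability detections are unaffected by
lower-probability ones, one greedy pass labels every detection TP/FP for
all thresholds simultaneously; the sweep is then a pair of cumulative
sums.  An optimal bipartite matching (maximum cardinality) is available as
``method="optimal"`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .postprocess import DetectionEvent

__all__ = [
    "MatchResult",
    "PRCurve",
    "match_detections",
    "precision",
    "recall",
    "pr_curve",
    "recall_at_precision",
    "evaluate_single_point",
]

TOLERANCE_DEFAULT = 0.010
#: absolute slack so the tolerance boundary is inclusive under float round-off
_EPS = 1e-9


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching detections to ground-truth call starts."""

    pairs: tuple[tuple[int, int], ...]  # (event index, gt index)
    false_positives: tuple[int, ...]  # unmatched event indices
    false_negatives: tuple[int, ...]  # unmatched gt indices
    tolerance: float

    @property
    def n_tp(self) -> int:
        return len(self.pairs)

    @property
    def n_fp(self) -> int:
        return len(self.false_positives)

    @property
    def n_fn(self) -> int:
        return len(self.false_negatives)


@dataclass(frozen=True)
class PRCurve:
    """Threshold-swept precision/recall plus the derived summary metrics."""

    thresholds: np.ndarray  # descending
    precision: np.ndarray
    recall: np.ndarray
    average_precision: float
    recall_at_p95: float

    def recall_at(self, min_precision: float) -> float:
        ok = self.precision >= min_precision
        return float(self.recall[ok].max()) if ok.any() else 0.0


def _greedy_order(events: list[DetectionEvent]) -> list[int]:
    return sorted(
        range(len(events)), key=lambda i: (-events[i].probability, events[i].time)
    )


def match_detections(
    events: list[DetectionEvent],
    gt_times,
    tolerance: float = TOLERANCE_DEFAULT,
    method: str = "greedy",
) -> MatchResult:
    """Match detections to ground-truth start times within ``tolerance``.

    Greedy (default): descending-probability order, nearest unconsumed
    ground truth.  Optimal: maximum-cardinality bipartite assignment
    (minimising total time offset among maximum matchings).
    """
    gt = np.asarray(list(gt_times), dtype=float)
    if method == "greedy":
        taken = np.zeros(gt.size, dtype=bool)
        pairs = []
        for i in _greedy_order(events):
            if gt.size == 0:
                break
            dist = np.abs(gt - events[i].time)
            dist[taken] = np.inf
            j = int(np.argmin(dist))
            if dist[j] <= tolerance + _EPS:
                taken[j] = True
                pairs.append((i, j))
    elif method == "optimal":
        pairs = _optimal_pairs(events, gt, tolerance)
    else:
        raise ValueError(f"unknown matching method {method!r}")
    matched_e = {i for i, _ in pairs}
    matched_g = {j for _, j in pairs}
    return MatchResult(
        pairs=tuple(sorted(pairs)),
        false_positives=tuple(i for i in range(len(events)) if i not in matched_e),
        false_negatives=tuple(j for j in range(gt.size) if j not in matched_g),
        tolerance=tolerance,
    )


def _optimal_pairs(events, gt, tolerance):
    from scipy.optimize import linear_sum_assignment

    if not events or gt.size == 0:
        return []
    t_e = np.array([e.time for e in events])
    cost = np.abs(t_e[:, None] - gt[None, :])
    # large-but-finite penalty keeps infeasible pairs out of max matchings
    big = 1e6 * (cost.max() + tolerance + 1.0)
    cost = np.where(cost <= tolerance + _EPS, cost, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] < big]


def precision(matches: MatchResult) -> float:
    """TP / (TP + FP); 1.0 by convention when there are no detections."""
    denom = matches.n_tp + matches.n_fp
    return matches.n_tp / denom if denom else 1.0


def recall(matches: MatchResult) -> float:
    """TP / (TP + FN): fraction of annotated calls that were detected."""
    denom = matches.n_tp + matches.n_fn
    if denom == 0:
        raise ValueError("recall undefined with no ground-truth calls")
    return matches.n_tp / denom


def _as_clip_map(events, gt):
    """Normalise (events, gt) into per-clip lists keyed by source_id."""
    if isinstance(gt, dict):
        gt_map = {k: np.asarray(list(v), float) for k, v in gt.items()}
        ev_map: dict[str, list[DetectionEvent]] = {k: [] for k in gt_map}
        for e in events:
            ev_map.setdefault(e.source_id, []).append(e)
    else:
        gt_map = {"": np.asarray(list(gt), float)}
        ev_map = {"": list(events)}
    return ev_map, gt_map


def pr_curve(
    events: list[DetectionEvent],
    gt,
    tolerance: float = TOLERANCE_DEFAULT,
) -> PRCurve:
    """Precision-recall curve over all distinct probability thresholds.

    ``gt`` is either a list of ground-truth times (single clip) or a mapping
    ``source_id -> times`` (matching is then per clip, metrics pooled).
    Ties in probability are evaluated as a single threshold step.
    """
    ev_map, gt_map = _as_clip_map(events, gt)
    n_gt = sum(g.size for g in gt_map.values())
    if n_gt == 0:
        raise ValueError("recall undefined: no ground-truth calls supplied")
    # one greedy matching pass labels each detection TP/FP for every threshold
    labelled: list[tuple[float, bool]] = []
    for sid, evs in ev_map.items():
        g = gt_map.get(sid, np.empty(0))
        m = match_detections(evs, g, tolerance)
        tp_idx = {i for i, _ in m.pairs}
        for i, e in enumerate(evs):
            labelled.append((e.probability, i in tp_idx))
    if not labelled:
        return PRCurve(
            thresholds=np.array([1.0]),
            precision=np.array([1.0]),
            recall=np.array([0.0]),
            average_precision=0.0,
            recall_at_p95=0.0,
        )
    labelled.sort(key=lambda t: -t[0])
    probs = np.array([p for p, _ in labelled])
    is_tp = np.array([tp for _, tp in labelled])
    cum_tp = np.cumsum(is_tp)
    cum_fp = np.cumsum(~is_tp)
    # collapse probability ties to single sweep points
    last_of_threshold = np.r_[probs[1:] != probs[:-1], True]
    thr = probs[last_of_threshold]
    tp = cum_tp[last_of_threshold]
    fp = cum_fp[last_of_threshold]
    prec = tp / (tp + fp)
    rec = tp / n_gt
    ap = _interpolated_ap(prec, rec)
    ok = prec >= 0.95
    r95 = float(rec[ok].max()) if ok.any() else 0.0
    return PRCurve(
        thresholds=thr,
        precision=prec,
        recall=rec,
        average_precision=ap,
        recall_at_p95=r95,
    )


def _interpolated_ap(prec: np.ndarray, rec: np.ndarray) -> float:
    """Area under the max-to-the-right interpolated precision envelope."""
    envelope = np.maximum.accumulate(prec[::-1])[::-1]
    r_prev = np.r_[0.0, rec[:-1]]
    return float(np.sum((rec - r_prev) * envelope))


def recall_at_precision(curve: PRCurve, min_precision: float = 0.95) -> float:
    """Highest recall at any threshold with precision >= ``min_precision``.

    Zero when the detector never reaches that precision — a detector that
    cannot retrieve any call at 5% false positives scores nothing.
    """
    return curve.recall_at(min_precision)


def evaluate_single_point(
    events: list[DetectionEvent], gt, tolerance: float = TOLERANCE_DEFAULT
) -> tuple[float, float]:
    """(precision, recall) for a binary detector with no probability sweep."""
    ev_map, gt_map = _as_clip_map(events, gt)
    tp = fp = fn = 0
    for sid, evs in ev_map.items():
        m = match_detections(evs, gt_map.get(sid, np.empty(0)), tolerance)
        tp += m.n_tp
        fp += m.n_fp
        fn += m.n_fn
    prec = tp / (tp + fp) if (tp + fp) else 1.0
    if tp + fn == 0:
        raise ValueError("recall undefined: no ground-truth calls supplied")
    return prec, tp / (tp + fn)


def single_point_ap(precision_value: float, recall_value: float) -> float:
    """Interpolated AP of a one-point PR curve: precision x recall.

    The envelope holds the point's precision up to its recall and drops to
    zero beyond, so the area is the product.  Used to place binary
    detectors on the same AP scale as probabilistic ones.
    """
    return precision_value * recall_value
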