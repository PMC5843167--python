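"""Training-set curation and detector training.

Detection is posed as binary classification of 23 ms spectrogram windows:
a window is positive when its start coincides (within a small jitter) with
an annotated search-phase call start, and negative when its start is at
least ``negative_margin`` away from every call start — the margin keeps
ambiguous part-call windows out of both classes.

Annotation hygiene mirrors field practice: a call and its harmonics are
sometimes annotated with slightly different start times, so annotations
within 6 ms of each other (transitively) are merged and represented by the
earliest time, the physical call onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import pr_curve
from .postprocess import DetectionEvent
from .spectrogram import (
    AudioClip,
    SpectrogramParams,
    compute_spectrogram,
    denoise,
    prepare_windows,
)

__all__ = [
    "Annotation",
    "TrainConfig",
    "LabelledWindows",
    "merge_annotations",
    "build_training_set",
    "train",
    "score_annotator",
    "read_annotations",
    "write_annotations",
]

LABELS = frozenset(
    {"search_phase", "feeding_buzz", "social", "insect", "mechanical"}
)

MERGE_GAP_DEFAULT = 0.006


@dataclass(frozen=True)
class Annotation:
    """One annotated sound event: clip id, real-time start, category."""

    source_id: str
    start_time: float
    label: str = "search_phase"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label {self.label!r} not in {sorted(LABELS)}")
        if self.start_time < 0:
            raise ValueError("start_time must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for window extraction and optimisation.

    ``positive_jitter`` widens each call start into a few positive windows
    (label smoothing in time); ``negative_margin`` is the exclusion zone
    around call starts that no negative may enter.
    """

    positive_jitter: float = 2.3e-3  # +-2 detector-grid-pooled frames
    negative_margin: float = 0.015
    negatives_per_positive: float = 1.0
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.negative_margin > self.positive_jitter >= 0):
            raise ValueError("require negative_margin > positive_jitter >= 0")


@dataclass
class LabelledWindows:
    """Training windows as arrays: X (N, 130, 20), y in {0, 1}."""

    X: np.ndarray
    y: np.ndarray
    start_times: np.ndarray
    source_ids: list[str]

    def __len__(self) -> int:
        return self.y.size


def merge_annotations(times, gap: float = MERGE_GAP_DEFAULT):
    """Merge call-start times closer than ``gap`` (transitively).

    Harmonics of one call can be annotated with slightly different starts;
    chains of annotations whose consecutive gaps are all <= ``gap`` collapse
    to a single call represented by the earliest time (the call onset).
    Input must be sorted ascending; output is strictly increasing with all
    consecutive gaps > ``gap``.
    """
    times = list(times)
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("annotation times must be sorted ascending")
    merged: list[float] = []
    last_member: float | None = None
    for t in times:
        if last_member is not None and t - last_member <= gap:
            last_member = t  # extends the current group
        else:
            merged.append(float(t))
            last_member = t
    return merged


def build_training_set(
    clips,
    annotations,
    cfg: TrainConfig,
    params: SpectrogramParams | None = None,
) -> LabelledWindows:
    """Extract labelled 130x20 windows from clips plus call annotations.

    ``annotations`` is a flat list of :class:`Annotation`; only
    ``search_phase`` entries define positives and the negative exclusion
    zone (insect/mechanical events simply remain part of the negative
    background, which is what the detector must reject).  Negatives are
    subsampled to ``negatives_per_positive`` times the positive count,
    reproducibly under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    by_clip: dict[str, list[float]] = {}
    for a in annotations:
        if a.label == "search_phase":
            by_clip.setdefault(a.source_id, []).append(a.start_time)
    pos_X, pos_t, pos_sid = [], [], []
    neg_X, neg_t, neg_sid = [], [], []
    for clip in clips:
        calls = np.array(sorted(by_clip.get(clip.source_id, [])))
        if calls.size and calls.max() > clip.duration_real:
            raise ValueError(
                f"{clip.source_id}: annotation at {calls.max():.4f}s beyond "
                f"clip extent {clip.duration_real:.4f}s"
            )
        spec = denoise(compute_spectrogram(clip, params))
        for win in prepare_windows(spec, stride_frames=1):
            if calls.size:
                d = np.abs(calls - win.start_time).min()
            else:
                d = np.inf
            if d <= cfg.positive_jitter:
                pos_X.append(win.values)
                pos_t.append(win.start_time)
                pos_sid.append(clip.source_id)
            elif d >= cfg.negative_margin:
                neg_X.append(win.values)
                neg_t.append(win.start_time)
                neg_sid.append(clip.source_id)
    n_neg = min(len(neg_X), int(round(cfg.negatives_per_positive * len(pos_X))))
    if len(pos_X) == 0:
        n_neg = min(len(neg_X), 64)  # degenerate corpus: keep some negatives
    keep = rng.choice(len(neg_X), size=n_neg, replace=False) if neg_X else []
    X = pos_X + [neg_X[i] for i in keep]
    y = np.r_[np.ones(len(pos_X), int), np.zeros(n_neg, int)]
    t = np.array(pos_t + [neg_t[i] for i in keep])
    sids = pos_sid + [neg_sid[i] for i in keep]
    return LabelledWindows(
        X=np.stack(X) if X else np.empty((0, 130, 20)),
        y=y,
        start_times=t,
        source_ids=sids,
    )


def train(detector, dataset: LabelledWindows, cfg: TrainConfig) -> list[float]:
    """Train a window CNN with Adam on softmax cross-entropy.

    Returns the per-epoch mean training loss.  Raises on divergence (NaN
    loss), naming the epoch and batch where it occurred.
    """
    from .nn import Adam

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(detector.params, lr=cfg.learning_rate)
    n = len(dataset)
    if n == 0:
        raise ValueError("empty training set")
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = detector.loss_and_grads(dataset.X[idx], dataset.y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}, "
                    f"batch {start // cfg.batch_size}"
                )
            opt.step(grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    detector.trained = True
    return history


def score_annotator(
    user_annotations,
    expert_annotations,
    tolerance: float = 0.010,
) -> float:
    """Average precision of one annotator against expert ground truth.

    User annotations are scored as probability-1.0 detections under the
    standard 10 ms matching tolerance.  Both sets must cover the same clip
    collection (clips the user left empty must still appear in the expert
    set for recall to be counted).
    """
    user_clips = {a.source_id for a in user_annotations}
    expert_clips = {a.source_id for a in expert_annotations}
    if user_clips and expert_clips and not (user_clips & expert_clips):
        raise ValueError("user and expert annotation sets cover disjoint clips")
    events = [
        DetectionEvent(time=a.start_time, probability=1.0, source_id=a.source_id)
        for a in user_annotations
    ]
    gt: dict[str, list[float]] = {sid: [] for sid in user_clips | expert_clips}
    for a in expert_annotations:
        gt[a.source_id].append(a.start_time)
    curve = pr_curve(events, gt, tolerance)
    return curve.average_precision


def write_annotations(annotations, path) -> None:
    """Write annotations as TSV: source_id, start_time_s, label."""
    with open(path, "w") as fh:
        fh.write("source_id\tstart_time_s\tlabel\n")
        for a in sorted(annotations, key=lambda a: (a.source_id, a.start_time)):
            fh.write(f"{a.source_id}\t{a.start_time!r}\t{a.label}\n")


def read_annotations(path) -> list[Annotation]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source_id"):
            raise ValueError(f"unrecognised annotation file header: {header!r}")
        for line in fh:
            sid, t, label = line.rstrip("\n").split("\t")
            out.append(Annotation(source_id=sid, start_time=float(t), label=label))
    return out
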