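"""Corpus-level helpers: train a detector on scenes, score it on held-out scenes.

These wrap the per-clip pipeline into the evaluation protocol used on the
synthetic benchmark: generate probability tracks per clip, apply
non-maximum suppression, pool detections over clips, and sweep the
precision-recall curve against the exact ground truth.
"""

from __future__ import annotations

import numpy as np

from .evaluation import PRCurve, evaluate_single_point, pr_curve
from .models import (
    ForestDetector,
    SegmentationParams,
    WindowCNN,
    forest_detect,
    predict_fullconv,
    segmentation_detect,
)
from .postprocess import DetectionEvent, nonmax_suppress
from .spectrogram import AudioClip, compute_spectrogram, denoise, prepare_windows
from .training import Annotation, TrainConfig, build_training_set, train

__all__ = [
    "corpus_ground_truth",
    "train_cnn_on_corpus",
    "train_forest_on_corpus",
    "evaluate_cnn",
    "evaluate_forest",
    "evaluate_segmentation",
]

NMS_FLOOR = 0.05


def corpus_ground_truth(clips, annotations) -> dict[str, list[float]]:
    """source_id -> sorted call start times (search-phase only)."""
    gt: dict[str, list[float]] = {c.source_id: [] for c in clips}
    for a in annotations:
        if a.label == "search_phase":
            gt[a.source_id].append(a.start_time)
    return {k: sorted(v) for k, v in gt.items()}


def train_cnn_on_corpus(
    clips, annotations, cfg: TrainConfig, arch="cnn_fast"
) -> tuple[WindowCNN, list[float]]:
    from .models import build_detector

    dataset = build_training_set(clips, annotations, cfg)
    detector = build_detector(arch, seed=cfg.seed)
    history = train(detector, dataset, cfg)
    return detector, history


def train_forest_on_corpus(
    clips, annotations, cfg: TrainConfig, n_estimators: int = 100
) -> ForestDetector:
    dataset = build_training_set(clips, annotations, cfg)
    return ForestDetector(n_estimators=n_estimators, seed=cfg.seed).fit(
        dataset.X, dataset.y
    )


def _pool_events(per_clip_tracks) -> list[DetectionEvent]:
    events = []
    for source_id, track in per_clip_tracks:
        events.extend(
            DetectionEvent(e.time, e.probability, source_id)
            for e in nonmax_suppress(track, floor=NMS_FLOOR)
        )
    return events


def evaluate_cnn(detector: WindowCNN, clips, annotations) -> PRCurve:
    """Fully-convolutional evaluation of a CNN over a held-out corpus."""
    tracks = []
    for clip in clips:
        spec = denoise(compute_spectrogram(clip))
        tracks.append((clip.source_id, predict_fullconv(detector, spec)))
    return pr_curve(_pool_events(tracks), corpus_ground_truth(clips, annotations))


def evaluate_forest(forest: ForestDetector, clips, annotations) -> PRCurve:
    """Sliding-window (stride 4) evaluation of the forest baseline."""
    tracks = []
    for clip in clips:
        spec = denoise(compute_spectrogram(clip))
        windows = prepare_windows(spec, stride_frames=4)
        tracks.append((clip.source_id, forest_detect(forest, windows)))
    return pr_curve(_pool_events(tracks), corpus_ground_truth(clips, annotations))


def evaluate_segmentation(
    clips, annotations, params: SegmentationParams | None = None
) -> tuple[float, float]:
    """(precision, recall) single point for the binary segmentation baseline."""
    params = params or SegmentationParams()
    events = []
    for clip in clips:
        spec = denoise(compute_spectrogram(clip))
        events.extend(segmentation_detect(spec, params))
    return evaluate_single_point(events, corpus_ground_truth(clips, annotations))
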