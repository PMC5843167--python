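"""End-to-end convenience: waveform in, detection events out."""

from __future__ import annotations

from .models import WindowCNN, predict_fullconv, predict_sliding
from .postprocess import DetectionEvent, apply_threshold, nonmax_suppress
from .spectrogram import (
    AudioClip,
    SpectrogramParams,
    compute_spectrogram,
    denoise,
    prepare_windows,
)

__all__ = ["detect_clip"]


def detect_clip(
    clip: AudioClip,
    detector: WindowCNN,
    threshold: float = 0.90,
    params: SpectrogramParams | None = None,
    nms_neighborhood: float = 11.5e-3,
    fullconv: bool = True,
) -> list[DetectionEvent]:
    """Run the whole detection pipeline on one clip.

    Spectrogram -> de-noise -> CNN probability track (fully-convolutional
    by default, stride 4) -> non-maximum suppression -> probability
    threshold (default 0.90, the conservative monitoring setting).
    """
    spec = denoise(compute_spectrogram(clip, params))
    if fullconv:
        track = predict_fullconv(detector, spec)
    else:
        track = predict_sliding(detector, prepare_windows(spec, stride_frames=4))
    events = nonmax_suppress(track, neighborhood=nms_neighborhood, floor=min(threshold, 0.05))
    events = [
        DetectionEvent(time=e.time, probability=e.probability, source_id=clip.source_id)
        for e in events
    ]
    return apply_threshold(events, threshold)
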