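"""Shared fixtures: small synthetic corpora and a trained detector.

Everything is generated programmatically from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from chirpnet.spectrogram import GRID_HOP, GRID_N_ROWS, Spectrogram, SpectrogramParams
from chirpnet.synthetic import generate_corpus


def random_canonical_spectrogram(rng: np.random.Generator, width: int) -> Spectrogram:
    """A denoised spectrogram directly on the canonical 260-row grid."""
    p = SpectrogramParams()
    step = (p.freq_max - p.freq_min) / GRID_N_ROWS
    return Spectrogram(
        values=rng.uniform(0.0, 5.0, size=(GRID_N_ROWS, width)),
        row_freqs=p.freq_min + (np.arange(GRID_N_ROWS) + 0.5) * step,
        frame_times=np.arange(width) * GRID_HOP,
        params=p,
        denoised=True,
        canonical=True,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """12 training scenes with their pooled annotations."""
    clips, annotations, configs = generate_corpus(12, seed=11, prefix="train")
    return clips, annotations


@pytest.fixture(scope="session")
def holdout_corpus():
    """6 held-out scenes (disjoint seed stream from small_corpus)."""
    clips, annotations, configs = generate_corpus(6, seed=900_000, prefix="test")
    return clips, annotations


@pytest.fixture(scope="session")
def trained_fast(small_corpus):
    """A CNN_FAST detector trained briefly on the small corpus."""
    from chirpnet.models import build_detector
    from chirpnet.training import TrainConfig, build_training_set, train

    clips, annotations = small_corpus
    cfg = TrainConfig(epochs=8, seed=0)
    dataset = build_training_set(clips, annotations, cfg)
    detector = build_detector("cnn_fast", seed=0)
    train(detector, dataset, cfg)
    return detector


def gt_map(clips, annotations) -> dict[str, list[float]]:
    gt: dict[str, list[float]] = {c.source_id: [] for c in clips}
    for a in annotations:
        if a.label == "search_phase":
            gt[a.source_id].append(a.start_time)
    return gt
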