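"""Seeded synthetic ultrasonic soundscapes with exact ground truth.

Scenes emulate the snapshot structure of classic time-expansion bat
surveys: each 3.84 s WAV (at 44.1 kHz, x10 expansion) holds 3.2 s of
expanded payload — 320 ms of real time — buffered by 320 ms of file-time
silence on either side.  The payload contains a train of downward FM
chirps (the call targets) over a noise bed of pink noise, broadband
impulses, and insect-like amplitude-modulated tones (the confuser
categories annotators mark in real data).

Every random draw flows through one seeded generator, so a scene is a pure
function of its configuration; ground-truth call start times are exact by
construction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np

from .spectrogram import AudioClip, save_audio
from .training import Annotation, write_annotations

__all__ = [
    "CallTemplate",
    "SceneConfig",
    "synth_call",
    "synth_scene",
    "make_benchmark",
    "generate_corpus",
]

CALL_SHAPES = ("linear_fm", "hyperbolic_fm", "cf_fm")


@dataclass(frozen=True)
class CallTemplate:
    """Parameters of one synthetic search-phase call (a downward FM sweep).

    Frequencies are real-time Hz (f_start > f_end within the 5-135 kHz
    analysis band); duration is real-time seconds, capped at the 23 ms
    detection window.  ``harmonic_gain`` adds a second harmonic at the given
    relative amplitude.
    """

    shape: str = "linear_fm"
    f_start: float = 80e3
    f_end: float = 40e3
    duration: float = 4e-3
    amplitude: float = 1.0
    harmonic_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in CALL_SHAPES:
            raise ValueError(f"shape must be one of {CALL_SHAPES}")
        if not (5e3 < self.f_end < self.f_start < 135e3):
            raise ValueError("require 5 kHz < f_end < f_start < 135 kHz")
        if not (0 < self.duration <= 23e-3):
            raise ValueError("duration must be in (0, 23 ms]")


@dataclass(frozen=True)
class SceneConfig:
    """One snapshot scene: clip geometry, call train, noise and confusers.

    ``snr_db`` is the ratio of per-call RMS (over the call's support) to the
    payload noise RMS.  ``template=None`` randomises each call's sweep
    within typical European-bat ranges.
    """

    file_sample_rate: int = 44100
    expansion_factor: int = 10
    clip_duration_file: float = 3.84
    payload_duration_file: float = 3.2
    n_calls: int = 5
    inter_pulse_interval: tuple[float, float] = (0.05, 0.2)  # seconds real
    snr_db: float = 12.0
    noise_rms: float = 0.01
    insect_rate: float = 1.0
    impulse_rate: float = 2.0
    template: CallTemplate | None = None
    seed: int = 0

    @property
    def effective_rate(self) -> int:
        return self.file_sample_rate * self.expansion_factor

    @property
    def payload_duration_real(self) -> float:
        return self.payload_duration_file / self.expansion_factor

    @property
    def buffer_duration_file(self) -> float:
        return (self.clip_duration_file - self.payload_duration_file) / 2.0


def synth_call(template: CallTemplate, effective_rate: float) -> np.ndarray:
    """Render one frequency-swept call at the given real-time rate.

    The instantaneous frequency runs ``f_start -> f_end`` over the call
    duration (linearly, hyperbolically, or constant-then-sweep for cf_fm)
    under a smooth cosine-tapered envelope; an optional second harmonic is
    added where it stays below Nyquist.
    """
    if effective_rate < 2 * template.f_start:
        raise ValueError(
            f"rate {effective_rate} Hz violates Nyquist for f_start "
            f"{template.f_start} Hz"
        )
    n = max(2, round(template.duration * effective_rate))
    tau = np.arange(n) / (n - 1)  # 0..1 over the call
    f0, f1 = template.f_start, template.f_end
    if template.shape == "linear_fm":
        f_inst = f0 + (f1 - f0) * tau
    elif template.shape == "hyperbolic_fm":
        f_inst = 1.0 / (1.0 / f0 + (1.0 / f1 - 1.0 / f0) * tau)
    else:  # cf_fm: constant tone then a linear terminal sweep
        knee = 0.6
        f_inst = np.where(tau < knee, f0, f0 + (f1 - f0) * (tau - knee) / (1 - knee))
    phase = 2 * np.pi * np.cumsum(f_inst) / effective_rate
    from scipy.signal.windows import tukey

    env = tukey(n, 0.4)
    wave = np.sin(phase) * env
    if template.harmonic_gain > 0 and 2 * f0 < effective_rate / 2:
        wave = wave + template.harmonic_gain * np.sin(2 * phase) * env
    return template.amplitude * wave


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n)
    return pink / np.sqrt(np.mean(pink**2))


def _random_template(rng: np.random.Generator) -> CallTemplate:
    return CallTemplate(
        shape=CALL_SHAPES[rng.integers(len(CALL_SHAPES))],
        f_start=rng.uniform(55e3, 110e3),
        f_end=rng.uniform(22e3, 45e3),
        duration=rng.uniform(2e-3, 8e-3),
        amplitude=1.0,
        harmonic_gain=rng.uniform(0.0, 0.3),
    )


def synth_scene(cfg: SceneConfig, source_id: str = "scene") -> tuple[AudioClip, list[Annotation]]:
    """Generate one snapshot clip plus its exact call-start annotations.

    The returned clip is in file time (WAV-writable at ``file_sample_rate``);
    annotation start times are in real time measured from the start of the
    clip.  The per-call SNR is attained exactly by scaling each call to
    ``noise_rms * 10^(snr_db/20)`` RMS over its support.
    """
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.effective_rate
    n_payload = round(cfg.payload_duration_file * cfg.file_sample_rate)
    payload = cfg.noise_rms * _pink_noise(n_payload, rng)

    # insect-like confusers: amplitude-modulated near-CF tones
    for _ in range(rng.poisson(cfg.insect_rate)):
        dur = rng.uniform(0.03, 0.1)  # seconds real
        n_i = min(round(dur * rate), n_payload)
        start = rng.integers(0, n_payload - n_i + 1)
        carrier = rng.uniform(8e3, 28e3)
        am_rate = rng.uniform(100.0, 400.0)
        t = np.arange(n_i) / rate
        tone = np.sin(2 * np.pi * carrier * t) * (0.5 + 0.5 * np.sin(2 * np.pi * am_rate * t))
        level = cfg.noise_rms * 10 ** (rng.uniform(6.0, 14.0) / 20.0)
        tone *= level / max(np.sqrt(np.mean(tone**2)), 1e-12)
        payload[start : start + n_i] += tone

    # broadband impulses (mechanical clicks)
    for _ in range(rng.poisson(cfg.impulse_rate)):
        n_c = round(0.5e-3 * rate)
        start = rng.integers(0, n_payload - n_c)
        click = rng.standard_normal(n_c) * np.hanning(n_c)
        level = cfg.noise_rms * 10 ** (rng.uniform(8.0, 16.0) / 20.0)
        click *= level / max(np.sqrt(np.mean(click**2)), 1e-12)
        payload[start : start + n_c] += click

    # call train; SNR is defined against the pink-noise bed level
    call_rms = cfg.noise_rms * 10 ** (cfg.snr_db / 20.0)
    payload_real = cfg.payload_duration_real
    starts_real: list[float] = []
    if cfg.n_calls > 0:
        # search-phase trains have near-regular pulse intervals: one IPI per
        # scene, drawn from the configured range
        ipi = rng.uniform(*cfg.inter_pulse_interval)
        templates = [
            cfg.template if cfg.template is not None else _random_template(rng)
            for _ in range(cfg.n_calls)
        ]
        span = (cfg.n_calls - 1) * ipi + templates[-1].duration
        if span > payload_real:
            raise ValueError(
                f"call train of {span * 1e3:.1f} ms real time does not fit the "
                f"{payload_real * 1e3:.0f} ms payload"
            )
        t0 = rng.uniform(0.0, payload_real - span)
        for i, tmpl in enumerate(templates):
            t = t0 + i * ipi
            snippet = synth_call(tmpl, rate)
            snippet = snippet * (call_rms * tmpl.amplitude / np.sqrt(np.mean(snippet**2)))
            i0 = round(t * rate)
            i1 = min(i0 + snippet.size, n_payload)
            payload[i0:i1] += snippet[: i1 - i0]
            starts_real.append(t)

    n_buf = round(cfg.buffer_duration_file * cfg.file_sample_rate)
    samples = np.concatenate([np.zeros(n_buf), payload, np.zeros(n_buf)])
    peak = np.abs(samples).max()
    if peak > 0.95:  # headroom for 16-bit PCM; pure rescale, SNR unaffected
        samples = samples * (0.95 / peak)
    clip = AudioClip(
        samples=samples,
        sample_rate=cfg.file_sample_rate,
        time_expansion_factor=cfg.expansion_factor,
        source_id=source_id,
    )
    buffer_real = cfg.buffer_duration_file / cfg.expansion_factor
    annotations = [
        Annotation(source_id=source_id, start_time=buffer_real + t, label="search_phase")
        for t in starts_real
    ]
    return clip, annotations


def _scene_seed(corpus_seed: int, index: int) -> int:
    return (corpus_seed * 1000003 + index) % (2**31)


def generate_corpus(
    n_scenes: int,
    seed: int,
    base: SceneConfig | None = None,
    max_calls: int = 6,
    snr_range: tuple[float, float] = (6.0, 18.0),
    prefix: str = "scene",
) -> tuple[list[AudioClip], list[Annotation], list[SceneConfig]]:
    """Generate a corpus of scenes with per-scene randomised difficulty.

    Call counts are uniform on {0..max_calls} and per-scene SNR uniform on
    ``snr_range`` dB, covering both empty clips and faint-call conditions.
    Scene i is fully determined by ``(seed, i)``.
    """
    base = base or SceneConfig()
    meta_rng = np.random.default_rng(seed)
    clips, annotations, configs = [], [], []
    for i in range(n_scenes):
        # pin a per-scene pulse interval, then draw a call count that fits
        ipi = float(meta_rng.uniform(*base.inter_pulse_interval))
        max_fit = 1 + int((base.payload_duration_real - 0.023) / ipi)
        cfg = replace(
            base,
            inter_pulse_interval=(ipi, ipi),
            n_calls=int(meta_rng.integers(0, min(max_calls, max_fit) + 1)),
            snr_db=float(meta_rng.uniform(*snr_range)),
            seed=_scene_seed(seed, i),
        )
        clip, anns = synth_scene(cfg, source_id=f"{prefix}_{i:04d}")
        clips.append(clip)
        annotations.extend(anns)
        configs.append(cfg)
    return clips, annotations, configs


def make_benchmark(
    out_dir,
    n_train: int = 200,
    n_test: int = 50,
    seed: int = 0,
    base: SceneConfig | None = None,
) -> dict:
    """Write a train/test benchmark of WAVs + annotation TSVs + manifest.

    Layout: ``train/*.wav``, ``train/annotations.tsv``, same under
    ``test/``, and a ``manifest.json`` recording every file with the seed
    that regenerates it bit-identically.
    """
    manifest = {"seed": seed, "splits": {}}
    for split, n, offset in (("train", n_train, 0), ("test", n_test, 1_000_000)):
        split_dir = os.path.join(str(out_dir), split)
        os.makedirs(split_dir, exist_ok=True)
        clips, annotations, configs = generate_corpus(
            n, seed=seed + offset, base=base, prefix=split
        )
        files = []
        for clip, cfg in zip(clips, configs):
            wav_path = os.path.join(split_dir, clip.source_id + ".wav")
            save_audio(wav_path, clip)
            files.append(
                {"file": clip.source_id + ".wav", "seed": cfg.seed,
                 "n_calls": cfg.n_calls, "snr_db": cfg.snr_db}
            )
        write_annotations(annotations, os.path.join(split_dir, "annotations.tsv"))
        manifest["splits"][split] = {"n_scenes": n, "files": files}
    with open(os.path.join(str(out_dir), "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
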