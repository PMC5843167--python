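"""Audio ingestion and calibrated spectrogram computation.

Ultrasonic bat recordings are often stored *time-expanded*: the waveform is
played back slowed by an integer factor (classically x10) so that ultrasound
fits in an audible-rate WAV file.  All quantities in this package are
expressed in *real* (pre-expansion) time and frequency unless explicitly
labelled as file time; the conversion is ``real = file / factor`` for time
and ``real = file * factor`` for frequency.

The processing chain is

1. ``load_audio``          -- read a mono WAV, normalise to [-1, 1];
2. ``compute_spectrogram`` -- log-magnitude STFT band-limited to 5-135 kHz;
3. ``denoise``             -- subtract each frequency band's mean over time;
4. ``to_detector_grid``    -- resample onto a fixed 260-row / 0.575 ms grid;
5. ``prepare_windows``     -- 2x2 mean-pool and cut 130x20 detector windows,
                              each spanning 23 ms of real time.

Step 4 makes the detector input geometry independent of the file sampling
rate: any recording whose band of interest covers 5-135 kHz lands on the
same grid, so one trained network serves all of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import RegularGridInterpolator
from scipy.io import wavfile
from scipy.signal import get_window

__all__ = [
    "AudioClip",
    "SpectrogramParams",
    "Spectrogram",
    "DetectorInputWindow",
    "load_audio",
    "compute_spectrogram",
    "denoise",
    "to_detector_grid",
    "prepare_windows",
    "GRID_N_ROWS",
    "GRID_HOP",
    "DETECTOR_SHAPE",
]

#: Number of frequency rows of the canonical detector grid (pre-halving).
GRID_N_ROWS = 260
#: Time hop of the canonical grid in seconds of real time (0.575 ms).
GRID_HOP = 0.575e-3
#: Shape (n_freq_bins, n_time_steps) of one detector input window.
DETECTOR_SHAPE = (130, 20)


@dataclass(frozen=True)
class AudioClip:
    """A mono waveform plus the metadata needed to undo time expansion.

    Parameters
    ----------
    samples
        PCM-normalised amplitudes in [-1, 1].
    sample_rate
        Sampling rate of the *file* in Hz.
    time_expansion_factor
        Integer slow-down factor applied when the file was written; 1 for
        real-time recordings, 10 for classic time-expansion detectors.
    source_id
        Opaque identifier (typically the file stem) carried through to
        detections and annotations.
    """

    samples: np.ndarray
    sample_rate: int
    time_expansion_factor: int = 1
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if int(self.time_expansion_factor) < 1:
            raise ValueError("time_expansion_factor must be >= 1")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))
        object.__setattr__(
            self, "time_expansion_factor", int(self.time_expansion_factor)
        )

    @property
    def effective_rate(self) -> int:
        """Sampling rate in real (pre-expansion) time, Hz."""
        return self.sample_rate * self.time_expansion_factor

    @property
    def duration_real(self) -> float:
        """Clip length in seconds of real time."""
        return self.samples.size / self.effective_rate

    @property
    def duration_file(self) -> float:
        """Clip length in seconds of file time."""
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT parameters, all in real-time units.

    ``frame_duration`` is a target: the actual frame length is the nearest
    power of two to ``frame_duration * effective_rate`` (1,024 samples at
    441 kHz effective), and the realised duration is recomputed from it.
    """

    frame_duration: float = 2.3e-3
    overlap_fraction: float = 0.75
    window_kind: str = "hann"
    freq_min: float = 5e3
    freq_max: float = 135e3
    #: log compression offset as a fraction of the full-scale magnitude
    log_offset: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not (self.freq_min < self.freq_max):
            raise ValueError("freq_min must be below freq_max")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be positive")

    def frame_length(self, effective_rate: float) -> int:
        """Frame length in samples: nearest power of two to the target."""
        target = self.frame_duration * effective_rate
        if target < 2:
            raise ValueError("frame_duration too short for this rate")
        return int(2 ** round(math.log2(target)))

    def hop_length(self, effective_rate: float) -> int:
        n = self.frame_length(effective_rate)
        return max(1, round(n * (1.0 - self.overlap_fraction)))


@dataclass(frozen=True)
class Spectrogram:
    """Log-magnitude time-frequency matrix with real-time axis calibration.

    ``values`` has one row per frequency (low to high) and one column per
    STFT frame; ``frame_times`` are the *start* times of each frame in
    seconds of real time.
    """

    values: np.ndarray
    row_freqs: np.ndarray
    frame_times: np.ndarray
    params: SpectrogramParams = field(default_factory=SpectrogramParams)
    denoised: bool = False
    canonical: bool = False
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (freq x time)")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "row_freqs", np.asarray(self.row_freqs, float))
        object.__setattr__(self, "frame_times", np.asarray(self.frame_times, float))
        if self.values.shape != (self.row_freqs.size, self.frame_times.size):
            raise ValueError("axis calibration does not match values shape")

    @property
    def hop_time(self) -> float:
        if self.frame_times.size < 2:
            return GRID_HOP
        return float(self.frame_times[1] - self.frame_times[0])


@dataclass(frozen=True)
class DetectorInputWindow:
    """One fixed-geometry detector input: 130 frequency bins x 20 steps."""

    values: np.ndarray
    start_time: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != DETECTOR_SHAPE:
            raise ValueError(f"window must have shape {DETECTOR_SHAPE}, got {v.shape}")
        object.__setattr__(self, "values", v)


def load_audio(path, time_expansion_factor: int = 1, channel: int | None = None) -> AudioClip:
    """Read a mono WAV file into an :class:`AudioClip`.

    Integer PCM is rescaled to [-1, 1]; float WAVs are taken as-is.  Files
    with more than one channel are rejected unless ``channel`` selects one
    explicitly.
    """
    if time_expansion_factor < 1:
        raise ValueError("time_expansion_factor must be >= 1")
    rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        if channel is None:
            raise ValueError(
                f"{path}: {data.shape[1]}-channel WAV; supply mono audio or pass "
                "channel=<index> to select one channel"
            )
        data = data[:, channel]
    if data.dtype.kind == "i":
        samples = data.astype(np.float64) / float(-np.iinfo(data.dtype).min)
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        info = np.iinfo(data.dtype)
        half = (info.max + 1) / 2.0
        samples = (data.astype(np.float64) - half) / half
    else:
        samples = data.astype(np.float64)
    import os

    stem = os.path.splitext(os.path.basename(str(path)))[0]
    return AudioClip(
        samples=samples,
        sample_rate=int(rate),
        time_expansion_factor=int(time_expansion_factor),
        source_id=stem,
    )


def save_audio(path, clip: AudioClip) -> None:
    """Write an :class:`AudioClip` as 16-bit PCM WAV (file-time rate)."""
    scaled = np.round(np.clip(clip.samples, -1.0, 1.0) * 32768.0)
    wavfile.write(
        str(path), clip.sample_rate, np.clip(scaled, -32768, 32767).astype(np.int16)
    )


def compute_spectrogram(
    clip: AudioClip, params: SpectrogramParams | None = None
) -> Spectrogram:
    """Band-limited log-magnitude STFT of a clip, axes in real-time units.

    Frames start at multiples of the hop (no centre padding), so frame k
    covers real time ``[k*hop, k*hop + frame_duration)``.
    """
    params = params or SpectrogramParams()
    rate = clip.effective_rate
    n_fft = params.frame_length(rate)
    hop = params.hop_length(rate)
    x = clip.samples
    if x.size < n_fft:
        raise ValueError(
            f"clip of {x.size} samples is shorter than one {n_fft}-sample frame"
        )
    frames = sliding_window_view(x, n_fft)[::hop]
    win = get_window(params.window_kind, n_fft)
    mag = np.abs(np.fft.rfft(frames * win, axis=1)).T  # (freq, time)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    band = (freqs >= params.freq_min) & (freqs <= params.freq_max)
    # full-scale reference: peak rfft magnitude of a unit-amplitude sine
    ref = float(np.sum(win)) / 2.0
    values = np.log(mag[band] + params.log_offset * ref)
    frame_times = np.arange(frames.shape[0]) * (hop / rate)
    return Spectrogram(
        values=values,
        row_freqs=freqs[band],
        frame_times=frame_times,
        params=params,
        source_id=clip.source_id,
    )


def denoise(spec: Spectrogram, clamp: bool = True) -> Spectrogram:
    """Spectral mean subtraction: remove each frequency band's mean over time.

    Stationary background noise contributes a near-constant level per band,
    so subtracting the per-row temporal mean whitens the background while
    leaving transient calls intact.  By the spectral-subtraction convention
    negative residuals are clamped to zero; pass ``clamp=False`` to keep the
    exact zero-mean residuals.
    """
    if spec.denoised:
        raise ValueError("spectrogram is already denoised")
    resid = spec.values - spec.values.mean(axis=1, keepdims=True)
    if clamp:
        resid = np.maximum(resid, 0.0)
    return replace(spec, values=resid, denoised=True)


def to_detector_grid(spec: Spectrogram) -> Spectrogram:
    """Resample a spectrogram onto the canonical detector grid.

    The grid has ``GRID_N_ROWS`` (260) rows with centres spread linearly
    over [freq_min, freq_max] and a fixed ``GRID_HOP`` (0.575 ms) time step,
    so detector inputs have identical geometry for any file sampling rate.
    Bilinear interpolation, edges clamped by linear extrapolation.
    """
    if spec.canonical:
        return spec
    p = spec.params
    step = (p.freq_max - p.freq_min) / GRID_N_ROWS
    grid_freqs = p.freq_min + (np.arange(GRID_N_ROWS) + 0.5) * step
    t0 = float(spec.frame_times[0])
    t_last = float(spec.frame_times[-1])
    n_cols = max(1, int(np.floor((t_last - t0) / GRID_HOP)) + 1)
    grid_times = t0 + np.arange(n_cols) * GRID_HOP
    if spec.frame_times.size == 1:
        interp_t = np.repeat(spec.values, n_cols, axis=1)
        interp = RegularGridInterpolator(
            (spec.row_freqs,), interp_t, bounds_error=False, fill_value=None
        )
        values = interp(grid_freqs)
    else:
        interp = RegularGridInterpolator(
            (spec.row_freqs, spec.frame_times),
            spec.values,
            bounds_error=False,
            fill_value=None,
        )
        ff, tt = np.meshgrid(grid_freqs, grid_times, indexing="ij")
        values = interp(np.stack([ff.ravel(), tt.ravel()], axis=1)).reshape(
            GRID_N_ROWS, n_cols
        )
    return Spectrogram(
        values=values,
        row_freqs=grid_freqs,
        frame_times=grid_times,
        params=p,
        denoised=spec.denoised,
        canonical=True,
        source_id=spec.source_id,
    )


def _mean_pool_2x2(values: np.ndarray) -> np.ndarray:
    h, w = values.shape
    h2, w2 = h // 2, w // 2
    if w2 == 0:
        values = np.pad(values, ((0, 0), (0, 2 - w)))
        w2 = 1
    return values[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def downsample_grid(spec: Spectrogram) -> tuple[np.ndarray, np.ndarray]:
    """2x2 mean-pool the canonical grid to the 130-row detector resolution.

    Returns ``(values, frame_times)`` where frame_times are the start times
    of each pooled column (hop = 1.15 ms real time).
    """
    grid = to_detector_grid(spec)
    pooled = _mean_pool_2x2(grid.values)
    times = grid.frame_times[0] + np.arange(pooled.shape[1]) * (2 * GRID_HOP)
    return pooled, times


def prepare_windows(
    spec: Spectrogram, stride_frames: int = 1
) -> list[DetectorInputWindow]:
    """Cut fixed 130x20 detector input windows from a denoised spectrogram.

    The spectrogram is resampled onto the canonical grid, 2x2 mean-pooled
    (halving both axes), and windows of 20 pooled frames (23 ms real time)
    are cut every ``stride_frames`` pooled frames.  Trailing windows are
    zero-padded so every start position yields a window.
    """
    if not spec.denoised:
        raise ValueError("prepare_windows expects a denoised spectrogram")
    if stride_frames < 1:
        raise ValueError("stride_frames must be >= 1")
    pooled, times = downsample_grid(spec)
    n_rows, n_steps = DETECTOR_SHAPE
    assert pooled.shape[0] == n_rows
    n_frames = pooled.shape[1]
    padded = np.pad(pooled, ((0, 0), (0, n_steps - 1)))
    windows = []
    for start in range(0, n_frames, stride_frames):
        windows.append(
            DetectorInputWindow(
                values=padded[:, start : start + n_steps],
                start_time=float(times[start]),
            )
        )
    return windows


def real_to_file_time(t_real: float, expansion_factor: int) -> float:
    """Convert seconds of real time to seconds of file (expanded) time."""
    return t_real * expansion_factor
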