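"""Call detectors: the window CNNs and the two classical baselines.

Every detector maps a (denoised) spectrogram to a :class:`ProbabilityTrack`
— a per-time-step probability that a search-phase echolocation call starts
there.  Two CNN presets are provided:

``CNN_FAST``
    Two conv(16 filters)+maxpool blocks and a 64-unit dense layer.  Because
    all convolutions are valid (unpadded), the dense layer can be evaluated
    as one more convolution, letting the whole network run over an entire
    spectrogram in a single pass (``predict_fullconv``) with an output of
    one probability per 4 detector-grid frames — identical, up to float
    round-off, to evaluating the window classifier at every 4th position.

``CNN_FULL``
    Three conv+maxpool blocks (32/32/64 filters) and a 64-unit dense layer.
    The interior filter geometry is a package default, configurable through
    :class:`CnnArchitecture`.

Baselines (both classic bioacoustic detection approaches):

* ``segmentation_detect`` — amplitude thresholding of the spectrogram with
  a minimum connected-component size; binary output.
* ``forest_detect`` — a random forest over the flattened gradient magnitude
  of each detector window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label, regionprops

from . import nn
from .postprocess import DetectionEvent
from .spectrogram import (
    DETECTOR_SHAPE,
    DetectorInputWindow,
    Spectrogram,
    downsample_grid,
)

__all__ = [
    "CnnArchitecture",
    "CNN_FAST",
    "CNN_FULL",
    "WindowCNN",
    "ProbabilityTrack",
    "SegmentationParams",
    "ForestDetector",
    "build_detector",
    "predict_sliding",
    "predict_fullconv",
    "segmentation_detect",
    "gradient_features",
    "forest_detect",
]


@dataclass(frozen=True)
class CnnArchitecture:
    """Geometry of a window CNN.

    ``conv_layers`` is a sequence of ``(n_filters, kernel_height,
    kernel_width)``; each conv is followed by ReLU and 2x2 max-pooling.
    A dense layer of ``fc_units`` and a 2-way softmax head complete the
    network.
    """

    conv_layers: tuple[tuple[int, int, int], ...]
    fc_units: int = 64
    input_shape: tuple[int, int] = DETECTOR_SHAPE
    name: str = "custom"

    @property
    def n_pool_layers(self) -> int:
        return len(self.conv_layers)

    @property
    def output_stride(self) -> int:
        """Time stride of fully-convolutional output, in grid frames."""
        return 2 ** self.n_pool_layers

    def feature_shapes(self) -> list[tuple[int, int]]:
        """(H, W) after each conv+pool block; raises if any collapses."""
        h, w = self.input_shape
        shapes = []
        for n_f, kh, kw in self.conv_layers:
            h, w = h - kh + 1, w - kw + 1
            if h < 1 or w < 1:
                raise ValueError(f"kernel {kh}x{kw} collapses feature map")
            h, w = nn.MaxPool2.out_shape(h, w)
            shapes.append((h, w))
        return shapes


CNN_FAST = CnnArchitecture(
    conv_layers=((16, 13, 5), (16, 13, 5)), fc_units=64, name="cnn_fast"
)
CNN_FULL = CnnArchitecture(
    conv_layers=((32, 13, 5), (32, 11, 3), (64, 9, 2)), fc_units=64, name="cnn_full"
)

_PRESETS = {"cnn_fast": CNN_FAST, "cnn_full": CNN_FULL}


@dataclass(frozen=True)
class ProbabilityTrack:
    """Per-time-step call probabilities, time-aligned to the detector grid."""

    probs: np.ndarray
    times: np.ndarray
    model_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        t = np.asarray(self.times, dtype=np.float64)
        if p.shape != t.shape or p.ndim != 1:
            raise ValueError("probs and times must be 1-D arrays of equal length")
        if p.size and (p.min() < -1e-9 or p.max() > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "probs", np.clip(p, 0.0, 1.0))
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.probs.size


class WindowCNN:
    """A small CNN classifying 130x20 spectrogram windows as call / no-call."""

    def __init__(self, arch: CnnArchitecture, seed: int = 0):
        arch.feature_shapes()  # validate geometry early
        self.arch = arch
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        layers: list = []
        in_ch = 1
        h, w = arch.input_shape
        for n_f, kh, kw in arch.conv_layers:
            layers.append(nn.Conv2D(in_ch, n_f, kh, kw, rng, first=not layers))
            layers.append(nn.ReLU())
            h, w = h - kh + 1, w - kw + 1
            layers.append(nn.MaxPool2())
            h, w = nn.MaxPool2.out_shape(h, w)
            in_ch = n_f
        self._feat_shape = (in_ch, h, w)
        layers.append(_Flatten())
        layers.append(nn.Dense(in_ch * h * w, arch.fc_units, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dense(arch.fc_units, 2, rng))
        self.layers = layers
        self.trained = False

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    # -- inference ----------------------------------------------------------
    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict_proba(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Positive-class probability for each window in ``(N, 130, 20)``."""
        windows = np.asarray(windows, dtype=np.float32)
        if windows.ndim == 2:
            windows = windows[None]
        x = windows[:, None, :, :]
        out = np.empty(x.shape[0])
        for i in range(0, x.shape[0], batch_size):
            lg = self.logits(x[i : i + batch_size])
            out[i : i + batch_size] = nn.SoftmaxCrossEntropy.probs(lg)[:, 1]
        return out

    # -- training -----------------------------------------------------------
    def loss_and_grads(self, windows: np.ndarray, y: np.ndarray):
        x = np.asarray(windows, dtype=np.float32)[:, None, :, :]
        lg = self.logits(x, train=True)
        loss, dlg = nn.SoftmaxCrossEntropy.loss_and_grad(lg, np.asarray(y))
        grads: list[np.ndarray] = []
        d = dlg
        for layer in reversed(self.layers):
            d, g = layer.backward(d)
            grads = g + grads
        return loss, grads

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Serialise weights + architecture descriptor to one ``.npz`` file."""
        meta = {
            "conv_layers": [list(c) for c in self.arch.conv_layers],
            "fc_units": self.arch.fc_units,
            "input_shape": list(self.arch.input_shape),
            "name": self.arch.name,
            "seed": self.seed,
            "trained": self.trained,
        }
        arrays = {f"param_{i}": p for i, p in enumerate(self.params)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "WindowCNN":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        arch = CnnArchitecture(
            conv_layers=tuple(tuple(c) for c in meta["conv_layers"]),
            fc_units=meta["fc_units"],
            input_shape=tuple(meta["input_shape"]),
            name=meta["name"],
        )
        model = cls(arch, seed=meta["seed"])
        for i, p in enumerate(model.params):
            p[...] = data[f"param_{i}"]
        model.trained = bool(meta["trained"])
        return model


class _Flatten:
    params: list = []

    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape), []


def build_detector(arch: CnnArchitecture | str, seed: int = 0) -> WindowCNN:
    """Instantiate a window CNN from a preset name or architecture."""
    if isinstance(arch, str):
        try:
            arch = _PRESETS[arch.lower()]
        except KeyError:
            raise ValueError(f"unknown preset {arch!r}; use one of {sorted(_PRESETS)}")
    return WindowCNN(arch, seed=seed)


def predict_sliding(
    detector: WindowCNN, windows: list[DetectorInputWindow]
) -> ProbabilityTrack:
    """Evaluate the window classifier at every window position."""
    if not windows:
        return ProbabilityTrack(np.empty(0), np.empty(0), detector.arch.name)
    x = np.stack([w.values for w in windows])
    if x.shape[1:] != detector.arch.input_shape:
        raise ValueError(
            f"window shape {x.shape[1:]} does not match architecture input "
            f"{detector.arch.input_shape}"
        )
    probs = detector.predict_proba(x)
    times = np.array([w.start_time for w in windows])
    return ProbabilityTrack(probs, times, detector.arch.name)


def predict_fullconv(detector: WindowCNN, spec: Spectrogram) -> ProbabilityTrack:
    """Run the CNN over a whole spectrogram in one fully-convolutional pass.

    The spectrogram is mapped to the 130-row detector grid, right-padded
    with zeros so that every window start at multiples of the output stride
    (4 grid frames for the two-pool ``CNN_FAST``) — including zero-padded
    trailing windows — produces one output.  Output length is therefore
    ``ceil(width / stride)``: one quarter of the input width for CNN_FAST.

    Values agree with :func:`predict_sliding` at the strided positions to
    float precision, because all convolutions are valid and every pooling
    partition of an embedded window coincides with the pooling partition of
    the isolated window (window starts are multiples of the pooling
    product).
    """
    if not spec.denoised:
        raise ValueError("predict_fullconv expects a denoised spectrogram")
    arch = detector.arch
    win_h, win_w = arch.input_shape
    # window-path pool inputs must all be even, otherwise the wide pass
    # pools across a boundary the window pass would crop
    w = win_w
    for _, _, kw in arch.conv_layers:
        w = w - kw + 1
        if w % 2:
            raise ValueError(
                "architecture pooling structure is incompatible with "
                "fully-convolutional evaluation (odd pre-pool width)"
            )
        w //= 2
    pooled, times = downsample_grid(spec)
    stride = arch.output_stride
    n_frames = pooled.shape[1]
    k = -(-n_frames // stride)  # ceil
    padded_w = stride * k + (win_w - stride)
    x = np.pad(pooled, ((0, 0), (0, padded_w - n_frames)))[None, None].astype(np.float32)
    convs = [l for l in detector.layers if isinstance(l, nn.Conv2D)]
    denses = [l for l in detector.layers if isinstance(l, nn.Dense)]
    for conv in convs:
        x = nn.conv_valid(x, conv.w, conv.b)
        x = np.maximum(x, 0.0)
        n, c, h, wd = x.shape
        x = (
            x[:, :, : 2 * (h // 2), : 2 * (wd // 2)]
            .reshape(n, c, h // 2, 2, wd // 2, 2)
            .max(axis=(3, 5))
        )
    c_f, h_f, w_f = detector._feat_shape
    fc, out = denses
    kernel = fc.w.T.reshape(arch.fc_units, c_f, h_f, w_f)
    x = nn.conv_valid(x, kernel, fc.b)  # (1, fc_units, 1, k)
    x = np.maximum(x, 0.0)
    logits = np.tensordot(x[0, :, 0, :].T, out.w, axes=([1], [0])) + out.b  # (k, 2)
    probs = nn.SoftmaxCrossEntropy.probs(logits)[:, 1]
    out_times = times[::stride]
    assert out_times.size == k
    return ProbabilityTrack(probs, out_times, arch.name)


@dataclass(frozen=True)
class SegmentationParams:
    """Amplitude-threshold segmentation baseline parameters.

    ``s_t`` is the spectrogram amplitude threshold; connected regions above
    it larger than ``s_r`` cells count as detections.
    """

    s_t: float = 3.0
    s_r: int = 25

    def __post_init__(self) -> None:
        if self.s_r < 1:
            raise ValueError("s_r must be >= 1")


def segmentation_detect(
    spec: Spectrogram, params: SegmentationParams
) -> list[DetectionEvent]:
    """Binary segmentation detector: threshold, label, filter by region size.

    Each sufficiently large 8-connected region of cells above ``s_t`` yields
    one detection at the region's earliest frame time, probability 1.0.
    """
    if not spec.denoised:
        raise ValueError("segmentation expects a denoised spectrogram")
    mask = spec.values > params.s_t
    if not mask.any():
        return []
    labels = cc_label(mask, connectivity=2)
    events = []
    for region in regionprops(labels):
        if region.area > params.s_r:
            first_col = int(region.bbox[1])
            events.append(
                DetectionEvent(
                    time=float(spec.frame_times[first_col]),
                    probability=1.0,
                    source_id=spec.source_id,
                )
            )
    events.sort(key=lambda e: e.time)
    return events


def gradient_features(window: DetectorInputWindow) -> np.ndarray:
    """Gradient-magnitude features of one window, flattened row-major.

    Central differences in both axes (one-sided at the edges), magnitude
    per cell; length 130*20 = 2600.  This is the candidate feature set for
    the random-forest baseline.
    """
    gy, gx = np.gradient(window.values)
    return np.hypot(gy, gx).ravel()


class ForestDetector:
    """Random-forest window classifier over gradient-magnitude features."""

    def __init__(self, n_estimators: int = 100, seed: int = 0, **kwargs):
        from sklearn.ensemble import RandomForestClassifier

        self.clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1, **kwargs
        )
        self.trained = False

    def fit(self, windows: np.ndarray, y: np.ndarray) -> "ForestDetector":
        feats = np.stack(
            [gradient_features(DetectorInputWindow(w, 0.0)) for w in windows]
        )
        self.clf.fit(feats, y)
        self.trained = True
        return self


def forest_detect(
    forest: ForestDetector, windows: list[DetectorInputWindow]
) -> ProbabilityTrack:
    """Per-window positive probability (fraction of trees voting positive)."""
    if not forest.trained:
        raise ValueError("forest detector has not been trained")
    if not windows:
        return ProbabilityTrack(np.empty(0), np.empty(0), "random_forest")
    feats = np.stack([gradient_features(w) for w in windows])
    proba = forest.clf.predict_proba(feats)
    pos_col = list(forest.clf.classes_).index(1)
    times = np.array([w.start_time for w in windows])
    return ProbabilityTrack(proba[:, pos_col], times, "random_forest")
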