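"""Detector models: CNN presets, fullconv/sliding equivalence, baselines."""

import numpy as np
import pytest

from chirpnet.models import (
    CNN_FAST,
    CNN_FULL,
    CnnArchitecture,
    ForestDetector,
    SegmentationParams,
    build_detector,
    forest_detect,
    gradient_features,
    predict_fullconv,
    predict_sliding,
    segmentation_detect,
)
from chirpnet.spectrogram import (
    DETECTOR_SHAPE,
    DetectorInputWindow,
    GRID_HOP,
    Spectrogram,
    SpectrogramParams,
    prepare_windows,
)

from conftest import random_canonical_spectrogram


class TestBuildDetector:
    def test_fast_preset_outputs_scalar_probability(self):
        det = build_detector("cnn_fast", seed=0)
        p = det.predict_proba(np.zeros(DETECTOR_SHAPE))
        assert p.shape == (1,)
        assert 0.0 <= p[0] <= 1.0

    def test_same_seed_identical_weights(self):
        a = build_detector(CNN_FAST, seed=42)
        b = build_detector(CNN_FAST, seed=42)
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa, pb)

    def test_fast_has_fewer_parameters_than_full(self):
        assert build_detector(CNN_FAST, 0).n_params < build_detector(CNN_FULL, 0).n_params

    def test_collapsing_geometry_rejected(self):
        bad = CnnArchitecture(conv_layers=((8, 13, 21),))  # wider than input
        with pytest.raises(ValueError):
            build_detector(bad, 0)

    def test_save_load_roundtrip(self, tmp_path):
        det = build_detector("cnn_fast", seed=3)
        path = tmp_path / "weights.npz"
        det.save(path)
        loaded = type(det).load(path)
        x = np.random.default_rng(0).normal(size=(4, *DETECTOR_SHAPE))
        np.testing.assert_array_equal(det.predict_proba(x), loaded.predict_proba(x))


class TestSlidingFullconvEquivalence:
    """The module's central correctness oracle: the dense layer evaluated as a
    convolution must reproduce naive window-by-window evaluation exactly."""

    @pytest.mark.parametrize("seed", range(8))
    def test_tracks_agree_on_random_spectrograms(self, seed):
        rng = np.random.default_rng(seed)
        det = build_detector("cnn_fast", seed=seed)
        spec = random_canonical_spectrogram(rng, width=int(rng.integers(40, 260)))
        sliding = predict_sliding(det, prepare_windows(spec, stride_frames=4))
        fullconv = predict_fullconv(det, spec)
        assert len(fullconv) == len(sliding)
        np.testing.assert_allclose(fullconv.probs, sliding.probs, atol=1e-4)
        np.testing.assert_allclose(fullconv.times, sliding.times, atol=1e-12)

    def test_output_length_is_quarter_of_input_width(self):
        rng = np.random.default_rng(0)
        det = build_detector("cnn_fast", seed=0)
        for pooled_width in (20, 40, 120):
            spec = random_canonical_spectrogram(rng, width=2 * pooled_width)
            track = predict_fullconv(det, spec)
            assert len(track) == pooled_width // 4 + (pooled_width % 4 > 0)

    def test_single_window_width_gives_five_outputs(self):
        rng = np.random.default_rng(1)
        det = build_detector("cnn_fast", seed=0)
        spec = random_canonical_spectrogram(rng, width=40)  # 20 pooled frames
        track = predict_fullconv(det, spec)
        assert len(track) == 5
        sliding = predict_sliding(det, prepare_windows(spec, stride_frames=4))
        assert track.probs[0] == pytest.approx(sliding.probs[0], abs=1e-4)

    def test_all_zero_spectrogram_gives_constant_track(self):
        rng = np.random.default_rng(2)
        spec = random_canonical_spectrogram(rng, width=160)
        zero = Spectrogram(
            values=np.zeros_like(spec.values),
            row_freqs=spec.row_freqs,
            frame_times=spec.frame_times,
            params=spec.params,
            denoised=True,
            canonical=True,
        )
        det = build_detector("cnn_fast", seed=0)
        track = predict_fullconv(det, zero)
        # every full (non-padded) window sees identical input
        interior = track.probs[:-5]
        assert np.ptp(interior) <= 1e-6

    def test_undenoised_spectrogram_rejected(self):
        from dataclasses import replace

        rng = np.random.default_rng(3)
        spec = replace(random_canonical_spectrogram(rng, width=40), denoised=False)
        with pytest.raises(ValueError, match="denoised"):
            predict_fullconv(build_detector("cnn_fast", 0), spec)


def _brute_force_components(mask):
    """Independent 8-connectivity labelling by flood fill."""
    mask = mask.copy()
    comps = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if not mask[i, j]:
                continue
            stack, cells = [(i, j)], []
            mask[i, j] = False
            while stack:
                a, b = stack.pop()
                cells.append((a, b))
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        na, nb = a + da, b + db
                        if (
                            0 <= na < mask.shape[0]
                            and 0 <= nb < mask.shape[1]
                            and mask[na, nb]
                        ):
                            mask[na, nb] = False
                            stack.append((na, nb))
            comps.append(cells)
    return comps


def _blob_spec(values):
    h, w = values.shape
    return Spectrogram(
        values=values,
        row_freqs=np.linspace(5e3, 135e3, h),
        frame_times=np.arange(w) * GRID_HOP,
        params=SpectrogramParams(),
        denoised=True,
    )


class TestSegmentation:
    def test_empty_spectrogram_yields_no_detections(self):
        spec = _blob_spec(np.zeros((20, 30)))
        assert segmentation_detect(spec, SegmentationParams(1.0, 4)) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_component_labelling(self, seed):
        rng = np.random.default_rng(seed)
        values = (rng.random((25, 40)) < 0.15) * 5.0
        spec = _blob_spec(values)
        params = SegmentationParams(s_t=1.0, s_r=2)
        got = [e.time for e in segmentation_detect(spec, params)]
        comps = _brute_force_components(values > params.s_t)
        expected = sorted(
            spec.frame_times[min(c[1] for c in cells)]
            for cells in comps
            if len(cells) > params.s_r
        )
        np.testing.assert_allclose(got, expected)

    def test_two_separated_blobs_two_detections_sorted(self):
        values = np.zeros((20, 40))
        values[5:8, 3:6] = 9.0
        values[10:13, 30:33] = 9.0
        spec = _blob_spec(values)
        events = segmentation_detect(spec, SegmentationParams(1.0, 4))
        assert len(events) == 2
        assert events[0].time == pytest.approx(spec.frame_times[3])
        assert events[1].time == pytest.approx(spec.frame_times[30])
        assert all(e.probability == 1.0 for e in events)


class TestGradientFeatures:
    def test_constant_window_gives_zero_vector(self):
        win = DetectorInputWindow(np.full(DETECTOR_SHAPE, 3.3), 0.0)
        feats = gradient_features(win)
        assert feats.shape == (2600,)
        assert np.all(feats == 0.0)

    def test_vertical_step_edge_localised(self):
        values = np.zeros(DETECTOR_SHAPE)
        values[:, 10:] = 1.0
        feats = gradient_features(DetectorInputWindow(values, 0.0)).reshape(DETECTOR_SHAPE)
        assert np.all(feats[:, [9, 10]] > 0)
        assert np.all(feats[:, :9] == 0)
        assert np.all(feats[:, 11:] == 0)


class TestForest:
    def _windows(self, rng, n=8):
        return [
            DetectorInputWindow(rng.random(DETECTOR_SHAPE), i * 4 * 2 * GRID_HOP)
            for i in range(n)
        ]

    def test_untrained_forest_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="trained"):
            forest_detect(ForestDetector(), self._windows(rng))

    def test_track_geometry_and_single_tree_probs(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, *DETECTOR_SHAPE))
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        forest = ForestDetector(n_estimators=1, seed=0).fit(X, y)
        windows = self._windows(rng, n=12)
        track = forest_detect(forest, windows)
        assert len(track) == 12
        assert set(np.unique(track.probs)) <= {0.0, 1.0}
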