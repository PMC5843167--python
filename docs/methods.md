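# Methods

## Problem

Passive acoustic monitoring of bats records ultrasonic audio in which
search-phase echolocation calls — short (2–10 ms) downward
frequency-modulated sweeps, typically between ~20 and ~120 kHz — must be
localised in time.  Recordings are frequently *time-expanded*: the waveform
is slowed by an integer factor (×10 is the classic survey setting) so that
a 44.1 kHz WAV file carries a 441 kHz effective sampling rate.  All
quantities in this package are expressed in real (pre-expansion) units;
file time = real time × expansion factor.

`chirpnet` detects call *start times*.  It does not classify species, and it
does not attempt feeding-buzz or social-call detection.

## Detection pipeline

1. **Spectrogram.**  Short-time Fourier transform with a target frame of
   2.3 ms real time, 75 % overlap, Hann window.  The frame length in
   samples is the nearest power of two to `frame_duration ×
   effective_rate` (1,024 samples at 441 kHz effective), and the realised
   frame duration is recomputed from that rounded length.  Magnitudes are
   log-compressed as `log(m + ε·ref)` with `ε = 1e-6` of the full-scale
   reference magnitude `ref = Σwindow/2`, and only the 5–135 kHz band is
   retained (302 rows for the 1,024-point FFT).

2. **De-noising.**  Spectral mean subtraction: each frequency row has its
   temporal mean removed.  Stationary background noise contributes a
   near-constant per-band level, so this whitens the background while
   leaving transient calls.  Negative residuals are clamped to zero
   (spectral-subtraction convention); a `clamp=False` mode preserves the
   exact zero-mean residuals and is what makes the operation idempotent.

3. **Canonical detector grid.**  The native spectrogram geometry depends on
   the file sampling rate, but the detector input must not.  The
   band-limited spectrogram is bilinearly resampled onto a fixed grid of
   260 frequency rows (linear between 5 and 135 kHz) × 0.575 ms time hop,
   then 2×2 mean-pooled to 130 rows × 1.15 ms.  Detector windows are 130
   bins × 20 steps = 23 ms of real time.  The native-to-canonical
   resampling step is this package's own construction: it guarantees the
   published 130×20 window for any input rate.  Trailing windows are
   zero-padded on the right.

4. **CNN window classifier.**  Binary classification (call start vs
   background) of 130×20 windows.  Two presets:

   * `CNN_FAST`: conv 16@13×5 → ReLU → maxpool 2×2 → conv 16@13×5 → ReLU
     → maxpool 2×2 → dense 64 → ReLU → dense 2 (softmax).  ≈65 k
     parameters.
   * `CNN_FULL`: conv 32@13×5, conv 32@11×3, conv 64@9×2 (each with ReLU +
     2×2 maxpool) → dense 64 → dense 2.  ≈106 k parameters.

   The `CNN_FULL` interior filter geometry and the `CNN_FAST` kernel sizes
   are package defaults, fully configurable through `CnnArchitecture`; only
   the block counts, the 16-filter width of `CNN_FAST`, and its 64-unit
   dense layer are fixed design points.

5. **Fully-convolutional evaluation.**  All convolutions are *valid*
   (unpadded).  Because of this, the dense layer can be evaluated as one
   more convolution over the whole spectrogram: two 2× pools give an output
   stride of 4 grid frames (4.6 ms), and padding the grid on the right so
   that every stride-4 window start (including zero-padded trailing
   windows) yields one output makes the output length exactly
   `ceil(width/4)`.  Window starts are multiples of the pooling product, so
   every pooling partition of an embedded window coincides with the
   partition of the isolated window; the fully-convolutional track is
   therefore *identical* to sliding-window evaluation up to float
   associativity (measured ≲1e-7 in float32, asserted ≤1e-4).

6. **Non-maximum suppression.**  The probability track is reduced to local
   maxima: a frame survives if it is the maximum within ±11.5 ms (half the
   detection window; configurable — the interval is not a published
   constant) and above a floor (0.05).  Exact ties keep the earliest frame
   of the plateau.

7. **Pass grouping.**  For monitoring statistics, calls in the same 3.84 s
   sound clip share a bat pass, and a pass continues across a clip boundary
   iff the adjacent clip also contains calls — i.e. passes are maximal runs
   of consecutive occupied clips.  The known failure mode (several bats
   calling at once are merged into one pass) is inherent to the heuristic
   and not addressed here.

## Training

Positives are windows whose start lies within ±2.3 ms (two pooled grid
frames) of an annotated call start; negatives must be ≥15 ms from every
call start, and are subsampled to a 1:1 ratio.  Both margins are package
defaults (they are not published constants).  Windows containing insect or
mechanical confusers are deliberately left in the negative pool.
Optimisation is Adam (lr 1e-3, batch 64, 20 epochs) on softmax
cross-entropy, implemented directly in numpy; with ~4,000 windows this
trains in a few CPU-minutes.  All randomness flows through
`numpy.random.default_rng(seed)`, so loss histories are bit-identical
across runs on one platform.

Annotation hygiene: call starts within 6 ms of each other (transitively)
are merged — harmonics of one call are often annotated separately — and
the merged group is represented by its *earliest* time, the physical call
onset.

## Evaluation protocol

A detection is a true positive if it falls within 10 ms of an annotated
call start (boundary inclusive, with a 1e-9 s slack so the boundary
survives float round-off); each annotation is consumed at most once.
Matching is greedy in descending probability (ties by earlier time), each
detection claiming the nearest unconsumed annotation; an optimal bipartite
matching is available for comparison (`method="optimal"`), and on random
instances never finds more pairs than greedy loses by more than the usual
adversarial constructions.  Precision = TP/(TP+FP) with the convention
that zero detections score precision 1 (the top of the sweep); recall =
TP/(number of annotated calls).

The PR curve sweeps every distinct probability; ties form a single step.
Because lower-probability detections cannot change the matches of
higher-probability ones, one greedy pass labels every detection TP/FP for
all thresholds at once, and the sweep is a cumulative sum (verified
against per-threshold re-matching by brute force).  Average precision is
the area under the max-to-the-right interpolated precision envelope.
Recall at 0.95 precision is the highest recall at any sweep point with
precision ≥0.95, and zero when that precision is never reached.  Binary
detectors (segmentation) are a single PR point; to place them on the AP
scale the one-point envelope integrates to precision × recall.

## Baselines

* **Segmentation**: 8-connected components of de-noised spectrogram cells
  above an amplitude threshold `S_t`, kept if larger than `S_r` cells; one
  detection per region at its earliest frame.  Defaults `S_t = 3.0` (log
  units), `S_r = 25` were chosen by a best-of-sweep on synthetic scenes —
  this baseline is evaluated at its best case, and even so shows the
  characteristic high-recall/low-precision behaviour.
* **Random forest**: 100 trees on the flattened per-window gradient
  magnitude (central differences; 2,600 features), probability = fraction
  of trees voting positive, applied with the same windowing, NMS and
  evaluation as the CNNs.

## Synthetic soundscapes

Scenes emulate the time-expansion snapshot protocol: a 3.84 s file at
44.1 kHz holding 3.2 s of ×10-expanded payload (320 ms real) with silent
buffers.  The payload contains:

* a train of downward FM calls (linear, hyperbolic, or CF-FM shapes;
  f_start ∈ 55–110 kHz, f_end ∈ 22–45 kHz, 2–8 ms, optional 2nd harmonic)
  with one near-regular inter-pulse interval per scene drawn from
  50–200 ms — trains that cannot fit the payload raise an error, and the
  corpus generator draws call counts that fit;
* a pink-noise bed (RMS 0.01 full scale);
* insect-like confusers: amplitude-modulated tones at 8–28 kHz, 6–14 dB
  above the noise bed;
* broadband impulses ("mechanical clicks"), 8–16 dB above the bed.

Per-call SNR (call RMS over its support vs the noise-bed RMS) defaults to
12 dB; benchmark corpora draw per-scene SNR uniformly from 6–18 dB and
call counts uniformly from 0 to 6.  Scene *i* of a corpus is generated
from seed `(corpus_seed × 1000003 + i) mod 2³¹`, so corpora regenerate
bit-identically and adjacent corpus seeds do not share scene streams.

What the generator does **not** emulate: atmospheric attenuation and
spreading loss, echoes/reverberation, Doppler, overlapping bats,
species-specific call libraries, and recorder frequency response.  Passing
the end-to-end tests therefore demonstrates that the pipeline machinery —
geometry, training loop, detection and scoring — recovers planted calls
under realistic noise and confusers; it does not certify field
performance on real recordings, which depends on training data.

## Benchmark scales and expected results

The end-to-end check trains `CNN_FAST` on 200 scenes (≈500 calls → ≈4,000
windows) and evaluates on 40 held-out scenes; the method-ordering check
(CNN ≥ forest ≥ segmentation in mean AP) uses five seeds at 30/12 scenes
with 8 epochs.  These sizes are the package's benchmark definition.  On
this benchmark the trained CNN reaches held-out AP ≥ 0.95 and recall at
0.95 precision ≥ 0.90 (the acceptance thresholds), the forest lands below
the CNN, and segmentation far below both.

## Numerical choices

* CNN arithmetic in float32; spectrograms in float64.
* He-normal initialisation; Adam β = (0.9, 0.999), ε = 1e-8.
* Log-compression offset 1e-6 of full scale; all-zero audio maps to a
  constant log floor.
* WAV I/O: mono PCM16 (or float) only; multi-channel files are rejected
  unless a channel is selected explicitly.  PCM16 write rounds at 1/32768
  full scale, so write/read round-trips to quantisation accuracy.
* Degenerate inputs: clips shorter than one frame, double de-noising,
  un-denoised input to windowing/detection, empty ground truth in recall,
  Nyquist-violating call synthesis, and overflowing call trains all raise
  `ValueError` rather than returning silently wrong results.

## Known limitations

* Calls longer than the 23 ms window (e.g. horseshoe-bat CF calls) exceed
  the detector's receptive field; templates are capped at 23 ms.
* The canonical-grid resampling assumes the 5–135 kHz band is present in
  the recording's Nyquist range.
* The pass-grouping heuristic undercounts simultaneous bats.
* The numpy CNN is single-threaded BLAS-bound; it is sized for the
  benchmark corpora, not for training on large field datasets.
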