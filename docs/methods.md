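# Methods

This note documents the models behind each pipeline, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the numerical conventions.

## Telemetry ECG analysis

### Signal model and detection

Mouse telemetry is treated as a uniformly sampled single-lead voltage
series (default 2 kHz; anything below 1 kHz is rejected because VT at
more than 800 bpm requires resolving RR intervals under 75 ms).  R peaks
are detected on the rectified, median-centered signal with
`scipy.signal.find_peaks`, using a refractory distance of 43 ms (the RR
of the maximum plausible murine rate, ~1400 bpm) and a prominence floor
of 0.3 × the 99th-percentile rectified amplitude.  Detecting on the
rectified trace makes the detector polarity-blind, which matters because
ventricular complexes are often inverted relative to sinus.

Per beat we record:

* **QRS width** at 20% of peak height (`peak_widths`, `rel_height=0.8`);
* **template correlation**: Pearson correlation of the signed ±30 ms
  window with the pointwise median window over all beats.  In any
  telemetry trace sinus beats dominate, so the median window is a sinus
  template.  The ±30 ms half-width is deliberately wider than the QRS:
  in a short window, mean-centering makes any narrow monophasic
  deflection resemble a biphasic complex and inflates the correlation of
  fibrillatory deflections with the sinus template; at ±30 ms the window
  also covers the T wave, which separates the classes cleanly.

### Beat classification and episode rules

A beat is **ventricular** iff its width exceeds 1.5 × the median sinus
width *or* its template correlation falls below 0.7; with fewer than 10
beats no template can be established and beats are indeterminate.  Both
thresholds are package defaults exposed as arguments — the original
readings were done manually, so the numeric operating point is a design
choice validated on synthetic data.

**VT**: maximal runs of ≥ 4 consecutive ventricular beats, every RR
< 60/800 s, not interrupted by any sinus beat.  Episodes are half-open
`[first R, last R)` intervals; `n_cycles` is the run length.  A
brute-force scanner that applies these criteria verbatim to every beat
window is kept in the test suite and must agree exactly with the run
detector on every input.

**Vfib**: 1-s windows at 50% overlap are flagged when detected peaks
inside show interval CV > 0.3 *and* amplitude CV > 0.3 *and* mean rate
> 800 bpm *and* maximal sinus-template correlation < 0.5; contiguous
flagged windows merge.  The criteria are qualitative in origin
("pronounced variability in waveform, peak–peak interval and height");
the window length and CV/correlation cut-offs are declared defaults.
Atrial dissociation is not implemented (P waves are neither synthesized
nor detected), so that criterion is satisfied vacuously.  Where a VT
call overlaps a Vfib interval, the beat belongs to Vfib (the more severe
class) and the VT episode is dropped.  Short ventricular runs at the
uncovered edges of a Vfib segment can survive as separate VT calls; at
window resolution this is an accepted boundary artifact.

### Derived metrics

* **Burden**: per kind, the sum of episode durations clipped to the
  observation horizon, after dropping episodes shorter than
  `min_episode_s` (0 in telemetry mode; 1.0 s in EP-study mode, which
  excludes all VTs under one second).  A per-hour vector partitions the
  total exactly.  Burden in cycles counts beats.  We clip at the horizon
  rather than counting episodes by onset, and count cycles as beats —
  both conventions are documented here because either reading is
  defensible.
* **Incidence** counts all subjects; burden summaries cover only
  subjects with burden > 0 (the convention borrowed from atrial-
  fibrillation burden guidelines).
* **Heart rate**: mean of 60/RR over beat pairs fully inside VT episodes
  (VT rate) or fully outside episodes with both beats sinus (sinus
  rate).
* **QTc**: windows around ≥ 5 clean sinus beats are ensemble-averaged
  before measurement (averaging suppresses noise by √n, which a
  per-cycle tangent measurement cannot).  QRS onset is the last upward
  crossing of 20% of R amplitude before the peak; T-wave end is the
  tangent at the steepest point of the decaying limb extrapolated to
  baseline, after Gaussian smoothing (σ = 1.5 ms).  The correction is
  the rodent normalization QTc = QT / √(RR / 100 ms), selected because
  the heart-rate correction formula for mice is a field standard while
  none is fixed by the analysis being reproduced; it is configurable.
* **Bland–Altman** agreement works on per-pair percent differences
  100 (a − b) / mean(a, b); pairs with zero mean are excluded with a
  warning; limits of agreement are bias ± 1.96 SD and are undefined for
  a single pair.

## Synthetic ECG generator

Sinus beats share one Mexican-hat (biphasic) QRS template
(σ = 2.5 ms, 1 mV) followed by a Gaussian T wave (amplitude 0.25 mV,
apex 25 ms after R, σ = 7 ms); ventricular beats use an inverted,
twice-as-wide template (σ = 5 ms, 0.8 mV) with no T wave, and replace
the sinus schedule inside their episode window.  Only the
width/morphology contrast matters for the classifier, so no attempt is
made at physiological realism (no P waves, no heart-rate variability,
no baseline wander).  Default rates follow the study regimes: 550 bpm
sinus, planted VT above 800 bpm (typically 900–1200).

The generator's ground-truth QT is computed from the same template by
the same onset rule and the closed-form tangent T end (for a Gaussian
limb the tangent at the inflection point crosses baseline exactly at
apex + 2σ), so the QT measurement can be validated to millisecond
accuracy.

**Vfib synthesis.**  Disorganized activity is an irregular train of
broad Gaussian deflections (σ 3–7 ms, random polarity, bimodal
amplitudes 0.7–1.0 / 1.5–2.2 mV) over a band-limited noise floor.
Inter-deflection intervals mix short couplings (43.5–50 ms) with
intermittent pauses (100–160 ms) scheduled every 3–6 deflections, so in
any 1-s window the realized mean rate stays above 800 bpm while the
interval CV exceeds 0.3; the bimodal amplitudes keep the amplitude CV
above 0.3; and because the sinus QRS template is zero-mean and biphasic,
smooth monophasic deflections are nearly orthogonal to it, keeping the
maximal template correlation below 0.5.  A filtered-noise-only synthesis
was evaluated first but cannot satisfy rate > 800 bpm and interval
CV > 0.3 simultaneously once the detector's 43 ms refractory floor is
applied, which motivated the designed point process.

Episode placement is validated against overlap and out-of-range starts;
VT rates ≤ 800 bpm are rejected at construction so planted truth always
satisfies the detection criteria.  All randomness comes from a single
`numpy.random.Generator` seeded per call, so identical spec + seed is
bit-reproducible.

## Dyssynchrony imaging

### Model

A paced myocyte grid (default 10 × 10 cells of 8 × 8 px at 2 µm/px,
8 Hz pacing, 30 cycles, 8 frames per cycle) emits one Ca²⁺ transient per
cycle: instantaneous rise at the cell's peak phase, exponential decay
with time constant 20% of the cycle.  Synchronous cells peak at the same
phase every cycle; dyssynchronous cells jitter their peak phase
per cycle (Gaussian, SD 8–12% of the cycle in the study conditions).
The nominal peak phase (0.125) coincides with a frame of the 8-per-cycle
raster, and gating at that phase maximizes sensitivity: with the gate at
the nominal peak, a jittered cell is caught before its rise (near
baseline) on roughly half the cycles and just after the peak (near full
amplitude) on the rest, making the gated series strongly bimodal.  In
noise-free movies the gated series of a synchronous cell is exactly
constant — this is asserted by test.

The neutrophil channel holds static Gaussian blobs (σ = 4 µm), placed
uniformly over the FOV or clustered uniformly within a disc
(default 25 µm) around randomly chosen dyssynchronous cells.  Planted
dyssynchronous cells are sampled non-adjacent on the grid (helper
`sample_separated_cells`) so each produces a separate hotspot component;
adjacent planted cells would merge into one component and make
recall accounting ambiguous rather than wrong.

What the generator does **not** emulate: tissue motion of the beating
heart, photobleaching, depth attenuation, non-square myocytes, partial
transient failure (alternans), or autofluorescence.  Passing tests
therefore show the pipeline recovers timing-variance structure under
ideal gating, not that it is robust to motion artifacts — motion
correction is explicitly out of scope.

### Pipeline conventions

* Gating keeps frames whose trigger phase is within a tolerance of the
  requested phase (circular distance), enforcing the 5–30 frame series
  convention (reject < 5, truncate at 30).
* The dyssynchrony map is the per-pixel sample SD (ddof = 1 — the series
  is a sample of cycles, and the choice is documented because either
  denominator is defensible); pixels whose series is exactly constant
  are set to exactly zero rather than the rounding residue of mean
  subtraction.  A naive two-pass SD oracle must agree to 1e-10.
* The hotspot threshold is μ_bg + k·σ_bg with k = 4, where the
  background is the set of map values below the 90th percentile.  This
  reads the "4 × SD" spark-detection convention as an SD multiple above
  background mean, with the background made explicit (the original
  plugin's internal background definition is not published); k, the
  percentile, and the minimum area (25 µm²) are all exposed.
  Components use 8-connectivity; centroids are unweighted pixel
  centroids; physical position of pixel (r, c) is ((c+0.5)·s, (r+0.5)·s)
  at pixel size s.
* Neutrophils are segmented from the time-maximum projection at the
  0.99 intensity quantile with a 20 µm² area floor.  Heavily clustered
  blobs can merge into fewer components; the analysis driver falls back
  to ground-truth coordinates when segmentation collapses entirely.
* Distances are centroid-to-centroid, hotspot → nearest neutrophil (the
  asymmetry with the neutrophil → hotspot direction is noted; only one
  direction is implemented).  Random spots are drawn on integer pixel
  coordinates, mirroring an integer-uniform spreadsheet draw, uniformly
  over the full FOV with no tissue mask.
* The FOV-level comparison uses per-FOV mean nearest distances, a
  seeded label-permutation test on the difference of means (two-sided)
  and Welch's t-test, both reported.

## FRI scoring

The slice generator draws a tissue disc (remote mean 100 counts) with an
infarct disc at `ratio` × the remote mean and a dim off-tissue
background (5 counts), plus Gaussian noise; the expected infarct/remote
mean ratio equals the spec ratio by construction.

The printed segmentation rule "MFI times 5 × s.d. of remote tissue" is
implemented as remote MFI **+** 5 × SD: the additive SD threshold is the
standard construction, and a literal product of three factors is
dimensionally and practically implausible (for any remote SD above
1/5 of the MFI it would exceed every pixel).  A literal-product mode
exists behind a flag, and every result records which rule produced it.
The Annexin target ROI is the largest connected positive component;
TMRE/CellROX use the supplied target mask.  The background convention is
bound to the assay enum (annexin → remote tissue; tmre/cellrox →
off-tissue) so a slice cannot be scored against the wrong background.
Intensities are treated as linear with no flat-field correction.
TBR is scale-invariant and shifts predictably under an additive offset
((t + c)/(b + c)); both properties are tested.

## Trend test

The JT statistic counts cross-group pairs with ties at ½.  The null
expectation is (N² − Σnᵢ²)/4 and the variance uses the Hollander–Wolfe
tie correction.  The normal approximation applies a 0.5 continuity
correction — the statistic lives on a half-integer lattice, and without
the correction the one-sided test is slightly anti-conservative.  The
exact null enumerates all distinct assignments of the pooled values to
groups when N ≤ 10 (so the "permutation" p equals the exact p by
construction at small N) and falls back to seeded Monte-Carlo
permutations otherwise, with the add-one rule (1 + hits)/(B + 1).
The default alternative is an increasing trend.  The clinical logistic
and Cox regressions are not re-implemented; they are ordinary fits that
standard libraries provide.

## Problem sizes and determinism

Study-condition sizes used by the tests and the acceptance script:
telemetry traces of 10 minutes at 2 kHz (cohorts of 12–20), movies of
80 × 80 px × 240 frames, slices of 128 × 128 px, spatial-null
calibration over 100–200 replicates of 6 FOVs with 400-permutation
tests, and JT simulations of 100–200 replicates.  These sizes give
stable Monte-Carlo estimates while keeping a full run in the minutes
range on one CPU.  Every stochastic component takes an explicit seed or
`numpy.random.Generator`; nothing touches global RNG state.

## Known limitations

* The beat classifier assumes sinus beats dominate the trace; a
  recording that is mostly VT would corrupt the median template.
* Vfib episode boundaries are quantized to half-window (0.5 s) steps,
  and edge beats of a Vfib segment can leak into short VT calls.
* QT measurement needs a T wave clearly separated from the next QRS; at
  sinus rates far above ~700 bpm the tangent fit degrades.
* Hotspot recovery guarantees hold for well-separated dyssynchronous
  cells; physically adjacent dyssynchronous myocytes merge into single
  hotspot components.
* The random-spot null ignores tissue geometry (no mask), matching the
  original procedure but not necessarily real tissue coverage.
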