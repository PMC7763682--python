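# Methods

## Pipeline

Given an ECG record, `tendos.pipeline.annotate` executes five stages:

0. **Preprocessing.** The record is resampled to the internal analysis
   rate of 250 Hz by rational-factor polyphase conversion (exact 4:5 for
   200 Hz sources). Baseline wander is *estimated* with a 4th-order
   Butterworth low-pass at `loff = 0.5 Hz` and subtracted — literally
   low-passing the signal would delete the QRS/T morphology, so the
   low-pass output is treated as the baseline estimate. Powerline
   interference is removed by second-order IIR notches at 50 and 60 Hz
   (Q = 30; both centres are notched because the mains frequency of a
   recording is not assumed known). Both filters are applied
   forward-backward: any phase distortion would shift the very quantity
   under study, the T-end location.
1. **R peaks** come either from supplied annotations (the evaluation
   mode: T-end performance isolated from R-peak errors) or from an
   Elgendi-style detector — two moving averages (97.5 ms QRS window,
   611 ms beat window, offset 0.08 × mean squared amplitude) over the
   squared 8–20 Hz band-passed signal, with each accepted block's peak
   snapped to the absolute extremum of the input within ±40 ms and a
   250 ms refractory rule.
2. **tSQI.** For cycle *i*, both delineators of `tsqi_pair` (default
   zhang + martinez) are compared on the window of ±1250 samples (±5 s)
   around R(i): A cycles with both estimates, B matching within
   γ = 50 ms (strict), tSQI = B/(2A−B); tSQI := 0 when A = 0 or when
   fewer than two R peaks fall in the window. The pipeline computes
   both full-record annotation sequences once and windows the counts —
   per-cycle estimates depend only on samples inside their own search
   window, so this equals running the delineators per segment (the
   segment-shaped `cycle_tsqi` exists and is tested against the fast
   path) while costing O(N) instead of O(N·beats).
3. **Optimal shrinkage** for cycles with tSQI < q (default q = 0.9).
   Templates are `z[R(i)−Lw .. R(i)+Rw]` with Lw = Rw = ⌈w/2⌉ and w the
   rounded 95% RR-interval quantile, so one template covers a whole
   P-QRS-T complex; boundary cycles that do not fit are excluded (and
   can therefore not be denoised). The noise level σ is estimated once
   per record as the RMS deviation of all templates from the
   per-coordinate **median** template. For each flagged cycle, its
   ξ = 19 nearest neighbours under the chosen metric (RR-interval
   difference by default; ℓ₂ template distance is the better choice for
   arrhythmic signals, where RR similarity does not imply morphology
   similarity) form S ∈ R^{p×(ξ+1)} with the cycle itself in column 1;
   ties in distance break by ascending cycle index so outputs are
   deterministic, and the last cycle uses its backward RR interval.
   S is oriented so rows ≤ columns, its singular values are normalized
   as y = λ/(σ√m) with m the larger dimension, the operator-norm
   optimal shrinker η*(y; β) (zero below the bulk edge 1 + √β) is
   applied, and the matrix is rebuilt on the same scale. The √m
   normalization is what places the noise bulk edge of an i.i.d.-noise
   matrix at 1 + √β; without it essentially no singular value would
   ever be shrunk. σ = 0 is an exact no-op.
4. **Final delineation.** Unflagged cycles take the base detector's
   full-record estimate. Flagged cycles are delineated on their single
   denoised template in local coordinates (R at index Lw, search window
   from the cycle's own RR) and mapped back via R(i) − Lw, so the gate
   changes *which waveform* is delineated, never the coordinate frame.
   If the template yields no decision the undenoised estimate is kept,
   and if the library is smaller than ξ+1 the pipeline warns and falls
   back to undenoised detection.

## Delineators

All three emit at most one T-end per cycle inside a search window of
0.15–0.70 of the local RR interval after R (clipped to (R(i), R(i+1))),
resolve T-wave polarity per cycle from the sign of the largest
excursion in the window (`auto`), and mark undecidable cycles as
missing rather than imputing — missing cycles are excluded from both
tSQI counts and evaluation.

* **zhang** maximizes the signed area A(t) = Σ_{k=t−W+1..t} (z(k) −
  z(t)) with W = 128 ms, after polarity normalization. For a positive
  T wave A is large and positive on the descending limb and peaks at
  the offset; the *absolute* area would instead peak at the T apex
  (where the −W·z(t) term dominates), so the signed form is used.
* **carlos** maximizes the trapezium area A(x_r) = ½ (y_s − y_r)(2x_m −
  x_r − x_s) between the T-peak (x_s, y_s) and a reference point x_m
  160 ms after it (clamped 20 ms short of the next R when necessary).
  T-peaks are taken from the wavelet delineator.
* **martinez_style** computes an undecimated smoothed-derivative
  transform at dyadic scales 16 then 32 (fallback): three cascaded
  boxcars of length `scale` approximate the quadratic B-spline and the
  kernel is its first difference — antisymmetric, zero-phase, with the
  same variance (63.75 samples² at scale 16) as the classic filter-bank
  cascade. The T-peak is the zero crossing between the dominant
  opposite-sign modulus-maxima pair in the window; the T-end is the
  first sample after the later maximum where the modulus falls below
  0.25 of it. This is a faithful-in-structure re-implementation of the
  classic multiscale delineator, not a port of its full multi-lead rule
  set, hence the `martinez_style` label.

The numeric defaults (window fractions, W, reference offset, decay
fraction) are visible in `DelineatorConfig` and overridable from the
YAML config; they are sensible mid-range choices for adult sinus rhythm
at 250 Hz, not values with special status.

## Noise models and SNR convention

Gaussian noise is i.i.d. N(0, 1). ARMA(1,1) noise follows
X_t = φX_{t−1} + c + Z_t + θZ_{t−1} with Student-t(4) innovations
(heavy-tailed, finite fourth moment only marginally), c = 0.5, φ = 0.5,
θ = −0.5; 1000 burn-in samples are discarded and the series is divided
by its realized sample SD *without* removing the stationary mean
c/(1−φ) = 1 — the baseline-removal stage absorbs the resulting offset.
With these constants the AR and MA polynomials cancel, so the process
is white around its mean (lag-1 autocorrelation 0), a property the
tests exploit as a closed-form oracle. Noise is added as
z + s·noise with s = RMS(z)/10^(SNR/20); since the generators normalize
to unit sample SD, SNR is defined against the noise SD, and a DC offset
in the noise does not count as noise power.

## Synthetic generator

`gen_synth_ecg` emulates quasi-periodic P-QRS-T cycles as sums of five
Gaussian bumps per beat (P, Q, R, S, T) with defaults typical of adult
sinus rhythm at 60 bpm (T wave: +300 ms from R, σ = 32 ms, 0.35 mV).
Beat-to-beat variability enters through RR jitter (SD 5% of the mean
RR) and per-wave amplitude jitter (SD 10%), both truncated at ±3 SD;
that variability is exactly the "clean-signal noise" that makes
unconditional shrinkage harmful and the tSQI gate necessary. The
ground-truth T-end of a beat is defined as T-centre + 3 × T-width
(where the Gaussian has decayed to ≈1.1% of its peak); any fixed
multiple would do for paired comparisons — the convention only shifts
all detectors' biases by a common constant. The generator does not
emulate pathological morphologies (biphasic T waves, ST shifts,
ectopy), structured artifacts, or real electrode noise; passing tests
demonstrate correct mechanics and the direction of the denoising gain
under the stated noise models, not clinical-grade accuracy on real
recordings.

On clean output the detectors carry small systematic biases relative to
the 3-width convention (zhang ≈ −14 ms, martinez ≈ +13 ms, carlos ≈
−18 ms at the defaults); they cancel in the paired with/without-OS
comparisons that the experiments report.

## Evaluation

Per recording, ME = mean |estimated − reference| in ms over cycles with
both present. Across recordings/rounds: median, MAD defined as the
*mean absolute deviation about the median*, and 2.5/97.5% empirical
quantiles with linear interpolation. Variants are compared by the
two-sided Wilcoxon signed-rank test (exact null for ≤ 25 non-zero
differences, else normal approximation with continuity correction; zero
differences dropped, all-zero input returns p = 1 with a warning). For
two-channel records with references made viewing both leads,
`best_channel_errors` takes, per cycle, the channel minimizing the
absolute error.

## Problem sizes and determinism

The packaged experiments use batteries of 2-minute, 60-bpm synthetic
records (≈120 cycles each — comfortably above the ξ + 1 = 20 templates
the denoiser needs): the acceptance tests run 10 records × {Gaussian,
ARMA(1,1)} × {10, 5 dB} × 20 rounds, and `scripts/acceptance.py` a
6-record, 5-round version of the same protocol plus the calibration
diagnostics. Every random quantity derives from explicit integer seeds
(`numpy` `SeedSequence` spawning per record/noise/round), so reruns are
bit-identical.

## Known limitations

* The spike model behind the shrinker treats beat-to-beat physiological
  variability as noise; the tSQI gate mitigates but does not remove the
  resulting clean-signal distortion risk (hence the guard tests).
* σ is estimated once per record; under strongly non-stationary noise a
  windowed estimate would be better.
* The wavelet delineator implements the single-lead core of the
  multiscale method only.
* Structured artifacts (electrode pops, motion) violate the i.i.d.
  noise assumption and are out of scope of the provided noise models.
* WFDB support covers format-16 single-`.dat` records and the MIT
  annotation scheme with SKIP escapes — enough for QT-database-style
  data, not the full format zoo.
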