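# tendos — noise-robust T-wave end annotation for ECG

Accurate automatic detection of the **T-wave end** (T-end, the offset of
ventricular repolarization and the endpoint of the QT interval) is a
prerequisite for QT-interval analysis in drug-safety studies and
long-term ambulatory monitoring. Classic T-end delineators work well on
clean recordings but degrade badly under the myogenic noise, motion
artifacts and electrode noise that dominate multi-day single-lead ECG.

`tendos` implements a two-part remedy for scientists and engineers who
need T-end annotations from noisy single- or two-channel ECG:

1. **A T-end signal quality index (tSQI).** Two independent delineators
   are run on each signal neighbourhood. With *A* cycles where both
   produced an estimate and *B* of those agreeing within a grace period
   γ (default 50 ms, strict inequality),

   tSQI = B / (2A − B) ∈ [0, 1],

   so 1 means the two algorithms agree perfectly and low values flag
   segments where the T wave is unreliable — a complement to R-peak
   agreement indices (bSQI, also provided), which cannot see T-wave
   quality.

2. **Optimal singular-value shrinkage (OS) of low-quality cycles.**
   Each cardiac cycle is cut into a fixed-length template around its R
   peak; a flagged cycle and its ξ = 19 nearest neighbours (by
   RR-interval difference, or ℓ₂ distance for arrhythmic ECG) form a
   p × (ξ+1) matrix S = X + N with low-rank signal X and i.i.d. noise
   N. With noise level σ estimated from the deviation of all templates
   from the per-coordinate median template, the operator-norm optimal
   shrinker

   η\*(y) = √(( y² − β − 1 + √((y² − β − 1)² − 4β) ) / 2)  for
   y ≥ 1 + √β, else 0,

   is applied to the noise-normalized singular values
   y = λ / (σ√m) (β = smaller/larger dimension, m the larger); the
   first column of the shrunk matrix is the denoised cycle, on which the
   base delineator then runs. Cycles with tSQI ≥ q (default q = 0.9)
   are left untouched — on clean signals beat-to-beat physiological
   variability masquerades as noise and unconditional shrinkage would
   distort the T wave.

Three delineators are included (area-function "zhang", trapezium-area
"carlos", wavelet "martinez_style"), plus WFDB/CSV I/O, an Elgendi-style
QRS detector, a synthetic-ECG generator with ground-truth fiducials,
Gaussian and heavy-tailed ARMA(1,1) noise models with SNR scaling, and
evaluation metrics (per-recording ME, median ± MAD, quantile intervals,
Wilcoxon signed-rank comparison).

## Worked example

```python
import numpy as np
import tendos as td
from tendos.pipeline import annotate_multi

# 2-minute synthetic ECG, contaminated with ARMA(1,1) noise at 5 dB SNR
rec, r_idx, tend_idx = td.gen_synth_ecg(td.SynthEcgSpec(duration_s=120, seed=0))
noisy = td.add_noise(rec, td.NoiseSpec("arma11", snr_db=5.0, seed=1))

rpeaks = td.AnnotationSeries("rpeak", r_idx, rec.fs, "truth")
truth = td.TendAnnotation(tend_idx, "truth", rec.fs, r_idx)

res = annotate_multi(noisy, td.PipelineConfig(), q_values=(0.0, 0.9), rpeaks=rpeaks)
for q in (0.0, 0.9):
    err, _ = td.detection_errors(res[q].tends, truth)
    print(f"q={q}: ME = {np.abs(err).mean():.1f} ms over {err.size} beats, "
          f"{res[q].denoised_flags.sum()} cycles denoised")
print(f"median tSQI = {np.median(res[0.9].tsqi_values):.2f}, "
      f"sigma_hat = {res[0.9].sigma_hat:.3f} mV")
```

prints

```
q=0.0: ME = 66.8 ms over 119 beats, 0 cycles denoised
q=0.9: ME = 15.7 ms over 119 beats, 118 cycles denoised
median tSQI = 0.38, sigma_hat = 0.089 mV
```

At 5 dB the raw area-function detector errs by 67 ms on average; the
tSQI gate flags nearly every cycle (median tSQI 0.38 ≪ 0.9), the
shrinkage rebuilds their morphology, and the mean error drops to 16 ms
— close to the ~14 ms the same detector achieves on the clean record.
`q=0` disables the denoiser and reproduces the base detector exactly.

The same run from the shell:

```bash
tendos simulate --kind arma11 --snr 5 --seed 0 --duration 120 --out rec.csv
tendos annotate rec.csv --rpeaks rec.csv.rpeaks.csv --detector zhang --q 0.9 --out demo
# -> 119 cycles, sigma_hat=0.08868, 118 denoised -> demo.tend.csv
```

`demo.tend.csv` lists one row per cycle: R index, T-end index and time,
tSQI, and whether the cycle was denoised. `tendos evaluate` scores an
estimate file against a reference and `tendos experiment` runs the full
noise-robustness protocol.

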