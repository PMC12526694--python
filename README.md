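# punchkan

Simulation and analysis pipeline for a repeated-measures NMES punch-force
study: 30 trained strikers complete a 3-minute maximal punch test (126
punches on a 0-2000 N transducer, 1 kHz) under Sham, upper-limb and
lower-limb neuromuscular electrical stimulation while 4-channel surface EMG
is recorded. The package is for sports-biomechanics and biosignal
researchers who want the whole chain — synthetic cohort, sEMG envelopes,
punch kinetics, condition statistics, and sEMG-to-force regression — as
tested, seeded, reproducible code.

Because no raw recordings are deposited, a calibrated generator stands in
for the cohort: per-punch kinetics are drawn around the published
per-condition summary cells with a shared per-subject intercept (the
within-subject correlation a repeated-measures design needs), realized as
force waveforms (piecewise-linear rise through the F5ms/tF50/tF90/peak
anchors, exponential decay, impulse matched in closed form) and as paired
pre-contact sEMG bursts whose channel amplitudes encode the punch kinetics
through a saturating activation map with a controllable unexplained-variance
share (`noise_share`, default 0.25).

Two analysis arms mirror the original study:

- **Condition statistics** — per-subject means -> box-plot outlier screen,
  Shapiro-Wilk, one-way repeated-measures ANOVA
  (F = MS_cond / MS_error with Greenhouse-Geisser correction of
  df = (k-1), (n-1)(k-1) when Mauchly's test rejects sphericity), and
  Bonferroni-adjusted paired t tests.
- **Force regression** — a Chebyshev-polynomial Kolmogorov-Arnold network
  (every edge carries phi(x) = sum_k Theta_k T_k(tanh x),
  T_k(x) = cos(k arccos x)) with per-step embedding, depthwise convolution,
  and per-frequency-component KAN blocks of increasing order (K = 2, 3, 5),
  trained with Adam (alpha = 0.001) on MSE + lambda sum w^2
  (lambda = 0.001), against 128-unit RNN and 2x128 LSTM baselines, with
  RMSE / MAE / R^2 reported on held-out subjects.

Models run on a small numpy reverse-mode autodiff engine included in the
package (`punchkan.autograd`), verified by central-difference tests.

## Worked example

```python
import numpy as np
from punchkan import CohortConfig, generate_cohort, pipeline
from punchkan.stats import rm_anova

ds = generate_cohort(CohortConfig(), seed=42, include_emg=False)
kin = pipeline.extract_kinetics(ds)
means = pipeline.subject_condition_means(kin)
for cond in ("Sham", "U-NMES", "L-NMES"):
    sub = means[means.condition == cond]
    print(f"{cond:7s} rel peak force {sub.relative_peak_force.mean():5.1f} N/kg, "
          f"impulse {sub.impulse.mean():5.1f} N*s, F5ms {sub.f5ms.mean():5.0f} N")
res = rm_anova(pipeline.rm_matrix(means, "relative_peak_force",
                                  ("Sham", "U-NMES", "L-NMES")))
print(f"RM-ANOVA: F = {res.F:.2f}, p = {res.p:.2e}")
```

prints

```
Sham    rel peak force  22.6 N/kg, impulse  11.2 N*s, F5ms   510 N
U-NMES  rel peak force  23.8 N/kg, impulse  13.3 N*s, F5ms   631 N
L-NMES  rel peak force  28.1 N/kg, impulse  16.3 N*s, F5ms   734 N
RM-ANOVA: F = 32.62, p = 3.22e-10
```

i.e. the extracted condition means land on the published calibration cells
(22.7 / 24.5 / 28.2 N/kg, 11.3 / 13.2 / 16.6 N*s, 511 / 631 / 754 N within
sampling error of a 30-subject draw) and the lower-limb stimulation effect
on force output is strongly significant, while the timing indicators are
not (see `docs/methods.md`).

The command-line surface chains the same stages:

```
punchkan simulate --seed 42 --out cohort.h5
punchkan extract --in cohort.h5 --out kinetics.csv
punchkan stats --in kinetics.csv --out stats.json
punchkan train --data cohort.h5 --indicator relative_peak_force \
               --condition L-NMES --model kan --out run/
punchkan reproduce --seed 42 --out report/     # one-shot full pipeline
```

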