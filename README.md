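# actipat

Early prediction of physical-activity recovery patterns in older patients
rehabilitating after hip-fracture surgery, from the first 5–8 days of
continuously monitored accelerometer data.

## The problem

During geriatric rehabilitation in a skilled nursing home, the daily overall
intensity of physical activity — the signal magnitude area (SMA) of a thigh-worn
25 Hz triaxial accelerometer — traces characteristic recovery trajectories.
The two most common are the **upward linear** pattern (steady rise from
admission; typically short stays) and the **S-shape** pattern (slow start,
steep mid-stay rise, plateau; typically long stays).  Because the pattern is
associated with the duration of the rehabilitation stay, predicting it from
only the first week of monitoring gives clinicians and patients an early
indication of the recovery course.

`actipat` implements the full analysis pipeline as scikit-learn-style
estimators plus a synthetic-cohort generator (no patient data are publicly
deposited, so the generator provides cohorts with the assumed statistical
structure):

1. **Preprocessing** — per day, 07:00–22:00: a 0.12 s moving average, a
   4th-order Butterworth high-pass at 1 Hz (gravity removal), then the SMA
   `(1/T) Σ_axes ∫|a(t)| dt` as the day's intensity.
2. **Features** on the first W ∈ {5,6,7,8} days: statistical (mean, median,
   SD, IQR, max, min–max range, RMS), amplitude (day-1 intensity, mean
   amplitude deviation), morphological (OLS slope, cubic coefficients a, b, c
   of `y = ax³ + bx² + cx + d`, mean first/second-order differences) and
   clinical scores (BI, FMS, FAC, MoCA); min–max normalised,
   `x′ = (x − min)/(max − min)`, fitted on the training rows.
3. **Feature selection** — symmetrical uncertainty
   `SU(X,Y) = 2·IG(X;Y)/(H(X)+H(Y))` on equal-frequency-discretised features;
   keep features whose SU with the class exceeds 0.9 *and* their SU with every
   other feature (empty selections fall back to all features, with a warning).
4. **Model** — stratified 80:20 patient split, a suite of classifiers
   (trees, discriminant analysis, logistic regression, SVMs, k-NN with
   euclidean/cosine distance, tree ensembles) ranked by stratified 5-fold CV
   accuracy; the winner predicts the held-out patients.
5. **Evaluation** — per-class precision/recall/F1 and the micro-F1
   `2ΣTP/(2ΣTP+ΣFP+ΣFN)` (equal to accuracy for single-label problems), plus
   a utility that reconstructs integer confusion matrices from rounded
   printed precision/recall percentages.

## Worked example

```python
import numpy as np
from actipat import (CohortSpec, RunConfig, run_pipeline)

cfg = RunConfig(cohort=CohortSpec(n_patients=200, seed=0), windows=(7,), seed=42)
manifest, reports = run_pipeline(cfg, "out/")
rep = reports[7]
print(rep["winner"], rep["evaluation"]["micro_f1"])
```

prints

```
logistic 1.0
```

i.e. on the default synthetic cohort (200 patients, 41% upward linear / 59%
S-shape) the best cross-validated classifier for the 7-day window classifies
all 40 held-out patients correctly (micro-F1 = 1.0).  The SU ranking in
`rep["selection"]["ranking"]` places the day-1 intensity among the strongest
class correlates, mirroring the central role of early activity levels in this
prediction task.  The same workflow is available from the shell:

```bash
actipat simulate --out cohort/
actipat extract-features --daily cohort/daily_intensity.csv \
    --patients cohort/patients.csv --window 7 --out features.csv
actipat select --features features.csv --out selection.json
actipat run --config examples/run.yml --out results/
actipat reconstruct-performance
```

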