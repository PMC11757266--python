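# opcirc

Quantification of intraoperative circulation time series and real-time
prediction of prolonged postoperative length of stay (PLOS).

## The problem

During long procedures such as head-and-neck surgery with free-flap
reconstruction, arterial blood pressure, heart rate and pulse are charted
every 5 minutes. Clinicians summarize these traces with a handful of manual
metrics — how long and how deeply pressure strayed beyond ±30% of its
pre-induction baseline, and how variable it was — but the traces carry far
more structure (spectral content, complexity, regularity, trend) that
generic time-series features can capture. `opcirc` implements both
assessment routes end to end and asks the operational question: which route
better predicts a prolonged stay, and can the prediction be updated live as
the surgery unfolds?

Because the underlying hospital data are not publicly available, the
package ships a synthetic cohort generator with fully recorded ground
truth, so every claim the pipeline makes can be tested against what was
actually planted.

## Core quantities

With MAP readings MAP_k at times t_k (k = 1..N, T = t_N − t_1, grid 5 min),
baseline MAP = reading 0 (pre-induction) and thresholds 0.7·baseline /
1.3·baseline:

- **TW hypotension** = ∫ max(0, thr_lo − MAP(t)) dt  (mmHg·min, trapezoid
  rule on the grid); TW hypertension analogously above thr_hi.
- **ARV** = (1/T) Σ_k Δt_k ·|MAP_{k+1} − MAP_k| — generalized average real
  variability; **ARVs** = (1/T) Σ_k |MAP_{k+1} − MAP_k|² / Δt_k.
- **Quantified features**: per channel (SBP, DBP, HR, pulse, MAP), seven
  families — DFT coefficients (k ≤ 9) with spectral centroid/variance,
  Ricker-wavelet CWT coefficients (widths 2/5/10/20), LZ76 complexity,
  approximate entropy ApEn(2, 0.2·SD), permutation entropy (order 3),
  block-aggregated linear trends (chunks 5/10 × mean/min/max), and
  duplicate-value fractions — 295 features in total.
- **Selection**: per-feature two-sided Mann-Whitney U (real) or Fisher
  exact (binary) against the PLOS label, Benjamini–Yekutieli FDR at
  q = 0.01, fitted on the primary cohort only.
- **Models**: random forest (500 trees) and xgboost (300 rounds, depth 3,
  η = 0.1) on {quantified | manual} + clinical covariates; min-max
  normalization fitted on the primary cohort; evaluation by AUROC with
  DeLong 95% CI, overall accuracy and the confusion matrix at 0.5; feature
  attribution by exact TreeSHAP (xgboost natively; an in-package
  path-dependent TreeSHAP for sklearn forests, validated against
  exhaustive Shapley enumeration).
- **Real-time scores**: the model is re-applied to every growing 5-minute
  prefix of a patient's record (features re-extracted per prefix,
  normalization frozen at training values); prefixes under 25 min fall
  back to the training prevalence.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/03_select_features.py
python analysis/04_compare_models.py
python analysis/05_realtime_replay.py
```

On the default synthetic cohort (804 patients, outcome driven by
time-weighted hypotension plus clinical risk factors) this prints, among
other things:

```
wrote 804 patients to results/cohort/
median LOS 10 d (IQR 10-12), PLOS prevalence 49.1%
quantified 295 features x 804 patients
3 / 295 features pass FDR q=0.01
  model   features algorithm  auroc  ci_lo  ci_hi    oa
Model 1 quantified        rf  0.602  0.514  0.690 0.575
Model 2 quantified       gbt  0.611  0.524  0.699 0.550
Model 3     manual        rf  0.652  0.567  0.737 0.594
Model 4     manual       gbt  0.643  0.557  0.728 0.569
patient p00704: 63 grid points, LOS 12 d, PLOS=1
score range 0.492-0.946, final 0.808
```

Read: the cohort median stay is 10 days, so PLOS prevalence sits near 50%
by construction. Under these default conditions the outcome loads directly
on TW hypotension, so the manual-metric models (which contain it verbatim)
edge out the quantified models — `tw_hypotension` tops the manual models'
SHAP ranking, and age/albumin/reoperation contribute consistently across
all four. When the generative signal is instead placed in oscillatory
(spectral) structure the ordering flips and the quantified models win;
that experiment is exercised in `tests/test_acceptance.py`. The replayed
patient's risk score starts at the training prevalence (0.492) and ends at
the model's static full-series prediction (0.808) exactly.

A `opcirc` console script exposes the same steps
(`simulate`, `extract`, `select`, `train`, `compare`, `score-rt`).

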