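# cmsehrv

Circadian, entropy-based heart-rate-variability analysis of 24 h ECG, and
the regression machinery to estimate left-ventricular ejection fraction
(LVEF, %) from it — with a synthetic cohort generator that plants known
ground truth so the whole pipeline is verifiable on a laptop.

## The problem

Echocardiographic LVEF is the workhorse measure of systolic function, but
it needs equipment and specialists that community screening settings lack.
Ambulatory ECG (Holter) is cheap and continuous, and beat-to-beat RR
variability carries autonomic information that tracks cardiac function.
Because heart rate and its complexity follow a circadian rhythm, an hourly
analysis can find the time window where that information is strongest.

`cmsehrv` implements that analysis end to end:

1. **Signal chain** — median-filter baseline removal; zero-phase 120 Hz
   low-pass, 50 Hz notch, 0.3 Hz high-pass; shift-invariant Haar wavelet
   denoising; Pan–Tompkins-style R-peak detection; RR correction (intervals
   deviating >20% from the running median of 11 neighbours are flagged and
   interpolated); segmentation into clock hours.
2. **Entropy features** — 15 estimators (PsdEn, Een, ApEn, SampEn, FuzzyEn,
   PEn, Aen, BubbEn, DispEn, DistEn, GdEn, IncrEn, PhaseEn, SlopEn, SyDyEn)
   evaluated as composite multiscale entropy: for scale factor τ the series
   is coarse-grained as

       y_j^(τ,k) = (1/τ) Σ_{i=(j−1)τ+k}^{jτ+k−1} x_i ,   k = 1..τ,

   the base entropy is averaged over the τ offset series, and the curve
   E(τ), τ = 1..20, is summarised by five parameters: E(1), E(5), the
   least-squares slope over scales 1–5, and the areas under the curve over
   scales 1–5 (short-term complexity index) and 6–20 (long-term).  With
   age, sex and hypertension history this gives 78 features per subject and
   clock hour.
3. **Estimation harness** — chained-equations multiple imputation; ten
   registered regressors (GPR, KNN, LR, MLP, RF, three SVM kernels,
   Treebag, CNN*); leave-one-out cross-validation with training-fold
   standardisation; greedy forward feature addition (add the candidate that
   minimises LOOCV RMSE, stop when nothing improves, cap 25); an hour ×
   model RMSE/MAE grid; Bland–Altman agreement (bias ± 1.96 SD).
4. **Reporting** — standardised-coefficient importance (0–100 axis),
   Monte-Carlo permutation Shapley values, heat-grid and ranked-bar
   figures.

*The CNN entry is registered but reported unavailable unless a
deep-learning backend is installed; nothing else depends on it.

## Worked example

Generate a 60-subject cohort whose LVEF is a known linear function of three
hour-21 CMSE features plus 4% noise, then run the hourly grid:

```python
from cmsehrv import pipeline

run = pipeline.run_planted_recovery(seed=1, n_subjects=60,
                                    hours=(20, 21, 22),
                                    models=("LR", "KNN", "GPR"))
print(run.grid_rmse.round(2))
print(run.best_hour, run.best_model)
print(run.selected_features[:3], run.planted_features)
```

Output from this exact call:

```
        LR   KNN   GPR
hour
20    6.02  7.03  6.13
21    2.19  3.65  2.38
22    6.72  6.57  5.74
21 LR
['SampEn_sc5', 'DispEn_a620', 'PEn_sc1'] ['SampEn_sc5', 'FuzzyEn_a15', 'PEn_sc1']
```

Reading it: hours 20 and 22 carry no LVEF signal, so their LOOCV RMSE sits
near the response SD (~6–7%); hour 21 carries the planted signal and every
model's error drops towards the planted noise level, with the true features
leading the greedy selection.  (At this small n the adaptive selection is
optimistic — the RMSE dips below the 4% noise floor; at n = 200 it
concentrates near 3.9–4.1%.)

The same stages are scriptable from the shell:

```
cmsehrv simulate --spec spec.yaml --out cohort/ --seed 1
cmsehrv extract-rr --in ecg.csv --out rr.csv
cmsehrv features --rr cohort/rr.csv --covariates cohort/covariates.csv --out feats/
cmsehrv evaluate --features feats/ --models LR,KNN,GPR --out results/ --seed 1
cmsehrv report --results results/ --out report/
```

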