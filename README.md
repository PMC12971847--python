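# suturemetrics

Quantitative suture assessment: from pixel-annotated images of sutured
specimens to spacing-irregularity metrics and their statistical relationship
with burst-pressure resistance.

Suture quality is still judged mostly by eye.  This package implements an
objective alternative for bench studies of minimally invasive suturing: a
checkerboard in each photograph calibrates pixels to millimetres, annotated
needle entry/exit points and the incision line yield the two primitive
distance families of the small-bites protocol —

* **PM** (point-to-margin): distance from each entry/exit point to the
  incision, target 5 mm;
* **PP** (point-to-point): distance between consecutive entry (or exit)
  points, target 5 mm —

and from them 18 spacing metrics per trial (max / mean / SD of each family
and of its absolute deviations from the 5 mm target, plus the pooled
family).  The statistical chain then links spatial precision to mechanical
outcome across platforms (laparoscopy, dVRK, flexible endoscope) and
operator experience levels:

* Tukey-fence (IQR) outlier screening, Kruskal–Wallis global tests with
  Dunn post hoc comparisons, and Monte-Carlo retrospective power /
  required-sample-size estimation;
* a Spearman screen of all metrics against burst pressure with Fisher-z
  correlation power analysis (selection at p < 0.05);
* VIF collinearity diagnostics, XGBoost regression under repeated K-fold
  cross-validation (k = 5, 10 repeats; per-fold MSE / R² / MAE), residual
  analysis, and exact TreeSHAP feature attributions;
* SUS usability scoring (0–100 with the standard bands) and per-dimension
  NASA-TLX workload banding.

Because no trial data are public, a first-class synthetic generator emulates
the study design (15 operators × 3 platforms, counterbalanced order,
7-stitch sutures) with a configurable negative coupling between spacing
irregularity and burst pressure, calibrated so the pooled Spearman
correlation for PP-SD averages −0.375 at n = 45.  See `docs/methods.md` for
the full model description.

## Worked example

Generate a cohort and run the whole pipeline:

```
suturemetrics generate --seed 7 --out-dir data
suturemetrics run-all --annotations-dir data/annotations \
    --cohort data/cohort.csv --questionnaires data/questionnaires.csv \
    --out-dir results --seed 7
```

or in Python:

```python
import pandas as pd
from suturemetrics import (CohortConfig, generate_cohort, cohort_frame,
                           spearman_screen, repeated_kfold_regression)

cfg = CohortConfig()
trials = generate_cohort(cfg, seed=7)
df = cohort_frame(trials, cfg)            # 45 trials x (outcomes + 18 metrics)

screen = spearman_screen(df[[c for c in df.columns if c.startswith(("pm", "pp", "p_all"))]],
                         df["burst_pressure_mmHg"])
print(screen.loc[screen["metric"] == "pp_std",
                 ["metric", "rho", "p_value", "required_n_80", "selected"]])
```

prints (seed 7):

```
   metric       rho   p_value  required_n_80  selected
10 pp_std -0.390646  0.007975             53      True
```

i.e. in this replicate the trial-to-trial variability of stitch spacing
(`pp_std`) is negatively rank-correlated with burst pressure (ρ = −0.39,
p = 0.008): more irregular spacing, weaker closure.  Detecting an effect of
this size with 80 % power needs ≈ 53 trials, so a 45-trial cohort is
marginal — the screen's power columns quantify that directly.  Fitting the
cross-validated XGBoost model on the screened subset of this replicate
(`repeated_kfold_regression`, k = 5, 10 repeats) gives a mean per-fold R²
of −0.52 with MSE ranging 11.9–120.1 across the 50 folds: the spacing
metrics correlate with strength but do not predict it reliably at this
sample size, with residuals shrinking towards the mean at both extremes.

The pipeline writes `metrics.csv`, `group_summary.csv`, `comparisons.json`,
`power.json`, `correlation_table.csv`, `vif.csv`, `regression_report.json`,
`residuals.csv`, `shap_attributions.csv`, SUS/TLX tables and a
`manifest.json` carrying the config echo, seeds, library versions and
content hashes; two runs with the same seed and config are byte-identical.

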