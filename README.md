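# assayerror

Assay error equations for therapeutic drug monitoring (TDM) assays:
estimate the standard deviation of every reported drug concentration,
from the blank to the top of the range, so that pharmacokinetic models
can weight each observation by 1/SD².

## The problem

Clinical LC-MS/MS drug assays are heteroscedastic: the SD of a measured
concentration grows (usually linearly) with the concentration itself.
Population and individual pharmacokinetic model fitting needs a numeric
SD for *every* assay result — including results below the lower limit of
quantification, where dosing decisions for drugs such as carbamazepine,
fluconazole, lamotrigine or levetiracetam are often made.  The assay
error equation (AEE)

```
SD(C) = C0 + C1·C + C2·C² + C3·C³
```

supplies that SD, and 1/SD(C)² is the weight an observation at
concentration `C` receives in the model fit.

The package builds AEEs from spiked-replicate validation campaigns
(N independent serum specimens spiked at M concentration levels plus a
blank), and answers the two design questions that matter in practice:

* **Which regression algorithm should fit the precision profile** — the
  series of (concentration, SD) points?  Six candidates are provided:
  unweighted linear / quadratic / cubic least squares, 1/x²-weighted
  linear least squares, Theil's median regression, and Theil's regression
  with Siegel's repeated-median estimator.  Fits are compared by the
  normalized sum of squared residuals, `NSSR = Σ (SDobs − SDpred)²/SDpred²`.
* **How stable is the fitted equation to the choice of specimens?**  The
  combinatorial analysis refits the equation on every size-R subset of
  the N specimens (all C(24,6) = 134 596 or C(24,20) = 10 626 subsets are
  enumerated exactly) and reports the spread of the slope, the high/low
  slope ratio, and NNI% — the percentage of subsets with a non-negative
  intercept.  A negative intercept is a negative blank SD, which is
  physically impossible, so NNI% is the primary admissibility screen.

Upstream calibration utilities (1/x²-weighted calibration lines,
back-calculated accuracy, single-point below-range quantitation, and the
one-sample location test of calibration intercepts against zero) and a
synthetic-campaign generator with a configurable linear error law,
serum-interference SD multipliers and outlier levels are included.

## Worked example

```python
from assayerror import (SyntheticConfig, generate_campaign,
                        profile_from_dataset, fit_algorithm, evaluate_fit,
                        combinatorial_analysis, rank_algorithms)

# 20 spiking levels + blank, 24 specimens/level, true SD = 0.002 + 0.05·C
campaign = generate_campaign(SyntheticConfig(seed=7))
profile = profile_from_dataset(campaign)          # M = 21 points

for alg in ("ols_linear", "wls_inv_x2", "theil", "theil_siegel"):
    fr = fit_algorithm(profile, alg)
    ev = evaluate_fit(profile, fr.aee)
    print(f"{alg:13s} {fr.aee.as_string():34s} NSSR={ev.nssr:.3f}")
```

```
ols_linear    y = -0.0774223 + 0.0571299x        NSSR=inf
wls_inv_x2    y = 0.0016861 + 0.0476228x         NSSR=0.378
theil         y = 0.00161739 + 0.0500009x        NSSR=0.380
theil_siegel  y = 0.00171676 + 0.0482796x        NSSR=0.374
```

Unweighted least squares returns an impossible negative blank SD
(−0.077 µg/mL) — its NSSR is reported as infinite because an equation
that predicts non-positive SDs cannot provide weights.  The weighted and
median-based fits recover the generating law (intercept ≈ 0.002, slope
≈ 0.05) closely.

```python
c6  = combinatorial_analysis(campaign, 6,  "theil_siegel", max_enumerate=5000, seed=7)
c20 = combinatorial_analysis(campaign, 20, "theil_siegel", max_enumerate=5000, seed=7)
print(c6.high_low_ratio, c6.nni_pct)    # 1.98  96.9
print(c20.high_low_ratio, c20.nni_pct)  # 1.22 100.0

print(rank_algorithms(campaign, r_values=(20,), max_enumerate=2000, seed=7).recommended)
# theil_siegel
```

Enlarging the subsets from R = 6 to R = 20 shrinks the high/low slope
ratio from 1.98 to 1.22 and lifts NNI% to 100 — replicate count, not
algorithm choice, is what stabilizes the equation.  The two-step ranking
(NNI% screen at 99.5%, then ascending NSSR) recommends the Siegel fit.

The same workflow is available from the shell:

```
assayerror simulate --out campaign.csv --seed 7
assayerror run campaign.csv --out results/ --seed 7
```

which writes level summaries, the precision profile, all fits with NSSR,
the combination summaries, the ranking, the winning equation as an
error-polynomial line (`C0 C1 C2 C3`) for pharmacometric software, and a
manifest sufficient to reproduce the run.

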