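# Methods

## The model

A drug assay's precision profile is the series of points
(C_i, SD_i, n_i), i = 1…M, where SD_i is the sample standard deviation
(denominator n−1) of the concentrations measured in n_i independent
spiked serum specimens at spiking level C_i, and the blank (C = 0) is an
ordinary profile point.  The assay error equation (AEE)

SD(C) = C0 + C1·C + C2·C² + C3·C³

is a regression of SD on concentration; its inverse square is the
observation weight in pharmacokinetic model fitting.  The working
assumption, typical of LC-MS/MS assays in serum, is that the error
pattern is linear (C2 = C3 = 0): a small constant blank SD plus a
proportional component.  The polynomial terms are retained so that
curved error patterns can be modelled and so that the exported
coefficient line `C0 C1 C2 C3` follows the error-polynomial convention
of pharmacometric software.

## The six regression algorithms

(a)–(c) Unweighted least squares of degree 1–3, solved through the
pseudo-inverse of the Vandermonde design.  A degree-d fit requires
M ≥ d + 2 points (one residual degree of freedom), so a cubic cannot be
fitted to a 4-level profile.

(d) 1/x²-weighted linear least squares: weight w_i = 1/C_i² for
C_i > 0.  The blank's weight 1/0² is undefined; by default it is capped
at the weight of the lowest nonzero level, so the blank still constrains
the intercept.  A `blank_policy="drop"` switch excludes the blank
instead.  The capped-weight choice is a reconstruction — with positive
profile data both policies give similar, positive intercepts, but the
capped blank anchors the fit at C = 0, which is the point of the whole
exercise — and its sensitivity is examined explicitly when reference
equations are reproduced.

(e) Theil's original median regression: the slope is the median of the
(M choose 2) pairwise slopes (SD_j − SD_i)/(C_j − C_i); the intercept is
the median over all M points of SD_i − slope·C_i.  This is the original
estimator, not the Theil–Sen variant with Sen's tie handling and
confidence procedure.  Its breakdown point is about 29%.

(f) Siegel's repeated-median estimator: for each point i, take the
median over j ≠ i of the pairwise slopes and of the pairwise intercept
terms (C_j·SD_i − C_i·SD_j)/(C_j − C_i); the estimates are the medians
over i of those per-point medians.  Breakdown point ~50% ("maximally
robust"): in the test suite a single gross outlier leaves the fit
exactly on the generating line, and 25% contamination moves the slope
by < 5% while unweighted OLS is displaced several-fold.

Numerical conventions shared by all fitters: the median of an
even-length set is the mean of the two central values; pairs with
identical concentrations are excluded from slope denominators (a valid
profile has strictly increasing concentrations, but merged
multi-experiment inputs are guarded anyway); fitted coefficients are
never clamped — a negative intercept is preserved and flagged, because
the admissibility screen operates on raw intercept signs.

## Goodness of fit: NSSR

NSSR = Σ_i (SD_obs,i − SD_pred,i)² / SD_pred,i².

Residuals are normalized to the predicted SD, so a 20% misfit at the
blank counts as much as a 20% misfit at the top level — a correlation
coefficient would be dominated by the top of the range.  If any
predicted SD is ≤ 0 the statistic is reported as infinite rather than
computed on the surviving points: an equation that predicts impossible
SDs must not look good by having its pathology excluded.  Because every
fitter is scale-equivariant, NSSR is invariant under rescaling all SDs
when the fit is re-estimated (asserted per algorithm in the tests).

## Combinatorial subset stability

With N specimens per level, every size-R subset of specimens yields a
resampled precision profile and hence a fitted equation.  All C(N, R)
subsets are enumerated exactly when feasible (C(24, 6) = 134 596 and
C(24, 20) = 10 626 both are; the enumeration is vectorized by computing,
per level, the SDs of all subsets at once and solving all fits against
the shared concentration grid in a single batch).  For larger N a seeded
uniform sample of `max_enumerate` subsets is drawn and the summary
records that it is not exhaustive.

Reported per (algorithm, R): median and range of the slope, the
high/low slope ratio (undefined and reported as ND when the minimum
slope is ≤ 0), median and range of the intercept, and NNI% — the
percentage of subsets with intercept ≥ 0 (zero counts as non-negative;
the boundary case is a zero blank SD, which is admissible).

The expected fractional error of an SD estimated from R replicates,
σ_S/σ ≈ 1/√(2(R−1)) (the large-sample normal approximation), is
attached to each summary as design guidance: 32% at R = 6 versus 16% at
R = 20 explains the roughly tenfold-smaller high/low ratios of "large"
subsets.

### Ranking rule

Algorithms are ranked in two steps: first the NNI screen — an algorithm
is admissible only if NNI% ≥ threshold (default 99.5%) at every
requested R and its full-profile intercept is non-negative — then
admissible algorithms are ordered by ascending full-profile NSSR.  The
threshold is configurable because no canonical cut exists; 99.5% treats
">99.9%-class" stability as acceptable while rejecting the 80–95% rates
that unweighted least squares typically produces on wide-range profiles.
The ranking is descriptive; no hypothesis test compares algorithms.

## Calibration utilities

The calibration line (response ratio on nominal concentration) is
fitted by 1/x²-weighted least squares via the closed-form weighted
normal equations; the reported determination coefficient is the
weighted R² (matching the WLS convention of standard statistical
packages, which the tests cross-check against statsmodels).
Back-calculated accuracy is 100·((ratio − intercept)/slope)/nominal per
calibrator.  Below-range quantitation is single-point proportionality
through the lowest calibrator with a forced zero intercept — justified
when the calibration intercepts are statistically indistinguishable
from zero, which is what `intercept_zero_test` checks: a one-sample
location test t = mean/(sd/√n) on n − 1 degrees of freedom of the
per-experiment intercepts (with one sample this coincides with the
ordinary one-sample t test; the Welch correction is a two-sample
concept).

## The synthetic campaign generator

`generate_campaign` draws, for specimen s at level C,

measured = C·accuracy_bias + ε,  ε ~ Normal(0, (c0 + c1·C)·m_s·o_C),

with m_s an SD multiplier attached to the specimen's serum interference
class (hemolytic / icteric / lipemic sera are measured with inflated
SD, constant across levels for a given specimen) and o_C an outlier
multiplier applied to a chosen fraction of levels.  Noise is additive
Gaussian on the concentration scale because the model being studied is
SD — not CV — linear in concentration.  Measured values are not
truncated at zero: blank-level back-calculated concentrations scatter
around zero, and truncation would bias the blank SD that the intercept
estimates.

Defaults are the study conditions used throughout the tests: error law
SD = 0.002 + 0.05·C (a 2 ng/mL blank SD and 5% proportional error,
realistic for a well-behaved serum LC-MS/MS assay), N = 24 specimens
per level, and a 20-level + blank spiking ladder spanning 0.0122–181
µg/mL assembled from merged 4-, 6- and 10-level sub-ladders, mirroring
a real three-experiment carbamazepine-type validation campaign.  No
quantitative estimates of interference SD inflation exist, so the
multiplier is a free parameter; 1.5 is the documented default in the
mixed-campaign examples, and the class fractions allocate specimens
deterministically (largest remainder), e.g. 6 + 6 + 6 + 6 for a
four-class mix of 24.

What the generator does *not* emulate: calibration-curve noise
propagation (measured values are drawn directly on the concentration
scale), drift or batch effects across experiments, ion-suppression
structure beyond a per-specimen SD multiplier, and non-Gaussian heavy
tails.  Passing tests therefore demonstrate correctness of the
estimators and the machinery under the stated error model, not that any
particular real assay is linear-error.

## Problem sizes and determinism

The test suite and the acceptance script regenerate all inputs at run
time.  Sizes were chosen as the smallest that make the statistical
assertions stable: oracle equivalence uses 200 random profiles with
M ≤ 8 (exhaustive pairwise enumeration; least-squares oracles solve the
normal equations in exact rational arithmetic, so 1e-9 agreement is
meaningful); parameter recovery uses 100 seeded campaigns at the full
study design with subset sampling capped at 5000; the exhaustive
C(24, 6) enumeration runs in about a second thanks to the batched
solver.  Every random draw flows from an explicit seed; identical
configuration and seed reproduce byte-identical pipeline outputs.

## Known limitations

* The reproduction of the reference per-analyte final equations needs
  the original raw measurement tables, which are not redistributable
  here; the corresponding check reports exactly that when the data are
  absent.  Two genuinely underdetermined choices — whether the profile
  x-axis is nominal or mean measured concentration, and how the blank
  is weighted in the 1/x² fit — are kept as switches, and the
  reproduction check tries all four combinations and reports the
  sensitivity on mismatch.
* No confidence intervals are provided for the Theil/Siegel
  coefficients.
* Subset resampling ignores interference-class composition: a size-R
  subset may be all-lipemic even if the campaign was balanced.
* The Siegel batch solver materializes an
  (n_subsets × M × M) slope tensor; at the default cap of 20 000
  subsets and M = 21 this is ~150 MB, which bounds how far
  `max_enumerate` should be raised on small machines.
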