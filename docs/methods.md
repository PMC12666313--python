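# Methods

`odrs` analyses ex vivo drug screens of patient-derived organoids (PDOs) and
relates screen sensitivity to the donor patient's clinical course. This note
records the statistical model behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate, and
the numerical decisions that a maintainer would otherwise have to reverse-
engineer from the code.

## Growth-rate-normalized dose response

End-point viability readouts confound drug effect with division rate: a
slowly growing culture looks "resistant" to a cytostatic drug simply because
it divides little during the assay. The GR (growth-rate inhibition) value
removes this confounder by anchoring each treated signal `x(c)` to the day-0
baseline `x0` and the untreated day-5 control `x_ctrl`:

    GR(c) = 2^( log2(x(c)/x0) / log2(x_ctrl/x0) ) − 1

GR = 1 means no drug effect, 0 complete cytostasis, negative values net cell
kill (→ −1 as the signal vanishes). The computation requires growing
controls (`x_ctrl > x0`); a screen in which the negative controls did not
grow is invalid and raises an error rather than returning a number.
Conventional viability `v(c) = x(c) / x_ctrl` is computed alongside.

Replicates are aggregated as the mean over technical triplicates per
concentration, then an unweighted mean of the surviving biological-replicate
curves. Means are the simplest symmetric choice; no weighting information
exists at the well level.

## Curve summaries

Curves are summarized without sigmoid fitting:

* **GR_AUC / AUC** — trapezoidal area under the raw curve in
  log10-concentration space, divided by the log-range, so a constant curve
  maps to its own value and grids of different widths stay comparable. This
  rescaling is what makes a dimensionless sensitivity cutoff meaningful.
* **GR50 / IC50** — first crossing of 0.5 scanning from the lowest
  concentration, located by linear interpolation in (log10 c, value) space.
  A curve that never reaches 0.5 is right-censored and encoded as
  `10 × c_max`; one already below 0.5 at the lowest dose is left-censored as
  `c_min / 10`. Sentinels carry explicit censoring flags and enter min–max
  normalization as-is, keeping the transform total.

Per drug, each summary metric is min–max normalized across the analyzed
cohort (`(x − min)/(max − min)`), mapping every regimen onto [0, 1]
regardless of its concentration range. A screen is classified **sensitive**
when the normalized GR_AUC is *strictly below* 0.63 — a cutoff predefined
from the ≈60% first-line response rate to fluoropyrimidine + oxaliplatin
doublets — and resistant otherwise (0.63 itself is resistant).

## Quality gates

* **Z′-factor** per assay plate, `1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|`,
  with sample (n−1) standard deviations (control counts are small). Plates
  below 0.3 are excluded wholesale.
* **Replicate concordance**: the sum over the 10 concentrations of the
  absolute GR difference between two biological replicates. Absolute rather
  than signed differences — a signed sum could cancel and wave discordant
  curves through. The pair is excluded (flagged for re-run) only when the
  sum *exceeds* 1.7; exactly 1.7 passes. With more than two replicates the
  gate applies to every pair, and both members of a failing pair drop out.

## Clinical endpoints

Lesion diameters from serial CT scans are reduced to the best (most
negative) percent change from baseline, separately for the biopsied index
lesion and for the sum of target lesions. RECIST 1.1 categories follow the
standard thresholds (PR ≤ −30%, PD ≥ +20% from nadir plus ≥5 mm absolute, or
new lesions; CR at disappearance; SD otherwise). The dichotomized endpoint
is decrease (< 0%) vs increase (≥ 0%); exactly 0% counts as increase —
absence of shrinkage is not a response — and is flagged for audit.

## Concordance statistics

The 2×2 table crosses the PDO call with the dichotomized response
(sensitive∧decrease = TP). PPV/NPV intervals use the Wilson score method,
which keeps small-sample endpoints inside [0, 1]; at k = 0 or k = n the
interval endpoint is exactly 0 or 1. The ROC treats *lower* normalized
GR_AUC as responder-like (scores are negated internally); the AUROC is the
Mann–Whitney concordance probability with ties counted ½, and its CI comes
from the DeLong placement-value variance (clipped to [0, 1]) — the standard
nonparametric choice for an empirical ROC. Group comparisons use the
rank-sum test for two groups and Kruskal–Wallis with Dunn post hocs
(Bonferroni-multiplied, capped at 1) for three or more. Categorical tables
use Fisher's exact test when any expected cell count is below 10 and the
table is 2×2, otherwise a chi-square test without continuity correction;
larger sparse tables fall back to chi-square with a warning. Enrollment
under dropout rounds `n/(1 − dropout)` to the *nearest* integer
(85/0.44 = 193.2 → 193), not the ceiling.

## Survival analysis

Kaplan–Meier estimation and the unweighted log-rank test are delegated to
`lifelines`; the median is the first time the survival function falls to
≤ 0.5, with an infinity sentinel when it never does.

The Cox regression of PFS/OS on the continuous normalized GR_AUC is
**Firth-penalized**: the Efron-tied partial log-likelihood is augmented with
half the log-determinant of the observed information,
`ℓ*(β) = ℓ(β) + ½ log det I(β)`. With ~20 patients and well-separated groups
the unpenalized likelihood is often monotone (infinite MLE); the Firth
penalty guarantees a finite, second-order-unbiased estimate. No installed
package provides Firth Cox, so it is implemented here: Newton iteration
using the observed information as curvature, the penalty gradient by central
differences of `log det I` (step 1e-5), step-halving whenever a step would
decrease ℓ*, convergence at a modified-score norm below 1e-8 (relative),
max 50 iterations. Standard errors come from the inverse information at the
optimum; CIs and p-values are Wald (`exp(β ± 1.96·se)`). The covariate is
pre-divided by 0.1 so hazard ratios read "per 0.1 increase in normalized
GR_AUC". Efron tie handling is the accurate default for the moderate ties
that month-scale follow-up produces. Tests cross-check the implementation
against `lifelines`' unpenalized fit on large well-conditioned data (<1%
relative difference at n = 2000) and against a bounded-scalar-optimizer
oracle on separated toy data.

## Establishment model

Culture success is modeled by maximum-likelihood logistic regression
(statsmodels GLM) on: age, sex, primary location (rectum/left/right),
differentiation, synchronous vs metachronous metastases, LDH > 250 U/L,
prior treatment, KRAS/BRAF/WT status, biopsy period, and academic vs
nonacademic hospital. Reference levels are fixed (female, rectum, good
differentiation, metachronous, no prior treatment, WT, nonacademic, first
period) for reproducibility. Biopsy date enters as a piecewise-constant
period factor because culture protocols evolve stepwise over a study; knots
are user input (default: terciles of the observed days). Model selection is
backward stepwise on AIC — repeatedly dropping the single term whose removal
most reduces AIC, ties broken by candidate order — which is deterministic
given the data. Multicollinearity is screened by VIF (`1/(1 − R²)` of each
predictor on the rest; > 5 flags a problem, perfect collinearity returns an
infinity sentinel). Discrimination is the in-sample (apparent) AUROC and
calibration is decile-binned predicted-vs-observed; no optimism correction
is applied, so reported AUROCs are mildly optimistic by construction — a
documented caveat, not a bug. Only complete cases are analyzed.

Note that AIC selection retains a 1-df noise predictor whenever its
chi-square improvement exceeds 2 (probability ≈ 0.157 under the null), so
even an all-noise candidate set yields a non-empty model in a substantial
fraction of cohorts; the tests assert this calibrated behavior rather than
universal exclusion.

## Synthetic data generator

The generator is first-class, tested code; it exists because no reusable
patient-level dataset accompanies the study design it emulates.

**Plates.** Each PDO×drug response is a Hill curve on the GR scale,
`GR(c) = e_inf + (1 − e_inf)/(1 + (c/ec50)^hill)`, with `e_inf ∈ (−1, 1]`.
Intensities follow exponential growth: untreated wells complete `growth`
doublings (default draw U(1.5, 3) per PDO) from a base intensity of 1000;
a treated well's day-5 signal is `x0 · 2^(log2(1 + GR(c)) · growth)` — the
exact algebraic inverse of the GR formula, so with zero noise the analysis
recovers the truth curve to machine precision (the end-to-end recovery
property is tested at <1e-9 over 100 random Hill truths). Layout per
biological replicate (default 2, on separate plates): 10-point logarithmic
concentration grid per drug in technical triplicate, 16 vehicle negative
controls, 16 staurosporine positive controls simulated at GR = −0.9, plus a
separate 16-well day-0 baseline plate. The default panel mirrors seven
standard-of-care colorectal regimens by name with synthetic four-decade
grids (10⁻³–10 µM). Noise is multiplicative log-normal with unit mean,
default CV 0.08 — plate-reader-like, keeps intensities positive, and leaves
default screens comfortably above the Z′ ≥ 0.3 gate.

**Cohort links.** A patient's latent sensitivity `s` is the analytic
normalized GR_AUC of the focal fluoropyrimidine + oxaliplatin regimen.
Lesion best percent change is `−45 + 80·s` plus N(0, 35²) noise per lesion;
the slope/intercept put the response zero-crossing near the middle of the
sensitivity range and the noise level yields Pearson correlations around
0.4–0.6 between screen and lesion response at n ≈ 23 — moderate coupling, as
observed in prospective organoid cohorts. Survival times are exponential
proportional-hazards draws with log-HR per 0.1 units of `s` equal to
log 1.35 for PFS and log 1.27 for OS, baseline medians 8 and 24 months at
s = 0.5, and independent exponential censoring with mean 60 months (≈20–30%
censoring). Lesion series are constructed so the best change equals the
intended value exactly (shrinking lesions pass a halfway scan first; growing
lesions grow monotonically).

**Establishment cohort.** Covariates are drawn from fixed marginal
frequencies typical of a metastatic colorectal cancer cohort; success comes
from a logistic model whose default coefficients (intercept −2.1; male +0.8;
elevated LDH +0.9; academic hospital +0.8; second/third biopsy period
+0.8/+1.6) encode the protocol-learning effect and give ≈50% marginal
success and an apparent AUROC near 0.75 at n = 205.

**Reproducibility.** One global seed expands into per-component substreams
via `numpy.random.SeedSequence.spawn` (plates, clinical, survival,
establishment, in that order); the same seed reproduces plate tables
byte-for-byte.

**What is not emulated:** plate-edge and gradient effects, dispensing
errors, inter-lesion heterogeneity beyond independent noise, non-target
lesions and symptomatic progression, reader variability in CT measurement,
informative censoring, and missing covariate data. Passing tests therefore
demonstrate correctness of the estimators under the stated statistical
links, not robustness to these real-world artifacts.

## Problem sizes and runtime defaults

The default study configuration runs 23 PDOs (the evaluable-cohort scale for
a single focal regimen), a 7-regimen panel, biological duplicates, and a
205-subject establishment cohort; simulation-based test properties use
n = 200 cohorts × 200 replicates (Firth coverage), 10⁵ permutations
(log-rank oracle), and n ≤ 12 instances (ROC pair-counting oracle). These
sizes were chosen so each property's Monte-Carlo error is small relative to
the tolerance it is tested at.

## Numerical choices and degenerate inputs

* Grid membership of concentrations read from text uses relative tolerance
  1e-9; grids must be strictly increasing and positive.
* GR requires positive signals and growing controls; violations raise typed
  errors (`NoGrowthError`, `DomainError`) rather than yielding NaN.
* Min–max normalization with all-equal values raises a degenerate-range
  error; the pipeline logs and leaves that metric unnormalized.
* Z′ with coincident control means raises an undefined-separation error.
* Report floats are serialized at 10 significant digits so reports diff
  cleanly; re-running with the same seed reproduces `report.json` byte-wise.

## Known limitations

Normalization is within-cohort, so a PDO's normalized GR_AUC (and hence its
class) depends on which other PDOs are analyzed with it; single-screen
classification requires a reference cohort. GR50/IC50 come from the
nonfitted curve, which is noisier than a fitted sigmoid midpoint at high
assay noise. The establishment AUROC is apparent, not validated. The Firth
penalty gradient is numerical; for the univariable models used here this
costs two extra likelihood evaluations per Newton step and is exact to
O(h²) with h = 1e-5.
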