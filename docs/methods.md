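# Methods

This note documents the statistical models implemented in `likingdqi`, the
design choices made where the methodology left room, and what the synthetic
cohort generator does and does not emulate.

## 1. Survey model

Ratings live on a bipolar hedonic scale in [−100, +100]; 0 is "neither like
nor dislike". Twelve conceptual food/beverage groups partition 61 food
items (no item belongs to two food groups); seven pleasant- and five
unpleasant-experience items form two non-food hedonic anchors used as
regression covariates. Group scores are arithmetic means of the group's
non-missing items; a subject must answer at least half of a group's items,
otherwise the group is unscorable and an explicit error names it. Averaging
over answered items (rather than imputing zero) preserves the scale of the
group score under item non-response.

The guideline-weighted index additionally needs a lean-protein group that
is not one of the twelve; it is configured as an *auxiliary* group
defaulting to {lean ham, baked chicken, canned tuna in water}. Auxiliary
groups may reuse items from food groups — they are index inputs, not part
of the partition.

**Reliability.** Cronbach's alpha is computed as
`k/(k−1) · (1 − Σ var(item)/var(sum))` with unbiased variances; it may be
negative and is undefined (error) at zero total variance.

**Abnormality counting.** Ten factors are screened against clinical normal
ranges: BMI < 30 kg/m², blood pressure < 130/85 mmHg (systolic or diastolic
elevation flags the single blood-pressure factor), fasting glucose
< 100 mg/dL, fasting insulin < 17 mIU/L, total cholesterol < 200 mg/dL,
LDL < 100 mg/dL, triglycerides < 150 mg/dL, HDL > 40 (men) / > 50 (women)
mg/dL, waist-to-hip ratio < 1.0 (men) / < 0.85 (women), and HOMA-IR < 2.0.
HOMA-IR uses the original closed-form model (glucose [mg/dL] × insulin
[mIU/L] / 405); the computer-model variant needs an external calculator, so
the computed value is exposed for substitution. The count is monotone in
every factor.

## 2. Cardiometabolic risk factor score

Candidates: insulin, glucose, HDL, triglycerides, BMI, waist-to-hip ratio,
SBP, DBP. Each is rank-inverse-normal transformed (Blom offsets,
`(r − 3/8)/(n + 1/4)`) and standardized; the transform stores the training
sample so held-out subjects are mapped through the *training* empirical CDF
(mid-ranks against the training order statistics). Rank-based
transformation is the default because the fasting measures are strongly
right-skewed and the transform is distribution-free and rank-preserving;
`log` and `none` are selectable per measure.

**Screening.** A two-factor principal-component extraction of the
correlation matrix is varimax-rotated; measures with |loading| ≥ 0.4
(conventional EFA cut-off, configurable) on the first (largest-variance)
rotated factor are retained. Absolute loadings make the rule orientation-
free, so HDL's protective (negative) loading counts. One subtlety: if the
second eigenvalue of the correlation matrix is below 1 (Kaiser criterion),
the structure is effectively unidimensional and a forced two-factor
rotation would split the common factor arbitrarily across both factors; in
that regime the threshold is applied to the single-factor loadings instead.
In the intended regime — a plasma/adiposity block with average pairwise
correlation near 0.32 and blood pressure only weakly coupled (near 0.12) —
the rule retains the six plasma/adiposity measures and excludes both
pressures, and the rotated solution shows the two blocks on separate
factors.

**Scoring.** The first principal component of the transformed retained
measures (eigen-decomposition of their correlation matrix) gives per-
subject scores, standardized to mean 0/SD 1 and oriented so that the score
correlates positively with insulin (an orientation anchor is necessary for
"higher index = healthier" statements downstream to be meaningful; insulin
is the canonical severity marker of the retained set). The frozen model —
screening outcome, per-measure transforms, loadings, orientation, training
standardization — scores held-out subjects without re-estimating anything.

## 3. Diet quality indexes

**Theoretical.** `DQI = (1/10) Σ w_g L_g` over the ten weighted groups with
raw group likings. The mean (rather than sum) aggregation is configurable;
with the default integer weights the index spans −240…+240. No reverse
coding: the weights encode healthiness directly.

**Group merging (hybrid).** Groups with pairwise r > 0.5 are combined by
per-subject averaging to avoid collinear ridge inputs. The default
clustering is average-linkage agglomeration: repeatedly join the two
clusters with the highest mean inter-cluster correlation until none exceeds
the threshold. Average linkage is order-independent and keeps clusters
internally coherent; a connected-components option exists but is more
aggressive — one borderline pair (the shipped matrix has refined
carbohydrate–salty at 0.55) chains otherwise distinct clusters together.
On the shipped correlation targets, average linkage yields nine groups,
merging {salty, high-fat protein} and {sweet, saturated fat, refined
carbohydrate}; the procedure is idempotent there (re-merging the merged
matrix changes nothing).

**Ridge weighting (empirical and hybrid).** The penalized fit minimizes
`‖y − β₀ − Xβ‖² + λ‖β_pen‖²` in closed form on standardized predictors; the
intercept is never penalized. By default the four covariates (sex, patient
status, pleasant and unpleasant anchors) are penalized like the food
predictors — all are standardized, and the mask is configurable for
sensitivity analysis. λ is selected from 50 log-spaced values in
[10⁻³, 10³] by k-fold cross-validation on the training data, minimizing
mean held-out squared error with ties broken toward the larger penalty.
At λ = 0 a rank-deficient design is a hard error rather than a silent
pseudo-inverse.

The index is the coefficient-weighted sum of the *food* predictors only
(factor scores for the empirical index, standardized merged groups for the
hybrid); covariate coefficients are controls and never enter the score.
Reverse coding multiplies by `−sign(corr(raw index, CRFS))` on training
data so higher index = lower risk; a zero correlation is an error, not an
arbitrary sign.

**Factor analysis.** Extraction is by principal components of the
correlation matrix — deterministic and standard for exploratory use;
factors are ordered by post-rotation explained variance with each factor's
largest-magnitude loading made positive. Varimax uses the classical
pairwise-rotation algorithm with the closed-form criterion-maximizing angle
per factor pair and Kaiser row normalization, iterated to a 10⁻⁹ angle
tolerance. (The one-step SVD variant of varimax was observed to converge
pathologically slowly — tens of thousands of iterations — on two-factor
biomarker problems; the pairwise algorithm reaches the same optimum, as
verified against a brute-force scan of the rotation angle.) Factor scores
use the regression (Thomson) method `Z R⁻¹ Λ`, frozen with the training
standardization for held-out scoring.

**0–100 standardization.** From a fitted hybrid index: components with
positive reverse-coded weight become adequacy components (recoded
`(L+100)/2`), the rest moderation (`(100−L)/2`); normalized weights are
`|β_g|/Σ|β|` over food components; the total score `Σ w̃_g · recoded_g` is
bounded in [0, 100], monotone increasing in adequacy likings and
decreasing in moderation likings. Integer maximum points are
`round(100 w̃)` with largest-remainder correction so they sum to exactly
100 (ties resolved toward the larger weight, then lexicographically). A
scale can also be loaded directly from a published points table.

## 4. Out-of-sample comparison

`incremental_r2_cv` partitions subjects into k folds (sizes differing by at
most one, assignment a pure function of (n, k, seed)). Per fold the CRFS
model and DQI weights are fit on the k−1 training folds and applied frozen
to the held-out fold; on that fold two OLS regressions of the held-out CRFS
on {sex, patient, pleasant, unpleasant} — with and without the DQI — are
compared. Two points deserve emphasis:

* The held-out regressions are fit on the held-out subsample itself (the
  convention of the methodology this package implements), not predicted
  from training coefficients. Adding any regressor, even noise, therefore
  inflates ΔR² by about `1/(fold size − 5)` on average; with small folds
  this matters and the null-control tests budget for it explicitly.
* By default the CRFS is rebuilt inside each training split
  (`crfs_scope="train"`); fixing it once on the full sample
  (`crfs_scope="full"`) reproduces the simpler single-sample convention
  but lets the outcome variable see held-out subjects, biasing ΔR² upward.

`compare_dqis` runs all requested methods on identical folds and seeds;
`n_repeats` re-randomizes folds for more stable means. `describe_dqi`
reports means, SDs, a Lilliefors-corrected Kolmogorov–Smirnov normality
test (plain KS with estimated parameters is anticonservative; p-values from
the statsmodels table), and the control-minus-patient contrast with a Welch
two-sample test (a two-sample KS option exists).

## 5. Synthetic cohort generator

The generator reproduces the statistical structure the analysis assumes, so
recovery, null and calibration properties are all testable.

* **Group likings** are multivariate normal with the shipped per-group
  means/SDs and correlation targets (non-PSD target matrices are repaired
  by eigenvalue clipping with a logged warning; the shipped matrix is PSD),
  clipped to the instrument range. At the shipped moments the clip bias is
  small — group means shift by under one liking point and large
  correlations shrink by under 0.01.
* **Items** disaggregate each group score G into k ratings
  `item_j = G + e_j − ē` with i.i.d. Gaussian e. Centering the noise makes
  the item mean reproduce G exactly, so the group-level calibration
  survives the round trip through item scoring; the noise SD is solved
  from the reliability identity for a k-item mean,
  `alpha = 1 − var(e)/(k·var(G))`, so each scale attains its target
  Cronbach alpha before clipping. Item-level clipping biases realized
  alphas downward by about 0.01 at the shipped targets.
* **Covariates**: sex ~ Bernoulli(0.623 female) and patient status ~
  Bernoulli(0.5), matching the cohort composition the defaults emulate.
  Patients optionally receive a liking shift (default: a few points toward
  sweets/fats and away from produce), applied centered (±shift/2) so
  marginal group means stay on target.
* **Latent risk** `T = s + γ_m·male + γ_p·patient + ε`, Var(T) = 1 by
  construction. The diet signal `s` is a normalized weighted sum of
  z-scored group likings scaled to a configurable variance share
  (default 0.08); the default weight direction mirrors the shipped scoring
  standard (produce protective; sweets/fats/refined and complex
  carbohydrates harmful). Covariate effects (γ_m = 0.25, γ_p = 0.85) size
  the covariate model's explained CRFS variance near the regime the
  defaults emulate (~25–30%).
* **Biomarkers**: the six core measures load √0.32 ≈ 0.566 on T (HDL
  negatively), giving average pairwise correlation 0.32 within the block;
  SBP/DBP load 0.12/0.566 ≈ 0.21 on T plus a shared own factor (0.72), so
  their average correlation with the block is 0.12 — the split that drives
  the screening step. Monotone links map Gaussian cores to physiological
  ranges; insulin, triglycerides and BMI are exponentiated (right-skewed)
  so the normality-transform stage has real work to do. LDL couples weakly
  (0.25) and total cholesterol is the Friedewald composition
  LDL + HDL + TG/5.
* `with_planted_partial_r2(r2)` rescales the diet share so that adding the
  true signal to the covariate model raises held-out explained CRFS
  variance by exactly `r2` in population: the increment equals the diet
  share times the biomarker attenuation ρ² = corr²(CRFS, T), computed
  analytically from the loadings (≈ 0.739 at defaults). `null()` removes
  the diet→risk pathway entirely.

Everything is deterministic under a fixed seed (fixed stage order drawing
from one generator), so identical spec + seed give byte-identical cohorts.

**What the generator does not emulate.** Real liking data are bounded,
discretized and zero-inflated rather than clipped Gaussian; item noise is
homoscedastic here; patient status shifts only liking means, not
covariances; biomarker links are stylized monotone curves, not
physiological models; and no measurement error model links liking to actual
intake. Passing tests therefore demonstrate that the *pipeline* recovers
structure it was told the world has — not that liking surveys measure diet
well in any particular human population.

## 6. Simulation sizes and tolerances

The acceptance suite uses sizes chosen once for statistical stability:
worked examples and oracle checks are exact or at 10⁻⁶; planted-recovery
runs 20 cohorts of n = 2,000 (two-fold CV, so each held-out half has 1,000
subjects); the null control runs 50 cohorts of n = 500 with five-fold CV
and budgets the analytic one-noise-regressor inflation `1/(fold − 5)` on
top of a 0.01 margin; the ordering comparison runs 20 cohorts of n = 1,000;
generator calibration uses one cohort of n = 50,000 (Monte-Carlo SE of a
realized alpha ≈ 0.001 at that size, against ±0.03 tolerances).

## 7. Known limitations

* The empirical index requires more training subjects than food items
  (61); it is not defined for very small cohorts.
* Rank-based transforms map held-out values through the training ECDF;
  values far outside the training range saturate at the extreme ranks.
* The merge map, like any threshold rule, is unstable for correlations
  near the threshold; the average-linkage default mitigates but does not
  remove this.
* Ridge coefficients for weakly associated groups are shrinkage-dominated;
  their signs (and hence adequacy/moderation classification of minor
  components) are seed-sensitive at realistic sample sizes — visible in
  the worked example, where the smallest components earn 0–1 of the 100
  points.
* `crfs_scope="full"` and the held-out-OLS convention are both faithful to
  the methodology but leak optimism into ΔR²; the defaults (train-only
  CRFS) and the documented inflation bound are the package's guard rails.
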