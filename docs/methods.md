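# Methods

## Cohort phenotype

Weight change is expressed as annual percent change relative to the
Year-2 (baseline) weight: Δ₃ = 100·(W₃−W₂)/W₂ and Δ₄ = 100·(W₄−W₃)/W₂.
Both intervals use W₂ in the denominator so the two changes add to the
net change; when W₃ is missing but W₄ observed, the single annualized
change 100·(W₄−W₂)/(2W₂) is used. The default classifier
(`any-interval`) labels a participant *loss* if any change is below −3%
and none above +3%, *gain* by symmetry, *stable* when all changes are
within ±3% (the boundary value ±3.000% is stable). A trajectory with
both a >+3% and a <−3% interval is resolved by the sign of the net
change, with |net| ≤ 3% falling back to stable; this tie-break is a
package design choice, as is the alternative `final-visit-annualized`
strategy, since it is genuinely ambiguous whether the 3% criterion should
apply per interval or annualized to the last visit. Losers are
subdivided by the baseline intention flag; losers with a missing flag are
dropped from four-group analyses (complete-case) and logged.

The exclusion cascade runs in a fixed order — non-fasting, both follow-up
weights missing, prior-year (Year 1→2) change beyond the stability
threshold, any computed change beyond 40% — and each record is tallied
under the first matching reason only, so the funnel counts add exactly to
the input count.

Derived covariates: BMI categories use half-open boundaries [25,30) and
≥30 kg/m²; walking/stair energy expenditure uses 4.0/3.0/2.0 kcal/kg/h
for brisk/moderate/strolling walking and 4.0 (+1.0 with a carried load)
for stairs; protein and fat intakes are energy-adjusted by the residual
method (OLS of nutrient on total energy, residuals re-centered at the
nutrient mean, which the adjustment preserves to numerical precision).

## Metabolite QC

Features must be quantified in ≥90% of the analysis sample and have a
QC-pool CV ≤10% (sample SD/mean, ddof=1); boundary values pass. Blanks
are treated as below detection and imputed as half the minimum detected
value per feature. Metabolites measured on more than one platform are
collapsed: lipids keep the lipid-platform copy when available, others the
lowest-CV copy, ties broken by a fixed platform order. Retained columns
are natural-log transformed and z-scored (ddof=1) over the analysis
sample after imputation; the log base cancels in the z-score. CVs come
from a dedicated QC-replicate table rather than participant samples;
duplicate resolution is applied to all names (not only significant ones)
so the pipeline output is deterministic and association tables never
contain a metabolite name twice.

## Multinomial logistic screen

The fitter maximizes the multinomial log-likelihood by full Newton–
Raphson on the stacked (K−1)×p coefficient matrix, with step-halving (up
to 30 halvings) whenever a proposed step would decrease the objective.
Convergence requires both |Δ log-likelihood| < 1e-10 and a gradient
sup-norm < 1e-6; the covariance is the inverse observed information at
the optimum, and 95% CIs use the normal quantile 1.959964. Runaway
coefficients (|β| > 15 with no penalty) are treated as quasi-complete
separation and raise with advice to re-fit with a small ridge penalty on
non-intercept coefficients (the screen falls back to ridge = 1e-8
automatically and flags the fit). Rank-deficient designs raise naming
the collinear columns. Wald tests are used per coefficient, matching the
reported odds-ratio-with-CI style of association screens.

BH FDR is applied per contrast across unique metabolites (the default
family; a pooled family across the three contrasts is available).
Categorical codings default to race reference White, sex reference men,
BMI reference "<25", appetite reference "very good"; age enters in years
as a continuous term. Each model is estimated on its own complete cases
with the per-model n recorded. Square-term and interaction checks refit
the BMI-adjusted model with metabolite² or metabolite×modifier columns
and report the joint Wald chi-square p for the added block in a single
contrast equation (default unintentional loss, the contrast the
interaction question targets).

## Attenuation ledger

For each screened-significant metabolite and each confounder block,
percent attenuation is 100·(β₁−β₂)/β₁, where β₁ comes from the
age/sex/race/BMI model and β₂ from the same model plus the block, both
refit on the intersection of their complete cases so the two coefficients
always describe the same participants. Values are reported unclipped
(negative = strengthening, >100 = sign flip); |β₁| < 1e-6 marks the entry
undefined. Summaries give the per-block median and IQR (linear
interpolation between order statistics) and the list of metabolites
attenuated by more than a 20% flag threshold, sorted descending. The
fully adjusted block contains every candidate column except total body
fat, which is omitted for collinearity with the BMI categories already in
the base model.

## Synthetic cohort

The generator emulates the post-integration data of an LC–MS metabolomics
sub-study of a biracial aging cohort. Defaults are the study conditions:
group base logits from the reference group sizes (980 stable, 237 gain,
220 unintentional, 99 intentional of 1,536), age ~ N(74.7, 2.9), 35%
Black, 50% men, smoking 8%, appetite 44/38/18%, Table-style marginals
for body composition, diet, inflammation markers, diseases and
medications; four-platform feature panel with log-normal peak areas
(log-means uniform on [ln 1e4, ln 1e6]), default censoring quantile 0.02,
six QC-pool replicates with CVs drawn from (0.01, 0.08).

Confounders are standard-normal latent factors that load linearly on
designated log-metabolites and add γ per contrast to the outcome logit;
planted effects add β per SD of the latent metabolite. The four-level
group is drawn directly from the multinomial logit (so effects can be
planted per contrast); the intention flag is then *determined* by the
loss subgroup and Bernoulli(0.31) background noise for stable/gain
participants — intention is a label, independent of metabolites given
group. Weight trajectories are sampled inside the class-consistent
ranges (stable ±2%, loss/gain magnitude 3.2–8% on one interval), so
re-classification recovers the assigned group exactly; the
`weight_noise_sd` parameter (default 17, percent units) is the lognormal
spread of baseline BMI across participants, not per-visit measurement
noise, which would break that exact-recovery contract. Planted
exclusions occupy the leading rows with disjoint reasons so funnel counts
are exact. Each table (and each feature) has its own seeded substream,
so enlarging the panel never perturbs participant draws.

What the generator does **not** emulate: raw spectra and peak
integration, batch/plate drift, correlated metabolite modules, missing
covariates, longitudinal intention change, or informative (outcome-
dependent) censoring. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not
robustness to those real-data features.

## Oracles and frozen expectations

`attenuation_oracle` simulates one large cohort (n ≥ 1e5) and fits the
base and adjusted models on the exact latent z, serving as ground truth
for attenuation recovery. The frozen expectations used by the recovery
tests were computed at n = 200,000 (seed 20240917): fully confounded
(λ=1, γ=0.5, β=0) → 100.5%, unconfounded (λ=0) → −2.2%, mixed (β=0.3,
λ=0.8, γ=0.4) → 45.4%. Downstream recovery is checked at n = 20,000
through the full QC path (default censoring included) within 10
percentage points.

## Problem sizes

Null calibration uses n = 2,000 participants and 400 null features, with
the false-discovery proportion averaged over 50 replicates in the test
suite (20 replicates in the acceptance script); parameter recovery uses
n = 5,000; attenuation recovery n = 20,000. These sizes put Monte-Carlo
error comfortably inside the stated tolerances while keeping a full run
of suite plus script in a few minutes on one core.

## Known limitations

Wald (not likelihood-ratio or score) inference; no shrinkage across
metabolites; no bootstrap CI for percent attenuation; complete-case
handling of covariate missingness; single-process execution. The
half-minimum LOD imputation is the conventional choice but biases
low-abundance features toward the detection floor; the censoring levels
the defaults plant (2%) keep that bias negligible.
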