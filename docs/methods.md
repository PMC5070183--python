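# Methods

This note records the models, defaults and design choices behind
`ki67prog`, and what the synthetic-data experiments do and do not
establish.

## Image model and scoring protocol

Stained tissue is modelled by Beer–Lambert absorption: each pixel's
optical density is a non-negative mixture of unit-norm stain vectors,
`OD = M·c`, with `M` the 3×3 H-DAB basis (haematoxylin ≈ (0.65, 0.70,
0.29), DAB ≈ (0.27, 0.57, 0.78), third vector the normalised cross
product — the widely used published pair; the basis is configurable).
Scoring inverts this: `OD = −log10((I + ε)/255)` with `ε = 1e−6` to keep
zero-intensity pixels finite, then per-pixel concentrations
`c = M⁻¹·OD`, clamped at zero after inversion. On rendered images the
round trip recovers the generator's concentration maps with r ≥ 0.99 and
mean absolute error < 0.02, so the deconvolution step is effectively
exact and all scoring error comes from segmentation and classification.

Segmentation thresholds the combined nuclear signal (haematoxylin +
DAB). The threshold defaults to Otsu per core — robust across rendering
intensities — and can be fixed in the protocol. Touching nuclei are
split by a watershed on the distance transform with peak separation
4 µm; regions below 8 µm² are discarded as debris. Feature units are
microns via the image's µm-per-pixel scale so protocol windows transfer
across magnifications (emulated cores span 0.6–1.0 mm at varying
resolution).

Five shape features drive classification: spot width (equivalent-circle
diameter), width (ellipse minor axis from second-order moments),
roundness `4πA/P²`, compactness `P²/4πA` and axis ratio (minor/major).
Roundness and compactness are reciprocal by construction; pixelated
perimeters (slightly underestimated by the perimeter estimator) can push
roundness a few percent above 1, so the malignant windows admit values
up to 1.3. A nucleus is malignant iff **every** feature lies in its
window; windows are fitted on a labelled synthetic training core by a
small grid search over tail quantiles of the malignant class (the
shipped defaults come from that procedure and give ≥ 99 % training and
held-out accuracy on generator scenes). Positivity for malignant nuclei
defaults to mean deconvolved DAB density > 0.15; an HSI colour-box rule
is available for workflows that specify positive/negative colour ranges
in hue–saturation–intensity space.

The CAV (computer-assisted visual) emulator tiles the core into 250 µm
squares, half-open `[x, x + 250)`, and assigns each nucleus to exactly
one tile by its centroid — no double counting, and per-tile counts sum
exactly to the whole-core counts. A core is *satisfactory* when more
than 500 cells are counted; the counting target is 1000.

## Quality control and aggregation

Core QC: pass iff malignant nuclei count > 50 (strict) and < 15,000
(strict) and the score, rounded to 4 decimals, is below 100 % (a
saturated score is treated as artefactual). Patient KI67 is the
unweighted mean over QC-passing cores. Exclusion is hierarchical — QC
first, then missing follow-up — so every excluded patient carries
exactly one primary reason, and the ledger identity
`analysed = collected − failed_qc − missing_followup` is asserted at
construction. Descriptive comparisons use the tie-corrected
Kruskal–Wallis test for continuous scores and the Pearson chi-squared
test (no continuity correction) on the category × high/low table; no
pairing structure exists between tumour categories, so a marginal
(McNemar-type) test would not apply.

## Cut-offs and agreement

The prognostic cut-off is the upper-quartile boundary of the analysed
patients' scores, computed with linear-interpolation (type-7) quantiles,
the most common software default. Dichotomisation is strict: high iff
score > cut, so a score exactly at the boundary is low. The visual
cut-off is extrapolated by OLS of visual on automated patient-level
scores; the mapped value is rounded **up** to the next multiple of 5
(an exact multiple stays), generalising the usual clinical rounding of
extrapolated thresholds; callers can override the rounding step.
Agreement statistics: observed agreement and Cohen's kappa from the 2×2
marginals (kappa undefined when chance agreement is 1), sensitivity and
specificity with visual-high as the positive class, and ROC AUC by the
Mann–Whitney rank formulation with midranks for ties, with a 95 % CI
from the Hanley–McNeil variance.

## Survival models

Time zero is diagnosis. Subjects enter the risk set at study entry
(left truncation accommodates prevalent cancers) and exit at
`min(death, last follow-up, 10 years)`; the 10-year administrative
horizon censors later exits. The Kaplan–Meier estimator and the
log-rank test both honour delayed entry; the log-rank variance uses the
multivariate hypergeometric form, which handles tied event times.

Cox models maximise the partial likelihood with the Efron tie
correction by Newton–Raphson with step halving. Convergence requires
the gradient max-norm to fall below `tol · max(1, |logPL|)` (default
`tol = 1e−8`) or the Newton step below 1e−12: on cohort-scale data the
attainable gradient is bounded by floating-point accumulation at about
`eps·|logPL|`, so a purely absolute criterion would spin. On ≤ 6-subject
fixtures the fitted coefficient agrees with direct maximisation of the
explicitly written likelihood to < 1e−7. The engine supports stratified
baseline hazards; study group enters the fully adjusted models as a
categorical covariate (dummy coding), with stratification available as
an option.

The time-varying KI67 effect is `log h(t) ∋ β·x + θ·x·t`, i.e.
`HR(t) = HR₀·T^t` with `T = exp(θ)` the per-year multiplier of the
hazard ratio: `T < 1`, effect wanes; `T > 1`, effect grows. This is the
episode-split (start–stop) model with the covariate `x·t` refreshed at
every event time, but the risk-set sums are evaluated analytically per
event time instead of materialising the split dataset — identical
estimates (verified against an explicit episode-split fit to 1e−6) at a
fraction of the cost. A `log1p(t)` time scale is available. Any
covariate violating proportionality (ER, classically) can be listed in
`tvc_vars` and is handled identically. `HR₀` is the hazard ratio at
t = 0 exactly.

Model comparison uses `AIC = −2·logPL + 2k` and
`BIC = −2·logPL + k·ln(n)` with `n` = number of events by default (the
conventional effective sample size for a partial likelihood), switchable
to subjects. Subgroup heterogeneity is Cochran's Q about the
inverse-variance mean with P from χ²(k−1); the cross-study analysis is
a fixed-effect inverse-variance meta-analysis of study-specific log
hazard ratios with `I² = max(0, (Q − df)/Q)` (undefined for a single
study).

## Missing data (MI+)

Covariate missingness is handled by chained equations whose predictor
set always includes the outcome: the event indicator and the
Nelson–Aalen cumulative hazard at exit (computed with delayed-entry risk
sets) — the standard recipe for imputation compatible with a survival
analysis model. Continuous and multi-category variables use predictive
mean matching with a Bayesian parameter draw and 5 donors, so only
observed values are ever imputed and category codes are preserved;
binary variables use a posterior logistic draw (ridge 1e−6 for
stability). Each of the m chains (default m = 20) is initialised from
the observed margins and cycled 10 times. All randomness descends from
one seed through spawned generators, so imputations are exactly
reproducible. With no missing cells the imputation is the identity and
the pooled fit reproduces the complete-data fit to 1e−8.

Rubin's rules pool the per-imputation Cox fits: pooled β is the mean,
total variance `W̄ + (1 + 1/m)·B`, and degrees of freedom follow
Barnard–Rubin with complete-data df = events − parameters. In the
pipeline, imputation runs within each analysis stratum, matching the
stratum-specific fully adjusted models.

## Synthetic-data generator

The generator is the package's test bed and defines its study
conditions.

**Images.** Nuclei are filled ellipses with a 0.8 µm linear edge ramp
and mild multiplicative log-normal noise (σ = 0.06) on the concentration
maps; haematoxylin (amplitude 0.7) on all nuclei, DAB (0.55) on positive
ones; pixels are `background·10^(−M·c)`. Malignant nuclei are drawn
larger and rounder (equivalent diameter ~ N(10, 1) µm clipped to 7–14,
axis ratio 0.82–0.98) than non-malignant ones (N(5.5, 0.7) µm clipped to
3.5–7, axis ratio 0.45–0.72), so shape classification has a real but
learnable margin. Scenes whose nuclei overlap by more than half the
smaller radius are rejected. Dart-throwing placement enforces a 12 µm
minimum separation inside a circular core.

**Cohorts.** Defaults mirror a 10-study consortium: per-study patient
counts summing to 8088, 1–9 cores per patient (geometric-ish weights,
mean ≈ 1.9), core sizes 0.6–1.0 mm. True KI67 is a per-ER-status gamma
mixture — ER+ ~ Gamma(1.2, 5.0), ER− ~ Gamma(1.8, 10.0), scaled by
grade (×0.7/1.0/1.3) — calibrated once so the overall upper-quartile
boundary sits near 12 % positive cells; only that quartile shape, not
any real cohort, is targeted. The hazard is
`h(t) = h₀(t)·exp(β'z + (b₀ + b₁t)·x_high)` with piecewise-constant
yearly baseline (default 0.02/yr, giving roughly the observed death rate
over a median 7.5-year follow-up), default `b₀ = ln 2`, `b₁ = ln 0.90`.
Event times are drawn by exact inversion on a 0.1-year grid with a
constant-rate tail, so the non-proportional effect is sampled without
approximation beyond the grid. Censoring is exponential (0.03/yr) plus
the 10-year horizon. Half the subjects enter late (exponential delay,
mean 0.8 y); subjects whose event or censoring precedes entry are never
observed and are dropped — genuine left truncation, so a simulated
cohort is slightly smaller than the configured count. Covariate
missingness is MAR through the (always observed) study label, with
per-covariate rates; visual scores exist for a 30 % subset as
`0.2 + 2.0·auto + N(0, 12)`, clipped to [0, 100], putting the visual
equivalent of an automated cut of 12 % in the mid-20s.

For cohort-scale pipeline runs, per-core counts can be emulated
statistically (`emulate_core_scores`: Poisson totals, binomial
positives, with injected low-count and saturated QC failures) instead of
rendering ~15,000 images; image-based scoring itself is validated
separately on rendered cores.

**What this does not show.** The renderer produces idealised
histology: no chromatin texture, stain batch variation, tissue folds,
out-of-focus regions, necrosis or stromal architecture, and classes are
separable by construction. Passing the scoring tests demonstrates the
pipeline's internal consistency and calibration on its own forward
model, not clinical accuracy on scanner output. Likewise the cohort
simulator draws covariates independently (apart from the built-in
ER–PR, ER–treatment and grade–KI67 links), so adjusted and partially
adjusted effects differ only through those channels.

## Problem sizes and numerical conventions

Test and acceptance runs use: 50 rendered cores of 500 nuclei for
scoring calibration (slope must fall in 0.9–1.1, |intercept| ≤ 2 points);
50 cohorts of n = 4000 for time-varying-effect recovery (means within
10 % of HR₀ = 2.0 and T = 0.90); 50 cohorts of n = 2000 with 20 % MAR
missingness and m = 20 for MI coverage (90–98 %); 10,005 synthetic
patients for the exclusion cascade. Pixel coordinates are 0-based
row-major; grid tiles half-open; quantiles type-7; scores stored at 4
decimals (the saturation rule applies after this rounding); Wald CIs use
1.96; the ROC uses midranks. Random draws everywhere descend from a
single user seed via `numpy` `SeedSequence` spawning.

## Known limitations

- The segmentation is tuned for non-confluent nuclei; heavily
  overlapping clusters beyond the watershed's reach are merged.
- The log-rank and Nelson–Aalen implementations iterate over distinct
  event times in Python and are comfortable up to ~10⁵ subjects, not
  beyond.
- The imputation model is linear/logistic in the observed covariates;
  interactions must be added as explicit columns.
- `I²` from few studies is noisy; the fixed-effect model is reported as
  specified and no random-effects alternative is provided.
- Visual-score emulation is a linear-plus-noise stand-in; real
  pathologist scores are discretised and systematically clustered at
  round values, which affects agreement statistics in ways the
  simulation does not reproduce.
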