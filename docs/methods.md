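# Methods

This note documents the models `omixvar` implements, the defaults it ships,
the numerical choices that matter, and what the synthetic-data validation
does and does not establish.

## Quality control

Order is fixed: zero-variance removal → missingness filter (features, then
samples, one pass each) → half-minimum imputation → log transform →
winsorization. The order matters: imputation must see only features/samples
that survived filtering, and winsorization bounds are meaningful only on the
log scale.

* **Missingness filter.** A feature or sample is dropped when its missing
  fraction strictly exceeds the threshold (default 0.25); the boundary is
  retained. Features are filtered before samples so that a sample is never
  penalized for cells belonging to doomed features; one pass each keeps the
  result deterministic.
* **Half-minimum imputation** assumes missingness reflects concentrations
  below the limit of detection: each missing cell becomes half the feature's
  minimum observed value, computed per feature on the scale the matrix
  enters with (raw for metabolites; log2 NPX for proteins, since the
  provider delivers log2 — a known approximation, as half-minimum on a log
  scale is not the log of half the minimum).
* **Log transform** uses the natural log for metabolites; protein NPX values
  pass through unchanged. The base used is recorded in the QC report.
* **Winsorization** clips each feature to mean ± 5 SD with bounds computed
  once from the pre-clip distribution. Re-clipping with those fixed bounds
  is exactly idempotent; recomputing bounds after clipping tightens them
  slightly (the outliers inflated the original SD), so recomputed-bounds
  idempotence is only approximate. One-shot bounds are used because
  iterating to a fixed point is unstable and data-dependent.
* A feature with exactly one observed value counts as zero-variance.

## Multiplicity

* **Li–Ji effective number of tests.** With eigenvalues λᵢ of the feature
  Pearson correlation matrix (computed on the post-QC matrix),
  M_eff = Σᵢ [𝟙(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋)]. M_eff equals the feature count for
  independent features and 1 for perfectly correlated ones; the per-test
  threshold is α / M_eff. M_eff is computed per omic.
* **ACAT.** T = Σ wᵢ tan((½ − pᵢ)π) / Σ wᵢ, combined p = ½ − arctan(T)/π.
  Inputs are clamped to [1e-300, 1 − 1e-16] before the tangent; below 1e-15
  the tangent is replaced by its asymptote 1/(πp), and for very large T the
  combined p uses the matching asymptote 1/(Tπ). ACAT is insensitive to the
  dependence structure of its inputs, which is why it aggregates partial-F
  p-values across correlated features.

## Covariate screening

Omic PCs come from the SVD of the column-standardized matrix; signs are fixed
by making each component's largest-magnitude loading positive. The number of
retained PCs is the smallest k reaching 70% cumulative variance, capped at 20
(the underlying criterion — "the major axes of variation" — is qualitative;
both knobs are configurable). Each candidate covariate is tested one at a
time against each retained PC by OLS (dummy-coded categoricals use a joint
F-test); a covariate is retained when any PC gives p below the screening
threshold (default 1e-4). Constant covariates are skipped with a warning.

## Variance decomposition

For each feature, OLS models over the domain structure give:

* `r2_full` — all mapped covariates;
* `r2_block[d]` — **domain-only** model (intercept + domain d's columns);
* `r2_unique[d]` = `r2_full` − R² of the model without domain d;
* `shared` = Σ_d `r2_block[d]` − `r2_full` (definitional identity, holds to
  1e-10 on every record by construction);
* `p_block[d]` — partial F-test of dropping domain d from the full model.

Block models deliberately contain *only* the domain in question: this makes
shared variance vanish under mutually independent domains, which is the
property the decomposition's interpretation rests on. Unique R² may be
slightly negative in finite samples (suppression); the raw value is kept in
records and floored at zero only for reporting and normalization.
Categorical covariates enter as full dummy blocks and are tested jointly.
Rows with any missing mapped covariate are dropped listwise (`n_used`
recorded); aliased design columns are dropped via rank-revealing QR with a
warning; fits require at least 10 residual degrees of freedom.

**Scoring.** genetic score = unique R²(genetic ancestry) × (−log₁₀ p);
environmental score = the same product averaged over the socioeconomic,
race/ethnicity and lifestyle domains. The product form preserves both effect
size and significance; rank-based alternatives were considered but the
product is monotone in both inputs and scale-free enough for within-omic
ranking, which is all the labels need. The top 30 per score (configurable)
are labelled; a feature in both lists goes to the better rank, ties to
genetic. The technical domain is adjustment only: it appears in every model
but never in scores or normalized contributions.

## Race/ethnicity vs genetic ancestry

Three models on top of a fixed adjustment set (technical, biological,
lifestyle, socioeconomic): A race only, B genetic PCs only, C both. All R²
are *partial* over the adjustment-only baseline, so
shared = R²_A + R²_B − R²_C is overlap net of confounders; unique
contributions are the nested ΔR². Contrasts (e.g. the NH-Black indicator vs
the AFR admixture proportion) use Type-II sums of squares — each term's SS is
the RSS increase from deleting it from the full model — so attribution does
not depend on term order. Perfect collinearity between race and PCs is
flagged rather than silently resolved.

## Survival association and meta-analysis

Cox partial likelihood is maximized by Newton–Raphson with step-halving,
implemented directly on sorted cumulative sums. Breslow tie handling is the
default (Efron available); simulated event times are continuous, so the two
coincide there, and the implementation is cross-checked against lifelines.
Features are standardized to unit SD first, making the reported log HR
per-SD — the common omics convention. Zero-event data raise; non-converged
fits are returned flagged and excluded from pooling.

DerSimonian–Laird pooling: w = 1/se², Q = Σw(b − b_FE)²,
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), pooled = Σw*b/Σw* with
w* = 1/(se² + τ²). A single cohort passes through with τ² = 0 and a warning.
Features with pooled p < 0.05 (strict) advance to causal follow-up.

## Mendelian randomization

Instrument selection: MAF > 0.01 and exposure p below the instrument
threshold (default 5e-8 — the conventional genome-wide level; the original
analysis does not print one), then greedy distance pruning in ascending-p
order with a 1 Mb exclusion window on either side, then greedy LD pruning on
a supplied D′ table (pairs with D′ > 0.2 resolved toward the smaller p;
missing pairs are assumed unlinked with a logged warning — LD comes from a
precomputed table because querying an external LD service is out of scope).
Harmonization flips outcome betas for swapped alleles, resolves strand flips
via complements, and drops palindromic (A/T, C/G) variants with EAF in
[0.42, 0.58] (a standard ambiguity window; configurable).

Estimators: IVW is weighted regression through the origin with weights
1/se_out² and multiplicative random-effects SE inflation max(1, √(Q/(k−1)))
(fixed-effect available); MR-Egger adds a free intercept after orienting
exposure betas positive, with residual-based overdispersion floored at 1 and
t-based inference on k−2 df; the weighted median interpolates the Wald-ratio
order statistics at 50% cumulative inverse-variance weight, with a seeded
parametric bootstrap SE. Heterogeneity is Cochran's Q; influence is a
leave-one-out IVW table (an explicit substitute for outlier-removal tests,
which are out of scope). An exposure is flagged causal only when **both**
IVW and weighted-median p pass the Bonferroni-corrected threshold α/n_tests;
an Egger intercept p < 0.05 attaches a pleiotropy caveat.

## Mediation

Counterfactual natural effects with a categorical race/ethnicity exposure
(pairwise contrasts against a configurable reference), a linear mediator
model M = b₀ + b₁A + b′C and a Cox outcome model
λ(t) = λ₀(t)exp(θ₁A + θ₂M + θ′C), no exposure–mediator interaction (none is
modelled by default; an interaction changes the effect formulas and is left
to a config-gated extension). Under a rare outcome, NDE = exp(θ₁Δa),
NIE = exp(θ₂b₁Δa), total = NDE·NIE exactly (the log-identity is checked),
and proportion mediated = NDE(NIE−1)/(NDE·NIE−1) on the HR scale — the
difference-scale alternative is not reported. Event fractions above 20%
trigger a warning that the approximation degrades. Inference is a seeded
nonparametric bootstrap over samples; the reported NIE p-value is a Wald p
on log(NIE) with the bootstrap SE, so screening thresholds far below 1/reps
(the pipeline screens at p < 1e-8 with PM > 10%) remain meaningful, with
percentile CIs reported alongside. PM is flagged unstable when the total
effect is within 0.01 of 1. The pipeline runs mediation on a single cohort
by design.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which every recovery claim is made.

* **Covariates.** Four race/ethnicity groups (NH-White 40%, NH-Black 25%,
  Hispanic 22%, NH-Asian 13%); ancestry proportions over {AFR, EUR, AMR,
  EASIA} drawn from race-specific Dirichlet distributions (concentration 50)
  around admixture means typical of a diverse US cohort; 5% of labels are
  randomly reassigned so race is a noisy proxy of ancestry rather than its
  deterministic image — without this, the shared-variance logic would be
  untestable. Genetic PCs are centered ancestry proportions projected onto
  their orthogonal axes (unit-variance scores) plus N(0, 0.05²) noise; PCs
  4–6 are pure noise. Age ~ N(60, 9²), 52% female, BMI ~ N(28.5, 5.5²),
  smoking 50/35/15% never/former/current, gamma-distributed diet/alcohol
  variables, ordinal education (5 levels) and income (8 levels), 4 batches,
  2 sites, fasting hours ~ N(12, 1.2²).
* **Features.** y = Σ_d √f_d s_d + √(1 − Σf) ε where each s_d is a
  unit-variance random linear combination of domain d's standardized
  covariates. Default fractions: technical 0.02, biological 0.10, lifestyle
  0.05, genetic ancestry 0.03, race/ethnicity 0.01, socioeconomic 0.02.
  Because race and ancestry covariates are correlated by construction, their
  *block* R² exceed their generating fractions (the excess is exactly the
  shared variance); the independent domains recover their fractions
  directly. Metabolites are exponentiated around a feature-specific mean
  log-abundance and left-censored below the 5% detection-limit quantile;
  proteins are emitted on the log2 NPX scale.
* **Outcome.** Weibull proportional hazards (scale 0.004, shape 1.5) on the
  standardized latent features plus a mild age effect, administratively
  censored at 15 years.
* **Summary statistics.** Instrument effects γ ~ ±N(0.10, 0.02²) with SE
  0.01 on both sides; outcome β = θγ + α·sign(γ) + noise, where directional
  pleiotropy α is defined relative to the exposure-increasing allele (that is
  the quantity the Egger intercept estimates; pleiotropy fixed to the
  arbitrary allele coding would average out under orientation). Variants are
  spaced ≥ 2 Mb; optional extras — close pairs 0.5 Mb from an instrument
  with D′ 0.5, palindromic A/T variants at EAF 0.5, rare variants at MAF
  0.005, and swapped-allele outcome rows — give the selection and
  harmonization steps known correct answers.
* **Determinism.** All randomness flows from one root seed through
  `numpy.random.SeedSequence` children spawned in a fixed order (covariates,
  metabolite features, protein features, outcome, sumstats); identical specs
  produce bit-identical tables, and derived cohort seeds stay below 2³¹.

**What passing tests show — and don't.** Recovery on this generator
demonstrates the estimators are correctly implemented and unbiased under
their own assumptions (linear domain effects, proportional hazards, valid or
known-invalid instruments, rare outcomes). Real cohort data add feature
skewness and heteroscedasticity, non-linear covariate effects, informative
missingness beyond left-censoring, batch-by-feature interactions, LD
structure richer than a pairwise D′ table, and unmeasured confounding —
none of which the generator emulates, so passing tests do not certify
robustness to those.

## Problem sizes and tolerances

Validation uses n = 5000 for variance-decomposition, classification and
mediation recovery (tolerances 0.03 on unique R², 80% top-30 recovery, 0.05
on proportion mediated over 50 seeds); two cohorts of n = 3000 over 100
seeds for Cox/meta recovery (±0.02 on the pooled log HR); 30–50 instruments
for MR (±0.05 IVW, ±0.08 weighted median, power > 0.8 for the Egger
intercept at α = 0.02 constant pleiotropy, 1000 null replicates for type-I
error); 10,000 draws for ACAT null uniformity. Algebraic identities (shared
variance, DL hand example, Li–Ji oracles) are checked to 1e-10.

## Known limitations

* Variance decomposition is OLS-based; no mixed-model/REML variance
  components or kinship-based heritability.
* The rare-outcome mediation formulas bias toward the null as events exceed
  ~20%; only a warning is issued.
* The weighted-median SE is a parametric bootstrap, which understates
  uncertainty if the Wald-ratio distribution is heavy-tailed.
* Half-minimum imputation on the protein log2 scale is an approximation (see
  QC above).
* The pipeline's orchestrated run analyzes the discovery cohort for
  screening/decomposition and both cohorts only for association/meta, which
  mirrors common practice but is a simplification of running everything per
  cohort.
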