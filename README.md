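# omixvar

**Variance decomposition of plasma omics profiles across covariate domains,
with causal follow-up to type 2 diabetes.**

Plasma metabolite and protein levels vary across people for many reasons at
once: assay batch, age and BMI, diet and smoking, income and education,
self-reported race/ethnicity, and genetic ancestry. `omixvar` is a library
for epidemiologists and omics analysts who want to ask, feature by feature,
*how much of this molecule's variance does each domain explain, is the
molecule predominantly genetically or environmentally shaped, and does it
lie on a causal path to disease?*

The pipeline has four layers:

1. **QC** — zero-variance removal, >25% missingness filters, half-minimum
   imputation of left-censored values, log transform (protein NPX stays
   log2), winsorization at mean ± 5 SD.
2. **Variance decomposition** — for feature *y* and covariate domains
   *d = 1..D* (technical, biological, lifestyle, genetic ancestry,
   race/ethnicity, socioeconomic), OLS fits give the full-model *R²*, each
   domain's block *R²* (domain-only model), the **unique** *R²*
   (*R²_full − R²_leave-d-out*) and the **shared** variance
   (*Σ_d R²_block(d) − R²_full*). Domain significance comes from partial
   F-tests, combined across features by the Cauchy combination test
   *T = Σ w_i tan((½−p_i)π) / Σ w_i*; multiplicity uses the Li–Ji effective
   number of tests *M_eff = Σ_i [1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)]* on the feature
   correlation eigenvalues. Features are ranked by
   *unique R² × (−log₁₀ p)* into genetically vs environmentally influenced.
3. **Disease association** — per-feature Cox proportional hazards on
   incident T2D (log HR per SD), pooled across cohorts by DerSimonian–Laird
   random effects (*τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw))*).
4. **Causal routing** — genetically influenced hits go to two-sample
   Mendelian randomization (instrument selection with MAF > 0.01, 1 Mb
   distance pruning, D′ > 0.2 LD pruning, allele harmonization; IVW,
   MR-Egger and weighted-median estimators); environmentally influenced hits
   go to counterfactual mediation of race/ethnicity → T2D with a Cox outcome
   model and rare-outcome natural effects
   (*NDE = e^{θ₁}, NIE = e^{θ₂β₁}, PM = NDE(NIE−1)/(NDE·NIE−1)*).

Because the motivating cohort data are access-restricted, the package ships
a **synthetic cohort generator** with known ground truth (per-domain variance
fractions, survival coefficients, MR causal effects, mediation path
coefficients); every stage is validated by parameter recovery against that
truth.

## Worked example

```python
from omixvar import TruthSpec, generate_bundle, run_qc, decompose_matrix, summarize_domains

bundle = generate_bundle(TruthSpec(n_samples=2000, seed=3))
clean, _ = run_qc(bundle.features["metabolite"])
records = decompose_matrix(clean, bundle.covariates, bundle.domain_map)
print(summarize_domains(records).round(4))
```

prints

```
                  mean_unique_r2_pct  mean_block_r2_pct  acat_p  n_features
domain
technical                     1.9854             2.1390  0.0000          50
biological                    9.9239            10.0680  0.0000          50
lifestyle                     5.2693             5.3697  0.0000          50
genetic_ancestry              2.0540             4.3032  0.0000          50
race_ethnicity                0.2397             2.3811  0.0001          50
socioeconomic                 2.1247             2.1717  0.0000          50
```

The generating fractions were technical 2%, biological 10%, lifestyle 5%,
genetic 3%, race 1%, socioeconomic 2%: mean unique R² recovers each domain's
contribution, while the gap between the genetic block R² (4.3%) and its
unique R² (2.1%) is the variance shared with the correlated race/ethnicity
labels — exactly the overlap the race-vs-ancestry module
(`overlap_decompose`, `contrast_partition`) quantifies.

The `examples/` directory walks through each capability (QC, multiplicity,
decomposition, race vs ancestry, Cox + meta-analysis, Mendelian
randomization, mediation, full pipeline); each script prints the numbers it
computes and what they mean. A thin CLI mirrors the stages:

```bash
omixvar simulate --seed 1 --out sim/
omixvar qc --features sim/features_metabolite.tsv --out qc/
omixvar mr --exposure sim/sumstats_MET_0001_exposure.tsv \
           --outcome sim/sumstats_MET_0001_outcome.tsv --ld sim/ld_MET_0001.tsv
omixvar run --config cfg.yaml
```

## Layout

- `src/omixvar/` — library (`synthetic`, `qc`, `multiplicity`, `screen`,
  `decompose`, `race_ancestry`, `survival`, `mr`, `mediation`, `pipeline`,
  `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, assumptions, defaults and limitations
- `tests/` — unit, property and acceptance tests
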