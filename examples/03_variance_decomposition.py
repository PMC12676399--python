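"""Decompose each metabolite's variance across covariate domains and classify
features as genetically vs environmentally influenced.

For every feature: full-model R2, per-domain block R2 (domain-only model),
unique R2 (full minus leave-one-domain-out) and shared variance
(sum of blocks minus full). Scores = unique R2 x -log10(p) rank features for
genetic-ancestry vs environmental influence.
"""

from omixvar import (
    TruthSpec,
    decompose_matrix,
    generate_bundle,
    run_qc,
    score_features,
    summarize_domains,
)

spec = TruthSpec(n_samples=2000, seed=3)
bundle = generate_bundle(spec)
clean, _ = run_qc(bundle.features["metabolite"])

records = decompose_matrix(clean, bundle.covariates.loc[clean.values.index],
                           bundle.domain_map)
print("domain summary (mean unique R2 %, ACAT-combined p):")
print(summarize_domains(records).round(4).to_string())
print()
print("generating fractions were: technical 2%, biological 10%, lifestyle 5%,"
      " genetic 3%, race 1%, socioeconomic 2% - the mean unique R2 column"
      " recovers them (race/genetic overlap partly, by design).")

scores = score_features(records, top_k=10)
genetic = [s.feature_id for s in scores if s.label == "genetic_ancestry_influenced"]
print(f"\ntop genetically influenced features: {genetic[:5]} ...")
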