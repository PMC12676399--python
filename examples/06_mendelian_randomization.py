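"""Two-sample Mendelian randomization of a metabolite on T2D from synthetic
GWAS summary statistics with a true causal effect of 0.4.

The instrument pipeline filters (MAF > 0.01, p < 5e-8), distance-prunes
(1 Mb), LD-prunes (D' > 0.2) and harmonizes alleles before running IVW,
MR-Egger and the weighted median.
"""

from omixvar import (
    MRTruth,
    TruthSpec,
    generate_sumstats,
    harmonize,
    ld_prune,
    run_mr,
    select_instruments,
)

spec = TruthSpec(
    seed=6,
    mr_truth=MRTruth(theta=0.4, n_instruments=30, n_close_pairs=2,
                     n_palindromic=2, n_rare=2),
)
exposure, outcome, ld = generate_sumstats(spec)
print(f"summary statistics: {len(exposure)} variants")

candidates = select_instruments(exposure)
pruned = ld_prune(candidates, ld)
inst = harmonize(pruned, outcome, exposure_id="MET_0001")
print(f"instruments after MAF/p/distance/LD/harmonization: {inst.n_instruments}")

res = run_mr(inst, n_boot=1000, seed=0)
for method, est in res.estimates.items():
    print(f"{method:16s} estimate {est['estimate']:.3f}  SE {est['se']:.3f}  p {est['p']:.2e}")
print(f"Egger intercept p = {res.egger_intercept_p:.2f} (no directional pleiotropy)"
      f"; Cochran Q = {res.cochran_q:.1f}")
print("all three estimators should sit near the true causal effect 0.4.")
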