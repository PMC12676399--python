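import itertools

import numpy as np
import pandas as pd
import pytest

from omixvar.containers import OmixvarError
from omixvar.mr import (
    InstrumentSet,
    harmonize,
    ivw,
    ld_prune,
    leave_one_out,
    mr_egger,
    mr_significance,
    run_mr,
    select_instruments,
    weighted_median,
)
from omixvar.synthetic import MRTruth, TruthSpec, generate_sumstats


def _ss(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P"])


def _inst(bx, by, sx=0.01, so=0.01):
    bx, by = np.asarray(bx, float), np.asarray(by, float)
    return InstrumentSet(
        "exp",
        pd.DataFrame(
            {
                "SNP": [f"rs{i}" for i in range(len(bx))],
                "beta_exp": bx,
                "se_exp": sx,
                "beta_out": by,
                "se_out": so,
            }
        ),
    )


class TestSelection:
    def test_distance_pruning_toy_configuration(self):
        # brute-force-verified greedy answer: most significant first
        rows = [
            ("rs1", 1, 1_000_000, "A", "G", 0.3, 0.5, 0.01, 1e-10),
            ("rs2", 1, 1_500_000, "A", "G", 0.3, 0.4, 0.01, 1e-8),
            ("rs3", 1, 3_000_000, "A", "G", 0.3, 0.4, 0.01, 1e-9),
        ]
        out = select_instruments(_ss(rows), p_threshold=1e-6)
        assert set(out["SNP"]) == {"rs1", "rs3"}

    def test_maf_filter_excludes_rare_variant(self):
        rows = [
            ("rs1", 1, 1_000_000, "A", "G", 0.005, 0.5, 0.01, 1e-10),
            ("rs2", 2, 1_000_000, "A", "G", 0.995, 0.5, 0.01, 1e-10),
            ("rs3", 3, 1_000_000, "A", "G", 0.30, 0.5, 0.01, 1e-10),
        ]
        out = select_instruments(_ss(rows))
        assert list(out["SNP"]) == ["rs3"]

    def test_single_variant_retained(self):
        rows = [("rs1", 1, 5_000_000, "A", "G", 0.3, 0.5, 0.01, 1e-10)]
        assert len(select_instruments(_ss(rows))) == 1

    def test_multiallelic_rows_rejected(self):
        rows = [
            ("rs1", 1, 1_000_000, "AT", "G", 0.3, 0.5, 0.01, 1e-10),
            ("rs2", 2, 1_000_000, "A", "G", 0.3, 0.5, 0.01, 1e-10),
        ]
        with pytest.warns(UserWarning, match="rejected"):
            out = select_instruments(_ss(rows))
        assert list(out["SNP"]) == ["rs2"]


class TestLDPrune:
    def _cand(self):
        return _ss(
            [
                ("rs1", 1, 1_000_000, "A", "G", 0.3, 0.5, 0.01, 1e-10),
                ("rs2", 1, 5_000_000, "A", "G", 0.3, 0.4, 0.01, 1e-8),
                ("rs3", 1, 9_000_000, "A", "G", 0.3, 0.45, 0.01, 1e-9),
            ]
        )

    def test_linked_pair_drops_less_significant(self):
        ld = pd.DataFrame({"SNP_A": ["rs1"], "SNP_B": ["rs2"], "DPRIME": [0.5]})
        with pytest.warns(UserWarning, match="assumed"):
            out = ld_prune(self._cand(), ld)
        assert set(out["SNP"]) == {"rs1", "rs3"}

    def test_zero_ld_is_identity(self):
        pairs = list(itertools.combinations(["rs1", "rs2", "rs3"], 2))
        ld = pd.DataFrame(
            {"SNP_A": [a for a, _ in pairs], "SNP_B": [b for _, b in pairs],
             "DPRIME": 0.0}
        )
        out = ld_prune(self._cand(), ld)
        assert set(out["SNP"]) == {"rs1", "rs2", "rs3"}

    def test_fully_linked_trio_keeps_only_most_significant(self):
        pairs = list(itertools.combinations(["rs1", "rs2", "rs3"], 2))
        ld = pd.DataFrame(
            {"SNP_A": [a for a, _ in pairs], "SNP_B": [b for _, b in pairs],
             "DPRIME": 0.9}
        )
        out = ld_prune(self._cand(), ld)
        assert list(out["SNP"]) == ["rs1"]  # smallest p


class TestHarmonize:
    def _pair(self, out_ea="A", out_oa="G", out_beta=0.2, eaf=0.3, ea="A", oa="G"):
        exp = _ss([("rs1", 1, 100, ea, oa, eaf, 0.5, 0.01, 1e-10)])
        out = _ss([("rs1", 1, 100, out_ea, out_oa, eaf, out_beta, 0.01, 1e-5)])
        return exp, out

    def test_identical_coding_unchanged(self):
        inst = harmonize(*self._pair())
        assert inst.table["beta_out"].iloc[0] == pytest.approx(0.2)

    def test_swapped_alleles_negate_beta(self):
        inst = harmonize(*self._pair(out_ea="G", out_oa="A"))
        assert inst.table["beta_out"].iloc[0] == pytest.approx(-0.2)

    def test_strand_flip_resolved(self):
        inst = harmonize(*self._pair(out_ea="T", out_oa="C"))  # complements of A/G
        assert inst.table["beta_out"].iloc[0] == pytest.approx(0.2)

    def test_palindromic_ambiguous_dropped(self):
        inst = harmonize(*self._pair(ea="A", oa="T", out_ea="A", out_oa="T", eaf=0.5))
        assert inst.n_instruments == 0
        assert any("palindromic" in m for m in inst.provenance)

    def test_palindromic_with_extreme_eaf_kept(self):
        inst = harmonize(*self._pair(ea="A", oa="T", out_ea="A", out_oa="T", eaf=0.1))
        assert inst.n_instruments == 1

    def test_irreconcilable_alleles_dropped(self):
        inst = harmonize(*self._pair(out_ea="C", out_oa="A"))
        assert inst.n_instruments == 0
        assert any("irreconcilable" in m for m in inst.provenance)


class TestEstimators:
    def test_ivw_constant_ratio_recovered_with_zero_q(self):
        bx = np.array([0.1, 0.2, 0.3])
        res = ivw(_inst(bx, 0.5 * bx))
        assert res["estimate"] == pytest.approx(0.5, abs=1e-12)
        assert res["q"] == pytest.approx(0.0, abs=1e-12)

    def test_ivw_single_instrument_unavailable(self):
        with pytest.raises(OmixvarError):
            ivw(_inst([0.1], [0.05]))

    def test_ivw_equals_weighted_mean_of_wald_ratios(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.05, 0.3, 20)
        by = 0.4 * bx + rng.normal(0, 0.01, 20)
        res = ivw(_inst(bx, by))
        ratios = by / bx
        w = (bx / 0.01) ** 2
        assert res["estimate"] == pytest.approx(np.sum(w * ratios) / np.sum(w), abs=1e-12)

    def test_allele_reorientation_invariance(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.3, 15)
        by = 0.4 * bx + rng.normal(0, 0.01, 15)
        flip = rng.choice([-1.0, 1.0], 15)
        a = ivw(_inst(bx, by))
        b = ivw(_inst(bx * flip, by * flip))
        assert a["estimate"] == pytest.approx(b["estimate"], abs=1e-12)
        wm_a = weighted_median(_inst(bx, by), n_boot=50, seed=0)
        wm_b = weighted_median(_inst(bx * flip, by * flip), n_boot=50, seed=0)
        assert wm_a["estimate"] == pytest.approx(wm_b["estimate"], abs=1e-12)

    def test_egger_slope_near_ivw_without_pleiotropy(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.3, 200)
        by = 0.4 * bx + rng.normal(0, 0.005, 200)
        inst = _inst(bx, by, so=0.005)
        assert mr_egger(inst)["estimate"] == pytest.approx(ivw(inst)["estimate"], abs=0.02)

    def test_egger_needs_three_instruments(self):
        with pytest.raises(OmixvarError):
            mr_egger(_inst([0.1, 0.2], [0.05, 0.1]))

    def test_weighted_median_symmetric_ratios(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.03, 0.05, 0.07])  # ratios 0.3/0.5/0.7, equal weights
        res = weighted_median(_inst(bx, by), n_boot=50, seed=0)
        assert res["estimate"] == pytest.approx(0.5, abs=1e-9)

    def test_weighted_median_identical_ratios_zero_se(self):
        bx = np.array([0.1, 0.2, 0.3])
        res = weighted_median(_inst(bx, 0.5 * bx, sx=1e-8, so=1e-8), n_boot=100, seed=0)
        assert res["estimate"] == pytest.approx(0.5, abs=1e-6)
        assert res["se"] < 1e-4

    def test_weighted_median_robust_to_forty_pct_pleiotropy(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.08, 0.25, 30)
        by = 0.4 * bx + rng.normal(0, 0.005, 30)
        by[:12] += 0.05  # 40% of instruments pleiotropic
        inst = _inst(bx, by, so=0.005)
        wm = weighted_median(inst, n_boot=200, seed=1)["estimate"]
        assert wm == pytest.approx(0.4, abs=0.08)
        assert ivw(inst)["estimate"] - 0.4 > 0.08  # IVW visibly biased


class TestEndToEnd:
    def test_theta_recovery_on_synthetic_sumstats(self):
        spec = TruthSpec(seed=42, mr_truth=MRTruth(theta=0.4, n_instruments=30))
        exp, out, ld = generate_sumstats(spec)
        inst = harmonize(ld_prune(select_instruments(exp), ld), out)
        assert inst.n_instruments == 30
        res = run_mr(inst, n_boot=300, seed=0)
        assert res.estimates["ivw"]["estimate"] == pytest.approx(0.4, abs=0.05)
        assert res.estimates["weighted_median"]["estimate"] == pytest.approx(0.4, abs=0.08)

    def test_null_theta_covered_by_ivw_ci(self):
        spec = TruthSpec(seed=43, mr_truth=MRTruth(theta=0.0, n_instruments=30))
        exp, out, _ = generate_sumstats(spec)
        inst = harmonize(select_instruments(exp), out)
        res = ivw(inst)
        assert abs(res["estimate"]) < 1.96 * res["se"] * 1.5

    def test_egger_intercept_clean_under_no_pleiotropy(self):
        hits = 0
        for s in range(20):
            spec = TruthSpec(seed=500 + s, mr_truth=MRTruth(theta=0.4, n_instruments=30))
            exp, out, _ = generate_sumstats(spec)
            inst = harmonize(select_instruments(exp), out)
            if mr_egger(inst)["intercept_p"] > 0.05:
                hits += 1
        assert hits >= 18  # >= 90% of seeds

    def test_leave_one_out_table_shape(self):
        spec = TruthSpec(seed=44, mr_truth=MRTruth(n_instruments=10))
        exp, out, _ = generate_sumstats(spec)
        inst = harmonize(select_instruments(exp), out)
        tab = leave_one_out(inst)
        assert len(tab) == inst.n_instruments
        assert np.allclose(tab["estimate"], 0.4, atol=0.1)


class TestSignificance:
    def _result(self, p_ivw, p_wm, egger_p=0.5):
        from omixvar.mr import MRResult

        return MRResult(
            "exp",
            {
                "ivw": {"estimate": 0.4, "se": 0.1, "p": p_ivw},
                "egger": {"estimate": 0.4, "se": 0.2, "p": 0.01},
                "weighted_median": {"estimate": 0.4, "se": 0.1, "p": p_wm},
            },
            0.0,
            egger_p,
            10.0,
            0.5,
            10,
        )

    def test_both_methods_required(self):
        tab = mr_significance([self._result(1e-5, 0.02)], n_tests=50)
        assert not tab["significant"].iloc[0]

    def test_bonferroni_threshold(self):
        tab = mr_significance([self._result(5e-4, 5e-4)], n_tests=50)
        assert tab["threshold"].iloc[0] == pytest.approx(0.001)
        assert tab["significant"].iloc[0]

    def test_pleiotropy_caveat_flag(self):
        tab = mr_significance([self._result(1e-5, 1e-5, egger_p=0.01)], n_tests=10)
        assert tab["significant"].iloc[0] and tab["pleiotropy_caveat"].iloc[0]
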