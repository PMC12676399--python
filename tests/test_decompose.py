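import numpy as np
import pandas as pd
import pytest

from conftest import orthogonal_covariates
from omixvar.containers import DecompositionRecord, DomainMap, OmixvarError
from omixvar.decompose import (
    decompose_feature,
    decompose_matrix,
    normalize_contributions,
    score_features,
    summarize_domains,
)


def brute_force_record(y, cov, dm):
    """From-scratch oracle using raw lstsq fits, independent of the package's
    QR/projection machinery."""

    def r2(cols):
        X = np.column_stack(
            [np.ones(len(cov))] + [cov[c].to_numpy(float)[:, None] for c in cols]
        ) if cols else np.ones((len(cov), 1))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = np.sum((y - y.mean()) ** 2)
        return 1 - resid @ resid / tss

    domains = dm.domains_present()
    full = r2(dm.columns)
    block = {d: r2(dm.columns_for(d)) for d in domains}
    unique = {
        d: full - r2([c for c in dm.columns if dm.mapping[c] != d]) for d in domains
    }
    return full, block, unique


class TestDecomposition:
    def test_recovers_single_domain_truth(self):
        n = 5000
        cov, dm = orthogonal_covariates(n, 2, ["biological", "lifestyle"], seed=0)
        rng = np.random.default_rng(1)
        signal = cov["biological_0"] + cov["biological_1"]
        signal = (signal - signal.mean()) / signal.std(ddof=1)
        y = np.sqrt(0.5) * signal + np.sqrt(0.5) * rng.standard_normal(n)
        rec = decompose_feature(pd.Series(y, index=cov.index, name="f"), cov, dm)
        assert rec.r2_unique["biological"] == pytest.approx(0.5, abs=0.03)
        assert abs(rec.r2_unique["lifestyle"]) < 0.01
        assert rec.p_block["biological"] < 1e-100

    def test_orthogonal_design_shared_near_zero(self):
        n = 5000
        cov, dm = orthogonal_covariates(n, 2, ["biological", "lifestyle", "socioeconomic"], 2)
        rng = np.random.default_rng(3)
        Y = pd.DataFrame(
            {f"f{j}": 0.3 * cov["biological_0"] + rng.standard_normal(n) for j in range(5)},
            index=cov.index,
        )
        recs = decompose_matrix(Y, cov, dm)
        assert abs(np.mean([r.shared for r in recs])) < 0.01

    def test_null_feature_matches_expected_r2(self):
        n = 2000
        cov, dm = orthogonal_covariates(n, 3, ["biological", "lifestyle"], 4)
        rng = np.random.default_rng(5)
        Y = pd.DataFrame(
            rng.standard_normal((n, 40)), index=cov.index,
            columns=[f"f{j}" for j in range(40)],
        )
        recs = decompose_matrix(Y, cov, dm)
        expected = 6 / (n - 1)  # E[R2] under the null with p regressors
        assert np.mean([r.r2_full for r in recs]) == pytest.approx(expected, abs=2e-3)

    def test_shared_identity_holds_exactly(self, small_bundle):
        from omixvar.qc import run_qc

        clean, _ = run_qc(small_bundle.features["metabolite"])
        recs = decompose_matrix(clean, small_bundle.covariates, small_bundle.domain_map)
        for r in recs:
            assert abs(sum(r.r2_block.values()) - r.r2_full - r.shared) < 1e-10
            assert 0 <= r.r2_full <= 1
            for d in r.r2_unique:
                assert r.r2_unique[d] <= r.r2_full + 1e-12

    def test_matches_brute_force_oracle(self):
        n = 300
        cov, dm = orthogonal_covariates(n, 2, ["biological", "lifestyle", "technical"], 6)
        rng = np.random.default_rng(7)
        y = 0.5 * cov["biological_0"].to_numpy() + rng.standard_normal(n)
        rec = decompose_feature(pd.Series(y, index=cov.index, name="f"), cov, dm)
        full, block, unique = brute_force_record(y, cov, dm)
        assert rec.r2_full == pytest.approx(full, abs=1e-12)
        for d in block:
            assert rec.r2_block[d] == pytest.approx(block[d], abs=1e-12)
            assert rec.r2_unique[d] == pytest.approx(unique[d], abs=1e-12)

    def test_too_few_rows_errors(self):
        cov, dm = orthogonal_covariates(12, 2, ["biological", "lifestyle"], 8)
        y = pd.Series(np.arange(12.0), index=cov.index)
        with pytest.raises(OmixvarError, match="too few rows"):
            decompose_feature(y, cov, dm)

    def test_listwise_deletion_recorded(self):
        n = 200
        cov, dm = orthogonal_covariates(n, 1, ["biological", "lifestyle"], 9)
        cov.iloc[:10, 0] = np.nan
        y = pd.Series(np.random.default_rng(0).standard_normal(n), index=cov.index, name="f")
        rec = decompose_feature(y, cov, dm)
        assert rec.n_used == n - 10


class TestSummaries:
    def _record(self, uq, pb=None):
        domains = list(uq)
        return DecompositionRecord(
            feature_id="f",
            r2_full=sum(uq.values()),
            r2_block=dict(uq),
            r2_unique=dict(uq),
            shared=0.0,
            p_block=pb or {d: 0.5 for d in domains},
            n_used=100,
        )

    def test_single_record_summary_equals_record(self):
        rec = self._record({"biological": 0.2, "lifestyle": 0.1})
        tab = summarize_domains([rec])
        assert tab.loc["biological", "mean_unique_r2_pct"] == pytest.approx(20.0)
        assert tab.loc["lifestyle", "acat_p"] == pytest.approx(0.5)

    def test_normalize_simple_arithmetic(self):
        rec = self._record(
            {"lifestyle": 0.1, "socioeconomic": 0.05, "race_ethnicity": 0.05}
        )
        out = normalize_contributions(rec)
        assert out == pytest.approx(
            {"lifestyle": 0.5, "socioeconomic": 0.25, "race_ethnicity": 0.25}
        )
        assert sum(out.values()) == pytest.approx(1.0)

    def test_normalize_single_domain_and_zero_record(self):
        rec = self._record({"lifestyle": 0.3, "socioeconomic": 0.0})
        assert normalize_contributions(rec)["lifestyle"] == pytest.approx(1.0)
        zero = self._record({"lifestyle": 0.0, "socioeconomic": 0.0})
        with pytest.warns(UserWarning, match="uniform"):
            out = normalize_contributions(zero)
        assert out == pytest.approx({"lifestyle": 0.5, "socioeconomic": 0.5})


class TestScoring:
    def _records(self, n, genetic_r2, p=1e-10):
        recs = []
        for i in range(n):
            uq = {
                "genetic_ancestry": genetic_r2[i],
                "lifestyle": 0.01,
                "socioeconomic": 0.01,
                "race_ethnicity": 0.01,
                "biological": 0.02,
            }
            recs.append(
                DecompositionRecord(
                    feature_id=f"f{i}",
                    r2_full=sum(uq.values()),
                    r2_block=dict(uq),
                    r2_unique=uq,
                    shared=0.0,
                    p_block={d: p for d in uq},
                    n_used=100,
                )
            )
        return recs

    def test_p_one_gives_zero_score(self):
        recs = self._records(3, [0.5, 0.1, 0.2], p=1.0 - 1e-16)
        scores = score_features(recs, top_k=1)
        assert all(s.genetic_score == pytest.approx(0.0, abs=1e-12) for s in scores)

    def test_top_k_equal_to_n_labels_everything(self):
        recs = self._records(4, [0.4, 0.3, 0.2, 0.1])
        scores = score_features(recs, top_k=4)
        assert all(s.label != "unclassified" for s in scores)

    def test_ranking_follows_genetic_r2(self):
        recs = self._records(5, [0.5, 0.4, 0.3, 0.2, 0.1])
        scores = score_features(recs, top_k=2)
        assert scores[0].rank_genetic == 1 and scores[4].rank_genetic == 5
        genetic = {s.feature_id for s in scores if s.label == "genetic_ancestry_influenced"}
        assert genetic == {"f0", "f1"}

    def test_ranks_are_permutations(self, small_bundle):
        from omixvar.qc import run_qc

        clean, _ = run_qc(small_bundle.features["metabolite"])
        recs = decompose_matrix(clean, small_bundle.covariates, small_bundle.domain_map)
        scores = score_features(recs, top_k=5)
        n = len(scores)
        assert sorted(s.rank_genetic for s in scores) == list(range(1, n + 1))
        assert sorted(s.rank_environmental for s in scores) == list(range(1, n + 1))
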