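"""Domain-level variance decomposition of molecular features.

For each feature ``y`` and a mapping of covariates into domains (technical,
biological, lifestyle, genetic ancestry, race/ethnicity, socioeconomic) we fit:

* the **full model** containing every mapped covariate -> ``r2_full``;
* one **block model** per domain containing only that domain's covariates
  (plus intercept) -> ``r2_block[d]``;
* one **leave-one-domain-out model** per domain ->
  ``r2_unique[d] = r2_full - r2_leave_d_out`` and the partial F-test p-value
  ``p_block[d]`` for dropping the domain from the full model.

**Shared variance** is defined as ``sum_d r2_block[d] - r2_full``: the overlap
in explanatory power across domains. Unique R² can be slightly negative in
finite samples (suppression); the raw value is kept in the record and floored
at zero only when contributions are normalized for reporting.

Features are then scored for their predominant source of variability:
``genetic_score = unique R²(genetic ancestry) x (-log10 p)`` and
``environmental_score`` = the same product averaged over the socioeconomic,
race/ethnicity and lifestyle domains. The top-k (default 30) features per
omic by each score receive the corresponding label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._linalg import OLSProjector, build_design, partial_f_pvalue
from .containers import (
    ENVIRONMENTAL_DOMAINS,
    SUBSTANTIVE_DOMAINS,
    DecompositionRecord,
    DomainMap,
    FeatureMatrix,
    FeatureScore,
    OmixvarError,
)
from .multiplicity import P_CEIL, P_FLOOR, acat_combine

MIN_EXTRA_DF = 10  # n_used must exceed model parameters by at least this


def _projectors(cov: pd.DataFrame, dm: DomainMap):
    """Full, per-domain block, and leave-one-out projectors for a covariate table."""
    domains = dm.domains_present()
    full = OLSProjector(build_design(cov, dm.columns, dm))
    blocks = {d: OLSProjector(build_design(cov, dm.columns_for(d), dm)) for d in domains}
    loo = {
        d: OLSProjector(
            build_design(cov, [c for c in dm.columns if dm.mapping[c] != d], dm)
        )
        for d in domains
    }
    return domains, full, blocks, loo


def decompose_matrix(
    features: FeatureMatrix | pd.DataFrame, cov: pd.DataFrame, dm: DomainMap
) -> list[DecompositionRecord]:
    """Decompose every feature column against the domain structure.

    Rows with any missing mapped covariate are dropped listwise (recorded in
    ``n_used``); feature values are assumed complete post-QC.
    """
    vals = features.values if isinstance(features, FeatureMatrix) else features
    if vals.isna().any().any():
        raise OmixvarError("features must be fully observed (run QC first)")
    cov = cov.loc[vals.index]
    mask = cov[dm.columns].notna().all(axis=1)
    cov_used, Y = cov.loc[mask], vals.loc[mask]
    n = int(mask.sum())

    domains, full, blocks, loo = _projectors(cov_used, dm)
    if n < full.rank + MIN_EXTRA_DF:
        raise OmixvarError(f"too few rows ({n}) for {full.rank} model parameters")

    Ymat = Y.to_numpy(float)
    tss = np.sum((Ymat - Ymat.mean(axis=0)) ** 2, axis=0)
    rss_full = full.rss(Ymat)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_full = np.where(tss > 0, 1 - rss_full / tss, 0.0)

    r2_block = {d: blocks[d].r2(Ymat) for d in domains}
    r2_loo, p_block = {}, {}
    for d in domains:
        rss_d = loo[d].rss(Ymat)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_loo[d] = np.where(tss > 0, 1 - rss_d / tss, 0.0)
        p_block[d] = np.clip(
            partial_f_pvalue(rss_full, rss_d, full.rank, loo[d].rank, n), P_FLOOR, P_CEIL
        )

    records = []
    for j, fid in enumerate(Y.columns):
        blocks_j = {d: float(r2_block[d][j]) for d in domains}
        records.append(
            DecompositionRecord(
                feature_id=str(fid),
                r2_full=float(r2_full[j]),
                r2_block=blocks_j,
                r2_unique={d: float(r2_full[j] - r2_loo[d][j]) for d in domains},
                shared=float(sum(blocks_j.values()) - r2_full[j]),
                p_block={d: float(p_block[d][j]) for d in domains},
                n_used=n,
            )
        )
    return records


def decompose_feature(y: pd.Series, cov: pd.DataFrame, dm: DomainMap) -> DecompositionRecord:
    """Single-feature variance decomposition (see :func:`decompose_matrix`)."""
    y = pd.Series(y)
    keep = y.notna()
    frame = y.loc[keep].to_frame(name=str(y.name or "feature"))
    return decompose_matrix(
        FeatureMatrix(frame, scale_state="winsorized"), cov.loc[keep], dm
    )[0]


def summarize_domains(records: list[DecompositionRecord]) -> pd.DataFrame:
    """Per-domain mean unique/block R² (%) and ACAT-combined p across features."""
    if not records:
        raise OmixvarError("no decomposition records")
    domains = list(records[0].r2_block)
    rows = []
    for d in domains:
        uniq = np.array([max(r.r2_unique[d], 0.0) for r in records])
        block = np.array([r.r2_block[d] for r in records])
        pvals = np.array([r.p_block[d] for r in records])
        rows.append(
            {
                "domain": d,
                "mean_unique_r2_pct": 100.0 * uniq.mean(),
                "mean_block_r2_pct": 100.0 * block.mean(),
                "acat_p": acat_combine(pvals),
                "n_features": len(records),
            }
        )
    return pd.DataFrame(rows).set_index("domain")


def normalize_contributions(record: DecompositionRecord) -> dict[str, float]:
    """Relative contribution of each substantive domain, summing to 1.

    Unique R² values (floored at 0) are divided by their total; shared
    variance is reported separately, not folded in. Technical adjustment is
    excluded. An all-zero record yields a uniform split with a warning.
    """
    domains = [d for d in SUBSTANTIVE_DOMAINS if d in record.r2_unique]
    uniq = {d: max(record.r2_unique[d], 0.0) for d in domains}
    total = sum(uniq.values())
    if total <= 0:
        warnings.warn(
            f"feature {record.feature_id}: no explained variance; uniform contributions",
            stacklevel=2,
        )
        return {d: 1.0 / len(domains) for d in domains}
    return {d: v / total for d, v in uniq.items()}


def score_features(
    records: list[DecompositionRecord], top_k: int = 30
) -> list[FeatureScore]:
    """Rank features by genetic vs environmental influence and label the top-k.

    Scores multiply effect size (unique R², floored at 0) by significance
    (-log10 of the domain partial-F p). A feature in both top-k lists goes to
    the score on which its rank is better; ties go to the genetic label.
    """
    if not records:
        return []
    if "genetic_ancestry" not in records[0].r2_unique:
        raise OmixvarError("genetic_ancestry domain absent; cannot score")

    def _score(r: DecompositionRecord, d: str) -> float:
        p = min(max(r.p_block[d], P_FLOOR), P_CEIL)
        return max(r.r2_unique[d], 0.0) * (-np.log10(p))

    gen = np.array([_score(r, "genetic_ancestry") for r in records])
    env_domains = [d for d in ENVIRONMENTAL_DOMAINS if d in records[0].r2_unique]
    env = np.array([np.mean([_score(r, d) for d in env_domains]) for r in records])

    # ranks: 1 = highest score; stable tie-break on feature order
    order_g = np.lexsort((np.arange(len(records)), -gen))
    order_e = np.lexsort((np.arange(len(records)), -env))
    rank_g, rank_e = np.empty(len(records), int), np.empty(len(records), int)
    rank_g[order_g] = np.arange(1, len(records) + 1)
    rank_e[order_e] = np.arange(1, len(records) + 1)

    scores = []
    for i, r in enumerate(records):
        in_g, in_e = rank_g[i] <= top_k, rank_e[i] <= top_k
        if in_g and in_e:
            label = (
                "genetic_ancestry_influenced"
                if rank_g[i] <= rank_e[i]
                else "environmentally_influenced"
            )
        elif in_g:
            label = "genetic_ancestry_influenced"
        elif in_e:
            label = "environmentally_influenced"
        else:
            label = "unclassified"
        scores.append(
            FeatureScore(
                feature_id=r.feature_id,
                genetic_score=float(gen[i]),
                environmental_score=float(env[i]),
                rank_genetic=int(rank_g[i]),
                rank_environmental=int(rank_e[i]),
                label=label,
            )
        )
    return scores


def records_to_frame(records: list[DecompositionRecord]) -> pd.DataFrame:
    """Flatten decomposition records for TSV/JSON export."""
    rows = []
    for r in records:
        row = {"feature_id": r.feature_id, "r2_full": r.r2_full, "shared": r.shared,
               "n_used": r.n_used}
        for d in r.r2_block:
            row[f"r2_block_{d}"] = r.r2_block[d]
            row[f"r2_unique_{d}"] = r.r2_unique[d]
            row[f"p_block_{d}"] = r.p_block[d]
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature_id")
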