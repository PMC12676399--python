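"""Data-driven covariate screening against the major axes of omic variation.

Principal components are computed per omic on the standardized post-QC
matrix; a covariate is retained when a simple linear regression of any
retained PC on that covariate (joint F-test for dummy-coded categoricals)
reaches the screening threshold (default p < 1e-4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import OLSProjector, build_design, partial_f_pvalue
from .containers import DomainMap, FeatureMatrix, OmixvarError


@dataclass
class OmicPCs:
    sample_ids: list
    pc_scores: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray
    variance_explained: np.ndarray  # fraction of total variance per PC

    @property
    def k(self) -> int:
        return self.pc_scores.shape[1]


def compute_omic_pcs(m: FeatureMatrix | pd.DataFrame, k: int) -> OmicPCs:
    """First k principal components of the standardized feature matrix.

    Uses SVD of the column-standardized matrix; the sign of each PC is fixed
    so its largest-magnitude feature loading is positive, making repeated
    calls deterministic.
    """
    vals = m.values if isinstance(m, FeatureMatrix) else m
    if vals.isna().any().any():
        raise OmixvarError("PCA requires a fully observed matrix")
    X = vals.to_numpy(float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise OmixvarError("zero-variance features present; run QC first")
    X = X / sd
    n, p = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds matrix rank {rank}; truncating", stacklevel=2)
        k = rank
    # sign convention: largest-|loading| positive per component
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * s[:k]
    eig = s**2 / (n - 1)
    var_explained = eig / p  # features standardized -> total variance = p
    return OmicPCs(
        sample_ids=list(vals.index),
        pc_scores=pd.DataFrame(
            scores, index=vals.index, columns=[f"PC{j + 1}" for j in range(k)]
        ),
        eigenvalues=eig[:k],
        variance_explained=var_explained[:k],
    )


def choose_n_pcs(
    m: FeatureMatrix | pd.DataFrame, cum_var: float = 0.70, max_pcs: int = 20
) -> int:
    """Smallest k whose cumulative variance explained reaches ``cum_var`` (capped)."""
    vals = m.values if isinstance(m, FeatureMatrix) else m
    full = compute_omic_pcs(m, min(vals.shape[0] - 1, vals.shape[1]))
    cum = np.cumsum(full.variance_explained)
    k = int(np.searchsorted(cum, cum_var) + 1)
    return min(k, max_pcs, len(cum))


def screen_covariates(
    pcs: OmicPCs,
    cov: pd.DataFrame,
    candidates: list[str] | None = None,
    dm: DomainMap | None = None,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Test each covariate against each retained PC; return the screen table.

    The returned frame has one row per covariate with ``min_p`` (best p over
    PCs), ``best_pc`` and ``retained``. Use ``retained_covariates`` for the
    list form. Constant covariates are skipped with a warning.
    """
    if pcs.k < 1:
        raise OmixvarError("need at least one retained PC")
    cov = cov.loc[pcs.pc_scores.index]
    if candidates is None:
        candidates = dm.columns if dm is not None else list(cov.columns)
    null = OLSProjector(np.empty((len(cov), 0)))  # intercept-only
    Y = pcs.pc_scores.to_numpy(float)
    rows = []
    for c in candidates:
        s = cov[c]
        if s.nunique(dropna=True) < 2:
            warnings.warn(f"covariate {c!r} constant; skipped", stacklevel=2)
            continue
        X = build_design(cov, [c], dm)
        proj = OLSProjector(X)
        pvals = partial_f_pvalue(proj.rss(Y), null.rss(Y), proj.rank, null.rank, len(cov))
        best = int(np.argmin(pvals))
        rows.append(
            {
                "covariate": c,
                "min_p": float(pvals[best]),
                "best_pc": pcs.pc_scores.columns[best],
                "retained": bool(pvals[best] < p_threshold),
            }
        )
    return pd.DataFrame(
        rows, columns=["covariate", "min_p", "best_pc", "retained"]
    ).set_index("covariate")


def retained_covariates(
    pcs: OmicPCs,
    cov: pd.DataFrame,
    candidates: list[str] | None = None,
    dm: DomainMap | None = None,
    p_threshold: float = 1e-4,
) -> list[str]:
    tab = screen_covariates(pcs, cov, candidates, dm, p_threshold)
    return list(tab.index[tab["retained"]])
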