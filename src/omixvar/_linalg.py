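"""Internal OLS helpers shared by the decomposition, screening and
race/ancestry modules.

All variance-decomposition models are ordinary least squares fits of one
feature on a block of covariate columns. The same design matrices are reused
across hundreds of features, so each model is factorized once (pivoted QR,
rank-revealing) and residual sums of squares are obtained by projection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .containers import DomainMap, OmixvarError


def build_design(cov: pd.DataFrame, columns: list[str], dm: DomainMap | None = None) -> np.ndarray:
    """Numeric design matrix (no intercept) for the given covariate columns.

    Categorical columns are expanded to full dummy blocks with the first
    level dropped (the intercept absorbs the reference level).
    """
    blocks: list[np.ndarray] = []
    for col in columns:
        if col not in cov.columns:
            raise OmixvarError(f"covariate {col!r} missing from table")
        s = cov[col]
        if (dm is not None and dm.is_categorical(col, cov)) or s.dtype == object or isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            d = pd.get_dummies(s, drop_first=True, dtype=float)
            blocks.append(d.to_numpy())
        else:
            blocks.append(s.to_numpy(float)[:, None])
    if not blocks:
        return np.empty((len(cov), 0))
    return np.column_stack(blocks)


class OLSProjector:
    """Rank-revealing QR of an intercept-augmented design; cheap RSS per feature."""

    def __init__(self, X: np.ndarray, add_intercept: bool = True):
        n = X.shape[0]
        if add_intercept:
            X = np.column_stack([np.ones(n), X])
        self.n = n
        self.p = X.shape[1]
        Q, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = (diag[0] if diag.size else 0.0) * max(X.shape) * np.finfo(float).eps
        self.rank = int(np.sum(diag > tol))
        if self.rank < self.p:
            warnings.warn(
                f"design rank deficient ({self.rank}/{self.p}); aliased columns dropped",
                stacklevel=2,
            )
        self.Q = Q[:, : self.rank]

    def rss(self, Y: np.ndarray) -> np.ndarray:
        """Residual sum of squares for each column of Y (1-D allowed)."""
        Y = np.asarray(Y, float)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        qty = self.Q.T @ Y
        out = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", qty, qty)
        out = np.clip(out, 0.0, None)
        return out[0] if squeeze else out

    def r2(self, Y: np.ndarray) -> np.ndarray:
        """R² about the mean for each column of Y."""
        Y = np.asarray(Y, float)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        tss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
        rss = np.atleast_1d(self.rss(Y))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        return float(r2[0]) if squeeze else r2


def partial_f_pvalue(
    rss_full: np.ndarray,
    rss_reduced: np.ndarray,
    rank_full: int,
    rank_reduced: int,
    n: int,
) -> np.ndarray:
    """Partial F-test p-value comparing nested OLS models (vectorized)."""
    q = rank_full - rank_reduced
    df2 = n - rank_full
    if q <= 0 or df2 <= 0:
        return np.ones_like(np.atleast_1d(np.asarray(rss_full, float)))
    num = np.clip(np.asarray(rss_reduced, float) - np.asarray(rss_full, float), 0.0, None) / q
    den = np.asarray(rss_full, float) / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(den > 0, num / den, np.inf)
    return stats.f.sf(f, q, df2)
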