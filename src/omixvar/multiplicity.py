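"""Multiple-testing machinery: effective number of tests and Cauchy combination.

Two primitives used throughout the pipeline:

* ``meff_liji`` — the Li & Ji effective number of independent tests, computed
  from the eigenvalues of the feature correlation matrix. Each eigenvalue
  lambda contributes ``f(lambda) = 1[lambda >= 1] + (lambda - floor(lambda))``,
  so M_eff interpolates between 1 (perfect correlation) and M (independence).
* ``acat_combine`` — the Cauchy combination (ACAT) of p-values:
  ``T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i`` and
  ``p = 0.5 - arctan(T)/pi``. ACAT is robust to dependence among the inputs,
  which is what makes it usable across correlated molecular features.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .containers import OmixvarError

# clamp window applied before the tangent transform; tan((0.5-p)*pi) overflows
# at the boundaries
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16

# below this the tangent is replaced by its asymptote 1/(pi*p)
_TINY_P = 1e-15


def correlation_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of a fully observed (post-QC) feature matrix."""
    if values.isna().any().any():
        raise OmixvarError("correlation_matrix requires a fully observed matrix")
    c = np.corrcoef(values.to_numpy(float), rowvar=False)
    c = np.atleast_2d(c)
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=values.columns, columns=values.columns)


def meff_liji(corr, psd_tol: float = 1e-8) -> float:
    """Li & Ji effective number of independent tests.

    Parameters
    ----------
    corr
        Symmetric correlation matrix (DataFrame or ndarray) with unit diagonal.
    psd_tol
        Eigenvalues below ``-psd_tol`` raise; small negative eigenvalues from
        round-off are clipped to zero.
    """
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise OmixvarError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise OmixvarError("correlation matrix must be symmetric (tol 1e-10)")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise OmixvarError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(c)
    if lam.min() < -psd_tol * max(1.0, lam.max()):
        raise OmixvarError(f"correlation matrix not PSD (min eigenvalue {lam.min():.3g})")
    lam = np.clip(lam, 0.0, None)
    m_eff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    # guard against round-off pushing past the theoretical bounds
    return float(min(max(m_eff, 1.0), c.shape[0]))


def acat_combine(p, weights=None) -> float:
    """Combine p-values with the Cauchy combination test (ACAT).

    p-values exactly 0 or 1 are clamped to ``[1e-300, 1 - 1e-16]`` with a
    warning; weights default to equal and must be positive.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise OmixvarError("acat_combine expects a non-empty 1-D array of p-values")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise OmixvarError("p-values must lie in [0, 1]")
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("p-values at 0 or 1 clamped before Cauchy transform", stacklevel=2)
        p = np.clip(p, P_FLOOR, P_CEIL)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or (w <= 0).any():
            raise OmixvarError("weights must be positive and match p in length")
        w = w / w.sum()

    tiny = p < _TINY_P
    terms = np.empty_like(p)
    terms[~tiny] = np.tan((0.5 - p[~tiny]) * math.pi)
    terms[tiny] = 1.0 / (p[tiny] * math.pi)  # asymptote of tan near p -> 0
    t = float(np.sum(w * terms))

    if t > 1e15:  # arctan saturates; use the matching asymptote
        return 1.0 / (t * math.pi)
    return min(max(0.5 - math.atan(t) / math.pi, P_FLOOR), 1.0)


def significance_threshold(alpha: float, m_eff: float) -> float:
    """Per-test threshold alpha / M_eff."""
    if not 0 < alpha < 1:
        raise OmixvarError("alpha must be in (0, 1)")
    if m_eff < 1:
        raise OmixvarError("m_eff must be >= 1")
    return alpha / m_eff
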