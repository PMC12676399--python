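"""Counterfactual mediation of race/ethnicity -> incident T2D through
environmentally influenced molecular features.

The exposure A is a pairwise race/ethnicity contrast (one group vs a
reference), the mediator M a baseline molecular feature, and the outcome a
survival time analyzed with Cox regression. Two working models are fit:

* mediator model:  M = b0 + b1 A + b'C + e            (linear)
* outcome model:   lambda(t) = lambda0(t) exp(t1 A + t2 M + t'C)   (Cox)

with no exposure-mediator interaction. Under a rare outcome the natural
effects on the hazard-ratio scale have closed forms:

    NDE = exp(t1 * da),  NIE = exp(t2 * b1 * da),  total = NDE * NIE
    proportion mediated = NDE * (NIE - 1) / (NDE * NIE - 1)

with ``da`` the exposure contrast (1 vs 0 here). Inference is by seeded
nonparametric bootstrap over samples; the reported ``p_nie`` is a Wald p on
log(NIE) using the bootstrap SE, so screening thresholds far below 1/reps
(e.g. 1e-8) remain meaningful.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import build_design
from .containers import (
    DomainMap,
    MediationEstimate,
    OmixvarError,
    SurvivalTable,
)
from .survival import _cox_newton

RARE_OUTCOME_MAX_EVENT_FRAC = 0.20


def _point_estimates(A, M, C, time, event):
    """(b1, t1, t2) from the two working models on numpy arrays."""
    n = len(A)
    Xm = np.column_stack([np.ones(n), A] + ([C] if C is not None else []))
    coef, *_ = np.linalg.lstsq(Xm, M, rcond=None)
    b1 = float(coef[1])
    Xc_cols = [A[:, None], M[:, None]] + ([C] if C is not None else [])
    Xc = np.column_stack(Xc_cols)
    Xc = Xc - Xc.mean(axis=0)
    beta, _, converged = _cox_newton(Xc, time, event)
    if not converged:
        raise OmixvarError("outcome Cox model did not converge")
    return b1, float(beta[0]), float(beta[1])


def _effects(b1: float, t1: float, t2: float, da: float = 1.0):
    nde = float(np.exp(t1 * da))
    nie = float(np.exp(t2 * b1 * da))
    total = nde * nie
    denom = total - 1.0
    pm = nde * (nie - 1.0) / denom if abs(denom) > 1e-12 else np.nan
    return nde, nie, total, pm


def mediate(
    exposure: pd.Series,
    mediator: pd.Series,
    outcome: SurvivalTable,
    cov: pd.DataFrame | None = None,
    adjust: list[str] | None = None,
    dm: DomainMap | None = None,
    contrast: tuple[str, str] = ("exposed", "reference"),
    reps: int = 1000,
    seed: int = 0,
) -> MediationEstimate:
    """Natural direct/indirect effects of a binary race contrast through one
    mediator, with a Cox outcome model and rare-outcome closed forms.

    ``exposure`` must be binary 0/1 (1 = index group, 0 = reference); rows
    outside the contrast should be excluded before calling. ``reps = 0``
    skips the bootstrap (point estimates only, ``p_nie`` NaN).
    """
    exposure = pd.Series(exposure)
    mediator = pd.Series(mediator)
    keep = exposure.notna() & mediator.notna()
    if cov is not None and adjust:
        keep &= cov.loc[exposure.index, adjust].notna().all(axis=1)
    A = exposure.loc[keep].to_numpy(float)
    if not set(np.unique(A)) <= {0.0, 1.0}:
        raise OmixvarError("exposure contrast must be coded 0/1")
    M = mediator.loc[keep].to_numpy(float)
    data = outcome.data.loc[exposure.index[keep]]
    time, event = data["time"].to_numpy(float), data["event"].to_numpy(int)
    if event.sum() == 0:
        raise OmixvarError("no events in survival data")
    event_frac = event.mean()
    if event_frac > RARE_OUTCOME_MAX_EVENT_FRAC:
        warnings.warn(
            f"event fraction {event_frac:.2f} > {RARE_OUTCOME_MAX_EVENT_FRAC}: "
            "rare-outcome approximation degrades",
            stacklevel=2,
        )
    C = None
    if cov is not None and adjust:
        C = build_design(cov.loc[exposure.index[keep]], adjust, dm)

    b1, t1, t2 = _point_estimates(A, M, C, time, event)
    nde, nie, total, pm = _effects(b1, t1, t2)
    unstable = abs(total - 1.0) < 0.01
    if unstable:
        warnings.warn("total effect near 1: proportion mediated unstable", stacklevel=2)

    p_nie, ci = np.nan, (np.nan, np.nan)
    if reps > 0:
        rng = np.random.default_rng(seed)
        n = len(A)
        log_nie = np.empty(reps)
        for b in range(reps):
            idx = rng.integers(0, n, n)
            try:
                b1_b, t1_b, t2_b = _point_estimates(
                    A[idx], M[idx], C[idx] if C is not None else None,
                    time[idx], event[idx],
                )
                log_nie[b] = t2_b * b1_b
            except (OmixvarError, np.linalg.LinAlgError):
                log_nie[b] = np.nan
        log_nie = log_nie[np.isfinite(log_nie)]
        if len(log_nie) >= max(10, reps // 2):
            se = float(log_nie.std(ddof=1))
            if se > 0:
                z = np.log(nie) / se
                p_nie = float(2 * stats.norm.sf(abs(z)))
            else:
                p_nie = 1.0 if nie == 1.0 else 0.0
            ci = tuple(np.exp(np.percentile(log_nie, [2.5, 97.5])))
        else:
            warnings.warn("bootstrap mostly failed; p_nie unavailable", stacklevel=2)

    return MediationEstimate(
        exposure_contrast=contrast,
        mediator_id=str(mediator.name or "mediator"),
        nde=nde,
        nie=nie,
        total=total,
        proportion_mediated=pm,
        p_nie=p_nie,
        nie_ci=ci,
        bootstrap_reps=reps,
        unstable=unstable,
    )


def mediation_screen(
    estimates: list[MediationEstimate], pm_min: float = 0.10, p_max: float = 1e-8
) -> pd.DataFrame:
    """Mediators with proportion mediated strictly above ``pm_min`` and NIE
    p-value strictly below ``p_max``."""
    rows = [
        {
            "mediator_id": e.mediator_id,
            "contrast": f"{e.exposure_contrast[0]} vs {e.exposure_contrast[1]}",
            "nde": e.nde,
            "nie": e.nie,
            "proportion_mediated": e.proportion_mediated,
            "p_nie": e.p_nie,
        }
        for e in estimates
        if np.isfinite(e.proportion_mediated)
        and e.proportion_mediated > pm_min
        and np.isfinite(e.p_nie)
        and e.p_nie < p_max
    ]
    cols = ["mediator_id", "contrast", "nde", "nie", "proportion_mediated", "p_nie"]
    return pd.DataFrame(rows, columns=cols).set_index("mediator_id")


def race_contrast(
    cov: pd.DataFrame, race_col: str, group: str, reference: str
) -> pd.Series:
    """0/1 exposure series for group-vs-reference; other rows are NaN."""
    race = cov[race_col].astype(str)
    out = pd.Series(np.nan, index=cov.index, name=f"{group}_vs_{reference}")
    out[race == group] = 1.0
    out[race == reference] = 0.0
    return out
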