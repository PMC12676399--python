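"""Disentangling self-reported race/ethnicity from genetic ancestry.

For each feature three nested OLS models are fit on top of a fixed adjustment
set (technical, biological, lifestyle, socioeconomic covariates):

* Model A: adjustment + race/ethnicity
* Model B: adjustment + genetic PCs
* Model C: adjustment + both

R² is attributed to the race/PC terms as *partial* R² over the
adjustment-only baseline, so that ``shared = r2_A + r2_B - r2_C`` measures
overlap between race- and ancestry-related signal net of confounders, and
``unique_race = r2_C - r2_B``, ``unique_gpcs = r2_C - r2_A`` are the nested
delta-R² contributions.

``contrast_partition`` compares one race indicator against one ancestry
proportion inside the same model using Type-II sums of squares (each term's
SS is the RSS increase from deleting it from the full model), so the
attribution does not depend on term order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._linalg import OLSProjector, build_design
from .containers import DomainMap, OmixvarError, OverlapRecord

ALIAS_TOL = 1e-8


def overlap_decompose(
    y: pd.Series,
    cov: pd.DataFrame,
    race_col: str,
    gpc_cols: list[str],
    adjust: list[str],
    dm: DomainMap | None = None,
) -> OverlapRecord:
    """Models A/B/C overlap decomposition for one feature."""
    if not gpc_cols:
        raise OmixvarError("need at least one genetic PC column")
    y = pd.Series(y)
    keep = y.notna() & cov[[race_col, *gpc_cols, *adjust]].notna().all(axis=1)
    y, cov = y.loc[keep], cov.loc[keep]
    yv = y.to_numpy(float)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss == 0:
        raise OmixvarError("feature has zero variance")

    def _r2(cols: list[str]) -> tuple[float, int]:
        proj = OLSProjector(build_design(cov, cols, dm))
        return 1.0 - float(proj.rss(yv)) / tss, proj.rank

    r2_adj, rank_adj = _r2(adjust)
    r2_a_full, rank_a = _r2(adjust + [race_col])
    r2_b_full, rank_b = _r2(adjust + gpc_cols)
    r2_c_full, rank_c = _r2(adjust + [race_col] + gpc_cols)

    r2_A, r2_B, r2_C = r2_a_full - r2_adj, r2_b_full - r2_adj, r2_c_full - r2_adj
    aliased = rank_c < rank_a + rank_b - rank_adj - ALIAS_TOL
    if aliased:
        warnings.warn(
            "race collinear with genetic PCs: unique contributions unidentifiable",
            stacklevel=2,
        )
    return OverlapRecord(
        feature_id=str(y.name or "feature"),
        r2_A=r2_A,
        r2_B=r2_B,
        r2_C=r2_C,
        shared=r2_A + r2_B - r2_C,
        unique_race=r2_C - r2_B,
        unique_gpcs=r2_C - r2_A,
        aliased=bool(aliased),
    )


def contrast_partition(
    y: pd.Series,
    cov: pd.DataFrame,
    race_label: str,
    race_col: str,
    ancestry_col: str,
    adjust: list[str],
    dm: DomainMap | None = None,
) -> dict:
    """Type-II variance shares for a race indicator vs an ancestry proportion.

    ``race_label`` names one race/ethnicity group (e.g. NH-Black); the
    indicator 1[race == label] and the ancestry proportion (e.g. AFR) enter
    the same adjusted model. Each term's Type-II SS is reported as a fraction
    of the total SS of y.
    """
    if race_label not in set(cov[race_col].astype(str)):
        raise OmixvarError(f"race label {race_label!r} absent from column {race_col!r}")
    if ancestry_col not in cov.columns:
        raise OmixvarError(f"ancestry column {ancestry_col!r} absent")
    y = pd.Series(y)
    keep = y.notna() & cov[[race_col, ancestry_col, *adjust]].notna().all(axis=1)
    y, cov = y.loc[keep], cov.loc[keep]
    yv = y.to_numpy(float)
    tss = float(np.sum((yv - yv.mean()) ** 2))

    cov = cov.copy()
    indicator = (cov[race_col].astype(str) == race_label).astype(float)
    cov["_race_ind"] = indicator

    adj = build_design(cov, adjust, dm)
    race = indicator.to_numpy()[:, None]
    anc = cov[ancestry_col].to_numpy(float)[:, None]

    full = OLSProjector(np.column_stack([adj, race, anc]))
    no_race = OLSProjector(np.column_stack([adj, anc]))
    no_anc = OLSProjector(np.column_stack([adj, race]))

    rss_full = float(full.rss(yv))
    ss_race = max(float(no_race.rss(yv)) - rss_full, 0.0)
    ss_anc = max(float(no_anc.rss(yv)) - rss_full, 0.0)
    aliased = full.rank < no_race.rank + 1
    if aliased:
        warnings.warn("race indicator aliased with ancestry proportion", stacklevel=2)
    return {
        "race_share": ss_race / tss if tss else 0.0,
        "ancestry_share": ss_anc / tss if tss else 0.0,
        "aliased": bool(aliased),
        "n_used": int(keep.sum()),
    }


def overlap_table(records: list[OverlapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "r2_A_race": r.r2_A,
                "r2_B_gpcs": r.r2_B,
                "r2_C_both": r.r2_C,
                "shared": r.shared,
                "unique_race": r.unique_race,
                "unique_gpcs": r.unique_gpcs,
                "aliased": r.aliased,
            }
            for r in records
        ]
    ).set_index("feature_id")
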