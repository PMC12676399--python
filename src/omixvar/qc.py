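"""Feature-level QC: zero-variance removal, missingness filters, half-minimum
imputation, log transform and winsorization.

The pipeline order is fixed and mirrors standard metabolomics practice:

    zero-variance -> missingness filter (features, then samples)
    -> half-minimum imputation -> log transform -> winsorize (+/- 5 SD)

Missing values are assumed to be left-censored at the limit of detection,
which is why each feature's missing cells are imputed at half its minimum
observed value. Metabolite abundances are natural-log transformed; Olink NPX
protein values arrive already on the log2 scale and pass through the log step
untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, OmixvarError


@dataclass
class QCReport:
    features_dropped_zero_variance: list = field(default_factory=list)
    features_dropped_missingness: list = field(default_factory=list)
    samples_dropped_missingness: list = field(default_factory=list)
    imputation_values: dict = field(default_factory=dict)
    winsorized_cell_count: int = 0
    log_base: str = ""
    empty_result: bool = False

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            features_dropped_zero_variance=self.features_dropped_zero_variance
            + other.features_dropped_zero_variance,
            features_dropped_missingness=self.features_dropped_missingness
            + other.features_dropped_missingness,
            samples_dropped_missingness=self.samples_dropped_missingness
            + other.samples_dropped_missingness,
            imputation_values={**self.imputation_values, **other.imputation_values},
            winsorized_cell_count=self.winsorized_cell_count + other.winsorized_cell_count,
            log_base=other.log_base or self.log_base,
            empty_result=self.empty_result or other.empty_result,
        )

    def to_dict(self) -> dict:
        return {
            "features_dropped_zero_variance": list(self.features_dropped_zero_variance),
            "features_dropped_missingness": list(self.features_dropped_missingness),
            "samples_dropped_missingness": list(self.samples_dropped_missingness),
            "imputation_values": {k: float(v) for k, v in self.imputation_values.items()},
            "winsorized_cell_count": int(self.winsorized_cell_count),
            "log_base": self.log_base,
        }


def drop_zero_variance(m: FeatureMatrix) -> tuple[FeatureMatrix, QCReport]:
    """Remove features with fewer than two distinct observed values.

    A feature with exactly one non-missing observation counts as zero-variance.
    """
    if m.n_features == 0:
        raise OmixvarError("empty feature matrix")
    nunique = m.values.nunique(dropna=True)
    keep = nunique >= 2
    dropped = list(m.values.columns[~keep])
    report = QCReport(features_dropped_zero_variance=dropped)
    out = m.copy_with(m.values.loc[:, keep])
    if out.n_features == 0:
        warnings.warn("all features dropped as zero-variance", stacklevel=2)
        report.empty_result = True
    return out, report


def filter_missingness(m: FeatureMatrix, threshold: float = 0.25) -> tuple[FeatureMatrix, QCReport]:
    """Drop features, then samples, with missing fraction strictly above ``threshold``.

    The boundary is retained: a feature at exactly 25% missingness stays.
    One pass each, features before samples, no iteration.
    """
    if not 0 < threshold <= 1:
        raise OmixvarError("missingness threshold must be in (0, 1]")
    feat_frac = m.values.isna().mean(axis=0)
    keep_feat = feat_frac <= threshold
    vals = m.values.loc[:, keep_feat]
    samp_frac = vals.isna().mean(axis=1) if vals.shape[1] else pd.Series(0.0, index=vals.index)
    keep_samp = samp_frac <= threshold
    report = QCReport(
        features_dropped_missingness=list(m.values.columns[~keep_feat]),
        samples_dropped_missingness=list(vals.index[~keep_samp]),
    )
    return m.copy_with(vals.loc[keep_samp]), report


def impute_half_min(m: FeatureMatrix) -> tuple[FeatureMatrix, QCReport]:
    """Replace each feature's missing cells with half its minimum observed value."""
    vals = m.values.copy()
    n_obs = vals.notna().sum(axis=0)
    if (n_obs == 0).any():
        empty = list(vals.columns[n_obs == 0])
        raise OmixvarError(
            f"features with no observed values should have been filtered: {empty[:5]}"
        )
    half_min = vals.min(axis=0, skipna=True) / 2.0
    imputed = {}
    for col in vals.columns[vals.isna().any(axis=0)]:
        vals[col] = vals[col].fillna(half_min[col])
        imputed[col] = float(half_min[col])
    report = QCReport(imputation_values=imputed)
    return m.copy_with(vals), report


def log_transform(m: FeatureMatrix) -> tuple[FeatureMatrix, QCReport]:
    """Natural-log transform raw abundances; pass through already-log matrices.

    Protein NPX values stay on the provider's log2 scale.
    """
    if m.scale_state != "raw":
        return m, QCReport(log_base="log2" if m.omic_type == "protein" else "e")
    vals = m.values
    nonpos = vals.columns[(vals <= 0).any(axis=0)]
    if len(nonpos):
        raise OmixvarError(f"non-positive values in features {list(nonpos)[:5]}; cannot log")
    return m.copy_with(np.log(vals), scale_state="log"), QCReport(log_base="e")


def winsorize(m: FeatureMatrix, k_sd: float = 5.0) -> tuple[FeatureMatrix, QCReport]:
    """Clip each feature to mean +/- k_sd * SD.

    Bounds are computed once from the pre-clip distribution (iterative
    recomputation is unstable); clipping with those fixed bounds is idempotent.
    """
    if m.scale_state == "raw":
        raise OmixvarError("winsorize expects a log-scale matrix")
    if k_sd <= 0:
        raise OmixvarError("k_sd must be positive")
    vals = m.values
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    lo, hi = mu - k_sd * sd, mu + k_sd * sd
    clipped = vals.clip(lower=lo, upper=hi, axis=1)
    n_clipped = int(((vals < lo) | (vals > hi)).to_numpy().sum())
    report = QCReport(winsorized_cell_count=n_clipped)
    return m.copy_with(clipped, scale_state="winsorized"), report


def run_qc(
    m: FeatureMatrix, missing_threshold: float = 0.25, winsor_k_sd: float = 5.0
) -> tuple[FeatureMatrix, QCReport]:
    """Full QC pipeline in the fixed order; output has no missing cells."""
    out, report = drop_zero_variance(m)
    out, r2 = filter_missingness(out, missing_threshold)
    out, r3 = impute_half_min(out)
    out, r4 = log_transform(out)
    out, r5 = winsorize(out, winsor_k_sd)
    for r in (r2, r3, r4, r5):
        report = report.merge(r)
    return out, report
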