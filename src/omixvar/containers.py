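"""Shared data containers for the omixvar pipeline.

Conventions
-----------
* Samples are rows everywhere; features (metabolites, proteins) are columns.
* A :class:`FeatureMatrix` carries its omic type and a ``scale_state`` flag so
  that QC stages can enforce the raw -> log -> winsorized ordering. Olink-style
  protein panels arrive already on the log2 NPX scale and enter at ``"log"``.
* Covariates live in a plain :class:`pandas.DataFrame`; the mapping from
  covariate column to domain (technical, biological, lifestyle,
  genetic_ancestry, race_ethnicity, socioeconomic) is a :class:`DomainMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DOMAINS = (
    "technical",
    "biological",
    "lifestyle",
    "genetic_ancestry",
    "race_ethnicity",
    "socioeconomic",
)

#: domains that enter the genetic/environmental scores (technical is adjustment only)
SUBSTANTIVE_DOMAINS = (
    "biological",
    "lifestyle",
    "genetic_ancestry",
    "race_ethnicity",
    "socioeconomic",
)

ENVIRONMENTAL_DOMAINS = ("socioeconomic", "race_ethnicity", "lifestyle")

SCALE_STATES = ("raw", "log", "winsorized")


class OmixvarError(Exception):
    """Base class for configuration and contract violations."""


@dataclass
class FeatureMatrix:
    """Samples x features abundance matrix with missingness (NaN) allowed.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are feature ids. Missing
        observations are NaN.
    omic_type
        ``"metabolite"`` or ``"protein"``.
    scale_state
        One of ``raw``, ``log``, ``winsorized``. Transitions only move
        forward; proteins may enter directly at ``log``.
    """

    values: pd.DataFrame
    omic_type: str = "metabolite"
    scale_state: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_state not in SCALE_STATES:
            raise OmixvarError(f"unknown scale_state {self.scale_state!r}")
        if self.omic_type not in ("metabolite", "protein"):
            raise OmixvarError(f"unknown omic_type {self.omic_type!r}")
        if self.values.index.has_duplicates:
            raise OmixvarError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise OmixvarError("duplicate feature ids")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self, axis: str = "feature") -> pd.Series:
        """Fraction missing per feature (``axis='feature'``) or sample."""
        if axis == "feature":
            return self.values.isna().mean(axis=0)
        return self.values.isna().mean(axis=1)

    def copy_with(self, values: pd.DataFrame, scale_state: str | None = None) -> "FeatureMatrix":
        new_state = self.scale_state if scale_state is None else scale_state
        if SCALE_STATES.index(new_state) < SCALE_STATES.index(self.scale_state):
            raise OmixvarError(
                f"scale_state cannot move backwards ({self.scale_state} -> {new_state})"
            )
        return FeatureMatrix(values=values, omic_type=self.omic_type, scale_state=new_state)


@dataclass
class DomainMap:
    """Maps each model covariate to exactly one domain.

    ``categorical`` lists columns that must enter models as dummy blocks
    (object/category dtype columns are treated as categorical automatically).
    """

    mapping: dict[str, str]
    categorical: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = {d for d in self.mapping.values()} - set(DOMAINS)
        if bad:
            raise OmixvarError(f"unknown domains in map: {sorted(bad)}")

    def columns_for(self, domain: str) -> list[str]:
        return [c for c, d in self.mapping.items() if d == domain]

    def domains_present(self) -> list[str]:
        present = set(self.mapping.values())
        return [d for d in DOMAINS if d in present]

    @property
    def columns(self) -> list[str]:
        return list(self.mapping)

    def is_categorical(self, col: str, cov: pd.DataFrame | None = None) -> bool:
        if col in self.categorical:
            return True
        if cov is not None and col in cov:
            return cov[col].dtype == object or isinstance(
                cov[col].dtype, pd.CategoricalDtype
            )
        return False


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (years) and event indicator for incident T2D."""

    data: pd.DataFrame  # columns: time, event; indexed by sample id

    def __post_init__(self) -> None:
        missing = {"time", "event"} - set(self.data.columns)
        if missing:
            raise OmixvarError(f"survival table missing columns {sorted(missing)}")
        if (self.data["time"] < 0).any():
            raise OmixvarError("negative follow-up time")
        if not self.data["event"].isin([0, 1]).all():
            raise OmixvarError("event indicator must be 0/1")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())


@dataclass
class DecompositionRecord:
    """Per-feature variance decomposition across covariate domains.

    ``shared`` is defined as ``sum_d r2_block[d] - r2_full``; negative unique
    R² (possible numerically or via suppression) is retained raw here and
    floored at zero only for reporting.
    """

    feature_id: str
    r2_full: float
    r2_block: dict[str, float]
    r2_unique: dict[str, float]
    shared: float
    p_block: dict[str, float]
    n_used: int


@dataclass
class FeatureScore:
    feature_id: str
    genetic_score: float
    environmental_score: float
    rank_genetic: int
    rank_environmental: int
    label: str  # genetic_ancestry_influenced | environmentally_influenced | unclassified


@dataclass
class EffectEstimate:
    """Generic (estimate, SE, p) record used by Cox, meta, MR and mediation."""

    feature_id: str
    estimate: float
    se: float
    p: float
    n: int = 0
    n_events: int = 0
    cohort: str = ""
    converged: bool = True


@dataclass
class MetaEstimate:
    feature_id: str
    estimate: float
    se: float
    p: float
    tau2: float
    q_stat: float
    q_p: float
    k_cohorts: int


@dataclass
class OverlapRecord:
    """Race/ethnicity vs genetic-ancestry variance overlap (models A/B/C)."""

    feature_id: str
    r2_A: float  # race only (partial, over adjustment)
    r2_B: float  # genetic PCs only
    r2_C: float  # both
    shared: float
    unique_race: float
    unique_gpcs: float
    aliased: bool = False


@dataclass
class MediationEstimate:
    """Natural direct/indirect effects on the hazard-ratio scale."""

    exposure_contrast: tuple[str, str]
    mediator_id: str
    nde: float
    nie: float
    total: float
    proportion_mediated: float
    p_nie: float
    nie_ci: tuple[float, float] = (np.nan, np.nan)
    bootstrap_reps: int = 0
    unstable: bool = False


def as_feature_matrix(obj, omic_type: str = "metabolite", scale_state: str = "raw") -> FeatureMatrix:
    """Coerce a DataFrame / ndarray into a FeatureMatrix."""
    if isinstance(obj, FeatureMatrix):
        return obj
    if isinstance(obj, np.ndarray):
        obj = pd.DataFrame(
            obj,
            index=[f"S{i}" for i in range(obj.shape[0])],
            columns=[f"F{j}" for j in range(obj.shape[1])],
        )
    return FeatureMatrix(values=obj, omic_type=omic_type, scale_state=scale_state)
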