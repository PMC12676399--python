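"""Synthetic multi-ethnic cohort generator with known ground truth.

The restricted cohorts this pipeline targets (diverse US population studies
with plasma metabolomics/proteomics, incident-diabetes follow-up and TOPMed
genotyping) cannot ship with the package, so every downstream stage is
exercised on simulated data whose generating parameters are known exactly:

* **Covariates** spanning six domains — technical (batch, site, fasting
  hours), biological (age, sex, BMI), lifestyle (smoking, alcohol, diet),
  socioeconomic (education, income), self-reported race/ethnicity, and
  genetic ancestry. Ancestry proportions over {AFR, EUR, AMR, EASIA} are
  drawn from race-specific Dirichlet distributions; genetic PCs are the
  centered ancestry proportions projected onto orthogonal axes plus noise;
  a configurable concordance makes race a noisy proxy of ancestry rather
  than its deterministic function.
* **Features**: each molecular feature is a linear combination of one latent
  signal per domain plus noise, with per-domain variance fractions fixed by
  the spec (``y = sum_d sqrt(f_d) s_d + sqrt(1 - sum f) e``, all signals unit
  variance), then exponentiated to a positive abundance scale for
  metabolites. Values below a per-feature detection-limit quantile are set
  missing (left-censoring at the LOD). Proteins are emitted directly on the
  log2 NPX scale.
* **Survival outcome** from a Weibull proportional-hazards model on the
  latent (uncensored) standardized feature values, with administrative
  censoring.
* **GWAS summary statistics** for exposures and the outcome, with true
  causal effect theta, optional directional pleiotropy, deliberately placed
  close variant pairs and palindromic/rare variants so instrument selection,
  pruning and harmonization have known correct answers, plus a pairwise D'
  table.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
spawned in a fixed order (covariates, features-metabolite, features-protein,
outcome, sumstats), so identical specs give bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import DOMAINS, DomainMap, FeatureMatrix, OmixvarError, SurvivalTable

ANCESTRIES = ("AFR", "EUR", "AMR", "EASIA")

DEFAULT_ADMIXTURE = {
    "NH-White": (0.01, 0.97, 0.01, 0.01),
    "NH-Black": (0.80, 0.17, 0.02, 0.01),
    "Hispanic": (0.08, 0.47, 0.43, 0.02),
    "NH-Asian": (0.01, 0.02, 0.01, 0.96),
}

#: per-domain variance fractions used when a feature has no explicit entry
DEFAULT_FRACTIONS = {
    "technical": 0.02,
    "biological": 0.10,
    "lifestyle": 0.05,
    "genetic_ancestry": 0.03,
    "race_ethnicity": 0.01,
    "socioeconomic": 0.02,
}


@dataclass
class SurvivalTruth:
    """Weibull PH outcome model: hazard scale/shape, per-feature log-HRs (per
    SD of the latent feature), and the administrative censoring horizon."""

    baseline_scale: float = 0.004
    baseline_shape: float = 1.5
    censor_time: float = 15.0
    coefficients: dict[str, float] = field(default_factory=dict)
    age_coef: float = 0.02  # mild covariate dependence of the hazard


@dataclass
class MRTruth:
    """Ground truth for one exposure's two-sample MR scenario."""

    theta: float = 0.4
    n_instruments: int = 30
    instrument_beta_mean: float = 0.10
    instrument_beta_sd: float = 0.02
    se_exposure: float = 0.01
    se_outcome: float = 0.01
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_close_pairs: int = 0  # extra variants 0.5 Mb from an instrument
    n_palindromic: int = 0  # extra A/T variants at EAF 0.5
    n_rare: int = 0  # extra variants with MAF < 0.01
    n_swapped: int = 3  # outcome rows with EA/OA swapped (harmonization test)
    dprime_linked: float = 0.5


@dataclass
class TruthSpec:
    """Full description of one synthetic cohort."""

    n_samples: int = 1000
    n_features_per_omic: dict = field(
        default_factory=lambda: {"metabolite": 50, "protein": 30}
    )
    domain_variance_fractions: dict | None = None  # feature -> {domain: frac}
    default_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    race_categories: tuple = ("NH-White", "NH-Black", "Hispanic", "NH-Asian")
    race_probs: tuple = (0.40, 0.25, 0.22, 0.13)
    ancestry_admixture: dict = field(default_factory=lambda: dict(DEFAULT_ADMIXTURE))
    admixture_concentration: float = 50.0  # inf -> ancestry exactly at race mean
    race_concordance: float = 0.95  # P(label kept given ancestry-drawn label)
    pc_noise_sd: float = 0.05
    lod_quantile: float = 0.05
    batch_count: int = 4
    site_count: int = 2
    survival_model: SurvivalTruth = field(default_factory=SurvivalTruth)
    mr_truth: MRTruth = field(default_factory=MRTruth)
    mr_exposures: tuple = ("MET_0001",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_count < 1 or self.site_count < 1:
            raise OmixvarError("batch_count and site_count must be >= 1")
        if len(self.race_categories) != len(self.race_probs):
            raise OmixvarError("race_categories and race_probs length mismatch")
        if not math.isclose(sum(self.race_probs), 1.0, abs_tol=1e-9):
            raise OmixvarError("race_probs must sum to 1")
        if not 0 <= self.lod_quantile < 1:
            raise OmixvarError("lod_quantile must be in [0, 1)")
        for r in self.race_categories:
            props = self.ancestry_admixture.get(r)
            if props is None:
                raise OmixvarError(f"no admixture means for race {r!r}")
            if not math.isclose(sum(props), 1.0, abs_tol=1e-6):
                raise OmixvarError(f"admixture means for {r!r} must sum to 1")
        for fid, fr in (self.domain_variance_fractions or {}).items():
            self._check_fractions(fid, fr)
        self._check_fractions("<default>", self.default_fractions)
        if self.survival_model.baseline_scale <= 0:
            raise OmixvarError("baseline hazard scale must be positive")
        if self.mr_truth.n_instruments < 1:
            raise OmixvarError("need at least one MR instrument")

    @staticmethod
    def _check_fractions(fid, fr) -> None:
        bad = set(fr) - set(DOMAINS)
        if bad:
            raise OmixvarError(f"{fid}: unknown domains {sorted(bad)}")
        if any(v < 0 for v in fr.values()) or sum(fr.values()) > 1 + 1e-12:
            raise OmixvarError(f"{fid}: domain fractions must be >= 0 and sum to <= 1")

    def fractions_for(self, feature_id: str) -> dict[str, float]:
        if self.domain_variance_fractions and feature_id in self.domain_variance_fractions:
            return dict(self.domain_variance_fractions[feature_id])
        return dict(self.default_fractions)

    def streams(self) -> dict[str, np.random.Generator]:
        names = ("covariates", "features_metabolite", "features_protein", "outcome",
                 "sumstats")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SyntheticBundle:
    spec: TruthSpec
    covariates: pd.DataFrame
    domain_map: DomainMap
    features: dict[str, FeatureMatrix]
    latent: dict[str, pd.DataFrame]  # uncensored log-scale feature values
    realized_fractions: dict[str, pd.DataFrame]  # feature x domain realized R2
    outcome: SurvivalTable
    mr_data: dict[str, dict]  # exposure -> {exposure, outcome, ld} DataFrames


def default_domain_map(n_gpcs: int = 6) -> DomainMap:
    mapping = {
        "batch": "technical",
        "site": "technical",
        "fasting_hours": "technical",
        "age": "biological",
        "sex": "biological",
        "bmi": "biological",
        "smoking": "lifestyle",
        "alcohol": "lifestyle",
        "diet_fish": "lifestyle",
        "diet_legumes": "lifestyle",
        "diet_red_meat": "lifestyle",
        "diet_energy": "lifestyle",
        "education": "socioeconomic",
        "income": "socioeconomic",
        "race": "race_ethnicity",
    }
    for j in range(1, n_gpcs + 1):
        mapping[f"gPC{j}"] = "genetic_ancestry"
    return DomainMap(mapping=mapping, categorical=("batch", "site", "smoking", "race"))


def generate_covariates(spec: TruthSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-sample covariate table with domain-tagged columns.

    Includes ancestry proportions (``anc_AFR`` ...) and six genetic PCs
    derived from centered ancestry proportions plus noise.
    """
    rng = rng if rng is not None else spec.streams()["covariates"]
    n = spec.n_samples
    idx = pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id")
    cats = list(spec.race_categories)

    race_latent = rng.choice(len(cats), size=n, p=spec.race_probs)
    means = np.array([spec.ancestry_admixture[c] for c in cats], float)
    if math.isinf(spec.admixture_concentration):
        ancestry = means[race_latent]
    else:
        alpha = spec.admixture_concentration * means[race_latent] + 1e-3
        ancestry = rng.gamma(alpha)
        ancestry = ancestry / ancestry.sum(axis=1, keepdims=True)
    # self-reported label: usually the ancestry-drawn group, occasionally not
    race = race_latent.copy()
    flip = rng.random(n) > spec.race_concordance
    race[flip] = rng.choice(len(cats), size=int(flip.sum()))

    centered = ancestry - (ancestry.mean(axis=0) if n else 0.0)
    gpcs = np.zeros((n, 6))
    # round-off from mean subtraction must not masquerade as structure
    if n > 1 and np.abs(centered).max() > 1e-10:
        U, s, _ = np.linalg.svd(centered, full_matrices=False)
        k = min(3, int(np.sum(s > max(s[0] * 1e-10, 1e-12)))) if s.size else 0
        for j in range(k):
            score = U[:, j] * s[j]
            sd = score.std(ddof=1)
            gpcs[:, j] = score / sd if sd > 0 else score
    gpcs += spec.pc_noise_sd * rng.standard_normal((n, 6))

    df = pd.DataFrame(index=idx)
    df["age"] = np.round(rng.normal(60, 9, n), 1)
    df["sex"] = rng.binomial(1, 0.52, n)
    df["bmi"] = np.round(rng.normal(28.5, 5.5, n), 2)
    df["smoking"] = rng.choice(["never", "former", "current"], size=n, p=[0.5, 0.35, 0.15])
    df["alcohol"] = np.round(rng.gamma(1.2, 0.5, n), 3)
    df["diet_fish"] = np.round(rng.gamma(2.0, 0.8, n), 3)
    df["diet_legumes"] = np.round(rng.gamma(2.0, 0.6, n), 3)
    df["diet_red_meat"] = np.round(rng.gamma(2.5, 0.7, n), 3)
    df["diet_energy"] = np.round(rng.normal(2000, 450, n), 1)
    df["education"] = rng.choice(np.arange(1, 6), size=n, p=[0.08, 0.22, 0.3, 0.25, 0.15])
    df["income"] = rng.choice(np.arange(1, 9), size=n)
    df["race"] = pd.Categorical([cats[i] for i in race], categories=cats)
    for j, a in enumerate(ANCESTRIES):
        df[f"anc_{a}"] = ancestry[:, j]
    for j in range(6):
        df[f"gPC{j + 1}"] = gpcs[:, j]
    df["batch"] = pd.Categorical([f"B{b + 1}" for b in rng.integers(0, spec.batch_count, n)])
    df["site"] = pd.Categorical([f"SITE{sx + 1}" for sx in rng.integers(0, spec.site_count, n)])
    df["fasting_hours"] = np.round(rng.normal(12, 1.2, n), 1)
    return df


def _domain_designs(cov: pd.DataFrame, dm: DomainMap) -> dict[str, np.ndarray]:
    """Standardized numeric design per domain (zero-variance columns dropped)."""
    from ._linalg import build_design

    designs = {}
    for d in dm.domains_present():
        X = build_design(cov, dm.columns_for(d), dm)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if len(X) > 1 else np.ones(X.shape[1])
        keep = sd > 0
        designs[d] = (X[:, keep] - mu[keep]) / sd[keep] if keep.any() else X[:, :0]
    return designs


def _feature_ids(omic: str, n: int) -> list[str]:
    prefix = "MET" if omic == "metabolite" else "PROT"
    return [f"{prefix}_{j + 1:04d}" for j in range(n)]


def generate_features(
    spec: TruthSpec,
    cov: pd.DataFrame,
    omic_type: str = "metabolite",
    dm: DomainMap | None = None,
    rng: np.random.Generator | None = None,
    return_latent: bool = False,
):
    """Feature matrix whose per-domain population R² matches the spec fractions.

    For each feature, one latent unit-variance signal per domain is built as a
    random linear combination of that domain's standardized covariates;
    domain signals are weighted by sqrt(fraction) and white noise fills the
    remaining variance. Metabolites are exponentiated to a positive raw scale
    and left-censored below the ``lod_quantile``; proteins stay on the log2
    NPX scale (censored on that scale).

    With ``return_latent=True`` also returns the uncensored log-scale matrix
    and the realized (OLS-refit) per-domain R² table.
    """
    dm = dm or default_domain_map()
    rng = rng if rng is not None else spec.streams()[f"features_{omic_type}"]
    n = len(cov)
    ids = _feature_ids(omic_type, spec.n_features_per_omic.get(omic_type, 0))
    designs = _domain_designs(cov, dm) if n > 1 else {}
    domains = list(designs)

    latent = np.empty((n, len(ids)))
    for j, fid in enumerate(ids):
        fr = spec.fractions_for(fid)
        resid = 1.0 - sum(fr.values())
        y = math.sqrt(max(resid, 0.0)) * rng.standard_normal(n)
        for d in domains:
            f_d = fr.get(d, 0.0)
            Z = designs[d]
            if f_d <= 0 or Z.shape[1] == 0:
                # keep the stream advancing identically regardless of fractions
                rng.standard_normal(Z.shape[1] if Z.shape[1] else 1)
                continue
            u = rng.standard_normal(Z.shape[1])
            s = Z @ u
            sd = s.std(ddof=1)
            if sd > 0:
                y = y + math.sqrt(f_d) * (s - s.mean()) / sd
        latent[:, j] = y

    mu = rng.normal(10.0, 1.0, len(ids))  # mean log-abundance per feature
    log_vals = latent + mu
    if omic_type == "metabolite":
        obs = np.exp(log_vals)
    else:
        obs = log_vals / math.log(2)  # latent natural-log scale -> log2 NPX

    vals = obs.copy()
    if spec.lod_quantile > 0 and n > 0:
        for j in range(vals.shape[1]):
            lod = np.quantile(vals[:, j], spec.lod_quantile)
            vals[vals[:, j] < lod, j] = np.nan

    fm = FeatureMatrix(
        pd.DataFrame(vals, index=cov.index, columns=ids),
        omic_type=omic_type,
        scale_state="raw" if omic_type == "metabolite" else "log",
    )
    if not return_latent:
        return fm
    latent_df = pd.DataFrame(latent, index=cov.index, columns=ids)
    realized = _realized_fractions(latent_df, designs)
    return fm, latent_df, realized


def _realized_fractions(latent: pd.DataFrame, designs: dict[str, np.ndarray]) -> pd.DataFrame:
    from ._linalg import OLSProjector

    Y = latent.to_numpy(float)
    out = {}
    for d, Z in designs.items():
        out[d] = OLSProjector(Z).r2(Y) if Z.shape[1] else np.zeros(Y.shape[1])
    return pd.DataFrame(out, index=latent.columns)


def generate_outcome(
    spec: TruthSpec,
    latent: pd.DataFrame,
    cov: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> SurvivalTable:
    """Weibull proportional-hazards event times with administrative censoring.

    The linear predictor uses the standardized latent (uncensored) feature
    values and the spec's per-feature log-HR coefficients, plus a mild age
    effect; event times follow ``h(t) = scale * shape * t^(shape-1) * exp(lp)``.
    """
    sm = spec.survival_model
    if sm.baseline_scale <= 0:
        raise OmixvarError("baseline hazard scale must be positive")
    rng = rng if rng is not None else spec.streams()["outcome"]
    n = len(cov)
    lp = np.zeros(n)
    for fid, coef in sm.coefficients.items():
        if fid not in latent.columns:
            raise OmixvarError(f"survival coefficient for unknown feature {fid!r}")
        z = latent[fid].to_numpy(float)
        sd = z.std(ddof=1)
        lp += coef * (z - z.mean()) / (sd if sd > 0 else 1.0)
    if sm.age_coef:
        age = cov["age"].to_numpy(float)
        lp += sm.age_coef * (age - age.mean())
    e = rng.exponential(1.0, n)
    t_event = (e / (sm.baseline_scale * np.exp(lp))) ** (1.0 / sm.baseline_shape)
    time = np.minimum(t_event, sm.censor_time)
    event = (t_event <= sm.censor_time).astype(int)
    return SurvivalTable(pd.DataFrame({"time": time, "event": event}, index=cov.index))


_BASES = np.array(["A", "C", "G", "T"])


def generate_sumstats(
    spec: TruthSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Exposure and outcome GWAS summary statistics plus a pairwise D' table.

    The first ``n_instruments`` variants are valid instruments: strong,
    common, well separated (>= 2 Mb spacing). Extra variants exercise the
    selection logic — close pairs (0.5 Mb from an instrument, less
    significant, D' = ``dprime_linked``), palindromic A/T variants at EAF
    0.5, and rare variants below the MAF filter. The first ``n_swapped``
    outcome rows have EA/OA swapped (with beta negated) so harmonization has
    work to do. Outcome betas are ``theta * gamma + pleiotropy + noise``.
    """
    mt = spec.mr_truth
    rng = rng if rng is not None else spec.streams()["sumstats"]
    k = mt.n_instruments

    chrom = (np.arange(k) % 22) + 1
    pos = 10_000_000 + (np.arange(k) // 22) * 5_000_000
    gamma = rng.normal(mt.instrument_beta_mean, mt.instrument_beta_sd, k) * rng.choice(
        [-1.0, 1.0], k
    )
    eaf = rng.uniform(0.10, 0.90, k)
    beta_x = gamma + mt.se_exposure * rng.standard_normal(k)
    alpha = (
        rng.normal(mt.pleiotropy_mean, mt.pleiotropy_sd, k)
        if (mt.pleiotropy_mean or mt.pleiotropy_sd)
        else np.zeros(k)
    )
    # pleiotropy is directional with respect to the exposure-increasing
    # allele, which is what the Egger intercept is designed to detect
    beta_y = mt.theta * gamma + alpha * np.sign(gamma) + mt.se_outcome * rng.standard_normal(k)

    # valid instruments get deliberately non-palindromic allele pairs; the
    # dedicated palindromic extras below exercise the ambiguity drop
    _pairs = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"), ("G", "A"),
              ("G", "T"), ("T", "C"), ("T", "G")]
    pair_idx = rng.integers(0, len(_pairs), k)
    rows = []
    for i in range(k):
        rows.append(
            dict(SNP=f"rs{i + 1:05d}", CHR=int(chrom[i]), POS=int(pos[i]),
                 EA=_pairs[pair_idx[i]][0], OA=_pairs[pair_idx[i]][1], EAF=float(eaf[i]),
                 BETA=float(beta_x[i]), SE=mt.se_exposure,
                 kind="instrument", gamma=float(gamma[i]), beta_y=float(beta_y[i]))
        )
    nxt = k + 1
    ld_rows = []
    for j in range(mt.n_close_pairs):
        anchor = rows[j % k]
        snp = f"rs{nxt:05d}"
        rows.append(
            dict(SNP=snp, CHR=anchor["CHR"], POS=anchor["POS"] + 500_000,
                 EA="A", OA="C", EAF=float(rng.uniform(0.1, 0.9)),
                 BETA=anchor["BETA"] * 0.9, SE=mt.se_exposure * 1.5,
                 kind="close_pair", gamma=0.0,
                 beta_y=float(mt.theta * anchor["gamma"] * 0.9))
        )
        ld_rows.append(dict(SNP_A=anchor["SNP"], SNP_B=snp, DPRIME=mt.dprime_linked))
        nxt += 1
    for _ in range(mt.n_palindromic):
        rows.append(
            dict(SNP=f"rs{nxt:05d}", CHR=int(rng.integers(1, 23)),
                 POS=int(200_000_000 + nxt * 3_000_000), EA="A", OA="T", EAF=0.5,
                 BETA=float(rng.normal(mt.instrument_beta_mean, mt.instrument_beta_sd)),
                 SE=mt.se_exposure, kind="palindromic", gamma=0.0, beta_y=0.0)
        )
        nxt += 1
    for _ in range(mt.n_rare):
        rows.append(
            dict(SNP=f"rs{nxt:05d}", CHR=int(rng.integers(1, 23)),
                 POS=int(150_000_000 + nxt * 3_000_000), EA="G", OA="T", EAF=0.005,
                 BETA=float(rng.normal(0.3, 0.05)), SE=mt.se_exposure,
                 kind="rare", gamma=0.0, beta_y=0.0)
        )
        nxt += 1

    full = pd.DataFrame(rows)
    z = full["BETA"].to_numpy() / full["SE"].to_numpy()
    from scipy import stats as _st

    full["P"] = np.clip(2 * _st.norm.sf(np.abs(z)), 1e-300, 1.0)
    exposure = full[["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P"]].copy()

    out = full.copy()
    out["BETA"] = out["beta_y"]
    out["SE"] = mt.se_outcome
    zo = out["BETA"].to_numpy() / out["SE"].to_numpy()
    out["P"] = np.clip(2 * _st.norm.sf(np.abs(zo)), 1e-300, 1.0)
    swap = min(mt.n_swapped, len(out))
    if swap:
        ea = out.loc[: swap - 1, "EA"].copy()
        out.loc[: swap - 1, "EA"] = out.loc[: swap - 1, "OA"].to_numpy()
        out.loc[: swap - 1, "OA"] = ea.to_numpy()
        out.loc[: swap - 1, "BETA"] = -out.loc[: swap - 1, "BETA"]
        out.loc[: swap - 1, "EAF"] = 1.0 - out.loc[: swap - 1, "EAF"]
    outcome = out[["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P"]].copy()

    ld = pd.DataFrame(ld_rows, columns=["SNP_A", "SNP_B", "DPRIME"])
    return exposure, outcome, ld


def generate_mediation_scenario(
    n_samples: int = 5000,
    theta1: float = 0.4822,
    theta2: float = 0.30,
    b1: float = 0.40,
    p_exposed: float = 0.4,
    baseline_scale: float = 0.0012,
    baseline_shape: float = 1.5,
    censor_time: float = 15.0,
    seed: int = 0,
) -> dict:
    """Rare-outcome mediation scenario with known path coefficients.

    ``A ~ Bernoulli(p_exposed)``; mediator ``M = b1 * A + e``; hazard
    ``h(t) = scale * shape * t^(shape-1) * exp(theta1 A + theta2 M)``.
    Under the rare-outcome approximation the true effects are
    ``NDE = exp(theta1)``, ``NIE = exp(theta2 * b1)`` and the defaults give a
    true proportion mediated of 0.25. Returns exposure, mediator, outcome and
    the truth dict.
    """
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"S{i:06d}" for i in range(n_samples)], name="sample_id")
    A = rng.binomial(1, p_exposed, n_samples).astype(float)
    M = b1 * A + rng.standard_normal(n_samples)
    lp = theta1 * A + theta2 * M
    e = rng.exponential(1.0, n_samples)
    t_event = (e / (baseline_scale * np.exp(lp))) ** (1.0 / baseline_shape)
    time = np.minimum(t_event, censor_time)
    event = (t_event <= censor_time).astype(int)
    nde = math.exp(theta1)
    nie = math.exp(theta2 * b1)
    truth = {
        "nde": nde,
        "nie": nie,
        "total": nde * nie,
        "proportion_mediated": nde * (nie - 1.0) / (nde * nie - 1.0),
    }
    return {
        "exposure": pd.Series(A, index=idx, name="exposed"),
        "mediator": pd.Series(M, index=idx, name="mediator"),
        "outcome": SurvivalTable(pd.DataFrame({"time": time, "event": event}, index=idx)),
        "truth": truth,
    }


def generate_bundle(spec: TruthSpec, dm: DomainMap | None = None) -> SyntheticBundle:
    """Everything a pipeline run needs, deterministically from ``spec.seed``."""
    dm = dm or default_domain_map()
    streams = spec.streams()
    cov = generate_covariates(spec, streams["covariates"])
    features, latent, realized = {}, {}, {}
    for omic in spec.n_features_per_omic:
        fm, lat, real = generate_features(
            spec, cov, omic, dm, streams[f"features_{omic}"], return_latent=True
        )
        features[omic], latent[omic], realized[omic] = fm, lat, real
    all_latent = pd.concat(latent.values(), axis=1) if latent else pd.DataFrame(index=cov.index)
    outcome = generate_outcome(spec, all_latent, cov, streams["outcome"])
    mr_data = {}
    rng_sumstats = streams["sumstats"]
    for exp_id in spec.mr_exposures:
        e, o, l = generate_sumstats(spec, rng_sumstats)
        mr_data[exp_id] = {"exposure": e, "outcome": o, "ld": l}
    return SyntheticBundle(
        spec=spec,
        covariates=cov,
        domain_map=dm,
        features=features,
        latent=latent,
        realized_fractions=realized,
        outcome=outcome,
        mr_data=mr_data,
    )


def generate_cohorts(spec: TruthSpec, n_cohorts: int = 2) -> dict[str, SyntheticBundle]:
    """Independent cohorts sharing the same truth, with derived seeds."""
    out = {}
    for i in range(n_cohorts):
        child = replace(spec, seed=(spec.seed * 1000 + i) % (2**31 - 1))
        out[f"cohort{i + 1}"] = generate_bundle(child)
    return out


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write bundle tables as TSV; returns {name: path}."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _w(name: str, df: pd.DataFrame, index=True):
        p = os.path.join(outdir, f"{name}.tsv")
        df.to_csv(p, sep="\t", index=index)
        paths[name] = p

    _w("covariates", bundle.covariates)
    for omic, fm in bundle.features.items():
        _w(f"features_{omic}", fm.values)
    _w("outcome", bundle.outcome.data)
    for exp_id, tabs in bundle.mr_data.items():
        _w(f"sumstats_{exp_id}_exposure", tabs["exposure"], index=False)
        _w(f"sumstats_{exp_id}_outcome", tabs["outcome"], index=False)
        _w(f"ld_{exp_id}", tabs["ld"], index=False)
    return paths
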