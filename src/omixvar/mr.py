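"""Two-sample Mendelian randomization for genetically influenced features.

Workflow: GWAS summary statistics for an exposure (metabolite/protein) and
the outcome (T2D) are filtered (MAF > 0.01, exposure p below the instrument
threshold), distance-pruned (most significant variant kept per 1 Mb window on
either side), optionally LD-pruned on a supplied D' table (pairs with
D' > 0.2 resolved toward the smaller p), harmonized across the two studies
(allele swap -> sign flip; strand flips via complements; palindromic variants
with intermediate allele frequency dropped), and analyzed with three
estimators:

* IVW: weighted regression of outcome betas on exposure betas through the
  origin, weights 1/se_out²; SE inflated multiplicatively by
  max(1, sqrt(Q/(k-1))) (random-effects on the residual scale).
* MR-Egger: same regression with a free intercept (exposure betas oriented
  positive); a non-zero intercept indicates directional pleiotropy.
* Weighted median: 50%-cumulative-weight order statistic of the Wald ratios;
  consistent when at least half the weight comes from valid instruments.
  SE by seeded parametric bootstrap.

Sum-stat tables are DataFrames with columns SNP, CHR, POS, EA, OA, EAF,
BETA, SE, P; the LD table has SNP_A, SNP_B, DPRIME.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmixvarError

SUMSTAT_COLS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class InstrumentSet:
    """Harmonized instruments for one exposure."""

    exposure_id: str
    table: pd.DataFrame  # SNP, beta_exp, se_exp, beta_out, se_out
    provenance: list[str] = field(default_factory=list)

    @property
    def n_instruments(self) -> int:
        return len(self.table)


@dataclass
class MRResult:
    exposure_id: str
    estimates: dict  # method -> {"estimate","se","p"} (or None if unavailable)
    egger_intercept: float
    egger_intercept_p: float
    cochran_q: float
    cochran_q_p: float
    n_instruments: int


def _validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(SUMSTAT_COLS) - set(df.columns)
    if missing:
        raise OmixvarError(f"summary statistics missing columns {sorted(missing)}")
    bad_alleles = ~(
        df["EA"].isin(_COMPLEMENT) & df["OA"].isin(_COMPLEMENT) & (df["EA"] != df["OA"])
    )
    if bad_alleles.any():
        warnings.warn(
            f"{int(bad_alleles.sum())} multi-allelic/invalid-allele rows rejected",
            stacklevel=3,
        )
        df = df.loc[~bad_alleles]
    return df


def select_instruments(
    sumstats: pd.DataFrame,
    p_threshold: float = 5e-8,
    maf_min: float = 0.01,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """MAF + significance filtering, then greedy distance pruning.

    Candidates are sorted by p ascending; a variant is accepted iff no
    already-accepted variant on the same chromosome lies within ``window_bp``
    on either side (strict: equal-to-window distance is kept).
    """
    df = _validate_sumstats(sumstats)
    maf = np.minimum(df["EAF"], 1 - df["EAF"])
    df = df.loc[(maf > maf_min) & (df["P"] < p_threshold)]
    if df.empty:
        warnings.warn("no candidate instruments after filtering", stacklevel=2)
        return df
    df = df.sort_values(["P", "SNP"], kind="stable")
    accepted: list[int] = []
    pos_by_chr: dict = {}
    for i, row in enumerate(df.itertuples(index=False)):
        near = pos_by_chr.get(row.CHR, [])
        if any(abs(row.POS - p) < window_bp for p in near):
            continue
        accepted.append(i)
        pos_by_chr.setdefault(row.CHR, []).append(row.POS)
    return df.iloc[accepted].reset_index(drop=True)


def ld_prune(
    candidates: pd.DataFrame, ld_table: pd.DataFrame | None, dprime_max: float = 0.2
) -> pd.DataFrame:
    """Greedy LD pruning: for each pair with D' > dprime_max the less
    significant member is removed, iterating from the most significant variant.

    Same-chromosome pairs absent from the table are treated as D' = 0 with a
    warning.
    """
    if candidates.empty or ld_table is None or ld_table.empty:
        if ld_table is None and len(candidates) > 1:
            same_chr = candidates["CHR"].duplicated(keep=False).any()
            if same_chr:
                warnings.warn("no LD table supplied; missing pairs assumed D'=0", stacklevel=2)
        return candidates.reset_index(drop=True)
    dprime: dict[frozenset, float] = {
        frozenset((a, b)): float(d)
        for a, b, d in zip(ld_table["SNP_A"], ld_table["SNP_B"], ld_table["DPRIME"])
    }
    ordered = candidates.sort_values(["P", "SNP"], kind="stable")
    kept: list[str] = []
    missing_pairs = 0
    for row in ordered.itertuples(index=False):
        linked = False
        for k in kept:
            key = frozenset((row.SNP, k))
            if key not in dprime:
                missing_pairs += 1
                continue
            if dprime[key] > dprime_max:
                linked = True
                break
        if not linked:
            kept.append(row.SNP)
    if missing_pairs:
        warnings.warn(
            f"{missing_pairs} candidate pairs absent from LD table; assumed D'=0",
            stacklevel=2,
        )
    out = candidates[candidates["SNP"].isin(kept)]
    return out.sort_values("POS", kind="stable").reset_index(drop=True)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    exposure_id: str = "exposure",
    palindromic_eaf: tuple[float, float] = (0.42, 0.58),
) -> InstrumentSet:
    """Align outcome effect alleles to the exposure's; build the instrument set.

    Allele-swapped records get their outcome beta negated; strand flips are
    resolved via complements; palindromic (A/T, C/G) variants with EAF in the
    ambiguity window are dropped.
    """
    log: list[str] = []
    out_by_snp = {r.SNP: r for r in _validate_sumstats(outcome).itertuples(index=False)}
    rows = []
    for r in _validate_sumstats(exposure).itertuples(index=False):
        o = out_by_snp.get(r.SNP)
        if o is None:
            log.append(f"{r.SNP}: absent from outcome study; dropped")
            continue
        pal = frozenset((r.EA, r.OA)) in _PALINDROMIC
        if pal and palindromic_eaf[0] <= r.EAF <= palindromic_eaf[1]:
            log.append(f"{r.SNP}: palindromic with EAF {r.EAF:.2f}; dropped")
            continue
        beta_out = None
        if (o.EA, o.OA) == (r.EA, r.OA):
            beta_out = o.BETA
        elif (o.EA, o.OA) == (r.OA, r.EA):
            beta_out = -o.BETA
            log.append(f"{r.SNP}: outcome alleles swapped; beta negated")
        elif not pal:
            flip = (_COMPLEMENT[o.EA], _COMPLEMENT[o.OA])
            if flip == (r.EA, r.OA):
                beta_out = o.BETA
                log.append(f"{r.SNP}: strand flip resolved")
            elif flip == (r.OA, r.EA):
                beta_out = -o.BETA
                log.append(f"{r.SNP}: strand flip + swap; beta negated")
        if beta_out is None:
            log.append(f"{r.SNP}: irreconcilable alleles {r.EA}/{r.OA} vs {o.EA}/{o.OA}; dropped")
            continue
        rows.append(
            {
                "SNP": r.SNP,
                "beta_exp": float(r.BETA),
                "se_exp": float(r.SE),
                "beta_out": float(beta_out),
                "se_out": float(o.SE),
            }
        )
    table = pd.DataFrame(rows, columns=["SNP", "beta_exp", "se_exp", "beta_out", "se_out"])
    return InstrumentSet(exposure_id=exposure_id, table=table, provenance=log)


def _ratios(inst: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Wald ratios and their first-order SEs."""
    t = inst.table
    bx, by = t["beta_exp"].to_numpy(), t["beta_out"].to_numpy()
    ratio = by / bx
    se = t["se_out"].to_numpy() / np.abs(bx)
    return ratio, se


def cochran_q(inst: InstrumentSet, estimate: float) -> tuple[float, float]:
    """Heterogeneity of the per-instrument Wald ratios about the IVW estimate."""
    ratio, se = _ratios(inst)
    q = float(np.sum((ratio - estimate) ** 2 / se**2))
    df = len(ratio) - 1
    return q, (float(stats.chi2.sf(q, df)) if df > 0 else 1.0)


def ivw(inst: InstrumentSet, random_effects: bool = True) -> dict:
    """Inverse-variance-weighted estimate (zero-intercept weighted regression)."""
    if inst.n_instruments < 2:
        raise OmixvarError("IVW needs at least 2 instruments")
    t = inst.table
    bx, by, so = t["beta_exp"].to_numpy(), t["beta_out"].to_numpy(), t["se_out"].to_numpy()
    w = 1.0 / so**2
    est = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se_fixed = float(1.0 / np.sqrt(np.sum(w * bx**2)))
    k = len(bx)
    q = float(np.sum(w * (by - est * bx) ** 2))
    se = se_fixed
    if random_effects and k > 1:
        se = se_fixed * max(1.0, float(np.sqrt(q / (k - 1))))
    z = est / se
    return {
        "estimate": est,
        "se": se,
        "p": float(2 * stats.norm.sf(abs(z))),
        "q": q,
        "q_p": float(stats.chi2.sf(q, k - 1)),
    }


def mr_egger(inst: InstrumentSet) -> dict:
    """Weighted regression with intercept; the intercept tests directional
    pleiotropy. Exposure betas are oriented positive first (InSIDE convention)."""
    if inst.n_instruments < 3:
        raise OmixvarError("MR-Egger needs at least 3 instruments")
    t = inst.table
    sign = np.sign(t["beta_exp"].to_numpy())
    sign[sign == 0] = 1.0
    bx = t["beta_exp"].to_numpy() * sign
    by = t["beta_out"].to_numpy() * sign
    so = t["se_out"].to_numpy()
    w = 1.0 / so**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    k = len(bx)
    # multiplicative overdispersion, floored at 1
    sigma2 = max(1.0, float(np.sum(w * resid**2) / (k - 2)))
    vcov = np.linalg.inv(xtx) * sigma2
    se_int, se_slope = np.sqrt(np.diag(vcov))
    t_int = coef[0] / se_int
    t_slope = coef[1] / se_slope
    return {
        "estimate": float(coef[1]),
        "se": float(se_slope),
        "p": float(2 * stats.t.sf(abs(t_slope), k - 2)),
        "intercept": float(coef[0]),
        "intercept_se": float(se_int),
        "intercept_p": float(2 * stats.t.sf(abs(t_int), k - 2)),
    }


def weighted_median(inst: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> dict:
    """Weighted median of Wald ratios; SE by seeded parametric bootstrap."""
    if inst.n_instruments < 3:
        raise OmixvarError("weighted median needs at least 3 instruments")
    ratio, ratio_se = _ratios(inst)
    w = 1.0 / ratio_se**2

    def _wm(r: np.ndarray, wt: np.ndarray) -> float:
        order = np.argsort(r)
        r, wt = r[order], wt[order]
        cum = np.cumsum(wt) - 0.5 * wt
        cum = cum / wt.sum()
        if cum[0] >= 0.5:
            return float(r[0])
        if cum[-1] <= 0.5:
            return float(r[-1])
        return float(np.interp(0.5, cum, r))

    est = _wm(ratio, w)
    rng = np.random.default_rng(seed)
    t = inst.table
    bx, sx = t["beta_exp"].to_numpy(), t["se_exp"].to_numpy()
    by, so = t["beta_out"].to_numpy(), t["se_out"].to_numpy()
    sims = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(len(bx))
        by_b = by + so * rng.standard_normal(len(by))
        bx_b[bx_b == 0] = 1e-12
        r_b = by_b / bx_b
        w_b = (np.abs(bx_b) / so) ** 2
        sims[b] = _wm(r_b, w_b)
    se = float(sims.std(ddof=1))
    z = est / se if se > 0 else np.inf * np.sign(est)
    return {"estimate": est, "se": se, "p": float(2 * stats.norm.sf(abs(z)))}


def run_mr(
    inst: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """All three estimators plus heterogeneity/pleiotropy diagnostics."""
    est: dict = {"ivw": None, "egger": None, "weighted_median": None}
    q = q_p = np.nan
    if inst.n_instruments >= 2:
        res = ivw(inst)
        q, q_p = res.pop("q"), res.pop("q_p")
        est["ivw"] = res
    egger_int = egger_int_p = np.nan
    if inst.n_instruments >= 3:
        eg = mr_egger(inst)
        egger_int, egger_int_p = eg.pop("intercept"), eg.pop("intercept_p")
        eg.pop("intercept_se")
        est["egger"] = eg
        est["weighted_median"] = weighted_median(inst, n_boot=n_boot, seed=seed)
    return MRResult(
        exposure_id=inst.exposure_id,
        estimates=est,
        egger_intercept=egger_int,
        egger_intercept_p=egger_int_p,
        cochran_q=q,
        cochran_q_p=q_p,
        n_instruments=inst.n_instruments,
    )


def leave_one_out(inst: InstrumentSet) -> pd.DataFrame:
    """IVW estimate excluding each instrument in turn (influence diagnostic)."""
    rows = []
    for i in range(inst.n_instruments):
        sub = InstrumentSet(
            inst.exposure_id, inst.table.drop(inst.table.index[i]).reset_index(drop=True)
        )
        if sub.n_instruments >= 2:
            r = ivw(sub)
            rows.append(
                {"excluded": inst.table["SNP"].iloc[i], "estimate": r["estimate"],
                 "se": r["se"], "p": r["p"]}
            )
    return pd.DataFrame(rows, columns=["excluded", "estimate", "se", "p"])


def mr_significance(
    results: list[MRResult], n_tests: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Bonferroni-corrected dual criterion: an exposure is flagged causal only
    when both IVW and weighted-median p fall below alpha/n_tests; an Egger
    intercept p < 0.05 adds a pleiotropy caveat."""
    thresh = alpha / max(n_tests, 1)
    rows = []
    for r in results:
        p_ivw = r.estimates["ivw"]["p"] if r.estimates["ivw"] else np.nan
        p_wm = (
            r.estimates["weighted_median"]["p"] if r.estimates["weighted_median"] else np.nan
        )
        flagged = bool(np.isfinite(p_ivw) and np.isfinite(p_wm)
                       and p_ivw < thresh and p_wm < thresh)
        rows.append(
            {
                "exposure_id": r.exposure_id,
                "p_ivw": p_ivw,
                "p_weighted_median": p_wm,
                "threshold": thresh,
                "significant": flagged,
                "pleiotropy_caveat": bool(
                    np.isfinite(r.egger_intercept_p) and r.egger_intercept_p < 0.05
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["exposure_id", "p_ivw", "p_weighted_median", "threshold",
                 "significant", "pleiotropy_caveat"],
    ).set_index("exposure_id")
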