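"""End-to-end orchestration: simulate -> qc -> screen -> decompose ->
classify -> associate -> meta -> route(MR | mediation).

A :class:`RunConfig` collects every tunable threshold of the analysis
(missingness 0.25, winsorization +/-5 SD, screening p 1e-4, meta alpha 0.05,
top-k 30, MR MAF 0.01 / D' 0.2 / 1 Mb window, mediation PM > 0.10 and
p < 1e-8) plus the root seed. ``run_pipeline`` executes the requested stages
on a synthetic cohort pair and writes TSV/JSON outputs plus a JSON manifest
with the counts at every filter; re-running the same config reproduces all
outputs bitwise (bootstrap stages are seeded from the root seed).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import OmixvarError, SurvivalTable
from .decompose import (
    decompose_matrix,
    records_to_frame,
    score_features,
    summarize_domains,
)
from .mediation import mediate, mediation_screen, race_contrast
from .mr import harmonize, ld_prune, mr_significance, run_mr, select_instruments
from .multiplicity import correlation_matrix, meff_liji, significance_threshold
from .qc import run_qc
from .screen import choose_n_pcs, compute_omic_pcs, screen_covariates
from .survival import cox_fit, meta_random_effects, meta_table, select_t2d_features
from .synthetic import SurvivalTruth, TruthSpec, generate_cohorts, write_bundle

ALL_STAGES = (
    "simulate",
    "qc",
    "screen",
    "decompose",
    "classify",
    "associate",
    "meta",
    "mr",
    "mediation",
)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    # simulation
    n_samples: int = 800
    n_cohorts: int = 2
    n_metabolites: int = 24
    n_proteins: int = 12
    lod_quantile: float = 0.05
    # qc
    missingness_threshold: float = 0.25
    winsor_k_sd: float = 5.0
    # screening
    screen_p: float = 1e-4
    pc_cum_var: float = 0.70
    pc_max: int = 20
    # decomposition / classification
    top_k: int = 30
    # association / meta
    meta_alpha: float = 0.05
    cox_adjust: tuple = ("age", "sex", "bmi", "fasting_hours")
    # MR
    mr_p_threshold: float = 5e-8
    mr_maf_min: float = 0.01
    mr_window_bp: int = 1_000_000
    mr_dprime_max: float = 0.2
    mr_alpha: float = 0.05
    # mediation
    mediation_reps: int = 200
    mediation_pm_min: float = 0.10
    mediation_p_max: float = 1e-8
    mediation_group: str = "NH-Black"
    mediation_reference: str = "NH-White"

    def __post_init__(self) -> None:
        checks = [
            (0 < self.missingness_threshold <= 1, "missingness_threshold in (0,1]"),
            (self.winsor_k_sd > 0, "winsor_k_sd > 0"),
            (0 < self.screen_p <= 1, "screen_p in (0,1]"),
            (0 < self.meta_alpha < 1, "meta_alpha in (0,1)"),
            (self.top_k >= 1, "top_k >= 1"),
            (0 < self.mr_maf_min < 0.5, "mr_maf_min in (0,0.5)"),
            (0 <= self.mr_dprime_max <= 1, "mr_dprime_max in [0,1]"),
            (self.mr_window_bp > 0, "mr_window_bp > 0"),
            (0 <= self.mediation_pm_min < 1, "mediation_pm_min in [0,1)"),
            (0 < self.mediation_p_max <= 1, "mediation_p_max in (0,1]"),
            (self.mediation_reps >= 0, "mediation_reps >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise OmixvarError(f"config invalid: require {msg}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise OmixvarError(f"unknown stages {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["cox_adjust"] = list(d["cox_adjust"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("stages", "cox_adjust"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _truth_spec(cfg: RunConfig) -> TruthSpec:
    """Synthetic truth used for orchestrated runs: a genetically driven
    metabolite routed to MR and a lifestyle-driven one routed to mediation."""
    fractions = {
        "MET_0001": {
            "technical": 0.02,
            "biological": 0.05,
            "lifestyle": 0.02,
            "genetic_ancestry": 0.15,
            "race_ethnicity": 0.01,
            "socioeconomic": 0.01,
        },
        "MET_0002": {
            "technical": 0.02,
            "biological": 0.05,
            "lifestyle": 0.12,
            "genetic_ancestry": 0.005,
            "race_ethnicity": 0.06,
            "socioeconomic": 0.05,
        },
    }
    return TruthSpec(
        n_samples=cfg.n_samples,
        n_features_per_omic={"metabolite": cfg.n_metabolites, "protein": cfg.n_proteins},
        domain_variance_fractions=fractions,
        lod_quantile=cfg.lod_quantile,
        # baseline scaled to ~10% cumulative incidence so the mediation
        # stage operates in its rare-outcome regime
        survival_model=SurvivalTruth(
            baseline_scale=0.0015,
            coefficients={"MET_0001": 0.35, "MET_0002": 0.30},
        ),
        mr_exposures=("MET_0001",),
        seed=cfg.seed,
    )


def _write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {
        "omixvar_version": __version__,
        "seed": cfg.seed,
        "config": {**dataclasses.asdict(cfg), "stages": list(cfg.stages),
                   "cox_adjust": list(cfg.cox_adjust)},
        "stages_completed": [],
        "counts": {},
    }
    stages = set(cfg.stages)

    try:
        spec = _truth_spec(cfg)
        cohorts = generate_cohorts(spec, cfg.n_cohorts)
        if "simulate" in stages:
            for name, bundle in cohorts.items():
                write_bundle(bundle, os.path.join(cfg.out_dir, name))
            manifest["counts"]["simulate"] = {
                name: {
                    "n_samples": len(b.covariates),
                    **{f"n_{o}": fm.n_features for o, fm in b.features.items()},
                }
                for name, b in cohorts.items()
            }
            manifest["stages_completed"].append("simulate")
        if stages <= {"simulate"}:
            _write_json(manifest, os.path.join(cfg.out_dir, "manifest.json"))
            return manifest

        dm = cohorts["cohort1"].domain_map
        qc_mats: dict[str, dict] = {}
        qc_counts: dict = {}
        for name, bundle in cohorts.items():
            qc_mats[name] = {}
            qc_counts[name] = {}
            for omic, fm in bundle.features.items():
                clean, report = run_qc(fm, cfg.missingness_threshold, cfg.winsor_k_sd)
                qc_mats[name][omic] = clean
                qc_counts[name][omic] = {
                    "features_in": fm.n_features,
                    "features_out": clean.n_features,
                    "features_dropped": fm.n_features - clean.n_features,
                    "samples_in": fm.n_samples,
                    "samples_out": clean.n_samples,
                    "winsorized_cells": report.winsorized_cell_count,
                }
                if "qc" in stages:
                    _write_tsv(
                        clean.values, os.path.join(cfg.out_dir, f"{name}_{omic}_qc.tsv")
                    )
                    _write_json(
                        report.to_dict(),
                        os.path.join(cfg.out_dir, f"{name}_{omic}_qc_report.json"),
                    )
        manifest["counts"]["qc"] = qc_counts
        if "qc" in stages:
            manifest["stages_completed"].append("qc")

        # multiplicity + screening on the discovery cohort
        disc = "cohort1"
        if "screen" in stages:
            screen_out = {}
            for omic, clean in qc_mats[disc].items():
                # the QC'd matrix is aligned to surviving samples only
                cov = cohorts[disc].covariates.loc[clean.values.index]
                m_eff = meff_liji(correlation_matrix(clean.values))
                k = choose_n_pcs(clean, cfg.pc_cum_var, cfg.pc_max)
                pcs = compute_omic_pcs(clean, k)
                tab = screen_covariates(pcs, cov, dm=dm, p_threshold=cfg.screen_p)
                screen_out[omic] = {
                    "m_eff": m_eff,
                    "threshold_0.05": significance_threshold(0.05, m_eff),
                    "n_pcs": k,
                    "retained": list(tab.index[tab["retained"]]),
                }
                _write_tsv(tab, os.path.join(cfg.out_dir, f"{disc}_{omic}_screen.tsv"))
            _write_json(screen_out, os.path.join(cfg.out_dir, "screen_summary.json"))
            manifest["counts"]["screen"] = {
                o: {"m_eff": v["m_eff"], "n_retained": len(v["retained"])}
                for o, v in screen_out.items()
            }
            manifest["stages_completed"].append("screen")

        labels: dict[str, str] = {}
        if {"decompose", "classify"} & stages:
            for omic, clean in qc_mats[disc].items():
                cov = cohorts[disc].covariates.loc[clean.values.index]
                records = decompose_matrix(clean, cov, dm)
                _write_tsv(
                    records_to_frame(records),
                    os.path.join(cfg.out_dir, f"{disc}_{omic}_decomposition.tsv"),
                )
                summary = summarize_domains(records)
                _write_tsv(summary, os.path.join(cfg.out_dir, f"{disc}_{omic}_domains.tsv"))
                if "classify" in stages:
                    scores = score_features(records, top_k=cfg.top_k)
                    labels.update({s.feature_id: s.label for s in scores})
                    _write_tsv(
                        pd.DataFrame([dataclasses.asdict(s) for s in scores]).set_index(
                            "feature_id"
                        ),
                        os.path.join(cfg.out_dir, f"{disc}_{omic}_scores.tsv"),
                    )
            manifest["counts"]["decompose"] = {
                o: qc_mats[disc][o].n_features for o in qc_mats[disc]
            }
            manifest["stages_completed"].append("decompose")
            if "classify" in stages:
                manifest["counts"]["classify"] = {
                    lab: sum(1 for v in labels.values() if v == lab)
                    for lab in set(labels.values())
                }
                manifest["stages_completed"].append("classify")

        metas = []
        if {"associate", "meta"} & stages:
            per_cohort: dict[str, list] = {}
            feature_ids = qc_mats[disc]["metabolite"].feature_ids
            for name, bundle in cohorts.items():
                clean = qc_mats[name]["metabolite"]
                cov = bundle.covariates.loc[clean.values.index]
                outcome = SurvivalTable(bundle.outcome.data.loc[clean.values.index])
                ests = []
                for fid in clean.feature_ids:
                    ests.append(
                        cox_fit(
                            clean.values[fid], outcome, cov,
                            adjust=list(cfg.cox_adjust), dm=dm, cohort=name,
                        )
                    )
                per_cohort[name] = ests
                _write_tsv(
                    pd.DataFrame([dataclasses.asdict(e) for e in ests]).set_index(
                        "feature_id"
                    ),
                    os.path.join(cfg.out_dir, f"{name}_cox.tsv"),
                )
            manifest["counts"]["associate"] = {
                name: sum(e.converged for e in ests) for name, ests in per_cohort.items()
            }
            manifest["stages_completed"].append("associate")
            if "meta" in stages:
                by_feature: dict[str, list] = {}
                for ests in per_cohort.values():
                    for e in ests:
                        if e.converged:
                            by_feature.setdefault(e.feature_id, []).append(e)
                metas = [
                    meta_random_effects(v) for v in by_feature.values() if len(v) >= 2
                ]
                _write_tsv(meta_table(metas), os.path.join(cfg.out_dir, "meta.tsv"))
                selected = select_t2d_features(metas, cfg.meta_alpha, labels)
                _write_tsv(selected, os.path.join(cfg.out_dir, "t2d_selected.tsv"))
                manifest["counts"]["meta"] = {
                    "n_pooled": len(metas),
                    "n_selected": int(len(selected)),
                }
                manifest["stages_completed"].append("meta")

        if "mr" in stages and metas:
            selected = select_t2d_features(metas, cfg.meta_alpha, labels)
            genetic = [
                f for f in selected.index
                if selected.loc[f, "label"] == "genetic_ancestry_influenced"
                and f in cohorts[disc].mr_data
            ]
            results = []
            for f in genetic:
                tabs = cohorts[disc].mr_data[f]
                cand = select_instruments(
                    tabs["exposure"], cfg.mr_p_threshold, cfg.mr_maf_min, cfg.mr_window_bp
                )
                pruned = ld_prune(cand, tabs["ld"], cfg.mr_dprime_max)
                inst = harmonize(pruned, tabs["outcome"], exposure_id=f)
                results.append(run_mr(inst, seed=cfg.seed))
            if results:
                sig = mr_significance(results, n_tests=len(results), alpha=cfg.mr_alpha)
                _write_tsv(sig, os.path.join(cfg.out_dir, "mr_significance.tsv"))
                _write_json(
                    {
                        r.exposure_id: {
                            "estimates": r.estimates,
                            "egger_intercept": r.egger_intercept,
                            "egger_intercept_p": r.egger_intercept_p,
                            "cochran_q": r.cochran_q,
                            "cochran_q_p": r.cochran_q_p,
                            "n_instruments": r.n_instruments,
                        }
                        for r in results
                    },
                    os.path.join(cfg.out_dir, "mr_results.json"),
                )
            manifest["counts"]["mr"] = {"n_exposures": len(results)}
            manifest["stages_completed"].append("mr")

        if "mediation" in stages and metas:
            selected = select_t2d_features(metas, cfg.meta_alpha, labels)
            env = [
                f for f in selected.index
                if selected.loc[f, "label"] == "environmentally_influenced"
            ]
            bundle = cohorts[disc]  # mediation is single-cohort by design
            clean = qc_mats[disc]["metabolite"]
            cov = bundle.covariates.loc[clean.values.index]
            outcome = SurvivalTable(bundle.outcome.data.loc[clean.values.index])
            exposure = race_contrast(
                cov, "race", cfg.mediation_group, cfg.mediation_reference
            )
            adjust = [c for c in dm.columns if dm.mapping[c] not in
                      ("race_ethnicity", "genetic_ancestry")]
            estimates = []
            for f in env:
                if f not in clean.values.columns:
                    continue
                estimates.append(
                    mediate(
                        exposure, clean.values[f], outcome, cov, adjust, dm,
                        contrast=(cfg.mediation_group, cfg.mediation_reference),
                        reps=cfg.mediation_reps, seed=cfg.seed,
                    )
                )
            if estimates:
                _write_tsv(
                    pd.DataFrame(
                        [
                            {
                                "mediator_id": e.mediator_id,
                                "nde": e.nde,
                                "nie": e.nie,
                                "total": e.total,
                                "proportion_mediated": e.proportion_mediated,
                                "p_nie": e.p_nie,
                            }
                            for e in estimates
                        ]
                    ).set_index("mediator_id"),
                    os.path.join(cfg.out_dir, "mediation.tsv"),
                )
                sig = mediation_screen(
                    estimates, cfg.mediation_pm_min, cfg.mediation_p_max
                )
                _write_tsv(sig, os.path.join(cfg.out_dir, "mediation_significant.tsv"))
            manifest["counts"]["mediation"] = {"n_mediators_tested": len(estimates)}
            manifest["stages_completed"].append("mediation")
    except Exception as exc:  # record partial completion before re-raising
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_json(manifest, os.path.join(cfg.out_dir, "manifest.json"))
        raise

    _write_json(manifest, os.path.join(cfg.out_dir, "manifest.json"))
    return manifest
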