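"""End-to-end orchestration: simulate/score -> QC -> cut-off -> survival.

``run_pipeline`` executes the full flow behind the CLI: obtain per-core
scores (from images or the statistical score emulator, or from CSV
inputs), apply the QC cascade and aggregate to patients, derive the
prognostic cut-off from quartiles, run the per-stratum partially and
fully adjusted (multiply imputed) time-varying Cox models, and pool
study-specific estimates in a fixed-effect meta-analysis.  Every stage
logs record counts so the exclusion cascade can be reconstructed from
the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, missing_data, qc_aggregation, survival_models, synthetic_data
from .threshold_agreement import dichotomise, extrapolate_cutoff, full_agreement, quartile_cuts

logger = logging.getLogger("ki67prog.pipeline")

#: analysis strata mirroring the subtype layout of a consortium analysis
DEFAULT_STRATA = (
    "all",
    "er_positive",
    "er_negative",
    "er_positive_node_positive",
    "er_positive_node_negative",
    "hrp_her2_negative",
    "hrp_her2_positive",
    "triple_negative",
    "her2_enriched",
)

FULL_ADJUST = ["ki67_high", "age", "study_id", "grade", "size_gt2cm",
               "node_positive", "er_positive", "pr_positive", "her2_positive",
               "endocrine", "chemo"]
PARTIAL_ADJUST = ["ki67_high", "age", "study_id"]


@dataclass
class RunConfig:
    """One pipeline run: either synthetic generation or CSV inputs."""

    out_dir: str = "ki67prog_run"
    seed: int = 0
    # synthetic mode
    cohort: synthetic_data.SimCohortConfig | None = None
    render_images: bool = False          # score rendered images instead of emulating counts
    # real-input mode
    core_scores_csv: str | None = None
    clinical_csv: str | None = None
    # analysis settings
    strata: tuple[str, ...] = DEFAULT_STRATA
    cutoff_mode: str = "derive"          # 'derive' (Q3) | 'fixed'
    fixed_cutoff: float = 12.0
    mi_m: int = 20
    mi_enabled: bool = True
    min_events_per_stratum: int = 30
    horizon: float = 10.0

    def __post_init__(self) -> None:
        synthetic = self.cohort is not None
        real = self.core_scores_csv is not None or self.clinical_csv is not None
        if synthetic == real:
            raise ValueError("provide exactly one of a synthetic cohort config or CSV inputs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "cohort" in d and d["cohort"] is not None:
            cohort = d["cohort"]
            for key in ("patients_per_study", "cores_per_patient_range", "core_size_mm_range",
                        "ki67_gamma_er_pos", "ki67_gamma_er_neg", "ki67_grade_scale",
                        "baseline_hazard"):
                if key in cohort and isinstance(cohort[key], list):
                    cohort[key] = tuple(cohort[key])
            d["cohort"] = synthetic_data.SimCohortConfig(**cohort)
        if "strata" in d:
            d["strata"] = tuple(d["strata"])
        return cls(**d)


def _stratum_mask(df: pd.DataFrame, name: str) -> pd.Series:
    er = df["er_positive"] == 1
    pr = df.get("pr_positive", pd.Series(np.nan, index=df.index)) == 1
    her2 = df.get("her2_positive", pd.Series(np.nan, index=df.index)) == 1
    node = df.get("node_positive", pd.Series(np.nan, index=df.index)) == 1
    hrp = er | pr
    masks = {
        "all": pd.Series(True, index=df.index),
        "er_positive": er,
        "er_negative": df["er_positive"] == 0,
        "er_positive_node_positive": er & node,
        "er_positive_node_negative": er & (df.get("node_positive") == 0),
        "hrp_her2_negative": hrp & (df.get("her2_positive") == 0),
        "hrp_her2_positive": hrp & her2,
        "triple_negative": (df["er_positive"] == 0) & (df.get("pr_positive") == 0)
        & (df.get("her2_positive") == 0),
        "her2_enriched": (df["er_positive"] == 0) & (df.get("pr_positive") == 0) & her2,
    }
    if name not in masks:
        raise ValueError(f"unknown stratum {name!r}")
    return masks[name].fillna(False)


def _adjustment_for(stratum: str) -> list[str]:
    """Fully adjusted covariate set, minus covariates fixed by the stratum."""
    fixed = {
        "er_positive": ["er_positive"],
        "er_negative": ["er_positive"],
        "er_positive_node_positive": ["er_positive", "node_positive"],
        "er_positive_node_negative": ["er_positive", "node_positive"],
        "hrp_her2_negative": ["her2_positive"],
        "hrp_her2_positive": ["her2_positive"],
        "triple_negative": ["er_positive", "pr_positive", "her2_positive"],
        "her2_enriched": ["er_positive", "pr_positive", "her2_positive"],
    }.get(stratum, [])
    return [c for c in FULL_ADJUST if c not in fixed]


def _fit_stratum(patients, stratum, config, rng):
    sub = patients[_stratum_mask(patients, stratum)].copy()
    n_events = int(sub["event"].sum())
    if n_events < config.min_events_per_stratum or sub["ki67_high"].nunique() < 2:
        logger.info("stratum %s skipped (%d events)", stratum, n_events)
        return None
    row = {"stratum": stratum, "n": len(sub), "n_events": n_events,
           "n_high": int(sub["ki67_high"].sum())}
    try:
        part = survival_models.cox_tvc_fit(
            sub, PARTIAL_ADJUST, tvc_vars="ki67_high", horizon=config.horizon
        )
        row.update(_tvc_row(part, "partial"))
    except survival_models.CoxNumericalError as err:
        logger.warning("stratum %s partial model failed: %s", stratum, err)
        return row
    covs = _adjustment_for(stratum)
    covs = [c for c in covs if c in sub.columns and sub[c].dropna().nunique() > 1]
    try:
        if config.mi_enabled and sub[covs].isna().any().any():
            keep = ["patient_id", "study_id", "entry_time", "exit_time", "event",
                    "ki67_pct", "ki67_high"] + [c for c in covs if c not in
                                                ("ki67_high", "study_id")]
            imp = missing_data.impute(
                sub[keep], m=config.mi_m,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            pooled, _ = missing_data.fit_pooled(
                imp, covs, tvc_vars="ki67_high", horizon=config.horizon
            )
            row.update(_pooled_row(pooled, "full"))
        else:
            fullfit = survival_models.cox_tvc_fit(
                sub, covs, tvc_vars="ki67_high", horizon=config.horizon
            )
            row.update(_tvc_row(fullfit, "full"))
    except (survival_models.CoxNumericalError, ValueError) as err:
        logger.warning("stratum %s full model failed: %s", stratum, err)
    return row


def _tvc_row(fit, prefix):
    s = fit.summary().loc["ki67_high"]
    lo, hi = fit.T_ci("ki67_high")
    return {
        f"{prefix}_hr": s["hr"], f"{prefix}_hr_lo": s["hr_lo"], f"{prefix}_hr_hi": s["hr_hi"],
        f"{prefix}_p": s["p"], f"{prefix}_T": fit.T("ki67_high"),
        f"{prefix}_T_lo": lo, f"{prefix}_T_hi": hi, f"{prefix}_T_p": fit.T_p("ki67_high"),
        f"{prefix}_aic": fit.aic, f"{prefix}_bic": fit.bic,
    }


def _pooled_row(pooled, prefix):
    s = pooled.summary()
    k = s.loc["ki67_high"]
    t = s.loc["ki67_high:t"]
    return {
        f"{prefix}_hr": k["hr"], f"{prefix}_hr_lo": k["hr_lo"], f"{prefix}_hr_hi": k["hr_hi"],
        f"{prefix}_p": k["p"], f"{prefix}_T": t["hr"],
        f"{prefix}_T_lo": t["hr_lo"], f"{prefix}_T_hi": t["hr_hi"], f"{prefix}_T_p": t["p"],
        f"{prefix}_aic": float("nan"), f"{prefix}_bic": float("nan"),
    }


def _score_cores_synthetic(config: RunConfig, manifest: pd.DataFrame) -> pd.DataFrame:
    if not config.render_images:
        return synthetic_data.emulate_core_scores(manifest, seed=config.seed + 17)
    from . import image_scoring

    rows = []
    for i, r in manifest.iterrows():
        truth = synthetic_data.random_core_truth(
            500, frac_positive=r["true_core_ki67_pct"] / 100.0,
            seed=config.seed * 100003 + i,
        )
        img, _ = synthetic_data.generate_core_image(
            truth, seed=config.seed * 100003 + i,
            core_id=r["core_id"], patient_id=r["patient_id"], study_id=r["study_id"],
        )
        score = image_scoring.score_core(img)
        rows.append({"core_id": r["core_id"], "patient_id": r["patient_id"],
                     "study_id": r["study_id"], "tma_id": r["tma_id"],
                     "n_total": score.n_total_malignant, "n_positive": score.n_positive,
                     "ki67_pct": score.ki67_pct})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report bundle and writes CSVs.

    Reruns with the same config and seed produce identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    log_lines = [f"ki67prog {__version__} seed={config.seed}"]

    # -- stage 1: per-core scores + clinical table ------------------------
    if config.cohort is not None:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        cohort = synthetic_data.simulate_cohort(cohort_cfg)
        manifest = synthetic_data.simulate_core_manifest(cohort, cohort_cfg)
        core_scores = _score_cores_synthetic(config, manifest)
        clinical = cohort.drop(columns=["n_cores"])
        log_lines.append(f"simulated cohort: {len(cohort)} patients, {len(manifest)} cores")
    else:
        core_scores = pd.read_csv(config.core_scores_csv)
        clinical = pd.read_csv(config.clinical_csv)
        log_lines.append(f"loaded {len(core_scores)} cores, {len(clinical)} patients")
    core_scores.to_csv(out / "core_scores.csv", index=False)

    # -- stage 2: QC + aggregation ---------------------------------------
    patients, qc = qc_aggregation.build_patient_table(core_scores, clinical)
    log_lines.append(
        f"QC cascade: collected={qc.n_collected_patients} failed_qc={qc.n_failed_qc} "
        f"missing_followup={qc.n_missing_followup} analysed={qc.n_analysed}"
    )
    qc.core_table.to_csv(out / "core_qc.csv", index=False)
    (out / "qc_report.txt").write_text(qc.summary())
    conc = qc_aggregation.core_concordance(
        core_scores.merge(qc.core_table[["core_id", "qc_pass"]], on="core_id"),
        cutoff=config.fixed_cutoff,
    )
    log_lines.append(
        f"multi-core concordance: {conc.proportion_concordant:.3f} over {conc.n_multicore} patients"
    )

    # -- stage 3: cut-off ------------------------------------------------
    if config.cutoff_mode == "derive":
        q1, q2, q3 = quartile_cuts(patients["ki67_pct"])
        cut = q3
    else:
        q1 = q2 = q3 = float("nan")
        cut = config.fixed_cutoff
    patients["ki67_high"] = dichotomise(patients["ki67_pct"], cut)
    log_lines.append(f"cut-off: {cut:.2f} % ({config.cutoff_mode}); "
                     f"{int(patients['ki67_high'].sum())} high of {len(patients)}")
    cutoff_info = {"q1": q1, "q2": q2, "q3": q3, "automated_cut": float(cut)}
    if "visual_ki67_pct" in patients.columns and patients["visual_ki67_pct"].notna().sum() >= 10:
        cm = extrapolate_cutoff(
            patients["ki67_pct"], patients["visual_ki67_pct"], automated_cut=cut
        )
        ag = full_agreement(
            patients["ki67_pct"], patients["visual_ki67_pct"],
            automated_cut=cut, visual_cut=cm.rounded_visual_cut,
        )
        cutoff_info.update(
            visual_slope=cm.slope, visual_intercept=cm.intercept, pearson_r=cm.pearson_r,
            extrapolated_visual_cut=cm.extrapolated_visual_cut,
            rounded_visual_cut=cm.rounded_visual_cut,
            agreement=ag.observed_agreement, kappa=ag.kappa,
            sensitivity=ag.sensitivity, specificity=ag.specificity, auc=ag.auc,
        )
    with open(out / "cutoff.yaml", "w") as fh:
        yaml.safe_dump(cutoff_info, fh)
    patients.to_csv(out / "patients.csv", index=False)

    # -- stage 4: KM + log-rank ------------------------------------------
    km_rows = []
    quart_lab = pd.cut(
        patients["ki67_pct"], [-np.inf, q1, q2, q3, np.inf], labels=["Q1", "Q2", "Q3", "Q4"]
    ) if config.cutoff_mode == "derive" else None
    groupings = {"ki67_high": patients["ki67_high"].map({0: "low", 1: "high"})}
    if quart_lab is not None:
        groupings["quartile"] = quart_lab
    logrank_results = {}
    for name, labels in groupings.items():
        curves = survival_models.km_estimate(patients, labels, horizon=config.horizon)
        stat, dof, p = survival_models.logrank(patients, labels, horizon=config.horizon)
        logrank_results[name] = {"chi2": stat, "df": dof, "p": p}
        log_lines.append(f"log-rank [{name}]: chi2={stat:.2f} df={dof} P={p:.3g}")
        for g, c in curves.items():
            for t, s, nr, v in zip(c.event_times, c.survival, c.at_risk, c.greenwood_var):
                km_rows.append({"grouping": name, "group": g, "time": t, "survival": s,
                                "at_risk": nr, "greenwood_var": v})
    pd.DataFrame(km_rows).to_csv(out / "km_curves.csv", index=False)

    # -- stage 5: per-stratum models -------------------------------------
    model_rows = []
    for stratum in config.strata:
        row = _fit_stratum(patients, stratum, config, rng)
        if row is not None:
            model_rows.append(row)
    models = pd.DataFrame(model_rows)
    models.to_csv(out / "models.csv", index=False)

    # -- stage 6: meta-analysis across studies ---------------------------
    meta_tables = {}
    for stratum in ("er_positive", "er_negative"):
        sub = patients[_stratum_mask(patients, stratum)]
        per_study = {}
        for sid, d in sub.groupby("study_id"):
            if d["event"].sum() < 10 or d["ki67_high"].nunique() < 2:
                continue
            try:
                f = survival_models.cox_fit(d, ["ki67_high", "age"], horizon=config.horizon)
            except survival_models.CoxNumericalError:
                continue
            se = float(f.se["ki67_high"])
            if se > 10:                      # essentially no information
                continue
            per_study[sid] = (float(f.coefficients["ki67_high"]), se)
        if len(per_study) >= 2:
            meta = survival_models.fixed_effect_meta(per_study)
            meta.forest_table().to_csv(out / f"forest_{stratum}.csv", index=False)
            meta_tables[stratum] = meta
            log_lines.append(
                f"meta [{stratum}]: pooled HR={meta.pooled_hr:.2f} "
                f"I2={meta.i2:.1%} P_het={meta.p_heterogeneity:.2f}"
            )

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {"qc": {"collected": qc.n_collected_patients, "failed_qc": qc.n_failed_qc,
                    "missing_followup": qc.n_missing_followup, "analysed": qc.n_analysed},
             "cutoff": cutoff_info, "logrank": logrank_results},
            fh, indent=2, default=float,
        )
    return {
        "patients": patients,
        "qc": qc,
        "concordance": conc,
        "cutoff": cutoff_info,
        "models": models,
        "meta": meta_tables,
        "logrank": logrank_results,
        "log": log_lines,
    }
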