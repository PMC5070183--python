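"""Core- and patient-level quality control, aggregation and descriptives.

The exclusion cascade mirrors the design of a centrally scored
multi-study TMA analysis: cores failing predefined quality checks
(total malignant nuclei must exceed 50 and stay below 15,000, and a
saturated score of exactly 100 % is rejected as artefactual) are
dropped; a patient's KI67 is the unweighted mean over the remaining
valid cores; patients with no valid core, or with missing follow-up
time / vital status, are excluded from survival analysis -- each under
exactly one primary reason, QC first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._types import CoreScore

__all__ = [
    "QCReport",
    "PatientRecord",
    "qc_core",
    "aggregate_patient",
    "build_patient_table",
    "core_concordance",
    "describe_by_category",
]

#: storage precision (decimals) at which a score counts as exactly 100 %
SCORE_DECIMALS = 4

QC_MIN_NUCLEI = 50        # pass requires strictly more than this
QC_MAX_NUCLEI = 15_000    # pass requires strictly fewer than this


def qc_core(score: CoreScore) -> tuple[bool, str]:
    """Core-level QC: ``(passed, reason)``; reason is '' on pass.

    Pass iff total malignant nuclei count > 50 and < 15,000 and the
    KI67 score is not saturated at 100 %.
    """
    n = score.n_total_malignant
    if n <= QC_MIN_NUCLEI:
        return False, "low_nuclei_count"
    if n >= QC_MAX_NUCLEI:
        return False, "high_nuclei_count"
    if round(score.ki67_pct, SCORE_DECIMALS) >= 100.0:
        return False, "saturated_score"
    return True, ""


@dataclass
class PatientRecord:
    """One patient's aggregated KI67 plus survival and covariate data."""

    patient_id: str
    study_id: str
    ki67_pct: float
    n_valid_cores: int
    entry_time: float = 0.0
    exit_time: float = float("nan")
    event: int | float = float("nan")
    covariates: dict = field(default_factory=dict)
    exclusion_reason: str | None = None     # None | 'qc' | 'follow_up'

    def __post_init__(self) -> None:
        if np.isfinite(self.exit_time) and not self.exit_time >= self.entry_time >= 0:
            raise ValueError("need exit_time >= entry_time >= 0")


@dataclass
class QCReport:
    """Exclusion ledger for one aggregation run.

    Conservation (``n_analysed = n_collected - n_failed_qc -
    n_missing_followup``) is asserted on construction.
    """

    n_collected_patients: int
    n_failed_qc: int
    n_missing_followup: int
    n_analysed: int
    core_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.n_analysed != (
            self.n_collected_patients - self.n_failed_qc - self.n_missing_followup
        ):
            raise ValueError("exclusion ledger does not conserve patients")

    def summary(self) -> str:
        return (
            f"collected patients : {self.n_collected_patients}\n"
            f"failed QC          : {self.n_failed_qc}\n"
            f"missing follow-up  : {self.n_missing_followup}\n"
            f"analysed           : {self.n_analysed}\n"
        )


def _as_float(x, default=float("nan")) -> float:
    try:
        return float(x)
    except (TypeError, ValueError):
        return default


def aggregate_patient(scores: list[CoreScore], clinical_row) -> PatientRecord:
    """Aggregate one patient's cores with their clinical row.

    KI67 is the unweighted mean over QC-passing cores.  A patient with
    no passing core is excluded under 'qc'; one with missing follow-up
    time or vital status under 'follow_up' (QC is the first gate, so a
    patient failing both counts under 'qc').
    """
    if len(scores) == 0:
        raise ValueError("aggregate_patient requires at least one core")
    ids = [s.core_id for s in scores]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate core ids for patient {scores[0].patient_id}")
    clinical = dict(clinical_row)
    valid = [s for s in scores if qc_core(s)[0]]
    exit_time = _as_float(clinical.get("exit_time", float("nan")))
    event = _as_float(clinical.get("event", float("nan")))
    fu_missing = not (np.isfinite(exit_time) and np.isfinite(event))
    reason = None
    if not valid:
        reason = "qc"
    elif fu_missing:
        reason = "follow_up"
    ki67 = float(np.mean([s.ki67_pct for s in valid])) if valid else float("nan")
    known = {"patient_id", "study_id", "entry_time", "exit_time", "event"}
    return PatientRecord(
        patient_id=str(clinical.get("patient_id", scores[0].patient_id)),
        study_id=str(clinical.get("study_id", scores[0].study_id)),
        ki67_pct=ki67,
        n_valid_cores=len(valid),
        entry_time=_as_float(clinical.get("entry_time", 0.0), 0.0),
        exit_time=exit_time,
        event=event,
        covariates={k: v for k, v in clinical.items() if k not in known},
        exclusion_reason=reason,
    )


def build_patient_table(
    core_scores: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, QCReport]:
    """Vectorised aggregation of a per-core score table to patient level.

    ``core_scores`` needs columns core_id, patient_id, n_total,
    n_positive (and optionally ki67_pct); ``clinical`` one row per
    patient with exit_time and event among its columns.  Returns the
    analysed patient table (clinical columns plus ki67_pct,
    n_valid_cores) and the :class:`QCReport` whose ledger conserves the
    collected patients.
    """
    cs = core_scores.copy()
    if cs["core_id"].duplicated().any():
        dup = cs.loc[cs["core_id"].duplicated(), "core_id"].iloc[0]
        raise ValueError(f"duplicate core id {dup!r} in score table")
    if "ki67_pct" not in cs.columns:
        with np.errstate(invalid="ignore", divide="ignore"):
            cs["ki67_pct"] = 100.0 * cs["n_positive"] / cs["n_total"]
    rounded = cs["ki67_pct"].round(SCORE_DECIMALS)
    cs["qc_pass"] = (
        (cs["n_total"] > QC_MIN_NUCLEI)
        & (cs["n_total"] < QC_MAX_NUCLEI)
        & (rounded < 100.0)
    )
    cs["qc_reason"] = np.select(
        [cs["n_total"] <= QC_MIN_NUCLEI, cs["n_total"] >= QC_MAX_NUCLEI, rounded >= 100.0],
        ["low_nuclei_count", "high_nuclei_count", "saturated_score"],
        default="",
    )

    per_pat = (
        cs[cs["qc_pass"]]
        .groupby("patient_id")["ki67_pct"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "ki67_pct", "size": "n_valid_cores"})
    )
    patients = clinical.copy()
    n_collected = len(patients)
    patients = patients.merge(per_pat, left_on="patient_id", right_index=True, how="left")
    patients["n_valid_cores"] = patients["n_valid_cores"].fillna(0).astype(int)

    qc_fail = patients["n_valid_cores"] == 0
    exit_ok = np.isfinite(pd.to_numeric(patients.get("exit_time", np.nan), errors="coerce"))
    event_ok = np.isfinite(pd.to_numeric(patients.get("event", np.nan), errors="coerce"))
    fu_missing = ~qc_fail & ~(exit_ok & event_ok)
    analysed = patients[~qc_fail & ~fu_missing].reset_index(drop=True)
    report = QCReport(
        n_collected_patients=n_collected,
        n_failed_qc=int(qc_fail.sum()),
        n_missing_followup=int(fu_missing.sum()),
        n_analysed=len(analysed),
        core_table=cs[["core_id", "patient_id", "qc_pass", "qc_reason"]],
    )
    return analysed, report


@dataclass
class ConcordanceResult:
    proportion_concordant: float    # among multi-core patients; NaN if none
    n_multicore: int
    n_concordant: int
    multicore_share: float          # multi-core patients / all patients


def core_concordance(core_scores: pd.DataFrame, cutoff: float = 12.0) -> ConcordanceResult:
    """Dichotomous agreement of a patient's cores at the cut-off.

    Over patients with >= 2 QC-valid cores, the fraction whose cores all
    fall on the same side of ``cutoff`` (high = strictly above).
    Returns an explicit empty result when no patient has multiple cores.
    """
    cs = core_scores
    if "qc_pass" in cs.columns:
        cs = cs[cs["qc_pass"]]
    high = cs["ki67_pct"] > cutoff
    g = high.groupby(cs["patient_id"])
    sizes = g.size()
    multi = sizes[sizes >= 2].index
    n_pat = sizes.size
    if len(multi) == 0:
        return ConcordanceResult(float("nan"), 0, 0, 0.0)
    agree = g.agg(lambda s: bool(s.all() or (~s).all()))
    n_conc = int(agree.loc[multi].sum())
    return ConcordanceResult(
        proportion_concordant=n_conc / len(multi),
        n_multicore=len(multi),
        n_concordant=n_conc,
        multicore_share=len(multi) / n_pat if n_pat else float("nan"),
    )


@dataclass
class CategoryDescription:
    variable: str
    categories: list
    kruskal_h: float
    kruskal_p: float
    chi2: float
    chi2_df: int
    chi2_p: float
    table: pd.DataFrame             # category x (low, high) counts


def describe_by_category(
    patients: pd.DataFrame,
    variable: str,
    ki67_col: str = "ki67_pct",
    cutoff: float = 12.0,
) -> CategoryDescription:
    """Distribution of KI67 across the categories of one variable.

    Continuous scores are compared with the tie-corrected Kruskal-Wallis
    test; dichotomised (high = strictly above ``cutoff``) scores with a
    Pearson chi-squared test on the category x high/low table,
    df = (categories - 1).
    """
    sub = patients[[variable, ki67_col]].dropna()
    groups = {k: v[ki67_col].to_numpy() for k, v in sub.groupby(variable, observed=True)}
    groups = {k: v for k, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise ValueError(f"{variable}: need >= 2 non-empty categories")
    h, p_kw = stats.kruskal(*groups.values())
    high = sub[ki67_col] > cutoff
    table = pd.crosstab(sub[variable], high).rename(columns={False: "low", True: "high"})
    for col in ("low", "high"):
        if col not in table:
            table[col] = 0
    table = table[["low", "high"]]
    arr = table.to_numpy()
    if (arr.sum(axis=0) > 0).sum() < 2 or (arr.sum(axis=1) > 0).sum() < 2:
        chi2, p_chi, df = float("nan"), float("nan"), len(groups) - 1
    else:
        chi2, p_chi, df, _ = stats.chi2_contingency(arr, correction=False)
    return CategoryDescription(
        variable=variable,
        categories=list(groups),
        kruskal_h=float(h),
        kruskal_p=float(p_kw),
        chi2=float(chi2),
        chi2_df=int(df),
        chi2_p=float(p_chi),
        table=table,
    )
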