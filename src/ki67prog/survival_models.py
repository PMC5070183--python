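"""10-year breast-cancer-specific survival models.

Kaplan-Meier curves and log-rank tests with delayed entry, left-truncated
Cox models with Efron tie handling, an extension in which the KI67
hazard ratio varies as an exponential function of time
(``HR(t) = HR0 * T**t`` with ``T = exp(theta)``; ``T < 1`` means the
effect wanes with follow-up), AIC/BIC model comparison, subgroup
heterogeneity (Cochran Q) and fixed-effect inverse-variance
meta-analysis across study groups with the I-squared statistic.

Time origin is diagnosis; subjects enter the risk set at study entry
(accommodating prevalent cancers) and exit at
``min(death, last follow-up, horizon)`` with a 10-year administrative
horizon by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from ._cox import CoxNumericalError, newton_cox, partial_likelihood_at

__all__ = [
    "KMCurve",
    "CoxFit",
    "TvcFit",
    "MetaResult",
    "apply_horizon",
    "design_matrix",
    "km_estimate",
    "logrank",
    "cox_fit",
    "cox_tvc_fit",
    "model_ic",
    "subgroup_heterogeneity",
    "fixed_effect_meta",
    "CoxNumericalError",
]

HORIZON_YEARS = 10.0


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------

def apply_horizon(df: pd.DataFrame, horizon: float = HORIZON_YEARS) -> pd.DataFrame:
    """Administratively censor exit/event at the analysis horizon."""
    out = df.copy()
    over = out["exit_time"] > horizon
    out.loc[over, "exit_time"] = horizon
    out.loc[over, "event"] = 0
    return out


def design_matrix(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design matrix; object/categorical columns become k-1 dummies."""
    cols = []
    for name in covariates:
        col = df[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(col.astype(float).rename(name))
    X = pd.concat(cols, axis=1)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates in the analysis set: {const}")
    return X


# --------------------------------------------------------------------------
# Kaplan-Meier and log-rank with delayed entry
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate for one group, honouring delayed entry."""

    group: str
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_var: np.ndarray
    horizon: float = HORIZON_YEARS

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(
    records: pd.DataFrame,
    groups,
    horizon: float = HORIZON_YEARS,
) -> dict[str, KMCurve]:
    """Kaplan-Meier curves per group with delayed-entry risk sets.

    ``groups`` is a column name or an array of labels aligned with
    ``records``; curves are truncated at the horizon.
    """
    df = apply_horizon(records, horizon)
    labels = df[groups] if isinstance(groups, str) else pd.Series(np.asarray(groups), index=df.index)
    curves = {}
    for g, sub in df.groupby(labels):
        if len(sub) == 0 or not (sub["exit_time"] > sub["entry_time"]).any():
            raise ValueError(f"group {g!r} has no entered subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(
            sub["exit_time"], sub["event"], entry=sub["entry_time"], label=str(g)
        )
        ev = kmf.event_table
        ev = ev[ev["observed"] > 0]
        times = ev.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.loc[ev.index].to_numpy().ravel()
        # Greenwood variance: S(t)^2 * sum d/(n(n-d))
        d = ev["observed"].to_numpy(dtype=float)
        n_at = ev["at_risk"].to_numpy(dtype=float)
        gw = surv**2 * np.cumsum(d / (n_at * (n_at - d)))
        keep = times <= horizon
        curves[str(g)] = KMCurve(
            group=str(g),
            event_times=times[keep],
            survival=surv[keep],
            at_risk=n_at[keep],
            greenwood_var=gw[keep],
            horizon=horizon,
        )
    return curves


def logrank(
    records: pd.DataFrame, groups, horizon: float = HORIZON_YEARS
) -> tuple[float, int, float]:
    """Log-rank test over shared risk sets with delayed entry.

    Returns (chi-squared statistic, df, P).  The variance of the
    observed-minus-expected vector uses the multivariate hypergeometric
    form, which handles ties in the standard way.
    """
    df = apply_horizon(records, horizon)
    labels = df[groups] if isinstance(groups, str) else pd.Series(np.asarray(groups), index=df.index)
    codes, uniq = pd.factorize(labels, sort=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("log-rank needs at least 2 groups")
    entry = df["entry_time"].to_numpy(float)
    exit_ = df["exit_time"].to_numpy(float)
    event = df["event"].to_numpy(int)
    ev_times = np.unique(exit_[event == 1])
    obs = np.zeros(k)
    exp = np.zeros(k)
    var = np.zeros((k, k))
    for t in ev_times:
        at_risk = (entry < t) & (exit_ >= t)
        n_j = at_risk.sum()
        if n_j == 0:
            continue
        n_gj = np.bincount(codes[at_risk], minlength=k).astype(float)
        died = at_risk & (exit_ == t) & (event == 1)
        d_j = died.sum()
        d_gj = np.bincount(codes[died], minlength=k).astype(float)
        obs += d_gj
        exp += d_j * n_gj / n_j
        if n_j > 1:
            frac = n_gj / n_j
            mult = d_j * (n_j - d_j) / (n_j - 1)
            var += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (obs - exp)[:-1]
    v = var[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(v) @ diff)
    dof = k - 1
    return stat, dof, float(stats.chi2.sf(stat, dof))


# --------------------------------------------------------------------------
# Cox models
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Estimated log-hazard coefficients with their covariance."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    log_partial_likelihood: float
    n: int
    n_events: int
    n_iter: int = 0

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)), index=self.coefficients.index)

    def summary(self) -> pd.DataFrame:
        """HR with 95 % CI (``exp(coef +/- 1.96 se)``) and Wald P per covariate."""
        se = self.se
        z = self.coefficients / se
        with np.errstate(over="ignore"):    # diverged coefficients -> inf HR
            return pd.DataFrame(
                {
                    "coef": self.coefficients,
                    "se": se,
                    "hr": np.exp(self.coefficients),
                    "hr_lo": np.exp(self.coefficients - 1.96 * se),
                    "hr_hi": np.exp(self.coefficients + 1.96 * se),
                    "p": 2 * stats.norm.sf(np.abs(z)),
                }
            )

    @property
    def aic(self) -> float:
        return model_ic(self)[0]

    @property
    def bic(self) -> float:
        return model_ic(self)[1]


@dataclass
class TvcFit(CoxFit):
    """Cox fit with time-varying coefficients ``beta_x + theta * t``.

    ``T = exp(theta)`` multiplies the covariate's hazard ratio per year
    of follow-up: T < 1 means the effect wanes, T > 1 that it grows.
    ``hr_baseline`` is the hazard ratio at t = 0.
    """

    tvc_vars: list[str] = field(default_factory=list)

    def _tvc_name(self, var: str) -> str:
        return f"{var}:t"

    def hr_baseline(self, var: str) -> float:
        return float(np.exp(self.coefficients[var]))

    def T(self, var: str) -> float:
        return float(np.exp(self.coefficients[self._tvc_name(var)]))

    def T_ci(self, var: str) -> tuple[float, float]:
        name = self._tvc_name(var)
        c, s = self.coefficients[name], self.se[name]
        return float(np.exp(c - 1.96 * s)), float(np.exp(c + 1.96 * s))

    def T_p(self, var: str) -> float:
        name = self._tvc_name(var)
        z = self.coefficients[name] / self.se[name]
        return float(2 * stats.norm.sf(abs(z)))

    def hazard_ratio_at(self, var: str, t: float) -> float:
        return self.hr_baseline(var) * self.T(var) ** t


def _extract(records: pd.DataFrame, covariates: list[str], horizon: float):
    df = apply_horizon(records, horizon)
    needed = ["entry_time", "exit_time", "event"] + covariates
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    X = design_matrix(df, covariates)
    return df, X


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    strata: str | None = None,
    horizon: float = HORIZON_YEARS,
    tol: float = 1e-8,
) -> CoxFit:
    """Left-truncated Cox proportional-hazards fit with Efron ties.

    ``strata`` names a column giving separate baseline hazards; rows
    with missing values in any covariate are dropped (complete-case;
    use the multiple-imputation pipeline for the fully adjusted models).
    """
    df, X = _extract(records, covariates, horizon)
    strata_arr = df[strata].to_numpy() if strata else None
    beta, cov, ll, it = newton_cox(
        df["entry_time"].to_numpy(float),
        df["exit_time"].to_numpy(float),
        df["event"].to_numpy(int),
        X.to_numpy(float),
        strata=strata_arr,
        tol=tol,
    )
    names = list(X.columns)
    return CoxFit(
        coefficients=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        log_partial_likelihood=ll,
        n=len(df),
        n_events=int(df["event"].sum()),
        n_iter=it,
    )


def cox_tvc_fit(
    records: pd.DataFrame,
    covariates: list[str],
    tvc_vars: str | list[str] = "ki67_high",
    strata: str | None = None,
    horizon: float = HORIZON_YEARS,
    time_scale: str = "identity",
    tol: float = 1e-8,
) -> TvcFit:
    """Cox fit with time-varying coefficients for the named covariates.

    Each variable in ``tvc_vars`` contributes ``beta_x * x + theta * x * t``
    to the log hazard (t in years since diagnosis, evaluated at event
    times, equivalent to episode-splitting the data at every event
    time).  ``time_scale='log'`` uses ``log1p(t)`` instead of ``t``.
    Non-proportional covariates other than KI67 (ER, classically) are
    handled identically by listing them in ``tvc_vars``.
    """
    if isinstance(tvc_vars, str):
        tvc_vars = [tvc_vars]
    df, X = _extract(records, covariates, horizon)
    missing = [v for v in tvc_vars if v not in X.columns]
    if missing:
        raise ValueError(f"tvc variables {missing} not among design columns")
    tvc_cols = [X.columns.get_loc(v) for v in tvc_vars]
    transform = (lambda t: np.log1p(t)) if time_scale == "log" else (lambda t: t)
    strata_arr = df[strata].to_numpy() if strata else None
    beta, cov, ll, it = newton_cox(
        df["entry_time"].to_numpy(float),
        df["exit_time"].to_numpy(float),
        df["event"].to_numpy(int),
        X.to_numpy(float),
        strata=strata_arr,
        tvc_cols=tvc_cols,
        time_transform=transform,
        tol=tol,
    )
    names = list(X.columns) + [f"{v}:t" for v in tvc_vars]
    return TvcFit(
        coefficients=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        log_partial_likelihood=ll,
        n=len(df),
        n_events=int(df["event"].sum()),
        n_iter=it,
        tvc_vars=list(tvc_vars),
    )


def model_ic(fit: CoxFit, n_for_bic: int | None = None) -> tuple[float, float]:
    """(AIC, BIC) of a converged fit.

    ``aic = -2 logPL + 2k``; ``bic = -2 logPL + k ln(n)`` with n the
    number of *events* by default, the usual effective sample size for
    the Cox partial likelihood (pass ``n_for_bic`` to use subjects).
    """
    k = len(fit.coefficients)
    n = fit.n_events if n_for_bic is None else n_for_bic
    aic = -2.0 * fit.log_partial_likelihood + 2.0 * k
    bic = -2.0 * fit.log_partial_likelihood + k * np.log(n) if k else aic
    return float(aic), float(bic)


# --------------------------------------------------------------------------
# heterogeneity and meta-analysis
# --------------------------------------------------------------------------

def subgroup_heterogeneity(estimates, ses) -> tuple[float, int, float]:
    """Cochran Q of subgroup log-HRs about their inverse-variance mean.

    Returns (Q, df, P-heterogeneity) with P from chi-squared(k - 1).
    """
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("heterogeneity needs at least 2 subgroups")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    dof = b.size - 1
    return q, dof, float(stats.chi2.sf(q, dof))


@dataclass
class MetaResult:
    """Fixed-effect (inverse-variance) pooling of study-specific log-HRs."""

    studies: list[str]
    log_hrs: np.ndarray
    ses: np.ndarray
    pooled_log_hr: float
    pooled_se: float
    q: float
    df: int
    i2: float                      # max(0, (Q - df)/Q); NaN for a single study
    p_heterogeneity: float

    @property
    def pooled_hr(self) -> float:
        return float(np.exp(self.pooled_log_hr))

    @property
    def pooled_ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.pooled_log_hr - 1.96 * self.pooled_se)),
            float(np.exp(self.pooled_log_hr + 1.96 * self.pooled_se)),
        )

    def forest_table(self) -> pd.DataFrame:
        with np.errstate(over="ignore"):    # near-degenerate studies -> inf CI
            return self._forest_table()

    def _forest_table(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "study": self.studies,
                "log_hr": self.log_hrs,
                "se": self.ses,
                "hr": np.exp(self.log_hrs),
                "hr_lo": np.exp(self.log_hrs - 1.96 * self.ses),
                "hr_hi": np.exp(self.log_hrs + 1.96 * self.ses),
                "weight_pct": 100.0 * (1 / self.ses**2) / np.sum(1 / self.ses**2),
            }
        )
        pooled = pd.DataFrame(
            {
                "study": ["pooled (fixed effect)"],
                "log_hr": [self.pooled_log_hr],
                "se": [self.pooled_se],
                "hr": [self.pooled_hr],
                "hr_lo": [self.pooled_ci[0]],
                "hr_hi": [self.pooled_ci[1]],
                "weight_pct": [100.0],
            }
        )
        return pd.concat([rows, pooled], ignore_index=True)


def fixed_effect_meta(per_study: dict | pd.DataFrame) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis of study log-HRs.

    ``per_study`` maps study label to (log_hr, se), or is a DataFrame
    with columns study, log_hr, se.  With a single study the pooled
    estimate degenerates to that study and I-squared is undefined (NaN).
    """
    if isinstance(per_study, pd.DataFrame):
        studies = per_study["study"].astype(str).tolist()
        b = per_study["log_hr"].to_numpy(float)
        s = per_study["se"].to_numpy(float)
    else:
        studies = [str(k) for k in per_study]
        b = np.array([v[0] for v in per_study.values()], dtype=float)
        s = np.array([v[1] for v in per_study.values()], dtype=float)
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    if b.size == 1:
        return MetaResult(studies, b, s, pooled, pooled_se, 0.0, 0, float("nan"), float("nan"))
    q = float(np.sum(w * (b - pooled) ** 2))
    dof = b.size - 1
    i2 = max(0.0, (q - dof) / q) if q > 0 else 0.0
    return MetaResult(
        studies, b, s, pooled, pooled_se, q, dof, i2, float(stats.chi2.sf(q, dof))
    )
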