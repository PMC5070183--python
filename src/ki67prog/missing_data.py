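"""Multiple imputation of missing covariates with the outcome included (MI+).

Chained-equations imputation in which every imputation model's
predictors include the event indicator and the Nelson-Aalen estimate of
the cumulative hazard at the subject's exit time -- the standard way to
carry the survival outcome into the imputation step.  Continuous and
multi-category variables are imputed by predictive-mean matching (5
donors, so only observed values are ever imputed); binary variables by
a logistic posterior draw.  Estimates across the completed datasets are
combined with Rubin's rules, with Barnard-Rubin degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survival_models import CoxFit, TvcFit, cox_fit, cox_tvc_fit

__all__ = [
    "ImputationSet",
    "PooledFit",
    "nelson_aalen_cumhaz",
    "impute",
    "pool_rubin",
    "fit_pooled",
]

_ID_COLS = {"patient_id", "study_id", "entry_time", "exit_time", "event"}


def nelson_aalen_cumhaz(entry, exit_, event) -> np.ndarray:
    """Nelson-Aalen cumulative hazard at each subject's exit time.

    Risk sets honour delayed entry: ``H(t) = sum_{u <= t} d_u / n_u``
    over event times u, with n_u the number at risk (entered, not yet
    exited) at u.
    """
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    event = np.asarray(event).astype(int)
    ev_times = np.unique(exit_[event == 1])
    increments = np.zeros_like(ev_times)
    for j, t in enumerate(ev_times):
        n_at = np.sum((entry < t) & (exit_ >= t))
        d = np.sum((exit_ == t) & (event == 1))
        increments[j] = d / n_at if n_at else 0.0
    cum = np.cumsum(increments)
    idx = np.searchsorted(ev_times, exit_, side="right") - 1
    return np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)


@dataclass
class ImputationSet:
    """m completed datasets, identical on observed cells."""

    datasets: list[pd.DataFrame]
    imputed_columns: list[str]
    seed: int
    model_spec: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)


def _ridge_logistic(X, y, ridge=1e-6, max_iter=50):
    """Newton logistic fit; returns (beta, covariance)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))
        W = p * (1 - p)
        H = X.T @ (W[:, None] * X) + ridge * np.eye(X.shape[1])
        g = X.T @ (y - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    p = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))
    W = p * (1 - p)
    cov = np.linalg.inv(X.T @ (W[:, None] * X) + ridge * np.eye(X.shape[1]))
    return beta, cov


def _pmm_draw(X_obs, y_obs, X_mis, rng, k_donors=5):
    """Predictive-mean matching with a Bayesian parameter draw."""
    n_obs, p = X_obs.shape
    beta_hat, res, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n_obs - p, 1)
    rss = float(resid @ resid)
    sigma2 = rss / max(stats.chi2.rvs(dof, random_state=rng), 1e-12)
    xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
    beta_star = rng.multivariate_normal(beta_hat, sigma2 * xtx_inv, method="cholesky")
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star
    k = min(k_donors, n_obs)
    dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
    donors = np.argpartition(dist, k - 1, axis=1)[:, :k]
    pick = donors[np.arange(len(pred_mis)), rng.integers(0, k, size=len(pred_mis))]
    return y_obs[pick]


def _classify(col: pd.Series) -> str:
    obs = col.dropna()
    if obs.dtype == object:
        return "categorical"
    vals = np.unique(obs.to_numpy(dtype=float))
    if vals.size <= 1:
        return "degenerate"
    if vals.size == 2:
        return "binary"
    return "continuous"


def impute(
    patients: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    n_cycles: int = 10,
    k_donors: int = 5,
    columns: list[str] | None = None,
    predictors: list[str] | None = None,
) -> ImputationSet:
    """MI+ chained-equations imputation of missing covariates.

    Missingness is only allowed in covariates: rows must have complete
    entry/exit/event.  Each of the m chains is initialised by random
    draws from the observed margins, cycled ``n_cycles`` times, and the
    final state kept.  Reproducible under ``seed``.
    """
    df = patients.reset_index(drop=True)
    for col in ("exit_time", "event"):
        if col in df.columns and df[col].isna().any():
            raise ValueError(f"missing values in outcome column {col!r}; impute covariates only")

    candidates = [
        c for c in df.columns
        if c not in _ID_COLS and c != "visual_ki67_pct" and not c.startswith("true_")
    ]
    if columns is None:
        columns = [c for c in candidates if df[c].isna().any()]
    spec = {}
    for c in columns:
        kind = _classify(df[c])
        if df[c].isna().all():
            raise ValueError(f"column {c!r} is 100 % missing; nothing to fit on")
        if kind == "degenerate":
            warnings.warn(
                f"column {c!r} has a single observed value; filled as constant "
                "and excluded from the imputation models", stacklevel=2,
            )
        spec[c] = kind

    if predictors is None:
        predictors = [
            c for c in candidates
            if spec.get(c) != "degenerate"
            and (c in columns or not df[c].isna().any())
        ]
    # the '+ outcome' part: event indicator and Nelson-Aalen cumulative hazard
    na_ch = nelson_aalen_cumhaz(
        df.get("entry_time", pd.Series(np.zeros(len(df)))).to_numpy(float),
        df["exit_time"].to_numpy(float),
        df["event"].to_numpy(int),
    )

    # object columns are modelled through factor codes, mapped back on output
    codes_map = {}
    work_base = df.copy()
    for c in candidates:
        if df[c].dtype == object:
            cat = pd.Categorical(df[c])
            codes_map[c] = cat.categories
            work_base[c] = np.where(cat.codes >= 0, cat.codes, np.nan).astype(float)

    order = sorted(columns, key=lambda c: work_base[c].isna().sum())
    miss_masks = {c: work_base[c].isna().to_numpy() for c in columns}

    root = np.random.SeedSequence(seed)
    datasets = []
    for chain_ss in root.spawn(m):
        rng = np.random.default_rng(chain_ss)
        work = work_base.copy()
        for c in columns:                      # initial fill from observed margins
            obs = work.loc[~miss_masks[c], c].to_numpy(dtype=float)
            work.loc[miss_masks[c], c] = rng.choice(obs, size=miss_masks[c].sum())
        for _cycle in range(n_cycles):
            for c in order:
                mask = miss_masks[c]
                if not mask.any() or spec.get(c) == "degenerate":
                    continue
                pred_cols = [p for p in predictors if p != c]
                Xd = work[pred_cols].to_numpy(dtype=float)
                X = np.column_stack([np.ones(len(work)), Xd, df["event"].to_numpy(float), na_ch])
                y = work[c].to_numpy(dtype=float)
                kind = spec[c] if df[c].dtype != object else "categorical"
                if kind == "binary":
                    vals = np.unique(df[c].dropna().to_numpy(dtype=float))
                    yb = (y == vals.max()).astype(float)
                    beta, cov = _ridge_logistic(X[~mask], yb[~mask])
                    bstar = rng.multivariate_normal(beta, cov, method="cholesky")
                    p = 1.0 / (1.0 + np.exp(-np.clip(X[mask] @ bstar, -30, 30)))
                    draw = np.where(rng.random(mask.sum()) < p, vals.max(), vals.min())
                    work.loc[mask, c] = draw
                else:                          # continuous or categorical-as-codes PMM
                    y_new = _pmm_draw(X[~mask], y[~mask], X[mask], rng, k_donors)
                    work.loc[mask, c] = y_new
        out = work.copy()
        for c, cats in codes_map.items():
            out[c] = cats[out[c].astype(int)]
        datasets.append(out)
    return ImputationSet(datasets=datasets, imputed_columns=list(columns), seed=seed, model_spec=spec)


# --------------------------------------------------------------------------
# Rubin's rules
# --------------------------------------------------------------------------

@dataclass
class PooledFit:
    """Rubin's-rules combination of Cox fits across imputations."""

    coefficients: pd.Series
    total_variance: pd.Series
    within_variance: pd.Series
    between_variance: pd.Series
    df: pd.Series
    m: int
    n: int
    n_events: int

    @property
    def se(self) -> pd.Series:
        return np.sqrt(self.total_variance)

    def summary(self) -> pd.DataFrame:
        se = self.se
        tcrit = pd.Series(stats.t.ppf(0.975, self.df), index=self.df.index)
        tstat = self.coefficients / se
        with np.errstate(over="ignore"):    # diverged coefficients -> inf HR
            return pd.DataFrame(
                {
                    "coef": self.coefficients,
                    "se": se,
                    "hr": np.exp(self.coefficients),
                    "hr_lo": np.exp(self.coefficients - tcrit * se),
                    "hr_hi": np.exp(self.coefficients + tcrit * se),
                    "p": 2 * stats.t.sf(np.abs(tstat), self.df),
                }
            )


def pool_rubin(fits: list[CoxFit], dfcom: int | None = None) -> PooledFit:
    """Pool coefficients over imputations with Rubin's rules.

    Pooled beta is the mean; total variance = within-mean +
    (1 + 1/m) * between; degrees of freedom by the Barnard-Rubin
    small-sample adjustment with complete-data df = events - k unless
    given.
    """
    if len(fits) < 2:
        raise ValueError("pooling needs m >= 2 fits")
    index = fits[0].coefficients.index
    for f in fits[1:]:
        if not f.coefficients.index.equals(index):
            raise ValueError("fits have mismatched coefficient sets")
    m = len(fits)
    betas = np.vstack([f.coefficients.to_numpy() for f in fits])
    withins = np.vstack([np.diag(f.covariance.to_numpy()) for f in fits])
    qbar = betas.mean(axis=0)
    ubar = withins.mean(axis=0)
    b = betas.var(axis=0, ddof=1)
    total = ubar + (1.0 + 1.0 / m) * b
    lam = np.clip((1.0 + 1.0 / m) * b / total, 1e-12, 1 - 1e-12)
    nu_old = (m - 1) / lam**2
    if dfcom is None:
        dfcom = max(fits[0].n_events - len(index), 1)
    nu_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
    nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
    return PooledFit(
        coefficients=pd.Series(qbar, index=index),
        total_variance=pd.Series(total, index=index),
        within_variance=pd.Series(ubar, index=index),
        between_variance=pd.Series(b, index=index),
        df=pd.Series(nu, index=index),
        m=m,
        n=fits[0].n,
        n_events=fits[0].n_events,
    )


def fit_pooled(
    imputations: ImputationSet,
    covariates: list[str],
    tvc_vars: str | list[str] | None = None,
    strata: str | None = None,
    horizon: float = 10.0,
) -> tuple[PooledFit, list[CoxFit]]:
    """Fit the same Cox model on every completed dataset and pool."""
    fits: list[CoxFit] = []
    for d in imputations.datasets:
        if tvc_vars:
            fits.append(cox_tvc_fit(d, covariates, tvc_vars=tvc_vars, strata=strata, horizon=horizon))
        else:
            fits.append(cox_fit(d, covariates, strata=strata, horizon=horizon))
    return pool_rubin(fits), fits
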