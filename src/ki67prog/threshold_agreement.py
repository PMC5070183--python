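"""Prognostic cut-off derivation and cross-method agreement statistics.

The prognostic threshold is taken from the quartile structure of the
automated KI67 distribution (high = strictly above the Q3 boundary); a
visual-scoring cut-off is extrapolated from the automated one by
ordinary least squares of visual on automated scores and rounded up to
the next multiple of 5.  Agreement between methods is summarised by
observed agreement, Cohen's kappa, sensitivity/specificity against the
visual reference, Pearson correlation, and the rank-based (Mann-Whitney)
ROC AUC with a Hanley-McNeil confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CutoffModel",
    "AgreementStats",
    "quartile_cuts",
    "dichotomise",
    "extrapolate_cutoff",
    "agreement",
    "roc_auc",
    "cross_classify",
    "full_agreement",
]


@dataclass
class CutoffModel:
    """Quartile boundaries, the automated cut and its visual extrapolation."""

    quartile_cuts: tuple[float, float, float]
    automated_cut: float
    slope: float = float("nan")
    intercept: float = float("nan")
    pearson_r: float = float("nan")
    extrapolated_visual_cut: float = float("nan")
    rounded_visual_cut: float = float("nan")

    def __post_init__(self) -> None:
        q1, q2, q3 = self.quartile_cuts
        if not q1 <= q2 <= q3:
            raise ValueError("quartile boundaries must be non-decreasing")


@dataclass
class AgreementStats:
    """Cross-method concordance bundle for two binary readings."""

    observed_agreement: float
    kappa: float
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    pearson_r: float = float("nan")
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    contingency: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), dtype=int))


def quartile_cuts(scores) -> tuple[float, float, float]:
    """Q1/Q2/Q3 boundaries by linear-interpolation quantiles.

    The dichotomisation boundary is Q3 ('high' = strictly above).
    Raises on fewer than 4 distinct values: there is no quartile
    structure to derive a cut-off from.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < 4:
        raise ValueError("quartile cut-offs need at least 4 distinct scores")
    q1, q2, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(q1), float(q2), float(q3)


def dichotomise(scores, cut: float) -> np.ndarray:
    """High/low labels: high (1) iff score strictly above the cut."""
    x = np.asarray(scores, dtype=float)
    return (x > cut).astype(int)


def round_up_to_multiple(value: float, step: float = 5.0) -> float:
    """Smallest multiple of ``step`` at or above ``value``."""
    return step * math.ceil(value / step - 1e-12)


def extrapolate_cutoff(automated, visual, automated_cut: float = 12.0) -> CutoffModel:
    """Extrapolate a visual cut-off from the automated one by OLS.

    Fits visual = intercept + slope * automated over paired patient
    scores, maps the automated cut through the fit, and rounds the
    result up to the next multiple of 5.  Also derives the quartile
    boundaries of the automated scores and reports Pearson r.
    """
    a = np.asarray(automated, dtype=float)
    v = np.asarray(visual, dtype=float)
    keep = np.isfinite(a) & np.isfinite(v)
    a, v = a[keep], v[keep]
    if a.size < 3:
        raise ValueError("need at least 3 paired scores")
    if np.ptp(a) == 0:
        raise ValueError("automated scores are constant; regression undefined")
    fit = stats.linregress(a, v)
    extrapolated = fit.intercept + fit.slope * automated_cut
    try:
        qcuts = quartile_cuts(a)
    except ValueError:
        qcuts = (float(np.min(a)), float(np.median(a)), float(np.max(a)))
    return CutoffModel(
        quartile_cuts=qcuts,
        automated_cut=automated_cut,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        extrapolated_visual_cut=float(extrapolated),
        rounded_visual_cut=float(round_up_to_multiple(extrapolated)),
    )


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """2x2 table with rows = a (1 then 0), columns = b (1 then 0)."""
    return np.array(
        [
            [int(np.sum((a == 1) & (b == 1))), int(np.sum((a == 1) & (b == 0)))],
            [int(np.sum((a == 0) & (b == 1))), int(np.sum((a == 0) & (b == 0)))],
        ]
    )


def agreement(binary_a, binary_b) -> AgreementStats:
    """Observed agreement and Cohen's kappa for two binary label vectors.

    Kappa uses chance agreement from the marginals; when both raters are
    constant and identical (chance agreement 1) kappa is undefined and
    reported as NaN.
    """
    a = np.asarray(binary_a, dtype=int)
    b = np.asarray(binary_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty label vectors")
    table = _contingency(a, b)
    po = float(np.trace(table)) / n
    pa1, pb1 = a.mean(), b.mean()
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    kappa = float("nan") if pe >= 1.0 else (po - pe) / (1.0 - pe)
    return AgreementStats(observed_agreement=po, kappa=float(kappa), contingency=table)


def roc_auc(scores, reference) -> tuple[float, tuple[float, float]]:
    """AUC of continuous scores against a binary reference, with 95 % CI.

    Uses the Mann-Whitney rank formulation with midranks for ties; the
    confidence interval comes from the Hanley-McNeil variance, clipped
    to [0, 1].
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(reference, dtype=int)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both reference classes must be present")
    ranks = stats.rankdata(x)            # midranks for ties
    auc = float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    half = 1.96 * math.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def cross_classify(auto_labels, visual_labels) -> AgreementStats:
    """Sensitivity/specificity of automated labels against visual reference.

    Visual-high is the positive class: sensitivity = TP/(TP + FN),
    specificity = TN/(TN + FP).  Entries are NaN when the corresponding
    reference class is empty.
    """
    auto = np.asarray(auto_labels, dtype=int)
    vis = np.asarray(visual_labels, dtype=int)
    if auto.shape != vis.shape:
        raise ValueError("label vectors must have equal length")
    tp = int(np.sum((auto == 1) & (vis == 1)))
    fn = int(np.sum((auto == 0) & (vis == 1)))
    fp = int(np.sum((auto == 1) & (vis == 0)))
    tn = int(np.sum((auto == 0) & (vis == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    base = agreement(auto, vis)
    base.sensitivity = sens
    base.specificity = spec
    return base


def full_agreement(
    automated, visual, automated_cut: float = 12.0, visual_cut: float = 25.0
) -> AgreementStats:
    """Complete cross-method bundle on paired continuous scores."""
    a = np.asarray(automated, dtype=float)
    v = np.asarray(visual, dtype=float)
    keep = np.isfinite(a) & np.isfinite(v)
    a, v = a[keep], v[keep]
    auto_lab = dichotomise(a, automated_cut)
    vis_lab = dichotomise(v, visual_cut)
    out = cross_classify(auto_lab, vis_lab)
    out.pearson_r = float(stats.pearsonr(a, v).statistic) if a.size > 2 else float("nan")
    if vis_lab.min() == 0 and vis_lab.max() == 1:
        out.auc, out.auc_ci = roc_auc(a, vis_lab)
    return out
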