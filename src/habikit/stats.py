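"""Evaluation statistics: ROC/AUC with DeLong variance, paired DeLong test,
classification metrics, McNemar, Hosmer-Lemeshow calibration, decision
curve analysis, average precision, Fleiss' kappa and baseline-table tests.

AUC uses midrank tie handling and is identical to the normalized
Mann-Whitney U statistic; its variance and the paired test come from the
DeLong placement-value covariance with a normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

__all__ = [
    "EvalReport",
    "CalibrationReport",
    "DcaCurve",
    "auc",
    "auc_ci",
    "eval_report",
    "delong_test",
    "mcnemar_test",
    "hosmer_lemeshow",
    "dca",
    "pr_auc",
    "fleiss_kappa",
    "chi_square_test",
    "group_location_test",
    "prevalence_percent",
]


# ---------------------------------------------------------------------------
# ROC / AUC via placements (DeLong)

def _placements(scores: np.ndarray, labels: np.ndarray):
    """Midrank placement values V10 (per positive) and V01 (per negative)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_s = np.concatenate([pos, neg])
    ranks = sps.rankdata(all_s)
    ranks_pos = sps.rankdata(pos)
    ranks_neg = sps.rankdata(neg)
    v10 = (ranks[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks[m:] - ranks_neg) / m
    return v10, v01


def auc(scores, labels) -> float:
    """Trapezoidal ROC AUC with midrank ties (= Mann-Whitney U / (n1*n0))."""
    v10, _ = _placements(np.asarray(scores), np.asarray(labels))
    return float(v10.mean())


def _delong_var(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """(AUC, lower, upper) with a DeLong-variance normal CI clipped to [0, 1]."""
    v10, v01 = _placements(np.asarray(scores), np.asarray(labels))
    a = float(v10.mean())
    se = float(np.sqrt(_delong_var(v10, v01)))
    z = sps.norm.ppf(1 - alpha / 2)
    return a, max(0.0, a - z * se), min(1.0, a + z * se)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """Paired DeLong test for two correlated AUCs on identical cases.

    Returns (z, p, auc_a, auc_b); identical score vectors give z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores must share the label vector shape")
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01])) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var_diff = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var_diff <= 0:
        if np.allclose(scores_a, scores_b) or np.isclose(auc_a, auc_b):
            return 0.0, 1.0, auc_a, auc_b
        var_diff = np.finfo(float).tiny
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p), auc_a, auc_b


# ---------------------------------------------------------------------------
# Classification metrics

@dataclass
class EvalReport:
    auc: float
    ci_lower: float
    ci_upper: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    n: int
    cohort: str = ""

    @property
    def precision(self) -> float:
        return self.ppv

    @property
    def recall(self) -> float:
        return self.sensitivity

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "n": self.n, "cohort": self.cohort,
        }


def eval_report(scores, calls, labels, cohort: str = "") -> EvalReport:
    """AUC with DeLong CI plus 2x2 metrics of binary calls vs labels."""
    scores = np.asarray(scores, float)
    calls = np.asarray(calls).astype(int)
    labels = np.asarray(labels).astype(int)
    a, lo, hi = auc_ci(scores, labels)
    tp = int(((calls == 1) & (labels == 1)).sum())
    tn = int(((calls == 0) & (labels == 0)).sum())
    fp = int(((calls == 1) & (labels == 0)).sum())
    fn = int(((calls == 0) & (labels == 1)).sum())
    n = tp + tn + fp + fn
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    f1 = 2 * ppv * sens / (ppv + sens) if (ppv + sens) > 0 else 0.0
    return EvalReport(
        auc=a, ci_lower=lo, ci_upper=hi, accuracy=(tp + tn) / n,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, f1=f1,
        n=n, cohort=cohort,
    )


def mcnemar_test(calls_a, calls_b, labels) -> float:
    """McNemar test on paired accuracy: discordant correct/incorrect pairs.

    Exact binomial for b + c < 25, else chi-square with continuity
    correction; b + c = 0 returns p = 1.
    """
    calls_a = np.asarray(calls_a).astype(int)
    calls_b = np.asarray(calls_b).astype(int)
    labels = np.asarray(labels).astype(int)
    correct_a = calls_a == labels
    correct_b = calls_b == labels
    b = int((correct_a & ~correct_b).sum())
    c = int((~correct_a & correct_b).sum())
    if b + c == 0:
        return 1.0
    if b + c < 25:
        k = min(b, c)
        p = 2 * sps.binom.cdf(k, b + c, 0.5)
        if b == c:  # symmetric point counted twice
            p -= sps.binom.pmf(k, b + c, 0.5)
        return float(min(1.0, p))
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    return float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Calibration

@dataclass
class CalibrationReport:
    chi_square: float
    df: int
    p_value: float
    bin_table: list[dict] = field(default_factory=list)  # per-bin O/E counts

    @property
    def curve(self) -> list[tuple[float, float]]:
        """(mean predicted, observed rate) per bin."""
        return [(b["mean_prob"], b["observed_rate"]) for b in self.bin_table]


def hosmer_lemeshow(
    probs, labels, bins: int = 10, fitted_params: int = 2
) -> CalibrationReport:
    """Hosmer-Lemeshow goodness-of-fit over deciles of predicted risk.

    Quantile bin edges with ties merged; df = n_bins - ``fitted_params``.
    The classic convention (default 2) applies when the probabilities come
    from a logistic model fit on the same data; for externally supplied
    probabilities no parameters were estimated and ``fitted_params=0`` gives
    the correct null distribution.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels).astype(int)
    if len(probs) < bins:
        raise ValueError("need at least as many cases as bins")
    if len(np.unique(probs)) < 3:
        raise ValueError("need at least 3 distinct probabilities")
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, bins + 1)))
    idx = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, len(edges) - 2)
    chi2 = 0.0
    table = []
    for g in range(len(edges) - 1):
        sel = idx == g
        n_g = int(sel.sum())
        if n_g == 0:
            continue
        obs = int(labels[sel].sum())
        exp = float(probs[sel].sum())
        mean_p = float(probs[sel].mean())
        denom = exp * (1 - exp / n_g)
        if denom > 0:
            chi2 += (obs - exp) ** 2 / denom
        table.append(
            {
                "bin": g, "n": n_g, "observed": obs, "expected": exp,
                "mean_prob": mean_p, "observed_rate": obs / n_g,
            }
        )
    df = max(len(table) - fitted_params, 1)
    return CalibrationReport(
        chi_square=float(chi2), df=df, p_value=float(sps.chi2.sf(chi2, df)), bin_table=table
    )


# ---------------------------------------------------------------------------
# Decision curve analysis

@dataclass
class DcaCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray       # model
    treat_all: np.ndarray
    treat_none: np.ndarray        # identically zero

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "model": self.net_benefit,
                "treat_all": self.treat_all,
                "treat_none": self.treat_none,
            }
        )


def dca(probs, labels, thresholds: Optional[np.ndarray] = None) -> DcaCurve:
    """Net benefit NB(t) = TP/n - FP/n * t/(1-t), calling positive at prob >= t."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, float)
    n = len(labels)
    prevalence = labels.mean()
    nb = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        call = probs >= t
        tp = (call & (labels == 1)).sum()
        fp = (call & (labels == 0)).sum()
        nb[i] = tp / n - fp / n * t / (1 - t)
    treat_all = prevalence - (1 - prevalence) * thresholds / (1 - thresholds)
    return DcaCurve(
        thresholds=thresholds, net_benefit=nb,
        treat_all=treat_all, treat_none=np.zeros_like(thresholds),
    )


# ---------------------------------------------------------------------------
# Precision-recall

def pr_auc(scores, labels) -> float:
    """Step-wise average precision (no interpolation)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / y.sum()
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    return float((precision * d_recall).sum())


# ---------------------------------------------------------------------------
# Agreement

def fleiss_kappa(ratings) -> float:
    """Fleiss' kappa for a cases x raters categorical matrix."""
    ratings = np.asarray(ratings)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("need a cases x raters matrix with >= 2 of each")
    if len(np.unique(ratings)) < 2:
        raise ValueError("kappa undefined: a single category was used throughout")
    counts, _ = aggregate_raters(ratings)
    return float(_sm_fleiss(counts))


# ---------------------------------------------------------------------------
# Baseline-table tests

def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    table = np.asarray(table, float)
    if table.sum() <= 0:
        raise ValueError("empty contingency table")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def group_location_test(groups: Sequence[np.ndarray], method: str = "auto") -> float:
    """Compare group means/locations: t-test (2 groups), ANOVA (3+), or
    Mann-Whitney/Kruskal-Wallis when normality fails (method='auto')."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if method == "auto":
        normal = all(
            len(g) >= 3 and np.ptp(g) > 0 and sps.shapiro(g).pvalue > 0.05 for g in groups
        )
        method = "parametric" if normal else "nonparametric"
    if method == "parametric":
        if len(groups) == 2:
            return float(sps.ttest_ind(*groups).pvalue)
        return float(sps.f_oneway(*groups).pvalue)
    if len(groups) == 2:
        return float(sps.mannwhitneyu(*groups, alternative="two-sided").pvalue)
    return float(sps.kruskal(*groups).pvalue)


def prevalence_percent(labels) -> float:
    """Percent positive, rounded to two decimals (cohort summary convention)."""
    labels = np.asarray(labels).astype(int)
    if labels.size == 0:
        raise ValueError("empty label vector")
    return round(100.0 * labels.mean(), 2)
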