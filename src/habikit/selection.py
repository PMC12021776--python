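"""Feature normalization and the four-step screening chain.

The screening chain reduces the 546/210/756-column feature tables to a
compact signature: (1) an inter-reader reproducibility filter keeping
features with ICC(2,1) >= 0.75 across two independent segmentations,
(2) a univariate outcome screen (t-test for columns normal in both classes
by Shapiro-Wilk, Mann-Whitney U otherwise; keep p < 0.05), (3) Spearman
correlation pruning of redundant pairs (|rho| > 0.9), and (4) L1-penalized
logistic regression with the penalty chosen by stratified 10-fold CV and
the one-standard-error rule.  Every threshold is config-exposed and every
step logs input/output counts.  Normalization parameters are fit on
training rows only and reapplied unchanged elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "NormalizationParams",
    "SelectionConfig",
    "SelectionResult",
    "fit_normalizer",
    "apply_normalizer",
    "icc_filter",
    "icc21",
    "univariate_filter",
    "correlation_prune",
    "sparse_select",
    "run_selection",
]


@dataclass
class NormalizationParams:
    """Per-column location/scale fit on the training cohort only."""

    method: str                      # 'minmax' or 'zscore'
    location: pd.Series              # min (minmax) or mean (zscore)
    scale: pd.Series                 # range or sd
    constant_columns: list[str]      # scale == 0, passed through as 0


def fit_normalizer(table: pd.DataFrame, method: str = "minmax") -> NormalizationParams:
    if len(table) < 2:
        raise ValueError("need at least 2 training rows")
    if method == "minmax":
        loc = table.min(axis=0)
        scale = table.max(axis=0) - loc
    elif method == "zscore":
        loc = table.mean(axis=0)
        scale = table.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    constant = scale.index[scale == 0].tolist()
    return NormalizationParams(method, loc, scale, constant)


def apply_normalizer(params: NormalizationParams, table: pd.DataFrame) -> pd.DataFrame:
    """Transform with stored params; out-of-range values are not clipped."""
    scale = params.scale.replace(0, 1.0)
    out = (table - params.location) / scale
    if params.constant_columns:
        out[params.constant_columns] = 0.0
    return out


# ---------------------------------------------------------------------------
# ICC(2,1): two-way random effects, absolute agreement, single measurement

def icc21(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1) for two raters measuring the same cases once each."""
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 cases for ICC")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 0.0
    return float((msr - mse) / denom)


def icc_filter(
    reader1: pd.DataFrame, reader2: pd.DataFrame, threshold: float = 0.75
) -> tuple[list[str], pd.Series]:
    """Keep columns with ICC(2,1) >= threshold between two reader tables."""
    shared_cases = reader1.index.intersection(reader2.index)
    if len(shared_cases) < 3:
        raise ValueError("need at least 3 shared cases")
    shared_cols = [c for c in reader1.columns if c in set(reader2.columns)]
    iccs = pd.Series(
        {
            c: icc21(reader1.loc[shared_cases, c].values, reader2.loc[shared_cases, c].values)
            for c in shared_cols
        }
    )
    kept = iccs.index[iccs >= threshold].tolist()
    return kept, iccs


# ---------------------------------------------------------------------------
# Univariate outcome screen

def _univariate_p(values: np.ndarray, labels: np.ndarray) -> float:
    g0, g1 = values[labels == 0], values[labels == 1]
    if np.ptp(values) == 0:
        return 1.0
    normal = True
    for g in (g0, g1):
        if np.ptp(g) == 0:
            normal = False
            break
        if len(g) >= 3:
            normal &= sps.shapiro(g).pvalue > 0.05
    if normal:
        return float(sps.ttest_ind(g0, g1).pvalue)
    return float(
        sps.mannwhitneyu(g0, g1, alternative="two-sided", method="asymptotic").pvalue
    )


def univariate_filter(
    table: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], pd.Series]:
    """Keep columns whose class difference has p < alpha."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pvals = pd.Series(
        {c: _univariate_p(table[c].values, labels) for c in table.columns}
    )
    kept = pvals.index[pvals < alpha].tolist()
    return kept, pvals


# ---------------------------------------------------------------------------
# Correlation pruning

def correlation_prune(table: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedy Spearman-redundancy pruning.

    Pairs with |rho| > threshold are visited in decreasing |rho|; the member
    with the larger mean absolute correlation to all other columns is
    dropped (ties: the lexicographically later name).
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    corr = sps.spearmanr(table.values).statistic
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    if corr.shape != (len(cols), len(cols)):  # spearmanr collapses 2 columns
        rho = float(corr.ravel()[0])
        corr = np.array([[1.0, rho], [rho, 1.0]])
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, np.nan)
    mean_abs = np.nanmean(abs_corr, axis=1)

    iu = np.triu_indices(len(cols), k=1)
    pair_rho = abs_corr[iu]
    order = np.argsort(-pair_rho, kind="stable")
    dropped: set[str] = set()
    for idx in order:
        rho = pair_rho[idx]
        if not np.isfinite(rho) or rho <= threshold:
            break
        a, b = iu[0][idx], iu[1][idx]
        ca, cb = cols[a], cols[b]
        if ca in dropped or cb in dropped:
            continue
        if mean_abs[a] > mean_abs[b]:
            dropped.add(ca)
        elif mean_abs[b] > mean_abs[a]:
            dropped.add(cb)
        else:
            dropped.add(max(ca, cb))
    return [c for c in cols if c not in dropped]


# ---------------------------------------------------------------------------
# Sparse multivariate selection

def sparse_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 42,
    c_path: Optional[np.ndarray] = None,
    n_folds: int = 10,
    fallback_top: int = 10,
) -> tuple[list[str], dict]:
    """L1-penalized logistic regression with CV (1-SE rule) over a C path.

    Returns (kept columns, log).  An all-zero solution falls back to the
    ``fallback_top`` smallest univariate p-values, flagged in the log.
    """
    labels = np.asarray(labels)
    if table.shape[1] < 1:
        return [], {"note": "empty input"}
    if c_path is None:
        c_path = np.logspace(-2, 2, 20)
    X = table.values
    y = labels
    n_folds = min(n_folds, int(np.bincount(y).min()))
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    mean_auc, se_auc = [], []
    for C in c_path:
        aucs = []
        for tr, va in skf.split(X, y):
            clf = LogisticRegression(
                penalty="l1", solver="liblinear", C=C, random_state=seed, max_iter=500
            ).fit(X[tr], y[tr])
            score = clf.decision_function(X[va])
            if len(np.unique(y[va])) < 2:
                continue
            aucs.append(roc_auc_score(y[va], score))
        aucs = np.asarray(aucs)
        mean_auc.append(aucs.mean() if aucs.size else 0.5)
        se_auc.append(aucs.std(ddof=1) / np.sqrt(len(aucs)) if aucs.size > 1 else 0.0)
    mean_auc = np.asarray(mean_auc)
    best = int(np.argmax(mean_auc))
    target = mean_auc[best] - se_auc[best]
    # 1-SE rule: strongest penalty (smallest C) within one SE of the best
    chosen = int(np.flatnonzero(mean_auc >= target)[0])
    clf = LogisticRegression(
        penalty="l1", solver="liblinear", C=c_path[chosen], random_state=seed, max_iter=500
    ).fit(X, y)
    kept = [c for c, coef in zip(table.columns, clf.coef_.ravel()) if coef != 0.0]
    log = {
        "c_path": list(map(float, c_path)),
        "mean_cv_auc": list(map(float, mean_auc)),
        "chosen_C": float(c_path[chosen]),
        "fallback": False,
    }
    if not kept:
        _, pvals = univariate_filter(table, labels, alpha=1.1)
        kept = pvals.nsmallest(min(fallback_top, len(pvals))).index.tolist()
        log["fallback"] = True
    return kept, log


@dataclass
class SelectionConfig:
    icc_threshold: float = 0.75
    alpha: float = 0.05
    corr_threshold: float = 0.9
    normalization: str = "minmax"
    seed: int = 42


@dataclass
class SelectionResult:
    kept: list[str]
    params: NormalizationParams
    steps: list[dict] = field(default_factory=list)
    config: SelectionConfig = field(default_factory=SelectionConfig)


def run_selection(
    train_table: pd.DataFrame,
    labels: np.ndarray,
    reader2_table: Optional[pd.DataFrame] = None,
    config: SelectionConfig = SelectionConfig(),
) -> SelectionResult:
    """Full chain: [ICC ->] normalize -> univariate -> correlation -> sparse.

    ``reader2_table`` (features re-extracted from a second reader's masks on
    a case subset) enables the reproducibility step; without it the chain
    starts at normalization.  Only training rows and labels are consumed.
    """
    steps = []
    cols = list(train_table.columns)

    if reader2_table is not None:
        kept, iccs = icc_filter(train_table, reader2_table, config.icc_threshold)
        steps.append({"step": "icc", "n_in": len(cols), "n_out": len(kept)})
        cols = kept

    params = fit_normalizer(train_table[cols], config.normalization)
    norm = apply_normalizer(params, train_table[cols])

    kept, pvals = univariate_filter(norm, labels, config.alpha)
    steps.append({"step": "univariate", "n_in": len(cols), "n_out": len(kept)})
    if not kept:  # nothing survives the screen: fall back to smallest p-values
        kept = pvals.nsmallest(min(10, len(pvals))).index.tolist()
        steps[-1]["fallback"] = True

    pruned = correlation_prune(norm[kept], config.corr_threshold)
    steps.append({"step": "correlation", "n_in": len(kept), "n_out": len(pruned)})

    final, log = sparse_select(norm[pruned], labels, seed=config.seed)
    steps.append({"step": "sparse", "n_in": len(pruned), "n_out": len(final), **{
        "chosen_C": log.get("chosen_C"), "fallback": log.get("fallback")}})

    params_final = fit_normalizer(train_table[final], config.normalization)
    return SelectionResult(kept=final, params=params_final, steps=steps, config=config)
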