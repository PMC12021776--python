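"""Shapley-value attributions for a trained scorer (kernel estimator).

The estimator solves the kernel-weighted linear regression of coalition
values, with the marginal-expectation value function: a coalition's value
is the mean model output over background rows in which the coalition's
features are replaced by the explained case's values.  The local-accuracy
constraint (base value + contributions = model output) is enforced exactly
by construction.  For small feature counts all 2^d - 2 proper coalitions
are enumerated, which makes the estimate exact; larger d falls back to
size-weighted coalition sampling.

Attributions explain the probability-scale output, so a positive
contribution pushes the case toward the positive (LNM) class.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ShapExplanation",
    "shapley_values",
    "rank_features",
    "export_plots_data",
    "medoid_background",
]


@dataclass
class ShapExplanation:
    base_value: float
    contributions: pd.DataFrame   # cases x features
    outputs: np.ndarray           # model output per explained case
    feature_values: pd.DataFrame  # raw feature values of explained cases

    def check_local_accuracy(self, tol: float = 1e-3) -> bool:
        recon = self.base_value + self.contributions.sum(axis=1).values
        return bool(np.all(np.abs(recon - self.outputs) <= tol))


def medoid_background(table: pd.DataFrame, max_rows: int = 50, seed: int = 42) -> pd.DataFrame:
    """Up to ``max_rows`` spread-out training rows (greedy medoid sampling)."""
    if len(table) <= max_rows:
        return table.copy()
    rng = np.random.default_rng(seed)
    X = (table - table.mean()) / table.std(ddof=0).replace(0, 1.0)
    X = X.values
    chosen = [int(rng.integers(len(table)))]
    d_min = np.linalg.norm(X - X[chosen[0]], axis=1)
    for _ in range(max_rows - 1):
        nxt = int(np.argmax(d_min))
        chosen.append(nxt)
        d_min = np.minimum(d_min, np.linalg.norm(X - X[nxt], axis=1))
    return table.iloc[sorted(chosen)].copy()


def _coalitions(d: int, n_samples: int, rng: np.random.Generator):
    """(mask matrix (n, d), weights (n,)) of proper coalitions."""
    n_full = 2 ** d - 2
    if n_full <= max(n_samples, 4096):
        masks = np.zeros((n_full, d), dtype=bool)
        weights = np.empty(n_full)
        row = 0
        for code in range(1, 2 ** d - 1):
            m = [(code >> j) & 1 for j in range(d)]
            masks[row] = m
            s = sum(m)
            weights[row] = (d - 1) / (comb(d, s) * s * (d - s))
            row += 1
        return masks, weights
    # sampling: draw sizes with the aggregated kernel distribution, subsets uniform
    sizes = np.arange(1, d)
    p = (d - 1) / (sizes * (d - sizes))
    p = p / p.sum()
    drawn = rng.choice(sizes, size=n_samples, p=p)
    masks = np.zeros((n_samples, d), dtype=bool)
    for r, s in enumerate(drawn):
        masks[r, rng.choice(d, size=s, replace=False)] = True
    return masks, np.ones(n_samples)


def _solve(masks, weights, values, base, fx):
    """Constrained kernel WLS: sum(phi) = fx - base enforced by elimination."""
    d = masks.shape[1]
    Z = masks.astype(float)
    y = values - base - Z[:, -1] * (fx - base)
    A = Z[:, :-1] - Z[:, [-1]]
    W = np.sqrt(weights)
    phi_head, *_ = np.linalg.lstsq(A * W[:, None], y * W, rcond=None)
    phi = np.empty(d)
    phi[:-1] = phi_head
    phi[-1] = (fx - base) - phi_head.sum()
    return phi


def shapley_values(
    model,
    background: pd.DataFrame,
    cases: pd.DataFrame,
    n_samples: int = 2048,
    seed: int = 42,
) -> ShapExplanation:
    """Kernel Shapley attributions for each row of ``cases``.

    ``model`` is a TrainedModel (its ``score`` method is used) or any
    callable mapping a feature DataFrame to scores.  ``background`` and
    ``cases`` must share the model's feature columns.
    """
    predict: Callable[[pd.DataFrame], np.ndarray]
    if hasattr(model, "score") and hasattr(model, "features"):
        features = list(model.features)
        predict = model.score
    else:
        features = list(background.columns)
        predict = model

    background = background[features]
    cases = cases[features]
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    d = len(features)
    if d < 1:
        raise ValueError("no features to explain")
    min_samples = 2 * d + 2
    if n_samples < min_samples:
        raise ValueError(
            f"n_samples={n_samples} too small for {d} features; need >= {min_samples}"
        )
    rng = np.random.default_rng(seed)

    base = float(np.mean(predict(background)))
    outputs = np.asarray(predict(cases), float)

    if d == 1:
        contrib = (outputs - base)[:, None]
        return ShapExplanation(
            base_value=base,
            contributions=pd.DataFrame(contrib, index=cases.index, columns=features),
            outputs=outputs,
            feature_values=cases.copy(),
        )

    masks, weights = _coalitions(d, n_samples, rng)
    n_coal = len(masks)
    n_bg = len(background)
    bg = background.values

    phis = np.empty((len(cases), d))
    for r in range(len(cases)):
        x = cases.values[r]
        # hybrid rows: coalition features from x, the rest from each background row
        synth = np.repeat(bg, n_coal, axis=0)
        tiled_masks = np.tile(masks, (n_bg, 1))
        synth[tiled_masks] = np.broadcast_to(x, tiled_masks.shape)[tiled_masks]
        preds = predict(pd.DataFrame(synth, columns=features))
        values = preds.reshape(n_bg, n_coal).mean(axis=0)
        phis[r] = _solve(masks, weights, values, base, outputs[r])

    return ShapExplanation(
        base_value=base,
        contributions=pd.DataFrame(phis, index=cases.index, columns=features),
        outputs=outputs,
        feature_values=cases.copy(),
    )


def rank_features(explanation: ShapExplanation) -> pd.Series:
    """Global importance: mean |contribution| per feature, descending.

    Deterministic tie-break by feature name.
    """
    imp = explanation.contributions.abs().mean(axis=0)
    order = sorted(imp.index, key=lambda c: (-imp[c], c))
    return imp.loc[order]


def export_plots_data(explanation: ShapExplanation) -> dict[str, pd.DataFrame]:
    """Tidy tables backing bar, beeswarm-summary, heatmap and stacked-force plots."""
    contrib = explanation.contributions
    imp = rank_features(explanation)
    bar = pd.DataFrame(
        {"feature": imp.index, "mean_abs_shap": imp.values, "rank": range(1, len(imp) + 1)}
    )

    long = contrib.reset_index(names="case").melt(
        id_vars="case", var_name="feature", value_name="shap_value"
    )
    fvals = explanation.feature_values.reset_index(names="case").melt(
        id_vars="case", var_name="feature", value_name="feature_value"
    )
    summary = long.merge(fvals, on=["case", "feature"])

    heatmap = summary[["case", "feature", "shap_value", "feature_value"]].copy()

    # stacked force: cases ordered by model output, features by global rank
    case_order = {
        c: i for i, c in enumerate(contrib.index[np.argsort(-explanation.outputs, kind="stable")])
    }
    feat_order = {f: i for i, f in enumerate(imp.index)}
    force = summary.copy()
    force["base_value"] = explanation.base_value
    force["model_output"] = force["case"].map(
        dict(zip(contrib.index, explanation.outputs))
    )
    force["case_order"] = force["case"].map(case_order)
    force["feature_order"] = force["feature"].map(feat_order)
    force = force.sort_values(["case_order", "feature_order"], kind="stable").reset_index(
        drop=True
    )
    return {"bar": bar, "summary": summary, "heatmap": heatmap, "force": force}
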