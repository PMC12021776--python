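"""Reader-study analysis: consensus calls, Node-RADS binarization,
round-to-round comparison, per-score metrics and Sankey reclassification flows.

Readers assess each case three times per round; the majority of the three
repeats is the final call.  Node-RADS scores (1-5) binarize at >= 3.  Model
assistance is quantified per reader by paired DeLong (AUC of the binary
calls, a two-point ROC) and McNemar (accuracy) tests between rounds.  The
Sankey export traces score -> model call -> outcome flows, marking cases
the model reclassifies against the score-implied call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import delong_test, eval_report, mcnemar_test

__all__ = [
    "consensus_call",
    "rads_binarize",
    "compare_rounds",
    "per_score_metrics",
    "sankey_data",
    "consensus_from_assessments",
    "SankeyData",
    "ReclassificationTable",
]


def consensus_call(repeats) -> int:
    """Majority vote of exactly three binary repeat assessments."""
    repeats = np.asarray(repeats).astype(int)
    if repeats.shape != (3,):
        raise ValueError("need exactly 3 repeats")
    if not np.isin(repeats, (0, 1)).all():
        raise ValueError("repeats must be binary")
    return int(repeats.sum() >= 2)


def rads_binarize(scores) -> np.ndarray:
    """Node-RADS score >= 3 indicates LNM."""
    scores = np.asarray(scores).astype(int)
    if scores.size and (scores.min() < 1 or scores.max() > 5):
        raise ValueError("Node-RADS scores must be in 1..5")
    return (scores >= 3).astype(int)


def consensus_from_assessments(assessments: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeat-level rows to consensus rows per (reader, round, case).

    Expects ReaderAssessment columns: case_id, reader_id, round, repeat,
    call, and optionally rads_score (consensus score = median of repeats).
    """
    keys = ["reader_id", "round", "case_id"]
    extra = [c for c in ("group", "seniority") if c in assessments.columns]
    grouped = assessments.sort_values("repeat").groupby(keys + extra, sort=True)
    call = grouped["call"].agg(lambda s: consensus_call(s.values))
    res = call.to_frame("call")
    if "rads_score" in assessments.columns:
        score = grouped["rads_score"].agg(
            lambda s: int(np.median(s.values)) if s.notna().all() else np.nan
        )
        res["rads_score"] = score
    res = res.reset_index()
    res["call"] = res["call"].astype(int)
    return res


def compare_rounds(round1_calls, round2_calls, labels) -> dict:
    """Per-reader assistance effect: metrics each round + paired tests.

    Binary calls serve as ROC scores (two-point ROC), so reader AUC =
    (sensitivity + specificity) / 2.
    """
    r1 = np.asarray(round1_calls).astype(int)
    r2 = np.asarray(round2_calls).astype(int)
    labels = np.asarray(labels).astype(int)
    if not (r1.shape == r2.shape == labels.shape):
        raise ValueError("rounds must be paired on the same cases")
    rep1 = eval_report(r1, r1, labels, cohort="round1")
    rep2 = eval_report(r2, r2, labels, cohort="round2")
    _, p_auc, *_ = delong_test(r2, r1, labels)
    p_acc = mcnemar_test(r2, r1, labels)
    return {
        "round1": rep1,
        "round2": rep2,
        "delta_auc": rep2.auc - rep1.auc,
        "delta_accuracy": rep2.accuracy - rep1.accuracy,
        "p_auc_delong": p_auc,
        "p_accuracy_mcnemar": p_acc,
    }


def _stratum_metrics(calls: np.ndarray, labels: np.ndarray) -> dict:
    tp = int(((calls == 1) & (labels == 1)).sum())
    tn = int(((calls == 0) & (labels == 0)).sum())
    fp = int(((calls == 1) & (labels == 0)).sum())
    fn = int(((calls == 0) & (labels == 1)).sum())
    n = tp + tn + fp + fn

    def safe(num, den):
        return num / den if den > 0 else None  # undefined, flagged as null

    return {
        "n": n,
        "accuracy": safe(tp + tn, n),
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "ppv": safe(tp, tp + fp),
        "npv": safe(tn, tn + fn),
    }


def per_score_metrics(scores, reader_calls, model_calls, labels) -> pd.DataFrame:
    """Reader vs model metrics within each Node-RADS stratum (1..5).

    Undefined metrics in small strata are reported as nulls, never 0.
    """
    scores = np.asarray(scores).astype(int)
    reader_calls = np.asarray(reader_calls).astype(int)
    model_calls = np.asarray(model_calls).astype(int)
    labels = np.asarray(labels).astype(int)
    rows = []
    for s in range(1, 6):
        sel = scores == s
        for who, calls in (("reader", reader_calls), ("model", model_calls)):
            row = {"rads_score": s, "rater": who}
            if sel.sum() == 0:
                row.update(
                    {"n": 0, "accuracy": None, "sensitivity": None,
                     "specificity": None, "ppv": None, "npv": None}
                )
            else:
                row.update(_stratum_metrics(calls[sel], labels[sel]))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ReclassificationTable:
    """Counts indexed by (rads_score, model call, true label)."""

    counts: pd.DataFrame
    reclassified_positive: list = field(default_factory=list)  # score 1-2, model 1
    reclassified_negative: list = field(default_factory=list)  # score 3-5, model 0


@dataclass
class SankeyData:
    nodes: list[dict]
    links: list[dict]

    def check_conservation(self) -> bool:
        """Inbound = outbound at every intermediate node."""
        inbound: dict[int, int] = {}
        outbound: dict[int, int] = {}
        for link in self.links:
            outbound[link["source"]] = outbound.get(link["source"], 0) + link["count"]
            inbound[link["target"]] = inbound.get(link["target"], 0) + link["count"]
        for node in self.nodes:
            if node["stage"] == "model":
                if inbound.get(node["id"], 0) != outbound.get(node["id"], 0):
                    return False
        return True


def sankey_data(scores, model_calls, labels, case_ids=None):
    """Score -> model-call -> outcome flows plus the reclassification table.

    Reclassified-positive: score in {1, 2} with model call 1;
    reclassified-negative: score in {3, 4, 5} with model call 0.
    """
    scores = np.asarray(scores).astype(int)
    model_calls = np.asarray(model_calls).astype(int)
    labels = np.asarray(labels).astype(int)
    if case_ids is None:
        case_ids = list(range(len(scores)))
    rads_binarize(scores)  # validates range

    nodes = []
    node_id = {}
    for s in range(1, 6):
        node_id[f"score{s}"] = len(nodes)
        nodes.append({"id": len(nodes), "name": f"Node-RADS {s}", "stage": "score"})
    for c in (0, 1):
        node_id[f"model{c}"] = len(nodes)
        nodes.append({"id": len(nodes), "name": f"model {'+' if c else '-'}", "stage": "model"})
    for o in ("correct", "incorrect"):
        node_id[o] = len(nodes)
        nodes.append({"id": len(nodes), "name": o, "stage": "outcome"})

    link_counts: dict[tuple[int, int, str], int] = {}
    recls_pos, recls_neg = [], []
    for cid, s, m, y in zip(case_ids, scores, model_calls, labels):
        if s <= 2 and m == 1:
            flow1 = "reclassified-positive"
            recls_pos.append(cid)
        elif s >= 3 and m == 0:
            flow1 = "reclassified-negative"
            recls_neg.append(cid)
        else:
            flow1 = "correct" if m == y else "incorrect"
        key1 = (node_id[f"score{s}"], node_id[f"model{m}"], flow1)
        link_counts[key1] = link_counts.get(key1, 0) + 1
        outcome = "correct" if m == y else "incorrect"
        key2 = (node_id[f"model{m}"], node_id[outcome], outcome)
        link_counts[key2] = link_counts.get(key2, 0) + 1

    links = [
        {"source": s, "target": t, "count": c, "flow": f}
        for (s, t, f), c in sorted(link_counts.items())
    ]
    counts = pd.DataFrame(
        {"rads_score": scores, "model_call": model_calls, "label": labels}
    ).value_counts().rename("count").reset_index()
    table = ReclassificationTable(
        counts=counts, reclassified_positive=recls_pos, reclassified_negative=recls_neg
    )
    return SankeyData(nodes=nodes, links=links), table
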