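#!/usr/bin/env python
"""Screen features, train HR/CR/combined SVM models and compare them.

Reads results/features.csv (run 03_extract_features.py first), splits 4:1
(stratified, seeded), runs the screening chain per feature set, trains an
RBF-SVM per set with CV-tuned hyperparameters and a training Youden cutoff,
and reports validation AUC/accuracy plus pairwise DeLong tests and
decision-curve tables.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from habikit.features import split_feature_sets
from habikit.models import ModelSpec, predict, tune_and_train
from habikit.pipeline import _stratified_split
from habikit.selection import SelectionConfig, run_selection
from habikit.stats import dca, delong_test, eval_report, pr_auc

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    table = pd.read_csv(OUT / "features.csv", index_col=0)
    labels = pd.read_csv(OUT / "labels.csv").set_index("case_id").loc[table.index, "label"].values

    tr, va = _stratified_split(labels, 0.8, SEED)
    sets = split_feature_sets(table.columns)
    models, preds, rows = {}, {}, []
    for name in ("HR", "CR", "combined"):
        sel = run_selection(
            table.iloc[tr][sets[name]], labels[tr], config=SelectionConfig(seed=SEED)
        )
        model = tune_and_train(
            table.iloc[tr], labels[tr],
            ModelSpec(algorithm="svm", cv_folds=10, seed=SEED),
            features=sel.kept, feature_set=name,
        )
        models[name] = model
        for cohort, idx in (("training", tr), ("validation", va)):
            p = predict(model, table.iloc[idx], cohort=cohort)
            preds[(name, cohort)] = (p, labels[idx])
            rep = eval_report(p.scores, p.calls, labels[idx], cohort=cohort)
            rows.append(
                {"model": name, "n_features": len(sel.kept), **rep.as_dict(),
                 "pr_auc": pr_auc(p.scores, labels[idx])}
            )
            dca(p.scores, labels[idx]).as_frame().to_csv(
                OUT / f"dca_{name}_{cohort}.csv", index=False
            )

    report = pd.DataFrame(rows)
    report.to_csv(OUT / "model_reports.csv", index=False)
    print(report[["model", "cohort", "n_features", "auc", "accuracy",
                  "sensitivity", "specificity"]].round(3).to_string(index=False))

    delong = {}
    for a, b in (("HR", "CR"), ("HR", "combined"), ("CR", "combined")):
        (pa, ya), (pb, _) = preds[(a, "validation")], preds[(b, "validation")]
        z, p, auc_a, auc_b = delong_test(pa.scores, pb.scores, ya)
        delong[f"{a}_vs_{b}"] = {"z": z, "p": p, "auc_a": auc_a, "auc_b": auc_b}
        print(f"DeLong {a} vs {b} (validation): "
              f"AUC {auc_a:.3f} vs {auc_b:.3f}, p = {p:.3f}")
    (OUT / "delong_tests.json").write_text(json.dumps(delong, indent=2))

    kept = {n: models[n].features for n in models}
    (OUT / "selected_features.json").write_text(json.dumps(kept, indent=2))
    print(f"reports -> {OUT / 'model_reports.csv'}")


if __name__ == "__main__":
    main()
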