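#!/usr/bin/env python
"""Shapley attributions for the HR model on the demo cohort.

Retrains the HR model on the training split (same seed as script 04), then
computes kernel Shapley values for the validation cases against a medoid
background, printing the top-five global features and exporting the tidy
tables behind bar / summary / heatmap / stacked-force displays.
"""

import json
from pathlib import Path

import pandas as pd

from habikit.explain import export_plots_data, medoid_background, rank_features, shapley_values
from habikit.features import split_feature_sets
from habikit.models import ModelSpec, tune_and_train
from habikit.pipeline import _stratified_split
from habikit.selection import SelectionConfig, run_selection

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    table = pd.read_csv(OUT / "features.csv", index_col=0)
    labels = pd.read_csv(OUT / "labels.csv").set_index("case_id").loc[table.index, "label"].values

    tr, va = _stratified_split(labels, 0.8, SEED)
    hr_cols = split_feature_sets(table.columns)["HR"]
    sel = run_selection(table.iloc[tr][hr_cols], labels[tr], config=SelectionConfig(seed=SEED))
    model = tune_and_train(
        table.iloc[tr], labels[tr], ModelSpec(algorithm="svm", cv_folds=10, seed=SEED),
        features=sel.kept, feature_set="HR",
    )

    background = medoid_background(table.iloc[tr][model.features], max_rows=30, seed=SEED)
    explained = table.iloc[va][model.features]
    expl = shapley_values(model, background, explained, n_samples=2048, seed=SEED)
    assert expl.check_local_accuracy(), "local accuracy violated"

    ranking = rank_features(expl)
    print(f"explained {len(explained)} validation cases over {len(model.features)} "
          f"HR features (base value {expl.base_value:.3f})")
    print("top five features by mean |SHAP|:")
    for name, imp in ranking.head(5).items():
        sign = expl.contributions[name].mean()
        direction = "raises" if sign > 0 else "lowers"
        print(f"  {name}: {imp:.4f} (on average {direction} the LNM score)")

    tables = export_plots_data(expl)
    for key in ("bar", "summary", "heatmap", "force"):
        tables[key].to_csv(OUT / f"shap_{key}.csv", index=False)
    (OUT / "shap_base.json").write_text(json.dumps({"base_value": expl.base_value}))
    print(f"SHAP tables -> {OUT}/shap_*.csv")


if __name__ == "__main__":
    main()
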