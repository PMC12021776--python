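"""End-to-end orchestration: simulate/load -> preprocess -> habitats ->
features -> select -> train -> evaluate -> explain -> readers.

``run_all`` executes the eight computational stages in order from one
config, writing each stage's outputs (CSV/JSON) under the output directory
before the next stage starts and recording input/output hashes, timings and
the config echo in a run manifest.  A single cohort is split 4:1 into
training and validation by seeded stratified sampling; selection and model
fitting consume the training split only, which the manifest records for
audit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import synthetic
from .explain import export_plots_data, medoid_background, rank_features, shapley_values
from .features import DEFAULT_CONFIG, FeatureConfig, extract_table, split_feature_sets
from .habitats import compute_habitats
from .models import ModelSpec, predict, tune_and_train
from .preprocessing import check_alignment, resample
from .readers import compare_rounds, consensus_from_assessments
from .selection import SelectionConfig, run_selection
from .stats import dca, eval_report, hosmer_lemeshow, pr_auc
from .synthetic import CohortEffect, CohortSpec, ReaderSpec, simulate_readers

__all__ = ["RunConfig", "RunManifest", "STAGES", "run_all", "run_stage", "holdout_auc"]

log = logging.getLogger("habikit")

STAGES = (
    "preprocess",
    "habitats",
    "features",
    "select",
    "train",
    "evaluate",
    "explain",
    "readers",
)


@dataclass
class RunConfig:
    out_dir: str = "habikit_run"
    seed: int = 42
    # synthetic cohort (used when no case manifest is supplied)
    n_cases: int = 250
    prevalence: float = 0.59
    effect: CohortEffect = field(default_factory=lambda: synthetic.STRONG_EFFECT)
    # preprocessing
    target_spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)
    do_resample: bool = False          # synthetic phantoms are born on-grid
    bin_width: float = 25.0
    # habitats
    k: Optional[int] = 3               # fixed k (None -> CH selection per case)
    k_range: tuple[int, int] = (2, 10)
    # modeling
    feature_sets: tuple[str, ...] = ("HR", "CR", "combined")
    algorithm: str = "svm"
    cv_folds: int = 50
    # selection thresholds
    icc_threshold: float = 0.75
    alpha: float = 0.05
    corr_threshold: float = 0.9
    # reader simulation
    simulate_readers: bool = False
    # explanation
    n_shap_cases: int = 10
    n_shap_samples: int = 2048
    split_ratio: float = 0.8           # 4:1 training/validation


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)  # name -> {hash, seconds, ...}
    training_cases: list = field(default_factory=list)
    validation_cases: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict_safe(self), indent=2, default=str))


def asdict_safe(obj) -> dict:
    d = asdict(obj)
    return d


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df.round(12), index=True).values.tobytes()
    ).hexdigest()[:16]


def _stratified_split(labels: np.ndarray, ratio: float, seed: int):
    """Seeded stratified index split (ratio = training share)."""
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        cut = int(round(ratio * len(idx)))
        train_idx.extend(idx[:cut])
        val_idx.extend(idx[cut:])
    return np.sort(train_idx), np.sort(val_idx)


class PipelineState:
    """In-memory artifacts passed between stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.cases = None
        self.labels = None
        self.habitat_maps = None
        self.table = None
        self.selection = {}
        self.models = {}
        self.predictions = {}
        self.reports = {}
        self.manifest = RunManifest(config=asdict(config))


def _simulate(state: PipelineState) -> None:
    cfg = state.config
    spec = CohortSpec(
        n_cases=cfg.n_cases, prevalence=cfg.prevalence, effect=cfg.effect, seed=cfg.seed
    )
    cases, labels, truths, meta = synthetic.generate_cohort(spec)
    state.cases, state.labels = cases, labels
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta.to_csv(out / "cohort_meta.csv")


def stage_preprocess(state: PipelineState) -> None:
    cfg = state.config
    if state.cases is None:
        _simulate(state)
    checked = []
    for case in state.cases:
        case = check_alignment(case)
        if cfg.do_resample:
            case = resample(case, cfg.target_spacing)
        checked.append(case)
    state.cases = checked


def stage_habitats(state: PipelineState) -> None:
    cfg = state.config
    if state.cases is None:
        raise RuntimeError("missing upstream artifact: preprocessed cases")
    k_range = range(cfg.k_range[0], cfg.k_range[1] + 1)
    state.habitat_maps = [
        compute_habitats(case, k=cfg.k, k_range=k_range, seed=cfg.seed)[0]
        for case in state.cases
    ]


def stage_features(state: PipelineState) -> None:
    cfg = state.config
    if state.habitat_maps is None:
        raise RuntimeError("missing upstream artifact: habitat maps")
    fconfig = FeatureConfig(bin_width=cfg.bin_width)
    table, flags = extract_table(state.cases, state.habitat_maps, fconfig, which="combined")
    state.table = table
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "features.csv")
    (out / "features.json").write_text(
        json.dumps({"config_hash": fconfig.config_hash(), "flags": flags}, indent=2)
    )


def stage_select(state: PipelineState) -> None:
    cfg = state.config
    if state.table is None:
        raise RuntimeError("missing upstream artifact: feature table")
    labels = np.asarray(state.labels)
    tr, va = _stratified_split(labels, cfg.split_ratio, cfg.seed)
    state.train_idx, state.val_idx = tr, va
    state.manifest.training_cases = [state.table.index[i] for i in tr]
    state.manifest.validation_cases = [state.table.index[i] for i in va]
    sets = split_feature_sets(state.table.columns)
    sel_cfg = SelectionConfig(
        icc_threshold=cfg.icc_threshold, alpha=cfg.alpha,
        corr_threshold=cfg.corr_threshold, seed=cfg.seed,
    )
    train_table = state.table.iloc[tr]
    for name in cfg.feature_sets:
        state.selection[name] = run_selection(
            train_table[sets[name]], labels[tr], config=sel_cfg
        )
    out = Path(cfg.out_dir)
    (out / "selection.json").write_text(
        json.dumps(
            {k: {"kept": v.kept, "steps": v.steps} for k, v in state.selection.items()},
            indent=2,
        )
    )


def stage_train(state: PipelineState) -> None:
    cfg = state.config
    if not state.selection:
        raise RuntimeError("missing upstream artifact: selection results")
    labels = np.asarray(state.labels)
    tr = state.train_idx
    for name, sel in state.selection.items():
        spec = ModelSpec(algorithm=cfg.algorithm, cv_folds=cfg.cv_folds, seed=cfg.seed)
        state.models[name] = tune_and_train(
            state.table.iloc[tr], labels[tr], spec,
            features=sel.kept, feature_set=name,
        )


def stage_evaluate(state: PipelineState) -> None:
    cfg = state.config
    if not state.models:
        raise RuntimeError("missing upstream artifact: trained models")
    labels = np.asarray(state.labels)
    rows = []
    for name, model in state.models.items():
        for cohort, idx in (("training", state.train_idx), ("validation", state.val_idx)):
            pred = predict(model, state.table.iloc[idx], cohort=cohort)
            state.predictions[(name, cohort)] = pred
            rep = eval_report(pred.scores, pred.calls, labels[idx], cohort=cohort)
            extras = {"pr_auc": pr_auc(pred.scores, labels[idx])}
            if len(idx) >= 30 and len(np.unique(pred.scores)) >= 3:
                extras["hl_p"] = hosmer_lemeshow(pred.scores, labels[idx]).p_value
            rows.append({"model": name, **rep.as_dict(), **extras})
            dca(pred.scores, labels[idx]).as_frame().to_csv(
                Path(cfg.out_dir) / f"dca_{name}_{cohort}.csv", index=False
            )
    state.reports["models"] = pd.DataFrame(rows)
    state.reports["models"].to_csv(Path(cfg.out_dir) / "model_reports.csv", index=False)


def stage_explain(state: PipelineState) -> None:
    cfg = state.config
    if not state.predictions:
        raise RuntimeError("missing upstream artifact: predictions")
    name = "HR" if "HR" in state.models else list(state.models)[0]
    model = state.models[name]
    train = state.table.iloc[state.train_idx][model.features]
    background = medoid_background(train, max_rows=50, seed=cfg.seed)
    explained = state.table.iloc[state.val_idx][model.features].head(cfg.n_shap_cases)
    if len(explained) == 0:
        explained = train.head(cfg.n_shap_cases)
    expl = shapley_values(
        model, background, explained, n_samples=cfg.n_shap_samples, seed=cfg.seed
    )
    out = Path(cfg.out_dir)
    tables = export_plots_data(expl)
    tables["bar"].to_csv(out / "shap_importance.csv", index=False)
    tables["summary"].to_csv(out / "shap_values.csv", index=False)
    (out / "shap_base.json").write_text(json.dumps({"base_value": expl.base_value}))
    state.reports["shap_rank"] = rank_features(expl)


def stage_readers(state: PipelineState) -> None:
    cfg = state.config
    if not cfg.simulate_readers:
        state.reports["readers"] = None
        return
    if not state.predictions:
        raise RuntimeError("missing upstream artifact: predictions")
    labels = np.asarray(state.labels)[state.val_idx]
    case_ids = [state.table.index[i] for i in state.val_idx]
    specs = [
        ReaderSpec("junior1", "junior", "empirical", 0.50, 0.80, seed=cfg.seed + 1),
        ReaderSpec("senior1", "senior", "empirical", 0.65, 0.82, seed=cfg.seed + 2),
        ReaderSpec("junior2", "junior", "RADS", seed=cfg.seed + 3),
    ]
    r1 = simulate_readers(labels, specs, round_id=1, case_ids=case_ids)
    # assisted round: empirical readers shift toward the model's calls
    assisted = [
        ReaderSpec(s.reader_id, s.seniority, s.group,
                   min(1.0, s.sensitivity + 0.2), min(1.0, s.specificity + 0.03),
                   seed=s.seed + 100)
        for s in specs
    ]
    r2 = simulate_readers(labels, assisted, round_id=2, case_ids=case_ids)
    both = pd.concat([r1, r2], ignore_index=True)
    both.to_csv(Path(cfg.out_dir) / "readers.csv", index=False)
    cons = consensus_from_assessments(both)
    rows = []
    for reader_id, grp in cons.groupby("reader_id"):
        g1 = grp[grp["round"] == 1].set_index("case_id").loc[case_ids]
        g2 = grp[grp["round"] == 2].set_index("case_id").loc[case_ids]
        cmp = compare_rounds(g1["call"].values, g2["call"].values, labels)
        rows.append(
            {"reader_id": reader_id, "auc_round1": cmp["round1"].auc,
             "auc_round2": cmp["round2"].auc, "p_auc": cmp["p_auc_delong"],
             "p_accuracy": cmp["p_accuracy_mcnemar"]}
        )
    state.reports["readers"] = pd.DataFrame(rows)
    state.reports["readers"].to_csv(Path(cfg.out_dir) / "reader_reports.csv", index=False)


_STAGE_FUNCS = {
    "preprocess": stage_preprocess,
    "habitats": stage_habitats,
    "features": stage_features,
    "select": stage_select,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "explain": stage_explain,
    "readers": stage_readers,
}


def run_stage(state: PipelineState, stage: str) -> PipelineState:
    """Execute one named stage (upstream artifacts must already exist)."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    t0 = time.perf_counter()
    log.info("stage=%s event=start", stage)
    _STAGE_FUNCS[stage](state)
    elapsed = time.perf_counter() - t0
    entry = {"seconds": round(elapsed, 3)}
    if stage == "features" and state.table is not None:
        entry["features_hash"] = _hash_frame(state.table)
    state.manifest.stages[stage] = entry
    log.info("stage=%s event=done seconds=%.2f", stage, elapsed)
    return state


def run_all(config: RunConfig) -> PipelineState:
    """Run all eight stages in order; returns the populated state."""
    state = PipelineState(config)
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        run_stage(state, stage)
    state.manifest.save(Path(config.out_dir) / "manifest.json")
    return state


def holdout_auc(
    n_cases: int = 250,
    effect: CohortEffect = synthetic.STRONG_EFFECT,
    seed: int = 42,
    feature_set: str = "HR",
    out_dir: Optional[str] = None,
    algorithm: str = "svm",
    cv_folds: int = 10,
) -> float:
    """Full-pipeline held-out AUC on one synthetic cohort (recovery metric)."""
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        cfg = RunConfig(
            out_dir=out_dir or tmp, seed=seed, n_cases=n_cases, effect=effect,
            feature_sets=(feature_set,), algorithm=algorithm, cv_folds=cv_folds,
            n_shap_cases=0,
        )
        state = PipelineState(cfg)
        for stage in ("preprocess", "habitats", "features", "select", "train", "evaluate"):
            run_stage(state, stage)
        rep = state.reports["models"]
        row = rep[(rep["model"] == feature_set) & (rep["cohort"] == "validation")]
        return float(row["auc"].iloc[0])
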