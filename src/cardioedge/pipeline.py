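"""End-to-end pipeline orchestration: records -> samples -> features ->
trained, selected, exported model, with evaluation artifacts.

``run_benchmark`` is the reference workflow on the built-in synthetic
dataset and is what the acceptance script executes. The default sizes
(300 windows per class from 15 synthetic patients each, gamma = 3
candidate models of eta = 10 features, 5 outer and 3 inner folds) keep a
full run on one CPU in the minutes range while exercising every stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cardioedge.delineation import UnfeaturizableError
from cardioedge.denoising import VmdConfig, vmd_denoise
from cardioedge.evaluation import MetricsReport, evaluate_predictions
from cardioedge.features import FEATURE_NAMES, featurize
from cardioedge.io_formats import RHYTHM_LABELS, EcgRecord
from cardioedge.preprocessing import EcgSample, preprocess_record
from cardioedge.synthetic_ecg import generate_labeled_dataset
from cardioedge.training import (
    ModelCandidate,
    SeedBank,
    TrainingConfig,
    grouped_stratified_split,
    make_candidate_subsets,
    nested_optimize,
    select_best,
    shuffle_without_adjacency,
    train_baseline_logreg,
)


@dataclass
class FeatureTable:
    """Featurized samples plus the metadata the split rules need."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray  # "(patient_id|record_id)" strings
    meta: list[dict]
    n_skipped: int = 0


def preprocess_records(records: list[EcgRecord]) -> list[EcgSample]:
    out: list[EcgSample] = []
    for rec in records:
        out.extend(preprocess_record(rec))
    return out


def build_feature_table(
    samples: list[EcgSample],
    denoise: bool = True,
    vmd_config: VmdConfig | None = None,
) -> FeatureTable:
    """Denoise (gated) and featurize samples; unfeaturizable ones are skipped."""
    rows, labels, groups, meta = [], [], [], []
    skipped = 0
    for s in samples:
        data = s.data
        if denoise:
            data, _ = vmd_denoise(data, vmd_config, fs=s.fs)
        try:
            rows.append(featurize(data, fs=s.fs))
        except UnfeaturizableError:
            skipped += 1
            continue
        labels.append(s.label)
        groups.append(f"{s.patient_id}|{s.record_id}")
        meta.append(
            {
                "database_id": s.database_id,
                "patient_id": s.patient_id,
                "record_id": s.record_id,
                "lead": s.lead,
                "window_index": s.window_index,
            }
        )
    if not rows:
        raise ValueError("no featurizable samples")
    return FeatureTable(
        X=np.vstack(rows),
        y=np.asarray(labels),
        groups=np.asarray(groups),
        meta=meta,
        n_skipped=skipped,
    )


@dataclass
class TrainingRun:
    """Everything produced by one training run."""

    selected: ModelCandidate
    candidates: list[ModelCandidate]
    baseline: object
    train_idx: np.ndarray
    holdout_idx: np.ndarray
    seed_bank: SeedBank
    holdout_report: MetricsReport | None = None
    cv_report: MetricsReport | None = None
    baseline_micro_auroc: float | None = None


def run_training(
    table: FeatureTable,
    config: TrainingConfig | None = None,
    seed: int = 0,
    seed_bank: SeedBank | None = None,
) -> TrainingRun:
    """The full candidate-generation / nested-optimization / selection flow."""
    config = config or TrainingConfig()
    bank = seed_bank or SeedBank(seed)

    train_idx, holdout_idx = grouped_stratified_split(
        table.y, table.groups, config.test_fraction, seed=bank.get("outer_split_80_20")
    )
    train_idx = shuffle_without_adjacency(
        train_idx, table.meta, seed=bank.get("train_shuffle")
    )
    Xtr, ytr, gtr = table.X[train_idx], table.y[train_idx], table.groups[train_idx]
    Xho, yho = table.X[holdout_idx], table.y[holdout_idx]

    subsets = make_candidate_subsets(config.gamma, config.eta, seed=bank.get("subsets"))
    candidates = [ModelCandidate(feature_subset=sub) for sub in subsets]
    for ci, cand in enumerate(candidates):
        nested_optimize(cand, Xtr, ytr, gtr, config, bank, name=f"cand{ci}")
    selected = select_best(candidates, Xho, yho, config.f1_threshold)
    baseline = train_baseline_logreg(Xtr, ytr, seed=bank.get("baseline"))

    run = TrainingRun(
        selected=selected,
        candidates=candidates,
        baseline=baseline,
        train_idx=train_idx,
        holdout_idx=holdout_idx,
        seed_bank=bank,
    )

    def _aligned_proba(model, X):
        # sklearn orders predict_proba columns by sorted class labels;
        # realign to the canonical rhythm order used by the evaluators
        proba = model.predict_proba(X)
        order = [list(model.classes_).index(c) for c in RHYTHM_LABELS]
        return proba[:, order]

    cols = selected.feature_indices
    pred_ho = selected.model.predict(Xho[:, cols])
    scores_ho = _aligned_proba(selected.model, Xho[:, cols])
    run.holdout_report = evaluate_predictions(yho, pred_ho, scores_ho)
    base_scores = _aligned_proba(baseline, Xho)
    base_report = evaluate_predictions(yho, baseline.predict(Xho), base_scores)
    run.baseline_micro_auroc = base_report.micro_auroc
    return run


def run_benchmark(
    n_per_class: int = 300,
    patients_per_class: int = 15,
    gamma: int = 3,
    eta: int = 10,
    outer_folds: int = 5,
    inner_folds: int = 3,
    seed: int = 0,
) -> dict:
    """Generate the synthetic benchmark, run the whole pipeline, and return
    the headline numbers."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = generate_labeled_dataset(
            n_per_class=n_per_class, patients_per_class=patients_per_class, seed=seed
        )
        samples = preprocess_records(records)
        table = build_feature_table(samples)
        config = TrainingConfig(
            gamma=gamma, eta=eta, outer_folds=outer_folds, inner_folds=inner_folds
        )
        run = run_training(table, config, seed=seed)

    sel = run.selected
    rep = run.holdout_report
    importances = sorted(sel.importances.items(), key=lambda kv: -kv[1])
    return {
        "table": table,
        "run": run,
        "selected_features": sel.feature_subset,
        "hyperparameters": sel.hyperparameters,
        "cv_macro_f1": float(np.mean(sel.cv_mean_f1)),
        "cv_f1": {c: float(v) for c, v in zip(RHYTHM_LABELS, sel.cv_mean_f1)},
        "holdout_f1": {c: rep.per_class[c]["f1"] for c in RHYTHM_LABELS},
        "holdout_macro_f1": rep.macro_f1,
        "selection_macro_f1": sel.selection_macro_f1(),
        "micro_auroc_tree": rep.micro_auroc,
        "micro_auroc_baseline": run.baseline_micro_auroc,
        "top_importances": importances[:3],
        "n_samples": len(table.y),
        "n_skipped": table.n_skipped,
    }
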