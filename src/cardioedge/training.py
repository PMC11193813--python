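"""Triple-nested self-optimizing decision-tree training.

The scheme trains and compares gamma candidate models, each tracking a
random subset of eta of the 17 features:

1. grouped stratified 80/20 split into outer-train and holdout sets — no
   (patient, record) group ever straddles a split;
2. outer 10-fold grouped stratified cross-validation for performance
   estimation;
3. inner 3-fold cross-validation driving a randomized search over the
   hyperparameter grid, refined by a local grid search around the
   randomized optimum, scored by macro-F1.

Per-outer-fold per-class F1 is recorded; the candidate is refit on the full
training set with the modal best hyperparameters. Selection first gates on
a per-class F1 threshold (0.75) and then maximizes the macro-F1 computed as
the class-wise mean of the average of CV-mean and holdout F1. A seeded
shuffle with repair keeps temporally adjacent windows of the same
record/lead from sitting next to each other in training arrays. Every
stochastic step draws a named seed from a persistable seed bank, making
runs bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import (
    GridSearchCV,
    RandomizedSearchCV,
    StratifiedGroupKFold,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from cardioedge.features import FEATURE_NAMES, N_FEATURES
from cardioedge.io_formats import RHYTHM_LABELS

#: search grid; contains the selected operating point
#: (entropy, depth 9, split 30, leaf 5)
DEFAULT_GRID: dict[str, list] = {
    "criterion": ["entropy"],
    "max_depth": [3, 5, 7, 9, 11, 13],
    "min_samples_split": [2, 10, 30, 50],
    "min_samples_leaf": [1, 5, 10, 20],
}


class NoSurvivorError(RuntimeError):
    """No candidate passed the per-class F1 threshold gate."""


class SeedBank:
    """Named, persistable seeds for every stochastic step of a run.

    Seeds are derived deterministically from a master seed and the step
    name, so two runs with the same bank (or same master seed) reproduce
    identical splits, subsets and searches.
    """

    def __init__(self, master_seed: int = 0, seeds: dict[str, int] | None = None):
        self.master_seed = int(master_seed)
        self.seeds: dict[str, int] = dict(seeds or {})

    def get(self, name: str) -> int:
        if name not in self.seeds:
            digest = hashlib.blake2b(
                f"{self.master_seed}:{name}".encode(), digest_size=4
            ).digest()
            self.seeds[name] = int.from_bytes(digest, "big") % (2**31)
        return self.seeds[name]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"master_seed": self.master_seed, "seeds": self.seeds}, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "SeedBank":
        d = json.loads(Path(path).read_text())
        return cls(d["master_seed"], d["seeds"])


@dataclass
class TrainingConfig:
    gamma: int = 3
    eta: int = 10
    outer_folds: int = 10
    inner_folds: int = 3
    test_fraction: float = 0.2
    f1_threshold: float = 0.75
    random_draws: int = 25
    grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})

    def __post_init__(self) -> None:
        if not 1 <= self.eta <= N_FEATURES:
            raise ValueError(f"eta must lie in [1, {N_FEATURES}]")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")


@dataclass
class ModelCandidate:
    """One candidate: feature subset, tuned tree and its scores."""

    feature_subset: tuple[str, ...]
    hyperparameters: dict = field(default_factory=dict)
    model: DecisionTreeClassifier | None = None
    fold_f1: np.ndarray | None = None  # (outer_folds, n_classes)
    cv_mean_f1: np.ndarray | None = None
    cv_sd_f1: np.ndarray | None = None
    holdout_f1: np.ndarray | None = None
    importances: dict[str, float] = field(default_factory=dict)
    classes: tuple[str, ...] = tuple(RHYTHM_LABELS)

    @property
    def feature_indices(self) -> list[int]:
        return [FEATURE_NAMES.index(f) for f in self.feature_subset]

    def selection_macro_f1(self) -> float:
        """Class-wise mean of the average of CV-mean and holdout F1."""
        return float(np.mean((self.cv_mean_f1 + self.holdout_f1) / 2.0))


# ---------------------------------------------------------------------------
# splitting and shuffling


def grouped_stratified_split(
    y: np.ndarray,
    groups: np.ndarray,
    fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Grouped stratified train/holdout split by sample index.

    No group straddles the split; class proportions are preserved as far as
    group sizes permit. Returns (train_idx, holdout_idx).
    """
    n_splits = max(2, int(round(1.0 / fraction)))
    min_groups = min(
        len(set(groups[y == label])) for label in np.unique(y)
    )
    if min_groups < n_splits:
        warnings.warn(
            f"only {min_groups} groups in the rarest class; holdout will be "
            f"coarser than the requested fraction {fraction}"
        )
        n_splits = max(2, min_groups)
    sgkf = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    train_idx, holdout_idx = next(sgkf.split(np.zeros(len(y)), y, groups))
    return train_idx, holdout_idx


def _temporally_adjacent(a: dict, b: dict) -> bool:
    return (
        a["record_id"] == b["record_id"]
        and a["lead"] == b["lead"]
        and abs(a["window_index"] - b["window_index"]) == 1
    )


def shuffle_without_adjacency(
    indices: np.ndarray, meta: list[dict], seed: int = 0, max_passes: int = 50
) -> np.ndarray:
    """Seeded shuffle with repair so no two temporally consecutive windows of
    the same record/lead end up adjacent in the output order."""
    rng = np.random.default_rng(seed)
    order = np.array(indices, dtype=int)
    rng.shuffle(order)
    for _ in range(max_passes):
        bad = [
            i
            for i in range(len(order) - 1)
            if _temporally_adjacent(meta[order[i]], meta[order[i + 1]])
        ]
        if not bad:
            break
        for i in bad:
            j = int(rng.integers(0, len(order)))
            order[i], order[j] = order[j], order[i]
    return order


def make_candidate_subsets(
    gamma: int, eta: int, seed: int = 0
) -> list[tuple[str, ...]]:
    """Draw gamma random subsets of eta distinct features.

    Subsets are pairwise distinct whenever C(17, eta) allows; otherwise
    duplicates are permitted with a warning.
    """
    rng = np.random.default_rng(seed)
    n_possible = comb(N_FEATURES, eta)
    if gamma > n_possible:
        warnings.warn(
            f"gamma={gamma} exceeds the {n_possible} distinct subsets of "
            f"size {eta}; duplicates allowed"
        )
    subsets: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    attempts = 0
    while len(subsets) < gamma:
        pick = tuple(
            FEATURE_NAMES[i] for i in sorted(rng.choice(N_FEATURES, eta, replace=False))
        )
        attempts += 1
        if pick in seen and len(seen) < n_possible and attempts < 1000:
            continue
        seen.add(pick)
        subsets.append(pick)
    return subsets


# ---------------------------------------------------------------------------
# model fitting


def train_decision_tree(
    X: np.ndarray, y: np.ndarray, hyperparameters: dict, seed: int = 0
) -> DecisionTreeClassifier:
    """Entropy-criterion decision tree with no class weighting."""
    hp = dict(hyperparameters)
    hp.setdefault("criterion", "entropy")
    tree = DecisionTreeClassifier(class_weight=None, random_state=seed, **hp)
    tree.fit(X, y)
    return tree


def _neighborhood_grid(grid: dict, best: dict) -> dict:
    """Grid restricted to the found optimum and its immediate grid neighbors."""
    out = {}
    for key, values in grid.items():
        if key not in best or not isinstance(values, (list, tuple)):
            out[key] = list(values)
            continue
        try:
            i = values.index(best[key])
        except ValueError:
            out[key] = list(values)
            continue
        out[key] = list(dict.fromkeys(values[max(0, i - 1) : i + 2]))
    return out


def nested_optimize(
    candidate: ModelCandidate,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: TrainingConfig,
    seed_bank: SeedBank,
    name: str = "cand",
) -> ModelCandidate:
    """Outer grouped CV with an inner randomized-then-grid search per fold.

    Records the per-fold per-class F1 matrix, refits on the full training
    set with the modal best hyperparameters and stores normalized feature
    importances.
    """
    cols = candidate.feature_indices
    Xs = X[:, cols]
    classes = list(candidate.classes)
    outer = StratifiedGroupKFold(
        n_splits=config.outer_folds,
        shuffle=True,
        random_state=seed_bank.get(f"{name}/outer_split"),
    )
    fold_rows: list[np.ndarray] = []
    best_params: list[tuple] = []
    for fi, (tr, va) in enumerate(outer.split(Xs, y, groups)):
        ytr = y[tr]
        if len(np.unique(ytr)) < len(classes) or len(np.unique(y[va])) < 1:
            warnings.warn(f"outer fold {fi} missing a class; skipped")
            continue
        inner = StratifiedGroupKFold(
            n_splits=config.inner_folds,
            shuffle=True,
            random_state=seed_bank.get(f"{name}/inner_split_f{fi}"),
        )
        inner_cv = list(inner.split(Xs[tr], ytr, groups[tr]))
        base = DecisionTreeClassifier(
            class_weight=None, random_state=seed_bank.get(f"{name}/tree_f{fi}")
        )
        n_grid = int(np.prod([len(v) for v in config.grid.values()]))
        rs = RandomizedSearchCV(
            base,
            config.grid,
            n_iter=min(config.random_draws, n_grid),
            scoring="f1_macro",
            cv=inner_cv,
            random_state=seed_bank.get(f"{name}/random_search_f{fi}"),
            n_jobs=1,
        )
        rs.fit(Xs[tr], ytr)
        gs = GridSearchCV(
            base,
            _neighborhood_grid(config.grid, rs.best_params_),
            scoring="f1_macro",
            cv=inner_cv,
            n_jobs=1,
        )
        gs.fit(Xs[tr], ytr)
        params = gs.best_params_
        best_params.append(tuple(sorted(params.items())))
        fold_model = train_decision_tree(
            Xs[tr], ytr, params, seed=seed_bank.get(f"{name}/tree_f{fi}")
        )
        pred = fold_model.predict(Xs[va])
        fold_rows.append(
            f1_score(y[va], pred, labels=classes, average=None, zero_division=0.0)
        )

    if not fold_rows:
        raise RuntimeError("all outer folds skipped; dataset too small/imbalanced")
    fold_f1 = np.vstack(fold_rows)
    modal = dict(Counter(best_params).most_common(1)[0][0])
    final = train_decision_tree(
        Xs, y, modal, seed=seed_bank.get(f"{name}/final_tree")
    )
    imp = final.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    candidate.hyperparameters = modal
    candidate.model = final
    candidate.fold_f1 = fold_f1
    candidate.cv_mean_f1 = fold_f1.mean(axis=0)
    candidate.cv_sd_f1 = fold_f1.std(axis=0)
    candidate.importances = {
        f: float(w) for f, w in zip(candidate.feature_subset, imp)
    }
    return candidate


def select_best(
    candidates: list[ModelCandidate],
    X_holdout: np.ndarray,
    y_holdout: np.ndarray,
    f1_threshold: float = 0.75,
) -> ModelCandidate:
    """Threshold-gated selection maximizing the blended macro-F1.

    Candidates with any per-class CV-mean F1 below the threshold are
    rejected. Survivors are ranked by the macro-F1 (class-wise mean of the
    average of CV-mean and holdout F1); ties prefer the smaller tree, then
    the earlier candidate.
    """
    for cand in candidates:
        pred = cand.model.predict(X_holdout[:, cand.feature_indices])
        cand.holdout_f1 = f1_score(
            y_holdout, pred, labels=list(cand.classes), average=None, zero_division=0.0
        )
    survivors = [c for c in candidates if np.all(c.cv_mean_f1 >= f1_threshold)]
    if not survivors:
        raise NoSurvivorError(
            "no candidate reached the per-class F1 threshold of "
            f"{f1_threshold}; raise gamma or revise the threshold"
        )
    return min(
        enumerate(survivors),
        key=lambda ic: (
            -round(ic[1].selection_macro_f1(), 12),
            ic[1].model.tree_.node_count,
            ic[0],
        ),
    )[1]


def train_baseline_logreg(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> Pipeline:
    """Multinomial logistic-regression baseline with calibrated-probability
    outputs (rows of ``predict_proba`` sum to 1)."""
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("logreg", LogisticRegression(max_iter=2000, random_state=seed)),
        ]
    )
    pipe.fit(X, y)
    return pipe
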