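"""Random-forest discrimination of true vs false precursor detections.

Each detection carries nine (three-site) or six (two-site) wavelet band
energies as features.  Because true positives are vastly outnumbered by
false alarms, training sets are balanced either by random undersampling of
the false positives or by moderate oversampling (exact replication of the
true-positive set by an integer factor, default 4, matched by an equal
number of sampled false positives).  Forests default to 1000 trees and
classify by strict majority vote of the trees; vote ties suppress the
alarm (classified as a false positive).

The in-sample protocol is a chronological 70/30 split of each recording;
100 forests are trained on fresh false-positive samples and the forest
whose hold-out balanced accuracy is closest to the ensemble mean is kept
as the representative model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .evaluation import (ClassificationMetrics, ConfusionMatrix,
                         classification_metrics)
from .labeling import FP, ICTAL_DISCARD, TP

__all__ = [
    "FeatureTable", "SamplingPlan", "ForestModel",
    "chronological_split", "build_balanced_training_set",
    "train_random_forest", "select_representative_forest",
    "classify_events", "forest_size_curve", "balanced_accuracy",
    "save_model", "load_model", "ClassificationOutcome",
]

LABEL_TO_INT = {FP: 0, TP: 1}


@dataclass
class FeatureTable:
    """Feature matrix of labeled detections: X (n x d), y in {0:FP, 1:TP}."""

    X: np.ndarray
    y: np.ndarray
    event_times: np.ndarray | None = None
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X and y shapes are inconsistent")
        if self.X.shape[1] not in (6, 9):
            raise ValueError(
                f"feature dimension must be 6 or 9, got {self.X.shape[1]}")
        if np.any(self.X < 0) or not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite and non-negative")

    @property
    def n_tp(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_fp(self) -> int:
        return int((self.y == 0).sum())


@dataclass(frozen=True)
class SamplingPlan:
    """Class-balancing regime for training-set construction."""

    mode: str = "undersample"            # or "oversample"
    oversample_factor: int = 4           # admissible 2-7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("undersample", "oversample"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.oversample_factor < 1:
            raise ValueError("oversample factor must be >= 1")
        if self.mode == "oversample" and self.oversample_factor < 2:
            raise ValueError("oversampling requires a factor of at least 2")


def feature_matrix(events) -> np.ndarray:
    return np.stack([e.features for e in events])


def labels_binary(events) -> np.ndarray:
    return np.array([LABEL_TO_INT[e.label] for e in events], dtype=int)


def labeled_subset(events):
    """Drop ictal-discarded and unlabeled events."""
    return [e for e in events if e.label in (TP, FP)]


def chronological_split(events, duration_s: float, train_frac: float = 0.7):
    """Split labeled events at ``train_frac`` of the recording duration:
    everything earlier trains, everything later evaluates (pseudo-
    prospective; no leakage by construction)."""
    cut = train_frac * duration_s
    evs = labeled_subset(events)
    train = [e for e in evs if e.t < cut]
    heldout = [e for e in evs if e.t >= cut]
    return train, heldout


def build_balanced_training_set(events, plan: SamplingPlan,
                                recording_id: str = "") -> FeatureTable:
    """Exactly class-balanced feature table from labeled detections.

    undersample: all TPs + an equal number of FPs sampled without
    replacement.  oversample: the TP set replicated ``factor`` times +
    ``factor x n_TP`` FPs sampled without replacement.
    """
    evs = labeled_subset(events)
    tps = [e for e in evs if e.label == TP]
    fps = [e for e in evs if e.label == FP]
    if len(tps) < 5:
        raise ValueError(f"need at least 5 true positives, have {len(tps)}")
    factor = 1 if plan.mode == "undersample" else plan.oversample_factor
    n_fp_needed = factor * len(tps)
    if len(fps) < n_fp_needed:
        raise ValueError(
            f"false-positive pool too small: need {n_fp_needed}, "
            f"have {len(fps)}")
    rng = np.random.default_rng(plan.rng_seed)
    fp_idx = rng.choice(len(fps), size=n_fp_needed, replace=False)
    chosen_fp = [fps[i] for i in fp_idx]
    chosen_tp = tps * factor

    X = np.concatenate([feature_matrix(chosen_tp), feature_matrix(chosen_fp)])
    y = np.concatenate([np.ones(len(chosen_tp), dtype=int),
                        np.zeros(len(chosen_fp), dtype=int)])
    t = np.concatenate([[e.t for e in chosen_tp], [e.t for e in chosen_fp]])
    perm = rng.permutation(y.size)
    return FeatureTable(X=X[perm], y=y[perm], event_times=t[perm],
                        recording_id=recording_id)


@dataclass
class ForestModel:
    """A fitted tree ensemble classifying by strict majority vote.

    Ties (possible with even tree counts) resolve to the false-positive
    class, i.e. the alarm is suppressed.
    """

    forest: RandomForestClassifier
    n_trees: int
    seed: int
    feature_dim: int

    def vote_fraction(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting TP for each row."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.feature_dim:
            raise ValueError(
                f"expected features of dimension {self.feature_dim}, "
                f"got shape {X.shape}")
        votes = np.zeros(X.shape[0])
        for tree in self.forest.estimators_:
            votes += tree.predict(X)
        return votes / len(self.forest.estimators_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 (TP) where a strict majority of trees votes TP, else 0."""
        return (self.vote_fraction(X) > 0.5).astype(int)


def train_random_forest(table: FeatureTable, n_trees: int = 1000,
                        rng_seed: int = 0,
                        max_features: str | int = "sqrt",
                        max_depth: int | None = None) -> ForestModel:
    """Fit a random forest on a balanced feature table (deterministic
    given the seed)."""
    if len(np.unique(table.y)) < 2:
        raise ValueError("training table must contain both classes")
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features=max_features, max_depth=max_depth,
        bootstrap=True, random_state=rng_seed, n_jobs=1)
    rf.fit(table.X, table.y)
    return ForestModel(forest=rf, n_trees=n_trees, seed=rng_seed,
                       feature_dim=table.X.shape[1])


def confusion_from_predictions(y_true: np.ndarray,
                               y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionMatrix(
        fp_as_fp=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp_as_tp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tp_as_fp=int(((y_true == 1) & (y_pred == 0)).sum()),
        tp_as_tp=int(((y_true == 1) & (y_pred == 1)).sum()),
    )


def balanced_accuracy(model: ForestModel, X: np.ndarray,
                      y: np.ndarray) -> float:
    """Hold-out balanced accuracy (%) of a fitted forest."""
    cm = confusion_from_predictions(y, model.predict(X))
    return classification_metrics(cm).balanced_accuracy_pct


def select_representative_forest(train_events, eval_events,
                                 plan: SamplingPlan, n_forests: int = 100,
                                 n_trees: int = 1000, base_seed: int = 0,
                                 ) -> tuple[ForestModel, np.ndarray]:
    """Train ``n_forests`` forests on fresh false-positive samples and
    return the one whose hold-out balanced accuracy is closest to the
    ensemble mean (ties -> lower seed), plus all accuracies."""
    evs = labeled_subset(eval_events)
    X_eval, y_eval = feature_matrix(evs), labels_binary(evs)
    models, accs = [], []
    for k in range(n_forests):
        plan_k = SamplingPlan(mode=plan.mode,
                              oversample_factor=plan.oversample_factor,
                              rng_seed=base_seed + k)
        table = build_balanced_training_set(train_events, plan_k)
        model = train_random_forest(table, n_trees=n_trees,
                                    rng_seed=base_seed + k)
        models.append(model)
        accs.append(balanced_accuracy(model, X_eval, y_eval))
    accs = np.array(accs)
    best = int(np.argmin(np.abs(accs - accs.mean())))  # argmin -> lowest seed
    return models[best], accs


@dataclass
class ClassificationOutcome:
    """Result of filtering detections through a trained forest."""

    kept_events: list
    suppressed_events: list
    confusion: ConfusionMatrix | None
    fp_reduction_pct: float | None

    @property
    def metrics(self) -> ClassificationMetrics | None:
        return (classification_metrics(self.confusion)
                if self.confusion is not None else None)


def classify_events(model: ForestModel, events) -> ClassificationOutcome:
    """Suppress detections the forest calls false positives.

    Survivors are the system's final alarms.  When ground-truth labels are
    present, a confusion matrix and the percent false-alarm reduction
    (share of true FPs suppressed) are attached.
    """
    evs = [e for e in events if e.label != ICTAL_DISCARD]
    if not evs:
        return ClassificationOutcome([], [], None, None)
    X = feature_matrix(evs)
    pred = model.predict(X)
    kept = [e for e, p in zip(evs, pred) if p == 1]
    dropped = [e for e, p in zip(evs, pred) if p == 0]

    confusion = fp_red = None
    if all(e.label in (TP, FP) for e in evs):
        y = labels_binary(evs)
        confusion = confusion_from_predictions(y, pred)
        n_fp = confusion.n_fp_class
        if n_fp > 0:
            fp_red = 100.0 * confusion.fp_as_fp / n_fp
    return ClassificationOutcome(kept, dropped, confusion, fp_red)


def forest_size_curve(table: FeatureTable, sizes: Sequence[int], eval_events,
                      rng_seed: int = 0) -> list[tuple[int, float]]:
    """Hold-out balanced accuracy as a function of forest size, on common
    training data."""
    if any(s < 1 for s in sizes):
        raise ValueError("forest sizes must be >= 1")
    evs = labeled_subset(eval_events)
    X_eval, y_eval = feature_matrix(evs), labels_binary(evs)
    out = []
    for s in sorted(sizes):
        model = train_random_forest(table, n_trees=int(s), rng_seed=rng_seed)
        out.append((int(s), balanced_accuracy(model, X_eval, y_eval)))
    return out


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: ForestModel, path) -> Path:
    """Persist a forest (joblib container + JSON sidecar)."""
    import joblib

    path = Path(path)
    joblib.dump(model.forest, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "format_version": 1,
        "n_trees": model.n_trees,
        "seed": model.seed,
        "feature_dim": model.feature_dim,
    }, indent=2))
    return path


def load_model(path) -> ForestModel:
    import joblib

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    forest = joblib.load(path)
    return ForestModel(forest=forest, n_trees=meta["n_trees"],
                       seed=meta["seed"], feature_dim=meta["feature_dim"])
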