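"""Repeated stratified 70:15:15 splits and the three-layer MLP classifier.

The classifier is a backpropagation network with one logistic hidden layer
("three layers" counting input, hidden and output).  Each repeat draws an
independent stratified partition of the cohort into training (70%),
validation (15%) and test (15%) sets; features are z-scored with statistics
fitted on the training split only, the network is trained with early
stopping on validation cross-entropy, and the test split is scored once.
Metrics are averaged over repeats (a pooled-score ROC is available as an
alternative aggregate).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

from .evaluation import METRIC_NAMES, optimal_cutoff, roc_auc

__all__ = [
    "MLPConfig",
    "SplitEvaluation",
    "partition_sizes",
    "make_splits",
    "train_mlp",
    "evaluate_feature_set",
]


@dataclass(frozen=True)
class MLPConfig:
    """Training hyperparameters (defaults sized for ~100-patient cohorts)."""

    hidden_width: int = 10
    n_hidden_layers: int = 1  # "three-layer" = one hidden layer
    max_epochs: int = 500
    patience: int = 20
    learning_rate: float = 0.01


@dataclass
class SplitEvaluation:
    """One repeat: the partition, and the scores/metrics once evaluated."""

    repeat_index: int
    seed: int
    train_ids: list
    val_ids: list
    test_ids: list
    scaler: tuple | None = None  # (mean, sd) fitted on train
    test_scores: np.ndarray | None = None
    test_labels: np.ndarray | None = None
    auc: float | None = None
    cutoff: float | None = None
    metrics: dict = field(default_factory=dict)


def partition_sizes(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder rounding of ``n`` into parts proportional to ``ratios``."""
    raw = [r * n for r in ratios]
    sizes = [int(np.floor(x)) for x in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - x for s, x in zip(sizes, raw)])
    for k in order[:rem]:
        sizes[k] += 1
    return sizes


def make_splits(
    ids,
    labels,
    n_repeats: int = 100,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    min_per_class: int = 10,
) -> list[SplitEvaluation]:
    """Draw ``n_repeats`` independent stratified train/validation/test partitions.

    Stratification allocates each class across the three partitions by
    largest-remainder rounding, so every partition's positive fraction is
    within one patient of the cohort fraction.  Reproducible from ``seed``.
    """
    ids = np.asarray(ids)
    labels = np.asarray(labels)
    if abs(sum(ratios) - 1.0) > 1e-9 or len(ratios) != 3:
        raise ValueError(f"ratios must be three fractions summing to 1, got {ratios}")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < min_per_class:
        raise ValueError(
            f"smallest class has {counts.min()} patients; "
            f"need >= {min_per_class} to stratify a 70:15:15 split"
        )
    root = np.random.default_rng(seed)
    repeat_seeds = root.integers(0, 2**31 - 1, size=n_repeats)
    splits = []
    for rep, rep_seed in enumerate(repeat_seeds):
        rng = np.random.default_rng(rep_seed)
        parts: list[list] = [[], [], []]
        for cls in classes:
            # sort before permuting so splits depend on the id set, not row order
            cls_ids = np.sort(ids[labels == cls])
            perm = rng.permutation(cls_ids)
            sizes = partition_sizes(len(cls_ids), ratios)
            a, b = sizes[0], sizes[0] + sizes[1]
            parts[0].extend(perm[:a])
            parts[1].extend(perm[a:b])
            parts[2].extend(perm[b:])
        splits.append(
            SplitEvaluation(
                repeat_index=rep,
                seed=int(rep_seed),
                train_ids=sorted(parts[0]),
                val_ids=sorted(parts[1]),
                test_ids=sorted(parts[2]),
            )
        )
    return splits


def _check_finite(X: pd.DataFrame):
    bad = [c for c in X.columns if not np.isfinite(X[c].to_numpy(dtype=float)).all()]
    if bad:
        raise ValueError(f"non-finite feature values in columns {bad}")


def fit_scaler(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Train-split mean and SD for z-scoring (zero SDs replaced by 1)."""
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def train_mlp(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: MLPConfig = MLPConfig(),
    seed: int = 0,
) -> MLPClassifier:
    """Backpropagation training with early stopping on validation loss.

    One epoch per ``partial_fit`` pass; the weight state with the best
    validation cross-entropy is restored before returning.  Inputs are
    expected pre-standardized with train-split statistics.
    """
    for name, arr in (("X_train", X_train), ("X_val", X_val)):
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite values in {name}")
    clf = MLPClassifier(
        hidden_layer_sizes=(config.hidden_width,) * config.n_hidden_layers,
        activation="logistic",
        solver="adam",
        learning_rate_init=config.learning_rate,
        random_state=seed,
    )
    classes = np.array([0, 1])
    best_loss = np.inf
    best_state = None
    stale = 0
    for _epoch in range(config.max_epochs):
        clf.partial_fit(X_train, y_train, classes=classes)
        val_prob = clf.predict_proba(X_val)[:, 1]
        loss = log_loss(y_val, val_prob, labels=classes)
        if loss < best_loss - 1e-12:
            best_loss = loss
            best_state = (copy.deepcopy(clf.coefs_), copy.deepcopy(clf.intercepts_))
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        clf.coefs_, clf.intercepts_ = best_state
    return clf


def evaluate_feature_set(
    features: pd.DataFrame,
    feature_columns: list[str],
    label_column: str = "label_binary",
    id_column: str = "id",
    n_repeats: int = 100,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    config: MLPConfig = MLPConfig(),
    aggregate: str = "mean",
) -> dict:
    """Repeated-split MLP evaluation of one feature set.

    ``features`` holds one row per patient with the feature columns, a
    binary label column (1 = expansion) and an id column.  Returns a dict
    with the per-repeat table (``per_repeat``), mean/SD aggregates of AUC,
    cutoff and the confusion metrics, and — when ``aggregate="pooled"`` —
    the ROC of all test scores pooled across repeats.
    """
    df = features.reset_index(drop=True)
    X_all = df[feature_columns]
    _check_finite(X_all)
    y_all = df[label_column].to_numpy(dtype=int)
    ids = df[id_column].to_numpy()
    idx_of = {pid: k for k, pid in enumerate(ids)}

    splits = make_splits(ids, y_all, n_repeats=n_repeats, ratios=ratios, seed=seed)
    rows = []
    pooled_scores, pooled_labels = [], []
    for split in splits:
        tr = [idx_of[i] for i in split.train_ids]
        va = [idx_of[i] for i in split.val_ids]
        te = [idx_of[i] for i in split.test_ids]
        X = X_all.to_numpy(dtype=float)
        mean, sd = fit_scaler(X[tr])
        split.scaler = (mean, sd)
        Z = (X - mean) / sd
        clf = train_mlp(Z[tr], y_all[tr], Z[va], y_all[va], config, seed=split.seed)
        scores = clf.predict_proba(Z[te])[:, 1]
        split.test_scores = scores
        split.test_labels = y_all[te]
        roc = optimal_cutoff(roc_auc(scores, y_all[te]))
        split.auc, split.cutoff, split.metrics = roc.auc, roc.cutoff, roc.metrics
        pooled_scores.append(scores)
        pooled_labels.append(y_all[te])
        rows.append(
            {"repeat": split.repeat_index, "auc": roc.auc, "cutoff": roc.cutoff,
             **roc.metrics}
        )
    per_repeat = pd.DataFrame(rows)
    result = {
        "feature_columns": list(feature_columns),
        "n_repeats": n_repeats,
        "per_repeat": per_repeat,
        "auc_mean": float(per_repeat["auc"].mean()),
        "auc_sd": float(per_repeat["auc"].std(ddof=1)) if n_repeats > 1 else 0.0,
        "cutoff_mean": float(per_repeat["cutoff"].mean()),
    }
    for m in METRIC_NAMES:
        result[f"{m}_mean"] = float(per_repeat[m].mean(skipna=True))
    if aggregate == "pooled":
        pooled = optimal_cutoff(
            roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
        )
        result["pooled_auc"] = pooled.auc
        result["pooled_cutoff"] = pooled.cutoff
        result["pooled_metrics"] = pooled.metrics
    elif aggregate != "mean":
        raise ValueError(f"aggregate must be 'mean' or 'pooled', got {aggregate!r}")
    return result
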