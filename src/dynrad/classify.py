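"""Stability-vs-accuracy validation with single-feature decision trees.

Each feature gets its own classification tree on curves uniformly
subsampled to 12 frames.  Training and validation rows come from *all*
noise instances of their subjects; test rows use only each test subject's
reference (noise-free) curve, so test accuracy measures how well the
noise-augmented model transfers back to clean data.  Features reaching at
least 1/3 validation accuracy in the 5-class task count as informative,
and the link between stability and usefulness is summarized by the
Spearman correlation between consensus stability rank and test accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .curves import REFERENCE_LABEL, FeatureCurve
from .errors import (
    InsufficientFramesError,
    ParameterError,
    StratificationError,
    TrainingError,
)
from .stability import spearman_rho

__all__ = [
    "TreeConfig",
    "TreeEvalResult",
    "subsample_curve",
    "split_subjects",
    "evaluate_feature_tree",
    "evaluate_all_features",
    "stability_accuracy_correlation",
]

INFORMATIVE_THRESHOLD = 1.0 / 3.0


@dataclass(frozen=True)
class TreeConfig:
    """Decision-tree hyperparameters (rpart-like defaults) and the seed."""

    seed: int = 0
    criterion: str = "gini"
    max_depth: int = 30
    min_samples_split: int = 20
    min_samples_leaf: int = 7
    n_subsample_frames: int = 12


@dataclass(frozen=True)
class TreeEvalResult:
    feature_id: str
    validation_accuracy: float
    test_accuracy: float
    informative: bool


def subsample_curve(values: np.ndarray, k: int = 12) -> np.ndarray:
    """Uniformly subsample a length-T curve to k frames.

    Indices are ``round(j * (T-1) / (k-1))`` for j = 0..k-1 with
    round-half-up, so both endpoints are always included.  Indices must be
    strictly increasing (guaranteed for T >= k in practice and asserted).
    """
    values = np.asarray(values, dtype=np.float64)
    T = values.size
    if k < 2:
        raise ParameterError("k must be >= 2")
    if T < k:
        raise InsufficientFramesError(f"curve has {T} frames, need >= {k}")
    j = np.arange(k, dtype=np.float64)
    idx = np.floor(j * (T - 1) / (k - 1) + 0.5).astype(np.int64)
    if not np.all(np.diff(idx) > 0):
        raise InsufficientFramesError(
            f"subsample indices not strictly increasing for T={T}, k={k}"
        )
    return values[idx]


def split_subjects(
    labels: dict[str, str],
    counts: tuple[int, int, int] = (12, 4, 4),
    seed: int = 0,
) -> pd.DataFrame:
    """Class-balanced random train/validation/test partition of subjects.

    ``labels`` maps subject_id -> class label; ``counts`` are the exact
    per-class (train, val, test) sizes.  Deterministic given ``seed``.
    """
    n_train, n_val, n_test = counts
    need = n_train + n_val + n_test
    rng = np.random.default_rng(seed)
    rows = []
    by_class: dict[str, list[str]] = {}
    for sid in sorted(labels):
        by_class.setdefault(labels[sid], []).append(sid)
    for cls in sorted(by_class):
        members = by_class[cls]
        if len(members) < need:
            raise StratificationError(
                f"class {cls}: {len(members)} subjects < required {need}"
            )
        perm = rng.permutation(len(members))
        chosen = [members[i] for i in perm[:need]]
        for i, sid in enumerate(chosen):
            part = "train" if i < n_train else ("validation" if i < n_train + n_val else "test")
            rows.append(
                {"subject_id": sid, "class_label": cls, "partition": part, "seed": seed}
            )
    return pd.DataFrame(rows)


def _rows_for(
    curves: list[FeatureCurve],
    subjects: set[str],
    labels: dict[str, str],
    k: int,
    reference_only: bool,
) -> tuple[np.ndarray, np.ndarray]:
    X, y = [], []
    for c in curves:
        if c.subject_id not in subjects:
            continue
        if reference_only and c.level_label != REFERENCE_LABEL:
            continue
        X.append(subsample_curve(c.values, k))
        y.append(labels[c.subject_id])
    if not X:
        raise TrainingError("no rows selected for a partition")
    return np.stack(X), np.asarray(y)


def evaluate_feature_tree(
    feature_id: str,
    curves: list[FeatureCurve],
    split: pd.DataFrame,
    labels: dict[str, str],
    config: TreeConfig | None = None,
) -> TreeEvalResult:
    """Fit and score one feature's decision tree.

    ``curves`` are the normalized curves of this feature for all subjects
    in the split.  Train/validation rows use every noise instance of their
    subjects; test rows use reference curves only.  A leakage assertion
    guarantees the partitions are disjoint.
    """
    if config is None:
        config = TreeConfig()
    my = [c for c in curves if c.feature_id == feature_id]
    parts = {
        p: set(split.loc[split["partition"] == p, "subject_id"])
        for p in ("train", "validation", "test")
    }
    assert not (parts["train"] & parts["test"]), "train/test subject leakage"
    assert not (parts["train"] & parts["validation"]), "train/validation subject leakage"
    assert not (parts["validation"] & parts["test"]), "validation/test subject leakage"

    k = config.n_subsample_frames
    X_train, y_train = _rows_for(my, parts["train"], labels, k, reference_only=False)
    X_val, y_val = _rows_for(my, parts["validation"], labels, k, reference_only=False)
    X_test, y_test = _rows_for(my, parts["test"], labels, k, reference_only=True)
    if len(set(y_train)) < 2:
        raise TrainingError(f"{feature_id}: training data contains a single class")

    tree = DecisionTreeClassifier(
        criterion=config.criterion,
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        min_samples_leaf=config.min_samples_leaf,
        random_state=config.seed,
    )
    tree.fit(X_train, y_train)
    val_acc = float(np.mean(tree.predict(X_val) == y_val))
    test_acc = float(np.mean(tree.predict(X_test) == y_test))
    return TreeEvalResult(
        feature_id=feature_id,
        validation_accuracy=val_acc,
        test_accuracy=test_acc,
        informative=val_acc >= INFORMATIVE_THRESHOLD,
    )


def evaluate_all_features(
    curves: list[FeatureCurve],
    split: pd.DataFrame,
    labels: dict[str, str],
    config: TreeConfig | None = None,
) -> pd.DataFrame:
    """Run :func:`evaluate_feature_tree` for every feature present."""
    fids = sorted({c.feature_id for c in curves})
    rows = []
    for fid in fids:
        res = evaluate_feature_tree(fid, curves, split, labels, config)
        rows.append(
            {
                "feature_id": res.feature_id,
                "validation_accuracy": res.validation_accuracy,
                "test_accuracy": res.test_accuracy,
                "informative": res.informative,
            }
        )
    return pd.DataFrame(rows)


def stability_accuracy_correlation(
    consensus: pd.DataFrame,
    results: pd.DataFrame,
    top_n: int = 15,
) -> dict:
    """Spearman correlation between consensus rank and test accuracy.

    Restricted to informative features.  Also reports the median test
    accuracy of the ``top_n`` most and least stable informative features
    (``top_n`` is clipped to half the informative count so the two groups
    never overlap).  Returns NaN markers when fewer than 3 informative
    features exist.
    """
    merged = results.merge(
        consensus[["feature_id", "consensus_rank"]], on="feature_id", how="inner"
    )
    info = merged[merged["informative"] & merged["consensus_rank"].notna()]
    out = {
        "n_informative": int(info.shape[0]),
        "rank_accuracy_rho": float("nan"),
        "top_median_test_accuracy": float("nan"),
        "bottom_median_test_accuracy": float("nan"),
    }
    if len(info) < 3:
        return out
    rho = spearman_rho(
        info.set_index("feature_id")["consensus_rank"],
        info.set_index("feature_id")["test_accuracy"],
    )
    n = min(top_n, len(info) // 2)
    ordered = info.sort_values("consensus_rank")
    out["rank_accuracy_rho"] = rho
    out["top_median_test_accuracy"] = float(ordered.head(n)["test_accuracy"].median())
    out["bottom_median_test_accuracy"] = float(ordered.tail(n)["test_accuracy"].median())
    return out
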