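"""RBF-kernel SVM classification of feature vectors.

Covers training with per-feature standardization, prediction, grid search
over (C, gamma), K-fold cross-validation with nested tuning, and one-by-one
feature ablation.  Labels are +1 (intronless) and -1 (intron-containing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

SERIALIZATION_VERSION = 1

#: Default tuning grids; powers of two bracketing the useful RBF regime.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-2, 9))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-8, 3))

FULL_MASK = tuple(range(7))


class ModelError(ValueError):
    """Raised for invalid training input or model misuse."""


@dataclass(frozen=True)
class ModelSpec:
    """A fitted RBF-SVM with its standardization and feature mask."""

    C: float
    gamma: float
    feature_mask: tuple[int, ...]
    means: np.ndarray  # per masked feature, from training data
    sds: np.ndarray
    svc: SVC

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_mask):
            raise ModelError(
                f"expected {len(self.feature_mask)} features, got shape {X.shape}"
            )
        return (X - self.means) / self.sds


@dataclass(frozen=True)
class CVReport:
    """Outcome of a K-fold cross-validation run."""

    K: int
    fold_accuracies: tuple[float, ...]  # percent, one per fold
    chosen_params: tuple[tuple[float, float], ...]  # (C, gamma) per fold
    seed: int
    feature_mask: tuple[int, ...] = FULL_MASK

    @property
    def average_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "fold_accuracies": list(self.fold_accuracies),
            "average_accuracy": self.average_accuracy,
            "chosen_params": [list(p) for p in self.chosen_params],
            "seed": self.seed,
            "feature_mask": list(self.feature_mask),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ModelError(f"incompatible shapes {X.shape} and {y.shape}")
    if not np.all(np.isfinite(X)):
        raise ModelError("features must be finite")
    if not set(np.unique(y)) <= {-1, 1}:
        raise ModelError("labels must be +1 or -1")
    if len(set(y)) < 2:
        raise ModelError("training data must contain both classes")
    return X, y


def kfold_partition(
    n: int,
    K: int,
    seed: int,
    stratify_labels: Sequence[int] | None = None,
) -> list[np.ndarray]:
    """K disjoint index folds covering range(n); sizes differ by <= 1.

    With ``stratify_labels`` the per-fold class counts also differ by <= 1
    per class.  Reproducible given the seed.
    """
    if K < 2 or K > n:
        raise ModelError(f"K={K} invalid for {n} items")
    if stratify_labels is not None and K > int(np.min(np.bincount(
            np.unique(stratify_labels, return_inverse=True)[1]))):
        stratify_labels = None  # e.g. leave-one-out: stratification impossible
    if stratify_labels is not None:
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), np.asarray(stratify_labels))
    else:
        splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    return [test for _, test in splits]


def train(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    feature_mask: Sequence[int] = FULL_MASK,
) -> ModelSpec:
    """Fit an RBF SVM on the masked, standardized features."""
    if C <= 0 or gamma <= 0:
        raise ModelError(f"C and gamma must be positive, got C={C}, gamma={gamma}")
    X, y = _check_xy(X, y)
    mask = tuple(int(i) for i in feature_mask)
    if not mask or any(i < 0 or i >= X.shape[1] for i in mask):
        raise ModelError(f"feature mask {mask} invalid for {X.shape[1]} features")
    Xm = X[:, mask]
    means = Xm.mean(axis=0)
    sds = Xm.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)  # constant feature: leave centered
    svc = SVC(C=C, gamma=gamma, kernel="rbf")
    svc.fit((Xm - means) / sds, y)
    return ModelSpec(
        C=float(C), gamma=float(gamma), feature_mask=mask,
        means=means, sds=sds, svc=svc,
    )


def predict(model: ModelSpec, X: np.ndarray) -> np.ndarray:
    """Predict +1/-1 labels; ``X`` has the model's full feature width."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ModelError(f"expected 2-d feature array, got shape {X.shape}")
    n_needed = max(model.feature_mask) + 1
    if X.shape[1] < n_needed:
        raise ModelError(
            f"model needs feature columns up to {n_needed - 1}, got {X.shape[1]}"
        )
    return model.svc.predict(model.transform(X[:, model.feature_mask])).astype(int)


def discriminant_accuracy(predicted: Sequence[int], truth: Sequence[int]) -> float:
    """Percentage of predictions matching the known labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) == 0:
        raise ModelError("empty input")
    if len(predicted) != len(truth):
        raise ModelError(f"length mismatch: {len(predicted)} vs {len(truth)}")
    return float(100.0 * np.mean(predicted == truth))


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    K_inner: int = 10,
    seed: int = 0,
    feature_mask: Sequence[int] = FULL_MASK,
) -> tuple[float, float]:
    """Choose (C, gamma) minimizing inner-CV misclassification rate.

    Ties break toward smaller C, then smaller gamma (the grids are scanned
    in ascending order and only a strictly lower error replaces the
    incumbent), preferring the least complex model.
    """
    X, y = _check_xy(X, y)
    if not C_grid or not gamma_grid:
        raise ModelError("parameter grids must be non-empty")
    K_inner = min(K_inner, int(np.min(np.bincount((y + 1) // 2))))
    if K_inner < 2:
        raise ModelError("too few samples per class for inner cross-validation")
    folds = kfold_partition(len(y), K_inner, seed, stratify_labels=y)
    best: tuple[float, float] | None = None
    best_err = np.inf
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            errors = 0
            for test_idx in folds:
                train_mask = np.ones(len(y), dtype=bool)
                train_mask[test_idx] = False
                m = train(X[train_mask], y[train_mask], C, gamma, feature_mask)
                errors += int(np.sum(predict(m, X[test_idx]) != y[test_idx]))
            err = errors / len(y)
            if err < best_err:
                best_err = err
                best = (float(C), float(gamma))
    assert best is not None
    return best


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 5,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    K_inner: int = 10,
    seed: int = 0,
    feature_mask: Sequence[int] = FULL_MASK,
    folds: Sequence[np.ndarray] | None = None,
) -> CVReport:
    """K-fold cross-validation with nested (C, gamma) tuning.

    Each outer fold is held out once; (C, gamma) are tuned by ``K_inner``-fold
    search on the remaining folds, the model is refitted on them and scored
    on the held-out fold.  Pass precomputed ``folds`` to compare several
    feature masks on identical partitions.
    """
    X, y = _check_xy(X, y)
    if folds is None:
        folds = kfold_partition(len(y), K, seed, stratify_labels=y)
    if len(folds) != K:
        raise ModelError(f"expected {K} folds, got {len(folds)}")
    accs, params = [], []
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[np.asarray(test_idx)] = False
        Xtr, ytr = X[train_mask], y[train_mask]
        C, gamma = grid_search(
            Xtr, ytr, C_grid, gamma_grid, K_inner, seed, feature_mask
        )
        m = train(Xtr, ytr, C, gamma, feature_mask)
        accs.append(discriminant_accuracy(predict(m, X[test_idx]), y[test_idx]))
        params.append((C, gamma))
    return CVReport(
        K=K,
        fold_accuracies=tuple(accs),
        chosen_params=tuple(params),
        seed=seed,
        feature_mask=tuple(int(i) for i in feature_mask),
    )


def ablation_study(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 5,
    seed: int = 0,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    K_inner: int = 10,
) -> dict[str, CVReport]:
    """One-by-one feature deletion: the full 7-feature model plus the seven
    6-feature models, all cross-validated on identical partitions."""
    X, y = _check_xy(X, y)
    if X.shape[1] != 7:
        raise ModelError(f"ablation expects 7 features, got {X.shape[1]}")
    folds = kfold_partition(len(y), K, seed, stratify_labels=y)
    names = ["n1", "n2", "n3", "n4", "n5", "n6", "sigma"]
    reports: dict[str, CVReport] = {}
    reports["all"] = cross_validate(
        X, y, K, C_grid, gamma_grid, K_inner, seed, FULL_MASK, folds=folds
    )
    for drop in range(7):
        mask = tuple(i for i in range(7) if i != drop)
        reports[f"without_{names[drop]}"] = cross_validate(
            X, y, K, C_grid, gamma_grid, K_inner, seed, mask, folds=folds
        )
    return reports


def save_model(model: ModelSpec, path: str | Path) -> None:
    """Serialize a fitted model to one file (joblib, versioned)."""
    joblib.dump(
        {
            "format": "dfa7-model",
            "version": SERIALIZATION_VERSION,
            "C": model.C,
            "gamma": model.gamma,
            "feature_mask": model.feature_mask,
            "means": model.means,
            "sds": model.sds,
            "svc": model.svc,
        },
        path,
    )


def load_model(path: str | Path) -> ModelSpec:
    payload = joblib.load(path)
    if payload.get("format") != "dfa7-model":
        raise ModelError(f"{path} is not a dfa7 model file")
    if payload.get("version") != SERIALIZATION_VERSION:
        raise ModelError(f"unsupported model version {payload.get('version')}")
    return ModelSpec(
        C=payload["C"],
        gamma=payload["gamma"],
        feature_mask=tuple(payload["feature_mask"]),
        means=payload["means"],
        sds=payload["sds"],
        svc=payload["svc"],
    )
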