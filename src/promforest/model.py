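"""Random-forest promoter classifiers (RF-HOT and RF-TETRA).

Hyper-parameters are chosen by stratified k-fold grid-search
cross-validation, selecting on mean AUPRC (ties broken by AUROC, then by
the smaller forest), and the winning configuration is refit on the full
training set.  Class weights follow the inverse-frequency ("balanced")
rule weight_c = N / (2 * N_c), so a 1:10 set yields {0: 0.55, 1: 5.5}.

Two grid profiles are provided: ``full`` — max_features in
{None, sqrt, log2} x n_estimators in {1000, 2000, 3000} with 10 folds —
and ``fast`` — the same max_features rules at 100 trees with 3 folds,
for test-scale runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .encoders import FeatureMatrix, encode_sequences

MODEL_FORMAT_VERSION = 1

GRID_FULL: dict = {"max_features": [None, "sqrt", "log2"], "n_estimators": [1000, 2000, 3000]}
GRID_FAST: dict = {"max_features": [None, "sqrt", "log2"], "n_estimators": [100]}

PROFILES = {
    "full": {"grid": GRID_FULL, "folds": 10},
    "fast": {"grid": GRID_FAST, "folds": 3},
}


class TrainingError(ValueError):
    """Training input cannot support the requested fit."""


class ConfigurationError(ValueError):
    """Invalid CV / grid configuration."""


class ModelLoadError(RuntimeError):
    """A serialized model could not be loaded."""


@dataclass
class CVCell:
    hyper: dict
    mean_auprc: float
    mean_auroc: float


@dataclass
class CVReport:
    """Grid-search results: one row per hyper-parameter cell, plus the winner."""

    grid: list[CVCell]
    best: dict

    def as_dict(self) -> dict:
        return {
            "grid": [
                {"hyper": c.hyper, "mean_auprc": c.mean_auprc, "mean_auroc": c.mean_auroc}
                for c in self.grid
            ],
            "best": self.best,
        }


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to reapply it faithfully."""

    forest: RandomForestClassifier
    encoder_tag: str
    hyper: dict
    class_weights: dict[int, float]
    seed: int
    train_fingerprint: str

    @property
    def n_features(self) -> int:
        return self.forest.n_features_in_


def balanced_class_weights(y: np.ndarray) -> dict[int, float]:
    """Inverse-frequency weights weight_c = N / (n_classes * N_c)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n = y.shape[0]
    return {int(c): n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


def _fingerprint(features: FeatureMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(features.X).tobytes())
    h.update(np.ascontiguousarray(features.y).tobytes())
    h.update(features.encoder_tag.encode())
    return h.hexdigest()


def _make_forest(hyper: dict, class_weight: dict, seed: int, n_jobs: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=hyper["n_estimators"],
        max_features=hyper["max_features"],
        criterion="gini",
        class_weight=class_weight,
        random_state=seed,
        n_jobs=n_jobs,
    )


def train_rf(
    features: FeatureMatrix,
    grid: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    n_jobs: int = 1,
) -> tuple[TrainedModel, CVReport]:
    """Grid-search CV over the hyper-parameter space, then refit on all rows.

    Selection metric is mean fold AUPRC; ties break by mean AUROC, then by
    the smaller ``n_estimators``.  Deterministic for a fixed seed.
    """
    if grid is None:
        grid = GRID_FULL
    X, y = features.X, features.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TrainingError("training data contains a single class")
    minority = counts.min()
    if folds > minority:
        raise ConfigurationError(
            f"folds={folds} exceeds the minority-class count ({minority})"
        )
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")

    class_weight = balanced_class_weights(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    cells: list[CVCell] = []
    for m in grid["max_features"]:
        for n in grid["n_estimators"]:
            hyper = {"max_features": m, "n_estimators": n}
            auprcs, aurocs = [], []
            for train_idx, val_idx in splits:
                clf = _make_forest(hyper, class_weight, seed, n_jobs)
                clf.fit(X[train_idx], y[train_idx])
                p = clf.predict_proba(X[val_idx])[:, list(clf.classes_).index(1)]
                auprcs.append(average_precision_score(y[val_idx], p))
                aurocs.append(roc_auc_score(y[val_idx], p))
            cells.append(CVCell(hyper, float(np.mean(auprcs)), float(np.mean(aurocs))))

    best_cell = max(
        cells,
        key=lambda c: (c.mean_auprc, c.mean_auroc, -c.hyper["n_estimators"]),
    )
    report = CVReport(grid=cells, best=dict(best_cell.hyper))

    final = _make_forest(best_cell.hyper, class_weight, seed, n_jobs)
    final.fit(X, y)
    model = TrainedModel(
        forest=final,
        encoder_tag=features.encoder_tag,
        hyper=dict(best_cell.hyper),
        class_weights=class_weight,
        seed=seed,
        train_fingerprint=_fingerprint(features),
    )
    return model, report


def predict_proba_features(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Promoter probability for pre-encoded rows."""
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match the "
            f"{model.encoder_tag} model ({model.n_features})"
        )
    col = list(model.forest.classes_).index(1)
    return model.forest.predict_proba(X)[:, col]


def predict_proba(model: TrainedModel, sequences: Sequence[str]) -> np.ndarray:
    """Promoter probability per 40-nt sequence, order-preserving."""
    if len(sequences) == 0:
        return np.empty(0)
    X = encode_sequences(list(sequences), model.encoder_tag)
    return predict_proba_features(model, X)


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # joblib raises a zoo of unpickling errors
        raise ModelLoadError(f"could not load model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelLoadError(f"{path} is not a promforest model bundle")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelLoadError(
            f"model format version {payload['format_version']} != "
            f"supported version {MODEL_FORMAT_VERSION}"
        )
    return payload["model"]
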