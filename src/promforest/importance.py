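"""Model interpretation: feature-importance rankings and position profiles.

Two complementary scores are computed from a trained forest:

* impurity importance — mean decrease in Gini impurity, averaged over
  trees (each tree's importances are normalised, so the mean ranking sums
  to 1); the spread across trees gives the reported standard deviation;
* permutation importance — mean decrease in accuracy (threshold 0.5)
  after shuffling one feature column at a time, repeated ``n_repeats``
  times on an evaluation set.

For the one-hot model the 160 per-feature scores reshape into a 40x4
position-by-nucleotide profile (positions labelled -39..0 relative to
the TSS), which makes the learned Pribnow-box signal — A/T importance
concentrated ~10 bp upstream of the TSS — directly visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .encoders import (
    HOT_CHANNELS,
    N_HOT_FEATURES,
    SEQUENCE_LENGTH,
    FeatureMatrix,
    hot_feature_names,
    tetra_feature_names,
)
from .model import TrainedModel


class StateError(RuntimeError):
    """Operation requires a fitted model."""


@dataclass
class ImportanceEntry:
    feature: str
    mean: float
    sd: float


@dataclass
class ImportanceRanking:
    """Per-feature scores sorted by mean, descending."""

    entries: list[ImportanceEntry]
    method: str  # IMPURITY | PERMUTATION
    n_repeats: int | None = None

    def top(self, n: int = 10) -> list[ImportanceEntry]:
        return self.entries[:n]

    def rank_of(self, feature: str) -> int:
        """1-based rank of a feature name; raises KeyError if absent."""
        for i, e in enumerate(self.entries, start=1):
            if e.feature == feature:
                return i
        raise KeyError(feature)


@dataclass
class PositionNucleotideProfile:
    """40 positions x 4 nucleotides (A,G,C,T) importance matrix."""

    matrix: np.ndarray  # shape (40, 4)
    position_labels: list[int]  # -39 .. 0
    bases: str = HOT_CHANNELS

    def per_position(self) -> np.ndarray:
        """Total importance per position (sum over the four channels)."""
        return self.matrix.sum(axis=1)


def _feature_names_for(model: TrainedModel) -> list[str]:
    return hot_feature_names() if model.encoder_tag == "HOT" else tetra_feature_names()


def _sorted_entries(names, means, sds) -> list[ImportanceEntry]:
    order = np.argsort(-np.asarray(means), kind="stable")
    return [
        ImportanceEntry(names[i], float(means[i]), float(sds[i])) for i in order
    ]


def impurity_importance(model: TrainedModel) -> ImportanceRanking:
    """Mean decrease in impurity per feature, averaged over trees.

    Each tree's importances are normalised to sum to 1, so the averaged
    (and renormalised) scores also sum to 1; the sd is taken across trees.
    """
    if not hasattr(model.forest, "estimators_"):
        raise StateError("model is not fitted")
    per_tree = np.array([t.feature_importances_ for t in model.forest.estimators_])
    means = per_tree.mean(axis=0)
    total = means.sum()
    if total > 0:
        means = means / total
    sds = per_tree.std(axis=0)
    return ImportanceRanking(
        entries=_sorted_entries(_feature_names_for(model), means, sds),
        method="IMPURITY",
    )


def permutation_importance(
    model: TrainedModel,
    features: FeatureMatrix,
    n_repeats: int = 5,
    seed: int = 0,
) -> ImportanceRanking:
    """Mean decrease in accuracy after per-column shuffling of an
    evaluation set, repeated ``n_repeats`` times; deterministic per seed."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if len(np.unique(features.y)) < 2:
        raise ValueError("evaluation set must contain both classes")
    res = _sk_permutation_importance(
        model.forest,
        features.X,
        features.y,
        scoring="accuracy",
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    return ImportanceRanking(
        entries=_sorted_entries(
            _feature_names_for(model), res.importances_mean, res.importances_std
        ),
        method="PERMUTATION",
        n_repeats=n_repeats,
    )


def position_profile(ranking: ImportanceRanking) -> PositionNucleotideProfile:
    """Reshape a 160-feature one-hot ranking into the 40x4 position profile."""
    if len(ranking.entries) != N_HOT_FEATURES:
        raise ValueError(
            f"expected {N_HOT_FEATURES} one-hot features, got {len(ranking.entries)}"
        )
    matrix = np.zeros((SEQUENCE_LENGTH, 4))
    for e in ranking.entries:
        try:
            pos_part, base = e.feature.split(":")
            label = int(pos_part.removeprefix("pos"))
            channel = HOT_CHANNELS.index(base)
        except (ValueError, IndexError):
            raise ValueError(
                f"feature name {e.feature!r} is not a one-hot position feature"
            ) from None
        matrix[label + (SEQUENCE_LENGTH - 1), channel] = e.mean
    labels = list(range(-(SEQUENCE_LENGTH - 1), 1))
    return PositionNucleotideProfile(matrix=matrix, position_labels=labels)
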