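"""Per-pair feature vectors: ten k-mer scores for k = 1..10.

The ensemble classifier consumes one score per k-mer length.  Which
algorithm supplies the score at each k is configurable via the feature
map; the default assignment is

    k = 1       threshold-sum score at T = 0 (pure composition signal)
    k = 2..4    1 - NGD (so that, like every other feature, higher
                means more similar)
    k = 5..10   best-match score

Features for a pair where either sequence is shorter than k are set to
0 with a warning instead of raising, so that database-scale scoring
never aborts on a short entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import kmer_scores as ks
from .physchem import ResidueSimilarityMatrix, default_similarity_matrix

N_FEATURES = 10

_ALGORITHMS = ("shark_best", "shark_T", "ngd", "euclidean", "similarity_ratio")


@dataclass(frozen=True)
class ScoreSpec:
    """One (algorithm, k[, T]) choice of pair score."""

    algorithm: str
    k: int
    T: float | None = None

    def __post_init__(self):
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if (self.T is not None) != (self.algorithm == "shark_T"):
            raise ValueError("T must be given iff algorithm is shark_T")
        if self.T is not None and not 0.0 <= self.T <= 1.0:
            raise ValueError(f"T must be in [0, 1], got {self.T}")


def default_feature_map() -> dict[int, ScoreSpec]:
    fm = {1: ScoreSpec("shark_T", 1, 0.0)}
    for k in (2, 3, 4):
        fm[k] = ScoreSpec("ngd", k)
    for k in range(5, 11):
        fm[k] = ScoreSpec("shark_best", k)
    return fm


def validate_feature_map(feature_map: dict[int, ScoreSpec]) -> dict[int, ScoreSpec]:
    if sorted(feature_map) != list(range(1, N_FEATURES + 1)):
        raise ValueError(
            f"feature map must have exactly keys 1..{N_FEATURES}, "
            f"got {sorted(feature_map)}")
    for k, spec in feature_map.items():
        if spec.k != k:
            raise ValueError(f"feature map entry {k} has mismatched spec.k={spec.k}")
    return feature_map


@dataclass(frozen=True)
class PairFeatureVector:
    id1: str
    id2: str
    features: tuple[float, ...]  # index i -> score for k = i + 1

    def __post_init__(self):
        if len(self.features) != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features")


def _score_one(s1: str, s2: str, spec: ScoreSpec,
               S: np.ndarray | None) -> float:
    """Dispatch one ScoreSpec; NGD is flipped to the 1-NGD similarity."""
    if spec.algorithm == "shark_best":
        return ks._best_from_w(ks._window_mean(S, spec.k))
    if spec.algorithm == "shark_T":
        return ks._t_from_w(ks._window_mean(S, spec.k), spec.T)
    if spec.algorithm == "ngd":
        return 1.0 - ks.ngd(s1, s2, spec.k)
    if spec.algorithm == "euclidean":
        return ks.euclidean_kmer_distance(s1, s2, spec.k)
    return ks.similarity_ratio(s1, s2, spec.k)


def compute_feature_vector(s1: str, s2: str,
                           feature_map: dict[int, ScoreSpec] | None = None,
                           matrix: ResidueSimilarityMatrix | None = None,
                           id1: str = "seq1", id2: str = "seq2",
                           ) -> PairFeatureVector:
    """The 10 per-k scores for one sequence pair.

    The residue-level similarity grid is computed once and shared by all
    physicochemical features.  A k with a too-short sequence yields 0.0
    with a warning.
    """
    feature_map = validate_feature_map(feature_map or default_feature_map())
    matrix = matrix or default_similarity_matrix()
    s1, s2 = s1.upper(), s2.upper()
    needs_grid = any(feature_map[k].algorithm in ("shark_best", "shark_T")
                     for k in feature_map)
    S = ks.residue_level_similarity(s1, s2, matrix) if needs_grid else None
    shortest = min(len(s1), len(s2))
    values = []
    for k in range(1, N_FEATURES + 1):
        if shortest < k:
            warnings.warn(
                f"pair ({id1}, {id2}): sequence shorter than k={k}; "
                "feature set to 0.0")
            values.append(0.0)
        else:
            values.append(float(_score_one(s1, s2, feature_map[k], S)))
    return PairFeatureVector(id1=id1, id2=id2, features=tuple(values))


class KmerFeaturizer(BaseEstimator, TransformerMixin):
    """Transform sequence pairs into the (n, 10) k-mer score matrix.

    A stateless scikit-learn transformer: ``fit`` only validates the
    feature map.  ``X`` is a sequence of ``(s1, s2)`` residue-string
    pairs; ``transform`` returns a dense float array with column j
    holding the score for k = j + 1.
    """

    def __init__(self, feature_map: dict[int, ScoreSpec] | None = None,
                 matrix: ResidueSimilarityMatrix | None = None):
        self.feature_map = feature_map
        self.matrix = matrix

    def fit(self, X=None, y=None):
        self.feature_map_ = validate_feature_map(
            self.feature_map or default_feature_map())
        self.matrix_ = self.matrix or default_similarity_matrix()
        return self

    def transform(self, X: Sequence[tuple[str, str]]) -> np.ndarray:
        if not hasattr(self, "feature_map_"):
            self.fit()
        out = np.empty((len(X), N_FEATURES))
        for i, (s1, s2) in enumerate(X):
            out[i] = compute_feature_vector(
                s1, s2, self.feature_map_, self.matrix_).features
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array([f"k{k}_{self.feature_map_[k].algorithm}"
                         for k in range(1, N_FEATURES + 1)])
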