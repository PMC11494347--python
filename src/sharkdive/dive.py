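"""Ensemble homology classifier over the ten per-k k-mer scores.

The classifier is a 10-fold ensemble of gradient-boosted decision
trees.  Sequence *families* — not pairs — are partitioned into folds;
submodel i is trained only on pairs whose two families both lie
outside fold i, so no family ever leaks across a submodel's
train/held-out boundary.  The ensemble probability is the mean of the
submodel probabilities and a pair is called homologous when it reaches
the decision threshold (default 0.5, ties count as positive).

``DiveClassifier`` is a scikit-learn estimator operating on (n, 10)
feature matrices with per-pair family groups; ``DiveModel`` wraps it
together with the featurizer for sequence-level use (train_dive /
predict_pair / classify / search).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .features import (KmerFeaturizer, N_FEATURES, PairFeatureVector,
                       ScoreSpec, default_feature_map, validate_feature_map)
from .physchem import ResidueSimilarityMatrix, default_similarity_matrix

ARCHIVE_FORMAT_VERSION = 1


class ModelArchiveError(RuntimeError):
    """A model archive is corrupt or from an incompatible format version."""


@dataclass(frozen=True)
class LabeledPair:
    """One training pair: features plus family-derived label."""

    vector: PairFeatureVector
    label: int
    family1: str
    family2: str

    def __post_init__(self):
        if self.label != int(self.family1 == self.family2):
            raise ValueError("label must be 1 iff family1 == family2")


@dataclass(frozen=True)
class ImportanceSummary:
    """Gain-based feature importances per submodel, with mean/SD per k."""

    mean: np.ndarray      # shape (10,)
    sd: np.ndarray        # shape (10,)
    per_submodel: np.ndarray  # shape (n_submodels, 10), rows sum to 1


class DiveClassifier(BaseEstimator, ClassifierMixin):
    """Family-grouped ensemble of gradient-boosted submodels.

    Parameters
    ----------
    n_submodels : int
        Number of folds/submodels (default 10).
    n_estimators, max_depth, learning_rate :
        Hyperparameters shared by every gradient-boosted submodel.
        The feature space is small (10 scores), so a modest model
        suffices.
    threshold : float
        Decision threshold on the ensemble probability, in (0, 1).
    random_state : int
        Seeds the family shuffle and every submodel.

    Attributes
    ----------
    submodels_ : list of fitted gradient-boosted classifiers.
    fold_assignment_ : dict mapping family id -> fold index.
    classes_ : array([0, 1]).
    """

    def __init__(self, n_submodels: int = 10, n_estimators: int = 200,
                 max_depth: int = 3, learning_rate: float = 0.1,
                 threshold: float = 0.5, random_state: int = 0):
        self.n_submodels = n_submodels
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.random_state = random_state

    def _new_submodel(self, seed: int) -> XGBClassifier:
        return XGBClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate, random_state=seed,
            tree_method="hist", n_jobs=1, importance_type="gain",
            base_score=0.5, eval_metric="logloss")

    def fit(self, X, y, groups=None):
        """Fit the ensemble.

        ``groups`` is required: a length-n sequence of (family1, family2)
        pairs used to partition families into folds.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"X must be (n, {N_FEATURES}), got {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("y must contain both classes 0 and 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if groups is None:
            raise ValueError("groups (per-pair family ids) are required")
        groups = [(str(a), str(b)) for a, b in groups]
        if len(groups) != len(X):
            raise ValueError("groups length must match X")

        families = sorted({f for pair in groups for f in pair})
        if len(families) < self.n_submodels:
            raise ValueError(
                f"{len(families)} families cannot fill {self.n_submodels} "
                f"folds; reduce n_submodels")
        rng = np.random.default_rng(self.random_state)
        shuffled = list(rng.permutation(families))
        self.fold_assignment_ = {fam: i % self.n_submodels
                                 for i, fam in enumerate(shuffled)}

        fold_of = self.fold_assignment_
        self.submodels_ = []
        for i in range(self.n_submodels):
            mask = np.array([fold_of[a] != i and fold_of[b] != i
                             for a, b in groups])
            yi = y[mask]
            if len(np.unique(yi)) < 2:
                raise ValueError(f"fold {i}: training pairs collapse to one class")
            sub = self._new_submodel(seed=self.random_state + i)
            sub.fit(X[mask], yi)
            self.submodels_.append(sub)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "submodels_")
        X = np.asarray(X, dtype=float)
        p1 = np.mean([sub.predict_proba(X)[:, 1] for sub in self.submodels_],
                     axis=0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        # ties at the threshold count as positive
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    def feature_importances(self) -> ImportanceSummary:
        """Per-k gain importances, normalised to sum 1 per submodel."""
        check_is_fitted(self, "submodels_")
        rows = []
        for sub in self.submodels_:
            imp = np.asarray(sub.feature_importances_, dtype=float)
            total = imp.sum()
            rows.append(imp / total if total > 0 else imp)
        per = np.vstack(rows)
        return ImportanceSummary(mean=per.mean(axis=0), sd=per.std(axis=0),
                                 per_submodel=per)


# ---------------------------------------------------------------------------
# pair-level API

@dataclass
class DiveModel:
    """A fitted ensemble bundled with its featurizer and metadata."""

    classifier: DiveClassifier
    feature_map: dict[int, ScoreSpec]
    matrix: ResidueSimilarityMatrix
    threshold: float = 0.5
    training_metadata: dict = field(default_factory=dict)

    def featurize(self, pairs) -> np.ndarray:
        feat = KmerFeaturizer(feature_map=self.feature_map,
                              matrix=self.matrix).fit()
        return feat.transform(pairs)


def build_training_pairs(families, negative_ratio: float = 1.0,
                         seed: int = 0,
                         feature_map: dict[int, ScoreSpec] | None = None,
                         matrix: ResidueSimilarityMatrix | None = None,
                         ) -> list[LabeledPair]:
    """All within-family pairs plus sampled cross-family negatives.

    Negatives are drawn without replacement at ``negative_ratio`` times
    the positive count; when fewer cross-family pairs exist, all of
    them are used with a warning.
    """
    if len(families) < 2:
        raise ValueError("need at least 2 families")
    for fam in families:
        if len(fam.members) < 2:
            raise ValueError(f"family {fam.family_id} has fewer than 2 members")
    feature_map = validate_feature_map(feature_map or default_feature_map())
    matrix = matrix or default_similarity_matrix()
    rng = np.random.default_rng(seed)

    positives: list[tuple] = []   # (rec1, rec2, fam1, fam2)
    for fam in families:
        for r1, r2 in itertools.combinations(fam.members, 2):
            positives.append((r1, r2, fam.family_id, fam.family_id))

    cross: list[tuple] = []
    for fa, fb in itertools.combinations(families, 2):
        for r1 in fa.members:
            for r2 in fb.members:
                cross.append((r1, r2, fa.family_id, fb.family_id))
    n_neg = int(round(negative_ratio * len(positives)))
    if n_neg > len(cross):
        warnings.warn(
            f"only {len(cross)} cross-family pairs available "
            f"(requested {n_neg}); using all")
        n_neg = len(cross)
    negatives = [cross[i] for i in rng.choice(len(cross), size=n_neg,
                                              replace=False)]

    feat = KmerFeaturizer(feature_map=feature_map, matrix=matrix).fit()
    pairs: list[LabeledPair] = []
    for r1, r2, f1, f2 in positives + negatives:
        vec = feat.transform([(r1.sequence, r2.sequence)])[0]
        pairs.append(LabeledPair(
            vector=PairFeatureVector(id1=r1.id, id2=r2.id,
                                     features=tuple(float(v) for v in vec)),
            label=int(f1 == f2), family1=f1, family2=f2))
    return pairs


def train_dive(pairs: list[LabeledPair], n_submodels: int = 10,
               hyperparams: dict | None = None, seed: int = 0,
               feature_map: dict[int, ScoreSpec] | None = None,
               matrix: ResidueSimilarityMatrix | None = None,
               threshold: float = 0.5) -> DiveModel:
    """Train the family-grouped ensemble on labeled pairs."""
    feature_map = validate_feature_map(feature_map or default_feature_map())
    matrix = matrix or default_similarity_matrix()
    hyperparams = hyperparams or {}
    X = np.array([p.vector.features for p in pairs])
    y = np.array([p.label for p in pairs])
    groups = [(p.family1, p.family2) for p in pairs]
    clf = DiveClassifier(n_submodels=n_submodels, random_state=seed,
                         threshold=threshold, **hyperparams)
    clf.fit(X, y, groups=groups)
    return DiveModel(
        classifier=clf, feature_map=feature_map, matrix=matrix,
        threshold=threshold,
        training_metadata={
            "seed": seed, "n_pairs": len(pairs),
            "n_positives": int(y.sum()),
            "hyperparameters": clf.get_params(),
            "fold_assignment": dict(clf.fold_assignment_),
        })


def predict_pair(model: DiveModel, s1: str, s2: str) -> float:
    """Ensemble homology probability for one sequence pair."""
    if not isinstance(model, DiveModel):
        raise TypeError("model must be a DiveModel")
    check_is_fitted(model.classifier, "submodels_")
    X = model.featurize([(s1, s2)])
    return float(model.classifier.predict_proba(X)[0, 1])


def classify(model: DiveModel, s1: str, s2: str,
             threshold: float | None = None) -> tuple[int, float]:
    """(label, probability); label 1 when probability >= threshold."""
    threshold = model.threshold if threshold is None else threshold
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    prob = predict_pair(model, s1, s2)
    return int(prob >= threshold), prob


def feature_importance(model: DiveModel) -> ImportanceSummary:
    return model.classifier.feature_importances()


def save_model(model: DiveModel, path) -> None:
    """Serialize a model archive (predictions round-trip bit-exactly)."""
    check_is_fitted(model.classifier, "submodels_")
    payload = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "feature_map": model.feature_map,
        "threshold": model.threshold,
        "matrix": model.matrix,
        "classifier": model.classifier,
        "training_metadata": model.training_metadata,
    }
    joblib.dump(payload, path)


def load_model(path) -> DiveModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelArchiveError(f"cannot read model archive {path}: {exc}")
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelArchiveError("not a model archive (no format_version)")
    if payload["format_version"] != ARCHIVE_FORMAT_VERSION:
        raise ModelArchiveError(
            f"archive format {payload['format_version']} unsupported "
            f"(expected {ARCHIVE_FORMAT_VERSION})")
    missing = {"feature_map", "threshold", "classifier"} - payload.keys()
    if missing:
        raise ModelArchiveError(f"archive missing fields: {sorted(missing)}")
    return DiveModel(
        classifier=payload["classifier"],
        feature_map=validate_feature_map(payload["feature_map"]),
        matrix=payload.get("matrix") or default_similarity_matrix(),
        threshold=payload["threshold"],
        training_metadata=payload.get("training_metadata", {}))
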