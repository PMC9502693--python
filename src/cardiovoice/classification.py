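"""Per-participant trinary classifiers and soft-score decisions.

Two architectures are supported:

* ``margin_ovr`` — three linear one-vs-rest maximum-margin (SVM) binary
  classifiers, one per Stroop level, on standardized predictors.  The
  soft score for level k is the signed distance of the beat from
  classifier k's decision boundary, so a row of scores may be entirely
  negative; the argmax rule then picks the least negative (closest)
  class.
* ``tree_ensemble`` — a bootstrap ensemble (random forest) of decision
  trees grown to purity (minimum one observation per leaf).  The soft
  score for level k is the proportion of trees voting for k, so each row
  is a probability vector.

A heartbeat is classified by the argmax of its score row.  A screen
(sequence of heartbeats) is classified by summing the score matrix over
beats per class column and taking the argmax of the resulting 3-vector —
no calibration is applied to either score type before summation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .beat_sync import BeatFeatureMatrix

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "SoftScoreMatrix",
    "train",
    "score_beats",
    "classify_beat",
    "classify_sequence",
]

logger = logging.getLogger(__name__)

LEVELS = (1, 2, 3)


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    """Hyper-parameters for both classifier kinds.

    margin_c is the soft-margin regularization strength of the linear SVM
    (only ``margin_ovr``); n_trees and min_leaf configure the forest (only
    ``tree_ensemble``).  Standardization uses training-set mean/std and is
    stored with the model.
    """

    kind: str = "margin_ovr"
    margin_c: float = 1.0
    standardize: bool = True
    n_trees: int = 100
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("margin_ovr", "tree_ensemble"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclasses.dataclass(frozen=True)
class SoftScoreMatrix:
    """N x 3 per-beat class scores with the producing classifier's tag."""

    scores: np.ndarray
    classifier: str

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError(f"score matrix must be N x 3, got {s.shape}")

    @property
    def n_beats(self) -> int:
        return self.scores.shape[0]


@dataclasses.dataclass
class TrainedModel:
    """Fitted per-participant model plus its standardization parameters."""

    config: ClassifierConfig
    feature_set: str
    n_features: int
    mean: np.ndarray
    std: np.ndarray
    estimators: list  # one SVC per level, or [RandomForestClassifier]


def _standardize_params(x: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray]:
    if not enabled:
        return np.zeros(x.shape[1]), np.ones(x.shape[1])
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=1)
    std[std == 0] = 1.0  # constant predictors pass through centered
    return mean, std


def train(
    features: BeatFeatureMatrix,
    labels: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
) -> TrainedModel:
    """Fit a trinary classifier on labelled beat features.

    ``labels`` holds the Stroop level (1, 2 or 3) of every beat.  All
    three levels must be present: a one-vs-rest margin classifier cannot
    be built for an absent class, and the forest could never vote for it.
    """
    x = features.values
    y = np.asarray(labels)
    if y.shape != (x.shape[0],):
        raise ValueError(f"labels shape {y.shape} does not match {x.shape[0]} beats")
    if np.any(np.isnan(x)):
        raise ValueError("training features contain NaN")
    present = set(np.unique(y))
    missing = [k for k in LEVELS if k not in present]
    if missing:
        raise ValueError(
            f"level(s) {missing} absent from training data; cannot build "
            f"one-vs-rest classifiers for them"
        )
    mean, std = _standardize_params(x, config.standardize)
    z = (x - mean) / std
    if config.kind == "margin_ovr":
        estimators = []
        for k in LEVELS:
            clf = SVC(kernel="linear", C=config.margin_c, random_state=config.seed)
            clf.fit(z, (y == k).astype(int))
            estimators.append(clf)
    else:
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            min_samples_leaf=config.min_leaf,
            random_state=config.seed,
        )
        forest.fit(z, y)
        estimators = [forest]
    return TrainedModel(
        config=config,
        feature_set=features.feature_set,
        n_features=x.shape[1],
        mean=mean,
        std=std,
        estimators=estimators,
    )


def score_beats(model: TrainedModel, features: BeatFeatureMatrix) -> SoftScoreMatrix:
    """Soft scores for every beat: signed margins or tree-vote proportions."""
    x = features.values
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.n_features}, "
            f"got {x.shape[1]}"
        )
    z = (x - model.mean) / model.std
    if model.config.kind == "margin_ovr":
        cols = [clf.decision_function(z) for clf in model.estimators]
        scores = np.column_stack(cols)
    else:
        forest = model.estimators[0]
        proba = forest.predict_proba(z)
        # map the forest's class order onto levels 1..3 (all present by train())
        order = [list(forest.classes_).index(k) for k in LEVELS]
        scores = proba[:, order]
    return SoftScoreMatrix(scores, model.config.kind)


def _argmax_lowest_tie(scores: np.ndarray) -> int:
    best = int(np.argmax(scores))  # argmax returns the first (lowest) index on ties
    if np.sum(scores == scores[best]) > 1:
        logger.info("tied soft scores %s; choosing level %d", scores, best + 1)
    return best


def classify_beat(score_row: np.ndarray) -> int:
    """Level decision for one beat: argmax of its three soft scores.

    When every margin score is negative this picks the least negative
    (closest) boundary automatically.  Exact ties go to the lowest level.
    """
    row = np.asarray(score_row, dtype=float)
    if row.shape != (3,):
        raise ValueError(f"score row must have 3 entries, got shape {row.shape}")
    if not np.all(np.isfinite(row)):
        raise ValueError("non-finite soft score")
    return _argmax_lowest_tie(row) + 1


def classify_sequence(scores: SoftScoreMatrix) -> tuple[int, np.ndarray]:
    """Screen-level decision from the per-beat score matrix.

    The sequence score vector is the column sum of the N x 3 matrix; the
    returned level is its argmax (ties to the lowest level).
    """
    if scores.n_beats == 0:
        raise ValueError("cannot classify an empty score matrix")
    seq = scores.scores.sum(axis=0)
    return _argmax_lowest_tie(seq) + 1, seq
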