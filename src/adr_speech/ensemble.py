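"""Seed-ensembled classification with majority voting.

Single learners vary substantially in accuracy across random seeds on small
speech cohorts; the remedy used here is an ensemble of identically
configured learners differing only in seed, combined per instance by
majority vote.  Leave-one-out cross-validation (LOOCV) provides training-set
scores; late fusion combines the final votes of the top feature
configurations.  Accuracy is (TP + TN) / (TP + FP + TN + FN) with AD as the
positive class.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "AD"
NEGATIVE_LABEL = "NONAD"

#: Number of seed-varied members in the standard ensemble.
DEFAULT_N_MEMBERS = 50

#: Grid of cluster counts explored in the preliminary search.
DEFAULT_K_GRID = tuple(range(10, 90, 10))


def _make_learner(name: str, seed: int):
    """Instantiate a learner with the frozen hyperparameters."""
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=50, max_depth=5, random_state=seed)
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=50, max_depth=10, random_state=seed, subsample=0.8,
            colsample_bytree=0.8, verbosity=0,
        )
    if name == "svm":
        return SVC(kernel="linear", C=10, random_state=seed)
    if name == "logistic_regression":
        return LogisticRegression(C=10, max_iter=1000, random_state=seed)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown learner {name!r}")


@dataclass
class EnsembleSpec:
    """A learner family plus the list of member seeds."""

    learner: str = "random_forest"
    seeds: tuple[int, ...] = tuple(range(DEFAULT_N_MEMBERS))

    def __post_init__(self) -> None:
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("member seeds must be distinct")
        _make_learner(self.learner, 0)  # validate name eagerly

    @property
    def n_members(self) -> int:
        return len(self.seeds)


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + TN + FN)."""
    if counts.total == 0:
        raise ValueError("no evaluated instances")
    return (counts.tp + counts.tn) / counts.total


def confusion_counts(y_true, y_pred, positive: str = POSITIVE_LABEL) -> ConfusionCounts:
    counts = ConfusionCounts()
    for t, p in zip(y_true, y_pred, strict=True):
        if t == positive:
            if p == positive:
                counts.tp += 1
            else:
                counts.fn += 1
        else:
            if p == positive:
                counts.fp += 1
            else:
                counts.tn += 1
    return counts


@dataclass
class PredictionSet:
    """Per-instance member votes and the majority label."""

    instance_ids: list[str]
    votes: np.ndarray  # (n_instances, n_members) of label strings
    provenance: str = ""

    @property
    def majority(self) -> list[str]:
        return [majority_label(row) for row in self.votes]

    def to_frame(self, y_true=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "participant_id": self.instance_ids,
                "ad_votes": (self.votes == POSITIVE_LABEL).sum(axis=1),
                "nonad_votes": (self.votes == NEGATIVE_LABEL).sum(axis=1),
                "majority_label": self.majority,
            }
        )
        if y_true is not None:
            df["true_label"] = list(y_true)
        return df


def majority_label(votes) -> str:
    """Modal vote; an exact tie resolves to the non-AD label."""
    counts = Counter(votes)
    if counts[POSITIVE_LABEL] > counts[NEGATIVE_LABEL]:
        return POSITIVE_LABEL
    return NEGATIVE_LABEL


def _encode(y: np.ndarray) -> np.ndarray:
    return (np.asarray(y) == POSITIVE_LABEL).astype(int)


def _decode(y01: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(y01) == 1, POSITIVE_LABEL, NEGATIVE_LABEL)


def _fit_predict(learner_name: str, seed: int, X_tr, y_tr, X_te) -> np.ndarray:
    """Train one member and predict; degenerate single-class folds predict
    that fold's majority class."""
    y01 = _encode(y_tr)
    if len(np.unique(y01)) < 2:
        logger.warning("training fold contains a single class; predicting it")
        return _decode(np.full(len(X_te), int(round(y01.mean()))))
    model = _make_learner(learner_name, seed)
    model.fit(X_tr, y01)
    return _decode(model.predict(X_te))


def loocv_majority(
    X: np.ndarray,
    y: np.ndarray,
    spec: EnsembleSpec,
    instance_ids: list[str] | None = None,
) -> tuple[PredictionSet, float]:
    """Seed-wise LOOCV with per-instance majority voting.

    For every member seed a full leave-one-out pass yields one held-out
    prediction per instance; each instance's final label is the majority
    over its member-wise predictions.  Returns the prediction set and the
    majority-vote accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    label_counts = Counter(y)
    if min(label_counts.values()) < 2 or len(label_counts) < 2:
        raise ValueError("need at least 2 instances per class for LOOCV")
    if instance_ids is None:
        instance_ids = [str(i) for i in range(n)]
    votes = np.empty((n, spec.n_members), dtype=object)
    mask = np.ones(n, dtype=bool)
    for m, seed in enumerate(spec.seeds):
        for i in range(n):
            mask[i] = False
            votes[i, m] = _fit_predict(spec.learner, seed, X[mask], y[mask], X[i : i + 1])[0]
            mask[i] = True
    pset = PredictionSet(
        instance_ids=list(instance_ids),
        votes=votes,
        provenance=f"loocv/{spec.learner}/{spec.n_members}seeds",
    )
    acc = accuracy(confusion_counts(y, pset.majority))
    return pset, acc


def train_ensemble(X: np.ndarray, y: np.ndarray, spec: EnsembleSpec) -> list:
    """Fit one member per seed on the full training set."""
    X = np.asarray(X, dtype=float)
    y01 = _encode(y)
    members = []
    for seed in spec.seeds:
        model = _make_learner(spec.learner, seed)
        model.fit(X, y01)
        members.append(model)
    return members


def predict_majority(
    members: list, X: np.ndarray, instance_ids: list[str] | None = None,
    provenance: str = "test",
) -> PredictionSet:
    """Per-instance majority vote over the fitted members."""
    X = np.asarray(X, dtype=float)
    if instance_ids is None:
        instance_ids = [str(i) for i in range(len(X))]
    votes = np.stack([_decode(m.predict(X)) for m in members], axis=1).astype(object)
    return PredictionSet(instance_ids=list(instance_ids), votes=votes, provenance=provenance)


def late_fusion(prediction_sets: list[PredictionSet]) -> PredictionSet:
    """Majority over the final labels of the top configurations.

    With the canonical three voters no ties are possible.
    """
    if len(prediction_sets) != 3:
        raise ValueError("late fusion expects exactly the top-3 prediction sets")
    ids = prediction_sets[0].instance_ids
    for ps in prediction_sets[1:]:
        if ps.instance_ids != ids:
            raise ValueError("prediction sets cover different instances")
    votes = np.stack([ps.majority for ps in prediction_sets], axis=1).astype(object)
    return PredictionSet(
        instance_ids=list(ids),
        votes=votes,
        provenance="late_fusion(" + ",".join(ps.provenance for ps in prediction_sets) + ")",
    )


def grid_search(
    features_for_k,
    y: np.ndarray,
    k_values=DEFAULT_K_GRID,
    learners=("random_forest", "xgboost", "svm", "logistic_regression", "lda"),
    n_seeds: int = 5,
) -> pd.DataFrame:
    """Rank (learner, k) combinations by mean single-model LOOCV accuracy.

    ``features_for_k(k)`` must return the design matrix for cluster count k.
    Each combination is scored by ``n_seeds`` repetitions of plain (single
    member) LOOCV with distinct seeds; the mean accuracy ranks the table.
    """
    y = np.asarray(y)
    rows = []
    for k in k_values:
        X = features_for_k(k)
        for learner in learners:
            accs = []
            for seed in range(n_seeds):
                _, acc = loocv_majority(X, y, EnsembleSpec(learner=learner, seeds=(seed,)))
                accs.append(acc)
            rows.append(
                {
                    "learner": learner,
                    "k": k,
                    "mean_accuracy": float(np.mean(accs)),
                    "std_accuracy": float(np.std(accs)),
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["mean_accuracy", "learner", "k"], ascending=[False, True, True]
    )
    return table.reset_index(drop=True)
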