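"""Response classifiers: random forest, naive Bayes, ridge (L2) logistic
regression, a small neural network and an RBF support vector machine, all
trained on the selected features with probability-like scores in [0, 1].

Random forest training scores for downstream survival use are out-of-bag
(each case scored only by trees that did not see it); resubstitution scores
are available but flagged as such.  Ridge/ANN/SVM inputs are z-scored with
training-cohort statistics stored inside the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .roc import ROCResult, auc_with_p, delong_test

__all__ = [
    "ALGORITHMS",
    "TrainedModel",
    "PredictionScore",
    "train",
    "score_cases",
    "evaluate_roc",
    "delong_compare",
]

ALGORITHMS = ("RF", "NB", "RR", "ANN", "SVM")

_RIDGE_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class PredictionScore:
    case_id: str
    score: float
    source: str  # resubstitution | out_of_bag | held_out

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.source not in ("resubstitution", "out_of_bag", "held_out"):
            raise ValueError(f"unknown score source {self.source!r}")


@dataclass
class TrainedModel:
    algorithm: str
    estimator: object
    feature_ids: tuple[str, ...]
    seed: int
    training_index: tuple[str, ...]
    oob_scores: dict[str, float] | None = None


def _check_classes(labels: np.ndarray) -> None:
    pos = int(labels.sum())
    neg = int(len(labels) - pos)
    if pos < 2 or neg < 2:
        raise ValueError(
            f"need at least 2 cases per class, got {pos} positives / {neg} negatives"
        )


def _ridge_c(x: np.ndarray, y: np.ndarray, seed: int) -> float:
    """Pick the L2 penalty from a small fixed grid by seeded 3-fold CV AUC."""
    best = (-np.inf, _RIDGE_GRID[0])
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    for c in _RIDGE_GRID:
        aucs = []
        for tr, te in skf.split(xs, y):
            if len(np.unique(y[te])) < 2:
                continue
            clf = LogisticRegression(C=c, max_iter=5000)
            clf.fit(xs[tr], y[tr])
            s = clf.predict_proba(xs[te])[:, 1]
            aucs.append(auc_with_p(s, y[te]).auc)
        mean_auc = float(np.mean(aucs)) if aucs else 0.5
        if mean_auc > best[0] + 1e-12:
            best = (mean_auc, c)
    return best[1]


def train(algorithm: str, table: pd.DataFrame, labels, seed: int = 0,
          hyperparams: dict | None = None) -> TrainedModel:
    """Fit one of the five classifiers on a case-by-feature table.

    All estimators output a probability-like score (RF: fraction of trees
    voting responder; SVM: Platt-scaled decision values).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    hp = hyperparams or {}
    y = np.asarray(labels).astype(int)
    _check_classes(y)
    x = table.to_numpy(dtype=float)

    if algorithm == "RF":
        est = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500),
            max_features="sqrt",
            oob_score=True,
            random_state=seed,
        )
    elif algorithm == "NB":
        est = GaussianNB()
    elif algorithm == "RR":
        c = hp.get("C") or _ridge_c(x, y, seed)
        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=c, max_iter=5000)),
        ])
    elif algorithm == "ANN":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", MLPClassifier(hidden_layer_sizes=(hp.get("hidden", 8),),
                                  max_iter=3000, early_stopping=False,
                                  random_state=seed)),
        ])
    else:  # SVM
        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", SVC(kernel="rbf", probability=True, random_state=seed)),
        ])

    est.fit(x, y)
    oob = None
    if algorithm == "RF":
        oob_probs = est.oob_decision_function_[:, 1]
        # a case can miss OOB coverage with few trees; fall back to its
        # resubstitution score there
        resub = est.predict_proba(x)[:, 1]
        oob_probs = np.where(np.isnan(oob_probs), resub, oob_probs)
        oob = {cid: float(s) for cid, s in zip(table.index, oob_probs)}
    return TrainedModel(
        algorithm=algorithm,
        estimator=est,
        feature_ids=tuple(table.columns),
        seed=seed,
        training_index=tuple(table.index),
        oob_scores=oob,
    )


def score_cases(model: TrainedModel, table: pd.DataFrame,
                source: str | None = None) -> list[PredictionScore]:
    """Score cases with a trained model.

    For the RF model evaluated on exactly its training cohort, out-of-bag
    scores are returned (source ``out_of_bag``) unless ``source`` forces
    ``resubstitution``.  Unknown feature columns raise.
    """
    missing = set(model.feature_ids) - set(table.columns)
    if missing:
        raise KeyError(f"table lacks model features: {sorted(missing)[:5]}")
    x = table[list(model.feature_ids)].to_numpy(dtype=float)
    same_cohort = tuple(table.index) == model.training_index
    if (model.algorithm == "RF" and same_cohort and model.oob_scores
            and source != "resubstitution"):
        return [
            PredictionScore(str(cid), model.oob_scores[cid], "out_of_bag")
            for cid in table.index
        ]
    probs = model.estimator.predict_proba(x)[:, 1]
    if source is None:
        source = "resubstitution" if same_cohort else "held_out"
    return [
        PredictionScore(str(cid), float(np.clip(s, 0.0, 1.0)), source)
        for cid, s in zip(table.index, probs)
    ]


def evaluate_roc(scores, labels) -> ROCResult:
    """ROC of a score vector against response labels (DeLong 95% CI)."""
    vals = [s.score for s in scores] if scores and isinstance(scores[0], PredictionScore) else scores
    return auc_with_p(vals, labels)


def delong_compare(scores_a, scores_b, labels) -> float:
    """Paired DeLong p-value for two score vectors on the same cases."""
    a = [s.score for s in scores_a] if scores_a and isinstance(scores_a[0], PredictionScore) else scores_a
    b = [s.score for s in scores_b] if scores_b and isinstance(scores_b[0], PredictionScore) else scores_b
    return delong_test(a, b, labels)
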