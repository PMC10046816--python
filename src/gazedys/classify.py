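"""Single-feature dyslexia classification with leave-one-subject-out (LOSO)
evaluation.

Each model sees exactly one feature (one SI/VAS total at one sampling rate,
or the reading-time baseline) as its only predictor.  Evaluation is LOSO:
all trials of one subject form the test fold, the remaining subjects form
training; this is repeated once per subject and the test predictions of all
folds are concatenated before any metric is computed — the setting closest
to screening a previously unseen child.  Within every training fold the
feature is standardized and hyperparameters are chosen by grid search with
fivefold cross-validation, on training data only, so no information from
the held-out subject leaks into the fit.

The dyslexic class is positive throughout: sensitivity is dyslexic recall,
specificity control recall, and AUROC is computed from continuous decision
scores via the rank (Mann-Whitney) statistic, never from hard labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

ALGORITHMS = ("LR", "SVM", "KNN", "RF")

_C_GRID = [10.0 ** k for k in range(-3, 4)]

#: Hyperparameter grids searched per training fold (first-best in this
#: order wins ties, deterministically).
DEFAULT_GRIDS: Dict[str, dict] = {
    "LR": {"clf__C": _C_GRID},
    "SVM": {"clf__C": _C_GRID, "clf__kernel": ["linear", "rbf"]},
    "KNN": {"clf__n_neighbors": [1, 3, 5, 7, 9, 11]},
    "RF": {"clf__n_estimators": [50, 100, 200], "clf__max_depth": [2, 3, 5, None]},
}


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "LR":
        return LogisticRegression(max_iter=5000)
    if algorithm == "SVM":
        return SVC(gamma="scale")
    if algorithm == "KNN":
        return KNeighborsClassifier()
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


@dataclass
class EvalReport:
    """Concatenated-fold LOSO evaluation of one feature x one algorithm."""

    feature_name: str
    algorithm: str
    acc: float
    se: float
    sp: float
    f1: float
    auroc: float
    predictions: pd.DataFrame          # subject_id, cc, label, prediction, score
    fold_params: List[dict]

    def to_dict(self) -> dict:
        return {
            "feature_name": self.feature_name,
            "algorithm": self.algorithm,
            "acc": self.acc, "se": self.se, "sp": self.sp,
            "f1": self.f1, "auroc": self.auroc,
            "n_trials": int(len(self.predictions)),
            "n_folds": len(self.fold_params),
        }

    def summary(self) -> str:
        return (
            f"{self.feature_name} / {self.algorithm}: "
            f"ACC={self.acc:.3f} Se={self.se:.3f} Sp={self.sp:.3f} "
            f"F1={self.f1:.3f} AUROC={self.auroc:.3f} "
            f"({len(self.predictions)} trials, {len(self.fold_params)} folds)"
        )


def loso_split(records: pd.DataFrame) -> Iterator[Tuple[np.ndarray, np.ndarray, str]]:
    """Yield (train_index, test_index, subject) leave-one-subject-out folds.

    One fold per subject, in sorted subject order; every trial of the held
    subject is in its test fold and nowhere else.
    """
    subjects = sorted(records["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out requires at least 2 subjects")
    sid = records["subject_id"].to_numpy()
    pos = np.arange(len(records))
    for s in subjects:
        mask = sid == s
        yield pos[~mask], pos[mask], s


def rank_auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUROC as the normalized Mann-Whitney rank statistic of the scores."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = int(labels.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes present")
    r = rankdata(scores)
    u1 = r[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def compute_metrics(labels, predictions, scores) -> Dict[str, float]:
    """ACC, Se (dyslexic recall), Sp (control recall), F1, AUROC.

    ``labels`` and ``predictions`` are binary with 1 = dyslexic;
    ``scores`` are continuous decision values for the AUROC rank statistic.
    """
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (labels.size == predictions.size == scores.size):
        raise ValueError("labels, predictions and scores must have equal length")
    tp = int(((labels == 1) & (predictions == 1)).sum())
    tn = int(((labels == 0) & (predictions == 0)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    n = labels.size
    return {
        "acc": (tp + tn) / n,
        "se": tp / (tp + fn) if tp + fn else float("nan"),
        "sp": tn / (tn + fp) if tn + fp else float("nan"),
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
        "auroc": rank_auroc(labels, scores),
    }


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    return np.asarray(proba[:, classes.index(1)], dtype=float)


def fit_eval(
    records: pd.DataFrame,
    feature_name: str,
    algorithm: str,
    seed: int = 0,
    grids: Optional[Dict[str, dict]] = None,
    cv: int = 5,
) -> EvalReport:
    """LOSO-evaluate one algorithm on one feature of a cohort table.

    ``records`` is the long cohort feature table
    (``subject_id,group,cc,feature_name,value``).  Per fold: standardize on
    training data, grid-search hyperparameters by ``cv``-fold CV on training
    only, refit, and score the held-out subject's trials; metrics are
    computed once on the concatenation of all test folds.
    """
    algorithm = algorithm.upper()
    grid = (grids or DEFAULT_GRIDS)[algorithm]
    df = records.loc[records["feature_name"] == feature_name].reset_index(drop=True)
    if df.empty:
        present = sorted(records["feature_name"].unique())
        raise ValueError(f"feature {feature_name!r} not in cohort table; present: {present}")
    y = (df["group"] == "dyslexic").to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError("cohort must contain both dyslexic and control trials")
    X = df[["value"]].to_numpy(dtype=float)

    pred = np.empty(len(df), dtype=int)
    score = np.empty(len(df), dtype=float)
    fold_params: List[dict] = []
    for train_idx, test_idx, subject in loso_split(df):
        y_tr = y[train_idx]
        if y_tr.min() == y_tr.max():
            raise ValueError(f"training fold for subject {subject!r} has a single class")
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("clf", _make_estimator(algorithm, seed)),
        ])
        search = GridSearchCV(pipe, grid, cv=cv, scoring="accuracy", n_jobs=None)
        search.fit(X[train_idx], y_tr)
        pred[test_idx] = search.predict(X[test_idx])
        score[test_idx] = _decision_scores(search.best_estimator_, X[test_idx])
        fold_params.append({"subject": subject, **search.best_params_})

    m = compute_metrics(y, pred, score)
    predictions = pd.DataFrame({
        "subject_id": df["subject_id"],
        "cc": df["cc"],
        "label": y,
        "prediction": pred,
        "score": score,
    })
    return EvalReport(
        feature_name=feature_name,
        algorithm=algorithm,
        acc=m["acc"], se=m["se"], sp=m["sp"], f1=m["f1"], auroc=m["auroc"],
        predictions=predictions,
        fold_params=fold_params,
    )


__all__ = [
    "ALGORITHMS", "DEFAULT_GRIDS", "EvalReport",
    "loso_split", "rank_auroc", "compute_metrics", "fit_eval",
]
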