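"""Multi-model classification harness: hold-out, repeated CV, cross-cohort.

Eight classifiers are supported with fixed, literature-conventional
hyperparameters: logistic regression (max_iter 5000), KNN (k=7), linear-kernel
SVM, AdaBoost (learning-rate 0.01, ≤50 estimators), XGBoost with tree and
linear boosters (learning-rate 0.01; gamma 0.05 for the tree booster),
random forest (100 trees), and a dense neural network (one 512-unit hidden
layer trained with Adam on log-loss).  Every report carries accuracy,
sensitivity (PD = positive class), specificity, ROC AUC and the R² score of
the hard predictions, together with enough provenance (model, scheme,
split, seed, hyperparameters) to rerun it.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from pdeeg.feature_table import FeatureTable
from pdeeg.selection import SelectionScheme, SplitSpec, r2_binary

MODEL_NAMES = ("lr", "knn", "svm", "adaboost", "xgb-tree", "xgb-linear", "rf", "ann")

_DEFAULT_PARAMS: dict[str, dict] = {
    "lr": {"max_iter": 5000},
    "knn": {"n_neighbors": 7},
    "svm": {"kernel": "linear"},
    "adaboost": {"learning_rate": 0.01, "n_estimators": 50},
    "xgb-tree": {"booster": "gbtree", "learning_rate": 0.01, "gamma": 0.05,
                 "n_estimators": 100},
    "xgb-linear": {"booster": "gblinear", "learning_rate": 0.01, "n_estimators": 100},
    "rf": {"n_estimators": 100},
    "ann": {"hidden_layer_sizes": (512,), "solver": "adam", "alpha": 1e-3,
            "batch_size": 8, "max_iter": 200},
}


@dataclass(frozen=True)
class ModelConfig:
    """A model name plus hyperparameter overrides; defaults are the fixed zoo settings."""

    model: str
    params: dict = field(default_factory=dict)

    def resolved_params(self) -> dict:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; valid: {', '.join(MODEL_NAMES)}")
        return {**_DEFAULT_PARAMS[self.model], **self.params}


@dataclass
class EvaluationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc_roc: float
    r2: float
    n_test: int
    scheme: str
    model: str
    split: str
    seed: int
    hyperparameters: dict = field(default_factory=dict)
    train_r2: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def build_model(config: ModelConfig, seed: int = 0):
    """Instantiate one classifier from the zoo; deterministic given ``seed``."""
    params = config.resolved_params()
    name = config.model
    if name == "lr":
        return LogisticRegression(**params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "svm":
        return SVC(**params)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if name in ("xgb-tree", "xgb-linear"):
        return XGBClassifier(random_state=seed, eval_metric="logloss", verbosity=0, **params)
    if name == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "ann":
        return MLPClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model {name!r}; valid: {', '.join(MODEL_NAMES)}")


def _decision_scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=float)
    return np.asarray(clf.predict_proba(X)[:, 1], dtype=float)


def _metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> dict:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return {
        "accuracy": (tp + tn) / y_true.size,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "auc_roc": float(roc_auc_score(y_true, scores)),
        "r2": r2_binary(y_true, y_pred),
    }


def _fit_and_report(X_tr, y_tr, X_te, y_te, config: ModelConfig, seed: int,
                    scheme_name: str, split_desc: str, with_train_r2: bool = False
                    ) -> EvaluationReport:
    if len(np.unique(y_te)) < 2:
        raise ValueError("test set contains a single class; metrics undefined")
    scaler = StandardScaler().fit(X_tr)
    clf = build_model(config, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP batch-size clipping / convergence chatter
        clf.fit(scaler.transform(X_tr), y_tr)
    Xs = scaler.transform(X_te)
    m = _metrics(y_te, clf.predict(Xs), _decision_scores(clf, Xs))
    train_r2 = None
    if with_train_r2:
        train_r2 = r2_binary(y_tr, clf.predict(scaler.transform(X_tr)))
    return EvaluationReport(**m, n_test=int(len(y_te)), scheme=scheme_name,
                            model=config.model, split=split_desc, seed=seed,
                            hyperparameters=config.resolved_params(), train_r2=train_r2)


def evaluate_holdout(table: FeatureTable, scheme: SelectionScheme, config: ModelConfig,
                     split: SplitSpec | None = None,
                     eye_states: Sequence[str] | None = None,
                     with_train_r2: bool = False) -> EvaluationReport:
    """Subject-stratified hold-out evaluation restricted to a channel scheme."""
    split = split or SplitSpec()
    missing = [c for c in scheme.channels if c not in table.channels]
    if missing:
        raise ValueError(f"scheme channels absent from feature table: {missing}")
    subjects = table.subjects
    train, val = split.split(subjects, table.labels(subjects))
    X_tr, y_tr = table.matrix(train, channels=scheme.channels, eye_states=eye_states)
    X_va, y_va = table.matrix(val, channels=scheme.channels, eye_states=eye_states)
    return _fit_and_report(X_tr, y_tr, X_va, y_va, config, split.seed, scheme.name,
                           f"holdout({split.train_fraction:g})", with_train_r2)


def cross_validate(table: FeatureTable, scheme: SelectionScheme, config: ModelConfig,
                   folds: int = 3, rounds: int = 10, seed: int = 0,
                   eye_states: Sequence[str] | None = None
                   ) -> tuple[list[EvaluationReport], pd.DataFrame]:
    """``rounds`` rounds of ``folds``-fold stratified CV with per-round reshuffling.

    Returns all rounds×folds reports plus a mean/sd summary per metric.
    A fold that degenerates to one class is refolded with a fresh seed.
    """
    subjects = np.array(table.subjects)
    y = table.labels(subjects)
    if min(y.sum(), (1 - y).sum()) < folds:
        raise ValueError(f"need at least {folds} subjects per class")
    reports: list[EvaluationReport] = []
    for rnd in range(rounds):
        round_seed = seed + rnd
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=round_seed + 1000 * attempt)
            splits = list(skf.split(subjects, y))
            if all(len(np.unique(y[te])) == 2 for _, te in splits):
                break
            warnings.warn(f"round {rnd}: single-class fold, refolding", stacklevel=2)
        for fold_i, (tr, te) in enumerate(splits):
            X_tr, y_tr = table.matrix(subjects[tr], channels=scheme.channels,
                                      eye_states=eye_states)
            X_te, y_te = table.matrix(subjects[te], channels=scheme.channels,
                                      eye_states=eye_states)
            reports.append(
                _fit_and_report(X_tr, y_tr, X_te, y_te, config, round_seed, scheme.name,
                                f"cv(round={rnd},fold={fold_i})")
            )
    frame = pd.DataFrame([r.to_dict() for r in reports])
    metrics = ["accuracy", "sensitivity", "specificity", "auc_roc", "r2"]
    summary = frame[metrics].agg(["mean", "std"])
    return reports, summary


def out_of_sample(train_table: FeatureTable, test_table: FeatureTable,
                  scheme: SelectionScheme, config: ModelConfig,
                  eye_state_policy: str = "open", seed: int = 0) -> EvaluationReport:
    """Train on one cohort, test on an independently generated/recorded cohort.

    ``eye_state_policy`` selects the training samples: 'open' uses eyes-open
    recordings only, 'both' pools open and closed recordings as separate
    training samples.  The test cohort contributes its eyes-open recordings;
    scaling statistics come from the training cohort only.
    """
    if eye_state_policy not in ("open", "both"):
        raise ValueError("eye_state_policy must be 'open' or 'both'")
    if train_table.channels != test_table.channels:
        raise ValueError("cohorts are not harmonized to a common channel list")
    train_states = ("open",) if eye_state_policy == "open" else ("open", "closed")

    def stack(table: FeatureTable, states: tuple[str, ...]):
        rows, labels = [], []
        for (sid, st) in sorted(table.data):
            if st in states:
                rows.append(table.flatten(sid, channels=scheme.channels, eye_states=[st]))
                labels.append(int(table.groups[sid] == "pd"))
        return np.stack(rows), np.array(labels)

    X_tr, y_tr = stack(train_table, train_states)
    X_te, y_te = stack(test_table, ("open",))
    return _fit_and_report(X_tr, y_tr, X_te, y_te, config, seed, scheme.name,
                           f"out-of-sample({eye_state_policy})")


def feature_dimensionality(n_channels: int, n_segments: int, n_bands: int,
                           n_features: int) -> int:
    """Flattened per-subject feature-vector length: channels × segments × bands × features."""
    dims = (n_channels, n_segments, n_bands, n_features)
    if any(d <= 0 for d in dims):
        raise ValueError(f"all dimensions must be positive, got {dims}")
    return int(np.prod(dims))
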