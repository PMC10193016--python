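"""Classifier training with stratified splitting, grid-searched
cross-validation, and generalization-gap (Δ Training − Test) diagnostics.

The gap report is the overfitting diagnosis used to compare a model
trained on a handful of seed molecules against one trained with
fragment-grown augmentation: a large Δaccuracy/ΔMCC/ΔF1 means the model
memorized the training set; augmentation should shrink it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .chem import FeaturizerConfig, MoleculeRecord, ScalerParams, featurize


@dataclass
class SplitSpec:
    test_fraction: float = 0.25
    rng_seed: int = 0
    group_by_parent: bool = True

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return {"test_fraction": self.test_fraction, "rng_seed": self.rng_seed,
                "group_by_parent": self.group_by_parent}


def stratified_split(records: list[MoleculeRecord], spec: SplitSpec):
    """Class-stratified train/test split.

    With ``group_by_parent`` a seed and all of its augmented descendants
    land on the same side, so near-duplicate analogs can never leak
    across the split: the split is decided at seed level.
    """
    if spec.group_by_parent:
        units = [r for r in records if r.provenance != "augmented"]
    else:
        units = list(records)
    labels = [r.label for r in units]
    for cls in set(labels):
        if labels.count(cls) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members; "
                             "cannot stratify")
    train_units, test_units = train_test_split(
        units, test_size=spec.test_fraction, stratify=labels,
        random_state=spec.rng_seed, shuffle=True)
    if not spec.group_by_parent:
        return list(train_units), list(test_units)
    test_ids = {r.id for r in test_units}
    train, test = list(train_units), list(test_units)
    for r in records:
        if r.provenance == "augmented":
            (test if r.parent_id in test_ids else train).append(r)
    return train, test


@dataclass
class TrainConfig:
    model_family: str = "random_forest"
    class_weight_balanced: bool = True
    cv_folds: int = 5          # 5 for seed-only sets, 10 for augmented sets
    grid: dict = field(default_factory=dict)
    scoring: str = "recall"

    def __post_init__(self):
        if self.model_family not in _FAMILIES:
            raise ValueError(f"unknown model family: {self.model_family}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.scoring not in _SCORERS:
            raise ValueError(f"unknown scoring: {self.scoring}")
        if not self.grid:
            self.grid = dict(DEFAULT_GRIDS[self.model_family])

    def to_dict(self) -> dict:
        return {"model_family": self.model_family,
                "class_weight_balanced": self.class_weight_balanced,
                "cv_folds": self.cv_folds, "grid": self.grid,
                "scoring": self.scoring}


_FAMILIES = ("random_forest", "svm", "logistic_regression", "knn")
_SCORERS = {"recall": "recall", "accuracy": "accuracy", "f1": "f1",
            "mcc": "matthews_corrcoef"}

DEFAULT_GRIDS = {
    "random_forest": {"n_estimators": [100, 300], "max_depth": [10, None],
                      "min_samples_leaf": [3, 1]},
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]},
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0]},
    "knn": {"n_neighbors": [11, 5, 3]},
}


def _make_estimator(cfg: TrainConfig, rng_seed: int):
    weight = "balanced" if cfg.class_weight_balanced else None
    if cfg.model_family == "random_forest":
        return RandomForestClassifier(class_weight=weight, random_state=rng_seed)
    if cfg.model_family == "svm":
        return SVC(class_weight=weight, probability=True, random_state=rng_seed)
    if cfg.model_family == "logistic_regression":
        return LogisticRegression(class_weight=weight, max_iter=5000)
    return KNeighborsClassifier()


def _simplicity_ordered_grid(cfg: TrainConfig):
    """Grid points ordered simplest first, so score ties resolve to the
    simpler model: fewest trees / shallowest depth / strongest
    regularization / most neighbors."""
    names = list(cfg.grid)
    points = [{}]
    for name in names:
        points = [dict(p, **{name: v}) for p in points for v in cfg.grid[name]]

    def key(p):
        out = []
        for name in names:
            v = p[name]
            if name == "max_depth":
                out.append(math.inf if v is None else v)
            elif name in ("min_samples_leaf", "n_neighbors"):
                out.append(-v)     # larger leaf / more neighbors = simpler
            elif name == "C":
                out.append(v)      # smaller C = stronger regularization
            elif isinstance(v, (int, float)):
                out.append(v)
            else:
                out.append(str(v))
        return tuple(out)

    return sorted(points, key=key)


@dataclass
class ModelBundle:
    """Everything needed to reproduce predictions: fitted classifier,
    featurizer config, fitted property scaler, CV results and seeds."""

    estimator: object
    train_config: TrainConfig
    scaler: ScalerParams
    featurizer: FeaturizerConfig
    cv_results: pd.DataFrame
    best_params: dict
    rng_seed: int


def train_model(train_records: list[MoleculeRecord], cfg: TrainConfig,
                rng_seed: int = 0,
                featurizer: FeaturizerConfig | None = None) -> ModelBundle:
    """Grid-search CV on the training set, refit the best point.

    The scaler is fitted on the training set only. The selected grid
    point maximizes mean CV score under ``cfg.scoring``; ties go to the
    simpler model.
    """
    featurizer = featurizer or FeaturizerConfig()
    y = np.array([r.label for r in train_records])
    if len(set(y.tolist())) < 2:
        raise ValueError("training set has a single class")
    X, scaler = featurize(train_records, None, featurizer)
    base = _make_estimator(cfg, rng_seed)
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                         random_state=rng_seed)
    rows = []
    best_idx, best_score = 0, -np.inf
    points = _simplicity_ordered_grid(cfg)
    for i, params in enumerate(points):
        est = clone(base).set_params(**params)
        scores = cross_val_score(est, X, y, scoring=_SCORERS[cfg.scoring],
                                 cv=cv, error_score="raise")
        for fold, s in enumerate(scores):
            rows.append({"grid_index": i, **params, "fold": fold, "score": s})
        mean = scores.mean()
        if mean > best_score:        # strict: ties keep the earlier = simpler
            best_idx, best_score = i, mean
    best_params = points[best_idx]
    final = clone(base).set_params(**best_params).fit(X, y)
    return ModelBundle(estimator=final, train_config=cfg, scaler=scaler,
                       featurizer=featurizer, cv_results=pd.DataFrame(rows),
                       best_params=best_params, rng_seed=rng_seed)


def predict_proba(bundle: ModelBundle, records) -> np.ndarray:
    """Class-1 (active) probability per molecule; NaN for molecules that
    cannot be featurized."""
    ok_records, ok_idx = [], []
    for i, r in enumerate(records):
        try:
            from .chem import mol_from_smiles
            mol_from_smiles(r.smiles if isinstance(r, MoleculeRecord) else r)
            ok_records.append(r)
            ok_idx.append(i)
        except ValueError:
            warnings.warn(f"unfeaturizable molecule at position {i}")
    out = np.full(len(records), np.nan)
    if ok_records:
        X, _ = featurize(ok_records, bundle.scaler, bundle.featurizer)
        cls1 = list(bundle.estimator.classes_).index(1)
        out[ok_idx] = bundle.estimator.predict_proba(X)[:, cls1]
    return out


# ---------------------------------------------------------------------------
# Metrics

@dataclass
class MetricsReport:
    accuracy: float
    mcc: float | None
    f1: float
    roc_auc: float | None
    confusion: tuple  # (tn, fp, fn, tp)

    def to_dict(self) -> dict:
        tn, fp, fn, tp = self.confusion
        return {"accuracy": self.accuracy, "mcc": self.mcc, "f1": self.f1,
                "roc_auc": self.roc_auc, "tn": tn, "fp": fp, "fn": fn, "tp": tp}


@dataclass
class GapReport:
    delta_accuracy: float
    delta_mcc: float | None
    delta_f1: float

    def to_dict(self) -> dict:
        return {"delta_accuracy": self.delta_accuracy,
                "delta_mcc": self.delta_mcc, "delta_f1": self.delta_f1}


def metrics_from_confusion(tn: int, fp: int, fn: int, tp: int):
    """Accuracy, MCC and F1 straight from the confusion-matrix definition.

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined
    as 0 when any marginal is empty (the constant-classifier convention).
    """
    total = tn + fp + fn + tp
    accuracy = (tp + tn) / total
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    f1_denom = 2 * tp + fp + fn
    f1 = 0.0 if f1_denom == 0 else 2 * tp / f1_denom
    return accuracy, mcc, f1


def evaluate(bundle: ModelBundle, records,
             threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics at the probability threshold plus ROC-AUC
    from the full probability ranking.

    Single-class evaluation sets get mcc = roc_auc = None with a warning.
    """
    y = np.array([r.label for r in records])
    proba = predict_proba(bundle, records)
    pred = (proba >= threshold).astype(int)
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    tp = int(np.sum((y == 1) & (pred == 1)))
    accuracy, mcc, f1 = metrics_from_confusion(tn, fp, fn, tp)
    if len(set(y.tolist())) < 2:
        warnings.warn("single-class evaluation set: MCC and ROC-AUC undefined")
        mcc, roc_auc = None, None
    else:
        roc_auc = float(roc_auc_score(y, proba))
    return MetricsReport(accuracy=accuracy, mcc=mcc, f1=f1, roc_auc=roc_auc,
                         confusion=(tn, fp, fn, tp))


def generalization_gap(train_report: MetricsReport,
                       test_report: MetricsReport) -> GapReport:
    """Δ(Training − Test), element-wise."""
    d_mcc = (None if train_report.mcc is None or test_report.mcc is None
             else train_report.mcc - test_report.mcc)
    return GapReport(
        delta_accuracy=train_report.accuracy - test_report.accuracy,
        delta_mcc=d_mcc,
        delta_f1=train_report.f1 - test_report.f1)
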