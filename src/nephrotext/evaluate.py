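"""Cross-validated evaluation of the fusion classifier and tabular baselines.

Protocol: stratified 5-fold cross-validation; per fold, every fitted
statistic (standard scaler, class weights, augmentation noise scales) is
computed on the training folds only, and the held-out fold is scored with
F1 (positive class = severe for the binary task, macro for the 3-class
task), AUC (severe-class probability, or macro one-vs-rest), sensitivity
and specificity (macro-averaged one-vs-rest for multiclass).  Reported as
per-fold values plus mean +/- sd.

Baselines are trained on the standard-scaled numeric tabular features under
the *same* fold assignment: a 4-variable clinical logistic regression (age,
eGFR, 24-h proteinuria, PAR), full-feature logistic regression (1,000
iterations), an RBF-kernel SVM, a 100-tree random forest, and XGBoost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .backends import DEFAULT_K_LAYERS, extract_layer_stack, mean_pooled_primary
from .classifier import FusionMLPClassifier, TrainConfig
from .cohort import (GLOMERULAR_BINARY, IFTA_3CLASS, LabelScheme, PatientRecord,
                     cohort_to_frame)
from .errors import ConfigError, NephrotextError, UndefinedMetricError
from .serialize import PromptTemplate, serialize

__all__ = [
    "FoldAssignment",
    "MetricSet",
    "CVReport",
    "stratified_kfold",
    "compute_metrics",
    "build_feature_matrix",
    "run_cv",
    "run_baselines",
    "scheme_for_task",
]

CLINICAL_BASELINE_FEATURES = ["age", "egfr", "proteinuria_24h", "par"]


def scheme_for_task(task: str) -> LabelScheme:
    if task in ("glomerular", "glomerular_binary"):
        return GLOMERULAR_BINARY
    if task in ("ifta", "ifta_3class"):
        return IFTA_3CLASS
    raise ConfigError(f"unknown task {task!r}; expected glomerular or ifta")


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of sample indices into k stratified folds."""

    fold_id: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id != fold)


def stratified_kfold(labels: Sequence, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Deterministic stratified k-fold assignment (per-fold class counts within 1)."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ConfigError(
            f"every class needs >= k={k} members for stratified {k}-fold CV; "
            f"smallest class has {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_id = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_id[test_idx] = fold
    return FoldAssignment(fold_id=fold_id, k=k)


@dataclass(frozen=True)
class MetricSet:
    """One fold's metrics, all on the [0, 1] scale."""

    f1: float
    auc: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict:
        return {"f1": self.f1, "auc": self.auc,
                "sensitivity": self.sensitivity, "specificity": self.specificity}


def compute_metrics(y_true, y_pred, y_score, scheme: LabelScheme) -> MetricSet:
    """Score one fold.

    Binary task: F1/sensitivity on the severe class, specificity on the mild
    class, AUC from the severe-class probability.  Multiclass: macro-F1,
    macro one-vs-rest AUC, and macro-averaged one-vs-rest sensitivity and
    specificity.  ``y_score`` holds class probabilities (n, C).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    y_score = np.asarray(y_score, dtype=float)
    n_classes = len(scheme.class_names)
    present = np.unique(y_true)
    if len(present) < 2:
        raise UndefinedMetricError("AUC undefined: only one class present in y_true")

    if n_classes == 2:
        f1 = f1_score(y_true, y_pred, pos_label=1, zero_division=0)
        auc = roc_auc_score(y_true, y_score[:, 1])
        tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
    else:
        f1 = f1_score(y_true, y_pred, average="macro", zero_division=0)
        if len(present) == n_classes:
            auc = roc_auc_score(y_true, y_score, multi_class="ovr", average="macro",
                                labels=np.arange(n_classes))
        else:
            # a fold may miss a rare class: average one-vs-rest AUC over present classes
            aucs = [roc_auc_score((y_true == c).astype(int), y_score[:, c])
                    for c in present]
            auc = float(np.mean(aucs))
        cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
        sens_c, spec_c = [], []
        for c in present:
            tp = cm[c, c]
            fn = cm[c].sum() - tp
            fp = cm[:, c].sum() - tp
            tn = cm.sum() - tp - fn - fp
            sens_c.append(tp / (tp + fn) if tp + fn else 0.0)
            spec_c.append(tn / (tn + fp) if tn + fp else 0.0)
        sens = float(np.mean(sens_c))
        spec = float(np.mean(spec_c))
    return MetricSet(f1=float(f1), auc=float(auc), sensitivity=float(sens),
                     specificity=float(spec))


@dataclass
class CVReport:
    """Per-fold metrics plus mean +/- sd, for one task and model."""

    task: str
    model: str
    folds: list[MetricSet]
    extra: dict = field(default_factory=dict)

    @property
    def mean(self) -> dict:
        return {k: float(np.mean([f.as_dict()[k] for f in self.folds]))
                for k in ("f1", "auc", "sensitivity", "specificity")}

    @property
    def sd(self) -> dict:
        return {k: float(np.std([f.as_dict()[k] for f in self.folds]))
                for k in ("f1", "auc", "sensitivity", "specificity")}

    def as_dict(self) -> dict:
        return {"task": self.task, "model": self.model,
                "folds": [f.as_dict() for f in self.folds],
                "mean": self.mean, "sd": self.sd, **self.extra}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), indent=2, **kwargs)


# ---------------------------------------------------------------------------
# Embedding feature construction
# ---------------------------------------------------------------------------

def build_feature_matrix(records: Sequence[PatientRecord], primary, secondary,
                         k_layers: int = DEFAULT_K_LAYERS,
                         template: PromptTemplate | None = None,
                         cache=None) -> np.ndarray:
    """Serialize, embed and stack raw fusion inputs: rows of 11*D values.

    Column layout: the primary backend's K last-token layer vectors
    (ascending), the secondary's K, then the mean-pooled primary embedding.
    ``cache`` may be any mapping-like object keyed by (backend, text).
    """
    template = template or PromptTemplate()
    if primary.spec.hidden_dim != secondary.spec.hidden_dim:
        raise ConfigError("primary and secondary backends must share hidden_dim")
    rows = []
    for rec in records:
        narrative = serialize(rec, template)
        key = (primary.spec.name, secondary.spec.name, narrative.text)
        if cache is not None and key in cache:
            rows.append(cache[key])
            continue
        sp = extract_layer_stack(narrative, primary, k_layers=k_layers)
        ss = extract_layer_stack(narrative, secondary, k_layers=k_layers)
        vq = mean_pooled_primary(narrative, primary)
        row = np.concatenate([sp.matrix.ravel(), ss.matrix.ravel(), vq])
        if cache is not None:
            cache[key] = row
        rows.append(row)
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# Cross-validated pipelines
# ---------------------------------------------------------------------------

def _cv_over_estimator(make_estimator, X, y, folds: FoldAssignment,
                       scheme: LabelScheme, scale: bool = True):
    """Shared CV loop; fold-local scaler fitted on training indices only."""
    fold_metrics: list[MetricSet] = []
    predictions = []
    for fold in range(folds.k):
        tr = folds.train_indices(fold)
        te = folds.test_indices(fold)
        if scale:
            scaler = StandardScaler().fit(X[tr])
            # leakage guard: statistics must be reproducible from training rows alone
            ref_mean = X[tr].mean(axis=0)
            if not np.allclose(scaler.mean_, ref_mean, rtol=0, atol=1e-12):
                raise NephrotextError("internal error: scaler statistics leaked beyond training folds")
            Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
        else:
            Xtr, Xte = X[tr], X[te]
        est = make_estimator(fold)
        est.fit(Xtr, y[tr])
        proba = est.predict_proba(Xte)
        y_pred = est.classes_[np.argmax(proba, axis=1)]
        fold_metrics.append(compute_metrics(y[te], y_pred, proba, scheme))
        for i, idx in enumerate(te):
            predictions.append({"index": int(idx), "fold": fold,
                                "y_true": int(y[idx]), "y_pred": int(y_pred[i]),
                                **{f"p{c}": float(proba[i, c]) for c in range(proba.shape[1])}})
    return fold_metrics, predictions


def run_cv(records: Sequence[PatientRecord], task: str, primary, secondary,
           config: TrainConfig = TrainConfig(), proj_dim: int = 1024,
           k: int = 5, seed: int = 0, template: PromptTemplate | None = None,
           folds: FoldAssignment | None = None, cache=None,
           permute_labels: bool = False) -> CVReport:
    """Full tabular-to-text-to-vector pipeline under stratified k-fold CV.

    ``permute_labels=True`` shuffles labels before fold assignment — the
    permutation null, under which mean AUC should sit near 0.5.
    """
    scheme = scheme_for_task(task)
    y = scheme.encode_all(records)
    if permute_labels:
        y = np.random.default_rng(seed).permutation(y)
    X = build_feature_matrix(records, primary, secondary, template=template, cache=cache)
    folds = folds or stratified_kfold(y, k=k, seed=seed)
    fold_seeds = np.random.default_rng(seed).integers(2**31, size=folds.k)

    def make_estimator(fold: int) -> FusionMLPClassifier:
        return FusionMLPClassifier(
            proj_dim=proj_dim, hidden_dim=config.hidden_dim,
            learning_rate=config.learning_rate, weight_decay=config.weight_decay,
            epochs=config.epochs, batch_size=config.batch_size,
            dropout=config.dropout, smoothing_alpha=config.smoothing_alpha,
            augment_copies=config.augment_copies, noise_scale=config.noise_scale,
            epsilon=config.epsilon, random_state=int(fold_seeds[fold]),
        )

    fold_metrics, predictions = _cv_over_estimator(make_estimator, X, y, folds, scheme)
    return CVReport(task=scheme.task, model="fusion_mlp", folds=fold_metrics,
                    extra={"seed": seed, "k": folds.k, "predictions": predictions,
                           "permuted": permute_labels})


def tabular_features(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Numeric tabular design matrix (sex and hypertension encoded 0/1)."""
    df = cohort_to_frame(records).drop(columns=["id", "glomerular_class", "ifta_score"])
    df["sex"] = (df["sex"] == "male").astype(int)
    df["hypertension"] = df["hypertension"].astype(int)
    return df


def run_baselines(records: Sequence[PatientRecord], task: str, seed: int = 0,
                  k: int = 5, folds: FoldAssignment | None = None) -> dict[str, CVReport]:
    """Train the reference tabular baselines under shared stratified folds."""
    from xgboost import XGBClassifier  # heavyweight import kept local

    scheme = scheme_for_task(task)
    y = scheme.encode_all(records)
    df = tabular_features(records)
    folds = folds or stratified_kfold(y, k=k, seed=seed)

    X_full = df.to_numpy(dtype=float)
    X_clin = df[CLINICAL_BASELINE_FEATURES].to_numpy(dtype=float)

    model_specs = {
        "clinical_lr": (X_clin, lambda f: LogisticRegression(max_iter=1000)),
        "logistic_regression": (X_full, lambda f: LogisticRegression(max_iter=1000)),
        "svm_rbf": (X_full, lambda f: SVC(kernel="rbf", probability=True, random_state=seed)),
        "random_forest": (X_full, lambda f: RandomForestClassifier(n_estimators=100, random_state=seed)),
        "xgboost": (X_full, lambda f: XGBClassifier(random_state=seed, eval_metric="logloss")),
    }
    reports = {}
    for name, (X, make) in model_specs.items():
        fold_metrics, predictions = _cv_over_estimator(make, X, y, folds, scheme)
        reports[name] = CVReport(task=scheme.task, model=name, folds=fold_metrics,
                                 extra={"seed": seed, "k": folds.k,
                                        "n_features": X.shape[1]})
    return reports
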