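"""PD-vs-healthy classification from gait feature tables.

The screening task is binary: healthy elderly (negative) versus
Parkinson's patients of any stage (positive).  The workflow mirrors a
small-cohort clinical study:

1. recursive feature elimination with cross-validated scoring (RFECV,
   random-forest ranker, stratified ten-fold accuracy) picks the feature
   subset;
2. eight conventional classifiers — AdaBoost, decision tree, k-nearest
   neighbours, linear discriminant analysis, logistic regression,
   Gaussian naive Bayes, random forest, and a support-vector machine —
   are scored by stratified ten-fold cross-validation (accuracy,
   precision, recall, F1, pooled over folds, all in percent) and by
   leave-one-out prediction scores pooled into one ROC/AUC per model.

Standardization and every fitted component live inside a Pipeline, so
nothing is learned from a test fold (no leakage); all randomness is
seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score, roc_curve)
from sklearn.model_selection import (LeaveOneOut, StratifiedKFold,
                                     cross_val_predict)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ParameterError
from .gait_events import extract_all
from .pose_model import FEATURE_NAMES, GROUPS
from .synthetic_gait import blend_params, cohort_preset, generate_cohort

MODEL_NAMES = ("AdaBoost", "DT", "KNN", "LDA", "LOG", "NB", "RF", "SVM")

#: PD is the positive (screening-target) class.
POSITIVE_LABEL = 1


def _make_models(seed: int) -> dict[str, object]:
    return {
        "AdaBoost": AdaBoostClassifier(random_state=seed),
        "DT": DecisionTreeClassifier(random_state=seed),
        "KNN": KNeighborsClassifier(),
        "LDA": LinearDiscriminantAnalysis(),
        "LOG": LogisticRegression(max_iter=2000),
        "NB": GaussianNB(),
        "RF": RandomForestClassifier(random_state=seed),
        "SVM": SVC(kernel="rbf", random_state=seed),
    }


@dataclass
class ClassificationReport:
    """Cross-validated metrics for the eight classifiers."""

    metrics: pd.DataFrame           # index = model, columns = Acc/Prec/Rec/F1 (%)
    auc: dict[str, float]           # leave-one-out AUC per model
    roc: dict[str, pd.DataFrame]    # (fpr, tpr) points per model
    selected_features: list[str]
    seed: int
    n_folds: int = 10
    cv_curve: pd.DataFrame | None = None  # RFECV score vs n_features

    def to_json_dict(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "seed": self.seed,
            "n_folds": self.n_folds,
            "metrics": self.metrics.round(2).to_dict(orient="index"),
            "auc": {m: round(a, 4) for m, a in self.auc.items()},
        }


def binary_labels(features: pd.DataFrame) -> np.ndarray:
    """healthy -> 0, early/mid PD pooled -> 1."""
    groups = features["group"]
    unknown = set(groups.dropna()) - set(GROUPS)
    if unknown:
        raise ParameterError(
            f"non-binary or unknown group labels {sorted(unknown)}; pool "
            "stages into healthy vs pd first")
    return (groups != "healthy").astype(int).to_numpy()


def subject_level(features: pd.DataFrame) -> pd.DataFrame:
    """Average segment rows into one feature vector per subject."""
    agg = {name: "mean" for name in FEATURE_NAMES}
    agg["group"] = "first"
    return (features.groupby("subject_id", as_index=False)
            .agg(agg))


def _cv_folds(y: np.ndarray, seed: int, requested: int = 10) -> StratifiedKFold:
    smallest = int(np.bincount(y).min())
    n_splits = min(requested, smallest)
    if n_splits < requested:
        warnings.warn(f"class with {smallest} samples: folds reduced to "
                      f"{n_splits}", stacklevel=3)
    return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)


def rfecv_select(features: pd.DataFrame, seed: int = 0,
                 feature_names: tuple[str, ...] = FEATURE_NAMES,
                 ) -> tuple[list[str], pd.DataFrame]:
    """Feature subset maximizing cross-validated accuracy.

    A random-forest ranker drives recursive elimination, scored by
    stratified ten-fold CV accuracy; ties resolve toward fewer features.
    Returns the selected names and the CV curve (score vs subset size).
    """
    data = subject_level(features) if features["subject_id"].duplicated().any() \
        else features
    y = binary_labels(data)
    if np.bincount(y).min() < 2:
        raise ParameterError("need at least 2 samples per class")
    X = data[list(feature_names)].to_numpy()
    if not np.isfinite(X).all():
        raise ParameterError("missing feature values; RFECV does not impute")
    cv = _cv_folds(y, seed)
    if len(feature_names) == 1:
        # nothing to eliminate; report the lone feature's CV accuracy
        from sklearn.model_selection import cross_val_score
        score = cross_val_score(
            Pipeline([("scale", StandardScaler()),
                      ("model", RandomForestClassifier(random_state=seed))]),
            X, y, cv=cv, scoring="accuracy").mean()
        return list(feature_names), pd.DataFrame(
            {"n_features": [1], "cv_accuracy": [score]})
    selector = RFECV(
        estimator=RandomForestClassifier(random_state=seed),
        step=1, cv=cv, scoring="accuracy", min_features_to_select=1)
    # rank on standardized features for symmetry with the classifiers
    Xs = StandardScaler().fit_transform(X)
    selector.fit(Xs, y)
    scores = selector.cv_results_["mean_test_score"]
    curve = pd.DataFrame({"n_features": np.arange(1, len(scores) + 1),
                          "cv_accuracy": scores})
    selected = [n for n, keep in zip(feature_names, selector.support_) if keep]
    return selected, curve


def evaluate_models(features: pd.DataFrame, selected: list[str],
                    seed: int = 0) -> ClassificationReport:
    """Ten-fold CV metrics and leave-one-out ROC/AUC for all 8 models."""
    if not selected:
        raise ParameterError("selected feature list is empty")
    data = subject_level(features) if features["subject_id"].duplicated().any() \
        else features
    y = binary_labels(data)
    if len(np.unique(y)) != 2:
        raise ParameterError("labels are not binary (healthy vs pd)")
    X = data[list(selected)].to_numpy()
    cv = _cv_folds(y, seed)
    loo = LeaveOneOut()
    rows = {}
    aucs: dict[str, float] = {}
    rocs: dict[str, pd.DataFrame] = {}
    for name, model in _make_models(seed).items():
        pipe = Pipeline([("scale", StandardScaler()), ("model", model)])
        pred = cross_val_predict(pipe, X, y, cv=cv)
        rows[name] = {
            "Acc": 100.0 * accuracy_score(y, pred),
            "Prec": 100.0 * precision_score(y, pred, pos_label=POSITIVE_LABEL,
                                            zero_division=0),
            "Rec": 100.0 * recall_score(y, pred, pos_label=POSITIVE_LABEL,
                                        zero_division=0),
            "F1": 100.0 * f1_score(y, pred, pos_label=POSITIVE_LABEL,
                                   zero_division=0),
        }
        method = ("predict_proba" if hasattr(model, "predict_proba")
                  else "decision_function")
        scores = cross_val_predict(pipe, X, y, cv=loo, method=method)
        if scores.ndim == 2:
            scores = scores[:, 1]
        aucs[name] = float(roc_auc_score(y, scores))
        fpr, tpr, _ = roc_curve(y, scores)
        rocs[name] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    metrics = pd.DataFrame.from_dict(rows, orient="index").loc[list(MODEL_NAMES)]
    return ClassificationReport(metrics=metrics, auc=aucs, roc=rocs,
                                selected_features=list(selected), seed=seed,
                                n_folds=cv.get_n_splits())


def cohort_experiment(n_healthy: int = 25, n_pd: int = 34,
                      effect_scale: float = 1.0, seed: int = 0,
                      noise_sd: float | None = None) -> ClassificationReport:
    """End-to-end rehearsal: simulate, extract, select, classify.

    ``effect_scale`` interpolates the PD presets between the healthy
    preset (0: no group difference, chance-level classification) and the
    full published separation (1).  PD subjects split early:mid in the
    study's 19:15 proportion.
    """
    if min(n_healthy, n_pd) < 10:
        raise ParameterError("need at least 10 subjects per class")
    n_early = round(n_pd * 19 / 34)
    n_mid = n_pd - n_early
    healthy = cohort_preset("healthy")
    presets = {
        "healthy": healthy,
        "early_pd": blend_params(healthy, cohort_preset("early_pd"), effect_scale),
        "mid_pd": blend_params(healthy, cohort_preset("mid_pd"), effect_scale),
    }
    sequences, _ = generate_cohort((n_healthy, n_early, n_mid), seed=seed,
                                   presets=presets, noise_sd=noise_sd)
    group_of = {}
    rows = []
    for seq in sequences:
        prefix = seq.subject_id[0]
        group = {"h": "healthy", "e": "early_pd", "m": "mid_pd"}[prefix]
        fs = extract_all(seq)
        fs.group = group
        rows.append(fs.to_row())
    features = pd.DataFrame(rows)
    selected, curve = rfecv_select(features, seed=seed)
    report = evaluate_models(features, selected, seed=seed)
    report.cv_curve = curve
    return report
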