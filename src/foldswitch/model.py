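"""Binary fold-switching classifier on 4-dimensional feature vectors.

A support-vector machine with a polynomial kernel of degree 2 separates
fold-switching from monomorphic proteins in the space of (max rolled
diversity, max rolled entropy, max rolled substitution, mean
uncertainty).  Features are standardized (zero mean, unit variance) with
parameters fitted on the training split only.  Validation uses
stratified six-fold cross-validation; hyperparameters (regularization
weight C, kernel coefficient gamma, independent term coef0) can be tuned
with a Gaussian-process expected-improvement search that maximizes mean
CV accuracy, breaking ties toward smaller C to keep model complexity low.

Labels: fold-switching is the positive class (+1); the confidence of a
prediction is the signed distance to the decision boundary, positive on
the fold-switching side.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from foldswitch.scoring import FeatureVector

logger = logging.getLogger(__name__)

FOLD_SWITCHING = "fold_switching"
MONOMORPHIC = "monomorphic"

#: Default SVM hyperparameters (the search's starting point).
DEFAULT_PARAMS = {"C": 1.0, "gamma": 0.1, "coef0": 1.0}

#: Search space: C log-uniform 1e-2..1e3, gamma log-uniform 1e-3..10,
#: coef0 uniform 0..5.
_SPACE = {"logC": (-2.0, 3.0), "log_gamma": (-3.0, 1.0), "coef0": (0.0, 5.0)}

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy",
                "f1", "mcc")


@dataclass(frozen=True)
class LabelledExample:
    """One training example: a protein's features and its class label."""

    protein_id: str
    features: FeatureVector
    label: str

    def __post_init__(self):
        if self.label not in (FOLD_SWITCHING, MONOMORPHIC):
            raise ValueError(f"unknown label {self.label!r}")
        if not np.all(np.isfinite(self.features.as_array())):
            raise ValueError(f"non-finite features for {self.protein_id!r}")


@dataclass
class TrainedModel:
    """A fitted degree-2 polynomial-kernel SVM with its hyperparameters."""

    params: dict
    pipeline: Pipeline

    @property
    def is_fitted(self) -> bool:
        return hasattr(self.pipeline, "n_features_in_")


@dataclass
class ValidationReport:
    """Per-fold and averaged cross-validation metrics.

    ``fold_confusions`` holds (TP, FN, TN, FP) per held-out fold;
    ``fold_metrics`` the metrics recomputed from each confusion matrix;
    ``mean``/``std`` their across-fold aggregates.  ``fold_scaler_means``
    records each fold's feature-standardization means, fitted on that
    fold's training split only.
    """

    fold_confusions: list[tuple[int, int, int, int]]
    fold_metrics: list[dict]
    mean: dict
    std: dict
    fold_scaler_means: list[np.ndarray] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["metric\tmean\tstd"]
        for m in METRIC_NAMES:
            lines.append(f"{m}\t{self.mean[m]:.4g}\t{self.std[m]:.4g}")
        return "\n".join(lines)


def _examples_to_xy(examples: list[LabelledExample]):
    X = np.array([ex.features.as_array() for ex in examples])
    y = np.array([1 if ex.label == FOLD_SWITCHING else -1 for ex in examples])
    return X, y


def _make_pipeline(params: dict) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="poly", degree=2, C=params["C"],
                        gamma=params["gamma"], coef0=params["coef0"])),
        ]
    )


def compute_metrics(confusion: tuple[int, int, int, int]) -> dict:
    """Standard binary-classification metrics from (TP, FN, TN, FP).

    Accuracy is reported in percent; the others as fractions, MCC in
    [-1, 1].  A ratio with a zero denominator is reported as NaN with a
    warning.
    """
    tp, fn, tn, fp = confusion
    if min(tp, fn, tn, fp) < 0:
        raise ValueError(f"negative counts in confusion matrix {confusion}")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return math.nan
        return num / den

    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    accuracy = 100.0 * (tp + tn) / total
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        warnings.warn("F1 undefined")
        f1 = math.nan
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        warnings.warn("MCC undefined (zero denominator)")
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / denom
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "accuracy": accuracy,
        "f1": f1,
        "mcc": mcc,
    }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    return tp, fn, tn, fp


def cross_validate(
    examples: list[LabelledExample],
    n_folds: int = 6,
    seed: int = 0,
    params: dict | None = None,
    tune_per_fold: bool = False,
    search_budget: int = 8,
) -> ValidationReport:
    """Stratified k-fold cross-validation of the SVM.

    The random partition is controlled by ``seed``; the model is refit
    on each fold's training split (with standardization parameters from
    that split only) and evaluated on the held-out fold.  With
    ``tune_per_fold`` the hyperparameter search is re-run inside each
    fold; otherwise ``params`` (default: :data:`DEFAULT_PARAMS`) are
    used throughout.
    """
    X, y = _examples_to_xy(examples)
    for cls in (1, -1):
        if np.sum(y == cls) < n_folds:
            raise ValueError(
                "fewer examples than folds in one class; use fewer folds "
                "or a different dataset"
            )
    params = dict(params or DEFAULT_PARAMS)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    confusions, fold_metrics, scaler_means = [], [], []
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                f"fold {fold_i}: a class is absent from the training split; "
                "try a different seed"
            )
        fold_params = params
        if tune_per_fold:
            sub = [examples[i] for i in train_idx]
            fold_params = tune_hyperparameters(
                sub, search_budget=search_budget, seed=seed
            ).params
        pipe = _make_pipeline(fold_params)
        pipe.fit(X[train_idx], y[train_idx])
        scaler_means.append(pipe.named_steps["scale"].mean_.copy())
        cm = _confusion(y[test_idx], pipe.predict(X[test_idx]))
        confusions.append(cm)
        fold_metrics.append(compute_metrics(cm))
    mean = {m: float(np.nanmean([fm[m] for fm in fold_metrics]))
            for m in METRIC_NAMES}
    std = {m: float(np.nanstd([fm[m] for fm in fold_metrics], ddof=1))
           for m in METRIC_NAMES}
    return ValidationReport(
        fold_confusions=confusions,
        fold_metrics=fold_metrics,
        mean=mean,
        std=std,
        fold_scaler_means=scaler_means,
    )


def _cv_accuracy(examples: list[LabelledExample], params: dict,
                 n_folds: int, seed: int) -> float:
    return cross_validate(examples, n_folds=n_folds, seed=seed,
                          params=params).mean["accuracy"]


def _params_from_point(x: np.ndarray) -> dict:
    return {"C": 10.0 ** x[0], "gamma": 10.0 ** x[1], "coef0": float(x[2])}


def tune_hyperparameters(
    examples: list[LabelledExample],
    search_budget: int = 16,
    seed: int = 0,
    n_folds: int = 6,
) -> TrainedModel:
    """Bayesian hyperparameter search maximizing mean CV accuracy.

    Starts at the default hyperparameter point (a budget of 1 returns
    it unchanged), then proposes points by expected improvement under a
    Gaussian-process surrogate over (log10 C, log10 gamma, coef0).
    Ties in CV accuracy are broken toward smaller C.  The returned model
    is refit on all examples with the best hyperparameters.
    """
    if search_budget < 1:
        raise ValueError("search_budget must be >= 1")
    rng = np.random.default_rng(seed)
    bounds = np.array(list(_SPACE.values()))
    lo, hi = bounds[:, 0], bounds[:, 1]

    default_point = np.array([
        math.log10(DEFAULT_PARAMS["C"]),
        math.log10(DEFAULT_PARAMS["gamma"]),
        DEFAULT_PARAMS["coef0"],
    ])
    X_obs = [default_point]
    y_obs = [_cv_accuracy(examples, DEFAULT_PARAMS, n_folds, seed)]

    # a few random probes before the surrogate takes over
    n_random = min(max(search_budget // 4, 2), search_budget - 1)
    for _ in range(n_random):
        x = rng.uniform(lo, hi)
        X_obs.append(x)
        y_obs.append(_cv_accuracy(examples, _params_from_point(x), n_folds, seed))

    while len(X_obs) < search_budget:
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.ones(3)),
            normalize_y=True,
            alpha=1e-4,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit((np.array(X_obs) - lo) / (hi - lo), np.array(y_obs))
        cand = rng.uniform(lo, hi, size=(256, 3))
        mu, sigma = gp.predict((cand - lo) / (hi - lo), return_std=True)
        best = max(y_obs)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / sigma
            from scipy.stats import norm
            ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
            ei[sigma == 0] = 0.0
        x = cand[int(np.argmax(ei))]
        X_obs.append(x)
        y_obs.append(_cv_accuracy(examples, _params_from_point(x), n_folds, seed))

    # best accuracy; ties broken toward smaller C (lower complexity)
    order = sorted(range(len(X_obs)), key=lambda i: (-y_obs[i], X_obs[i][0]))
    best_params = _params_from_point(X_obs[order[0]])
    return fit_model(examples, params=best_params)


def fit_model(examples: list[LabelledExample],
              params: dict | None = None) -> TrainedModel:
    """Fit the standardizer + SVM pipeline on all examples."""
    params = dict(params or DEFAULT_PARAMS)
    X, y = _examples_to_xy(examples)
    pipe = _make_pipeline(params)
    pipe.fit(X, y)
    return TrainedModel(params=params, pipeline=pipe)


def predict(model: TrainedModel,
            features: FeatureVector) -> tuple[str, float]:
    """Classify one feature vector.

    Returns the label and the signed distance to the decision boundary
    (positive on the fold-switching side), computed after applying the
    training-set standardization.
    """
    if not model.is_fitted:
        raise ValueError("model is not fitted")
    x = features.as_array().reshape(1, -1)
    confidence = float(model.pipeline.decision_function(x)[0])
    label = FOLD_SWITCHING if confidence > 0 else MONOMORPHIC
    return label, confidence


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump({"format": "foldswitch-svm-v1", "params": model.params,
                 "pipeline": model.pipeline}, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format") != "foldswitch-svm-v1":
        raise ValueError(f"{path}: not a recognized model file")
    return TrainedModel(params=payload["params"], pipeline=payload["pipeline"])
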