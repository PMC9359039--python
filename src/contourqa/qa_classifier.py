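"""SVM-based decision rules separating acceptable from unacceptable contours.

The positive ("flag") class is *unacceptable*. A rule is learned per
structure, either from a single metric (linear kernel — the only kernel
meaningful for a 1-D input, with the decision boundary reported back as a
scalar threshold in metric units) or from a named combination of metrics
with linear / polynomial(3) / RBF / sigmoid kernels. Supporting analyses:
penalty-parameter sweeps, stratified threefold cross-validation,
fixed-sensitivity operating points, threshold averaging across structures,
and ROC/AUC with percentile-bootstrap confidence intervals (n = 2000).

Conventions pinned for reproducibility (the originating study is silent on
them): features are centred/scaled on the training data before the SVM;
kernel coefficient gamma follows the 1/(n_features·Var) rule; a value lying
exactly on a threshold passes as acceptable; hinge loss is unweighted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .surface_metrics import METRIC_NAMES, MetricVector, SIMILARITY_METRICS

__all__ = [
    "REFERENCE_THRESHOLDS",
    "MULTI_METRIC_COMBINATIONS",
    "KERNELS",
    "QAModel",
    "CVReport",
    "ROCResult",
    "OperatingPoint",
    "fit_single_metric",
    "fit_multi_metric",
    "predict",
    "sweep_C",
    "cross_validate",
    "fixed_sensitivity_threshold",
    "average_thresholds",
    "roc_auc",
    "reference_model",
]

#: pooled single-metric thresholds reported for female pelvic structures;
#: usable without any training (all are similarity metrics: flag if below)
REFERENCE_THRESHOLDS: dict[str, float] = {
    "dsc": 0.75,
    "sdsc_1": 0.30,
    "sdsc_2": 0.54,
    "sdsc_3": 0.69,
}

#: named metric combinations for the multi-metric analysis
MULTI_METRIC_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "DSC_HD": ("dsc", "hd_100"),
    "Three_SDSC": ("sdsc_1", "sdsc_2", "sdsc_3"),
    "Five_SDSC": ("sdsc_1", "sdsc_2", "sdsc_3", "sdsc_4", "sdsc_5"),
    "Four_metrics": ("dsc", "hd_100", "hd_95", "msd"),
    "Five_metrics": ("dsc", "msd", "sdsc_1", "sdsc_2", "sdsc_3"),
    "Seven_metrics": ("dsc", "msd", "sdsc_1", "sdsc_2", "sdsc_3", "sdsc_4", "sdsc_5"),
    "Nine_metrics": ("dsc", "msd", "sdsc_1", "sdsc_2", "sdsc_3", "sdsc_4",
                     "sdsc_5", "sdsc_7", "sdsc_10"),
    "All_metrics": tuple(METRIC_NAMES),
}

KERNELS = ("linear", "poly", "rbf", "sigmoid")
_KERNEL_ALIASES = {"polynomial": "poly", "poly": "poly", "linear": "linear",
                   "rbf": "rbf", "sigmoid": "sigmoid"}

UNACCEPTABLE, ACCEPTABLE = "unacceptable", "acceptable"


def _encode_labels(labels: Sequence[str]) -> np.ndarray:
    """Map acceptable→0, unacceptable→1 (the flagged / positive class)."""
    arr = np.asarray(labels)
    bad = set(arr) - {ACCEPTABLE, UNACCEPTABLE}
    if bad:
        raise ValueError(f"labels must be acceptable/unacceptable, got {sorted(bad)}")
    y = (arr == UNACCEPTABLE).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes (acceptable and unacceptable) are required")
    return y


def resolve_metric_set(metric_or_combo) -> tuple[str, ...]:
    """Resolve a metric name, combination name, or explicit list of metrics."""
    if isinstance(metric_or_combo, str):
        if metric_or_combo in MULTI_METRIC_COMBINATIONS:
            return MULTI_METRIC_COMBINATIONS[metric_or_combo]
        if metric_or_combo in METRIC_NAMES:
            return (metric_or_combo,)
        raise KeyError(
            f"unknown metric or combination {metric_or_combo!r}; metrics: "
            f"{METRIC_NAMES}; combinations: {tuple(MULTI_METRIC_COMBINATIONS)}"
        )
    metric_set = tuple(metric_or_combo)
    unknown = [m for m in metric_set if m not in METRIC_NAMES]
    if not metric_set or unknown:
        raise KeyError(f"unknown metrics {unknown} (valid: {METRIC_NAMES})")
    return metric_set


@dataclass
class QAModel:
    """A fitted per-structure decision rule.

    For a single-metric linear model the rule is equivalently expressed as a
    scalar ``threshold`` in metric units with a ``direction``
    (``flag_if_below`` for similarity metrics, ``flag_if_above`` for
    distances); for every model the kernel decision function is stored
    explicitly (support vectors, dual coefficients, intercept) so that a
    JSON round-trip reproduces predictions exactly.
    """

    structure_name: str
    metric_set: tuple[str, ...]
    kernel: str
    penalty_C: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray  # scaled feature space
    dual_coef: np.ndarray
    intercept: float
    gamma: float = 1.0
    degree: int = 3
    coef0: float = 0.0
    threshold: float | None = None   # single-metric linear models only
    direction: str | None = None     # "flag_if_below" | "flag_if_above"

    # -- decision machinery -------------------------------------------------
    def _kernel_matrix(self, xs: np.ndarray) -> np.ndarray:
        sv = self.support_vectors
        if self.kernel == "linear":
            return xs @ sv.T
        if self.kernel == "rbf":
            sq = ((xs[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
            return np.exp(-self.gamma * sq)
        if self.kernel == "poly":
            return (self.gamma * (xs @ sv.T) + self.coef0) ** self.degree
        if self.kernel == "sigmoid":
            return np.tanh(self.gamma * (xs @ sv.T) + self.coef0)
        raise ValueError(f"unknown kernel {self.kernel!r}")

    def decision_function(self, features) -> np.ndarray:
        """Signed distance to the hyperplane; positive ⇒ unacceptable."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != len(self.metric_set):
            raise ValueError(
                f"expected {len(self.metric_set)} features {self.metric_set}, "
                f"got {x.shape[1]}"
            )
        xs = (x - self.scaler_mean) / self.scaler_scale
        return self._kernel_matrix(xs) @ self.dual_coef + self.intercept

    def _features_from(self, vector) -> np.ndarray:
        if isinstance(vector, MetricVector):
            return np.array([vector[m] for m in self.metric_set], dtype=float)
        if isinstance(vector, Mapping):
            missing = [m for m in self.metric_set if m not in vector]
            if missing:
                raise KeyError(f"metric vector is missing {missing}")
            return np.array([float(vector[m]) for m in self.metric_set])
        return np.asarray(vector, dtype=float)

    def predict(self, vector) -> str:
        """Classify one contour pair; degenerate pairs always flag."""
        if isinstance(vector, MetricVector) and vector.degenerate_flag:
            return UNACCEPTABLE
        if isinstance(vector, Mapping) and vector.get("degenerate_flag", False):
            return UNACCEPTABLE
        feats = self._features_from(vector)
        if self.threshold is not None:
            v = float(feats[0])
            if self.direction == "flag_if_below":
                return UNACCEPTABLE if v < self.threshold else ACCEPTABLE
            return UNACCEPTABLE if v > self.threshold else ACCEPTABLE
        # boundary (decision value exactly 0) passes as acceptable
        return UNACCEPTABLE if self.decision_function(feats)[0] > 0 else ACCEPTABLE

    def predict_many(self, features) -> np.ndarray:
        """Vectorised predict over a feature matrix; returns 0/1 (1 = flag)."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if self.threshold is not None:
            v = x[:, 0]
            if self.direction == "flag_if_below":
                return (v < self.threshold).astype(int)
            return (v > self.threshold).astype(int)
        return (self.decision_function(x) > 0).astype(int)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        d = {
            "structure_name": self.structure_name,
            "metric_set": list(self.metric_set),
            "kernel": self.kernel,
            "penalty_C": self.penalty_C,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "degree": self.degree,
            "coef0": self.coef0,
            "threshold": self.threshold,
            "direction": self.direction,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "QAModel":
        d = json.loads(text)
        return cls(
            structure_name=d["structure_name"],
            metric_set=tuple(d["metric_set"]),
            kernel=d["kernel"],
            penalty_C=float(d["penalty_C"]),
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(d["scaler_scale"], dtype=float),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            degree=int(d["degree"]),
            coef0=float(d["coef0"]),
            threshold=None if d["threshold"] is None else float(d["threshold"]),
            direction=d["direction"],
        )


def _fit_svc(X: np.ndarray, y: np.ndarray, kernel: str, C: float,
             degree: int = 3, coef0: float = 0.0):
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    svc = SVC(kernel=kernel, C=C, gamma="scale", degree=degree, coef0=coef0)
    svc.fit(Xs, y)
    gamma = svc._gamma if hasattr(svc, "_gamma") else svc.gamma
    return scaler, svc, float(gamma)


def _model_from_svc(scaler, svc, gamma, *, structure_name, metric_set, kernel, C,
                    degree=3, coef0=0.0, threshold=None, direction=None) -> QAModel:
    return QAModel(
        structure_name=structure_name,
        metric_set=tuple(metric_set),
        kernel=kernel,
        penalty_C=float(C),
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        gamma=float(gamma),
        degree=degree,
        coef0=coef0,
        threshold=threshold,
        direction=direction,
    )


def fit_single_metric(values: Sequence[float], labels: Sequence[str],
                      penalty_C: float = 10.0, metric_name: str = "",
                      structure_name: str = "") -> QAModel:
    """Fit a linear SVM on one metric and express it as a scalar threshold.

    The threshold is the zero of the decision function mapped back to metric
    units; the flag direction follows the class means (unacceptable contours
    score lower on similarity metrics, higher on distances).
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("metric values must be finite (cap degenerate "
                         "distances before fitting)")
    y = _encode_labels(labels)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 examples of each class")
    X = v.reshape(-1, 1)
    scaler, svc, gamma = _fit_svc(X, y, "linear", penalty_C)
    w = float(svc.coef_[0, 0])
    b = float(svc.intercept_[0])
    if w == 0.0:
        raise ValueError("degenerate linear SVM (zero weight); classes may "
                         "be indistinguishable on this metric")
    # decision(x) = w*(x-mu)/sd + b = 0  ->  x* = mu - b*sd/w
    mu, sd = float(scaler.mean_[0]), float(scaler.scale_[0])
    threshold = mu - b * sd / w
    direction = "flag_if_above" if w > 0 else "flag_if_below"
    name = metric_name or "metric"
    return _model_from_svc(scaler, svc, gamma, structure_name=structure_name,
                           metric_set=(name,), kernel="linear", C=penalty_C,
                           threshold=float(threshold), direction=direction)


def fit_multi_metric(features, labels: Sequence[str], kernel: str = "linear",
                     penalty_C: float = 10.0, metric_set=None,
                     structure_name: str = "", degree: int = 3,
                     coef0: float = 0.0) -> QAModel:
    """Fit an SVM on a metric combination (named or explicit).

    ``features`` may be a DataFrame (columns selected by ``metric_set``) or a
    matrix whose columns already follow ``metric_set`` order. Features are
    standardised internally; gamma uses the 1/(n_features·Var) rule and the
    polynomial degree is fixed at 3.
    """
    kernel = _KERNEL_ALIASES.get(kernel)
    if kernel is None:
        raise ValueError(f"kernel must be one of {KERNELS}")
    if metric_set is None:
        if isinstance(features, pd.DataFrame):
            metric_set = resolve_metric_set(list(features.columns))
        else:
            raise ValueError("metric_set is required for array features")
    else:
        metric_set = resolve_metric_set(metric_set)
    if isinstance(features, pd.DataFrame):
        X = features.loc[:, list(metric_set)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("metric features must be finite")
    y = _encode_labels(labels)
    scaler, svc, gamma = _fit_svc(X, y, kernel, penalty_C, degree, coef0)
    threshold = direction = None
    if kernel == "linear" and len(metric_set) == 1:
        w = float(svc.coef_[0, 0])
        if w != 0.0:
            threshold = float(scaler.mean_[0] - svc.intercept_[0] * scaler.scale_[0] / w)
            direction = "flag_if_above" if w > 0 else "flag_if_below"
    return _model_from_svc(scaler, svc, gamma, structure_name=structure_name,
                           metric_set=metric_set, kernel=kernel, C=penalty_C,
                           degree=degree, coef0=coef0,
                           threshold=threshold, direction=direction)


def predict(model: QAModel, vector) -> str:
    """Module-level alias for :meth:`QAModel.predict`."""
    return model.predict(vector)


def reference_model(metric: str = "sdsc_2") -> QAModel:
    """A ready-to-use single-metric rule at the published pooled threshold.

    Requires no training data: the stored thresholds (DSC 0.75, SDSC_1 0.30,
    SDSC_2 0.54, SDSC_3 0.69) flag a contour whose similarity falls below
    them.
    """
    if metric not in REFERENCE_THRESHOLDS:
        raise KeyError(f"no reference threshold for {metric!r}; "
                       f"available: {sorted(REFERENCE_THRESHOLDS)}")
    t = REFERENCE_THRESHOLDS[metric]
    return QAModel(
        structure_name="pooled_reference",
        metric_set=(metric,),
        kernel="linear",
        penalty_C=10.0,
        scaler_mean=np.array([t]),
        scaler_scale=np.array([1.0]),
        support_vectors=np.zeros((1, 1)),
        dual_coef=np.array([-1.0]),
        intercept=0.0,
        threshold=t,
        direction="flag_if_below",
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    """Fold-wise and aggregate accuracy / sensitivity / specificity.

    Sensitivity is the probability of flagging an unacceptable contour;
    specificity the probability of passing an acceptable one. Folds are
    stratified within each source set so every set contributes equally to
    each fold.
    """

    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    fold_assignments: np.ndarray
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.accuracy)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracy, ddof=1)) if self.n_folds > 1 else 0.0

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.specificity))

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": i, "accuracy": self.accuracy[i],
             "sensitivity": self.sensitivity[i],
             "specificity": self.specificity[i]}
            for i in range(self.n_folds)
        ]
        rows.append({"fold": "mean", "accuracy": self.mean_accuracy,
                     "sensitivity": self.mean_sensitivity,
                     "specificity": self.mean_specificity})
        return pd.DataFrame(rows)


def stratified_folds(source_sets: Sequence[str], n_folds: int,
                     seed: int) -> np.ndarray:
    """Assign each row to a fold, splitting every source set equally.

    Within each source set the rows are shuffled (seeded) and dealt
    round-robin, so fold sizes within a set differ by at most one.
    """
    sets = np.asarray(source_sets)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(sets), dtype=int)
    for s in sorted(set(sets.tolist())):
        idx = np.flatnonzero(sets == s)
        if len(idx) < n_folds:
            raise ValueError(f"source set {s!r} has {len(idx)} rows, "
                             f"fewer than n_folds={n_folds}")
        perm = rng.permutation(idx)
        for k, i in enumerate(perm):
            folds[i] = k % n_folds
    return folds


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    acc = float((y_true == y_pred).mean())
    pos, neg = y_true == 1, y_true == 0
    sens = float(y_pred[pos].mean()) if pos.any() else math.nan
    spec = float(1 - y_pred[neg].mean()) if neg.any() else math.nan
    return acc, sens, spec


def cross_validate(df: pd.DataFrame, metric_or_combo, kernel: str = "linear",
                   penalty_C: float = 10.0, n_folds: int = 3,
                   seed: int = 0) -> CVReport:
    """Threefold (by default) cross-validation of a QA rule.

    ``df`` needs the metric columns plus ``label`` and ``source_set``.
    Single-metric specs use the threshold-form linear fit; combinations use
    the requested kernel.
    """
    metric_set = resolve_metric_set(metric_or_combo)
    y = _encode_labels(df["label"].to_numpy())
    folds = stratified_folds(df["source_set"].to_numpy(), n_folds, seed)
    X = df.loc[:, list(metric_set)].to_numpy(dtype=float)
    acc, sens, spec = [], [], []
    for k in range(n_folds):
        tr, te = folds != k, folds == k
        if y[tr].min() == y[tr].max():
            raise ValueError(f"training folds for fold {k} contain one class only")
        labels_tr = np.where(y[tr] == 1, UNACCEPTABLE, ACCEPTABLE)
        if len(metric_set) == 1:
            model = fit_single_metric(X[tr, 0], labels_tr, penalty_C,
                                      metric_name=metric_set[0])
        else:
            model = fit_multi_metric(X[tr], labels_tr, kernel=kernel,
                                     penalty_C=penalty_C, metric_set=metric_set)
        pred = model.predict_many(X[te])
        a, sn, sp = _rates(y[te], pred)
        acc.append(a); sens.append(sn); spec.append(sp)
    return CVReport(np.array(acc), np.array(sens), np.array(spec), folds, seed)


def sweep_C(df: pd.DataFrame, metric_or_combo, C_grid: Iterable[float] = range(1, 51),
            kernel: str = "linear", n_folds: int = 3,
            seed: int = 0) -> pd.DataFrame:
    """Mean±sd CV accuracy for each penalty C; ties resolved toward C=10.

    Returns a DataFrame (columns C, mean_accuracy, sd_accuracy) whose
    ``attrs['best_C']`` holds the accuracy-maximising C, preferring 10 and
    then the smallest C among exact ties.
    """
    C_grid = list(C_grid)
    if not C_grid:
        raise ValueError("C grid is empty")
    rows = []
    for C in C_grid:
        rep = cross_validate(df, metric_or_combo, kernel=kernel, penalty_C=C,
                             n_folds=n_folds, seed=seed)
        rows.append({"C": C, "mean_accuracy": rep.mean_accuracy,
                     "sd_accuracy": rep.sd_accuracy})
    out = pd.DataFrame(rows)
    best = out["mean_accuracy"].max()
    tied = sorted(out.loc[out["mean_accuracy"] >= best - 1e-12, "C"].tolist())
    out.attrs["best_C"] = 10 if 10 in tied else tied[0]
    return out


# ---------------------------------------------------------------------------
# operating points, pooled thresholds, ROC


@dataclass
class OperatingPoint:
    """A threshold meeting a sensitivity floor, with its achieved rates."""

    threshold: float
    direction: str
    accuracy: float
    sensitivity: float
    specificity: float
    target_sensitivity: float


def _infer_direction(v: np.ndarray, y: np.ndarray) -> str:
    return "flag_if_below" if v[y == 1].mean() < v[y == 0].mean() else "flag_if_above"


def _candidate_thresholds(v: np.ndarray) -> np.ndarray:
    u = np.unique(v)
    mids = (u[:-1] + u[1:]) / 2.0
    span = max(u[-1] - u[0], 1.0)
    return np.concatenate([[u[0] - span], mids, [u[-1] + span]])


def fixed_sensitivity_threshold(values: Sequence[float], labels: Sequence[str],
                                target_sensitivity: float,
                                direction: str | None = None) -> OperatingPoint:
    """Exhaustive threshold sweep guaranteeing sensitivity ≥ target.

    Candidates are the midpoints of consecutive sorted unique values plus
    sentinels beyond both extremes; among those meeting the sensitivity
    floor the one maximising specificity is returned, with ties broken
    toward higher sensitivity (flag more when it costs nothing).
    """
    if not 0.0 < target_sensitivity <= 1.0:
        raise ValueError("target sensitivity must be in (0, 1]")
    v = np.asarray(values, dtype=float)
    y = _encode_labels(labels)
    direction = direction or _infer_direction(v, y)
    best = None
    for t in _candidate_thresholds(v):
        pred = (v < t).astype(int) if direction == "flag_if_below" else (v > t).astype(int)
        acc, sens, spec = _rates(y, pred)
        if sens >= target_sensitivity and (best is None or (spec, sens) > (best[0], best[3])):
            best = (spec, t, acc, sens)
    spec, t, acc, sens = best  # a sentinel flags everything -> sens = 1.0 always feasible
    return OperatingPoint(threshold=float(t), direction=direction,
                          accuracy=acc, sensitivity=sens, specificity=spec,
                          target_sensitivity=target_sensitivity)


def threshold_accuracy(values, labels, threshold: float, direction: str) -> float:
    """Accuracy of the threshold rule (boundary passes as acceptable)."""
    v = np.asarray(values, dtype=float)
    y = _encode_labels(labels)
    pred = (v < threshold).astype(int) if direction == "flag_if_below" \
        else (v > threshold).astype(int)
    return float((pred == y).mean())


def average_thresholds(models: Sequence[QAModel],
                       data: Mapping[str, tuple[pd.DataFrame, Sequence[str]]]
                       | None = None) -> pd.DataFrame:
    """Pool single-metric thresholds across structures and re-score each one.

    ``models`` are 1-metric linear rules (≥ 2 structures per metric). The
    pooled threshold is the arithmetic mean over structures. If ``data``
    maps structure → (metric DataFrame, labels), the returned frame also
    carries each structure's accuracy at its own vs. the pooled threshold.
    """
    per_metric: dict[str, list[QAModel]] = {}
    for m in models:
        if m.threshold is None or len(m.metric_set) != 1:
            raise ValueError("average_thresholds requires single-metric "
                             "threshold models")
        per_metric.setdefault(m.metric_set[0], []).append(m)
    rows = []
    for metric, group in per_metric.items():
        if len(group) < 2:
            raise ValueError(f"metric {metric!r}: need ≥ 2 structures to pool")
        directions = {g.direction for g in group}
        if len(directions) > 1:
            raise ValueError(f"metric {metric!r}: inconsistent flag directions "
                             f"{directions} across structures")
        direction = group[0].direction
        pooled = float(np.mean([g.threshold for g in group]))
        for g in group:
            row = {"metric": metric, "structure": g.structure_name,
                   "own_threshold": g.threshold, "pooled_threshold": pooled,
                   "direction": direction}
            if data is not None and g.structure_name in data:
                feats, labels = data[g.structure_name]
                v = feats[metric].to_numpy(dtype=float)
                row["own_accuracy"] = threshold_accuracy(v, labels, g.threshold,
                                                         direction)
                row["pooled_accuracy"] = threshold_accuracy(v, labels, pooled,
                                                            direction)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ROCResult:
    """ROC curve with trapezoidal AUC and a percentile-bootstrap 95% CI."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    boot_aucs: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


def roc_auc(values: Sequence[float], labels: Sequence[str], n_boot: int = 2000,
            seed: int = 0, direction: str | None = None) -> ROCResult:
    """ROC analysis of one metric with a bootstrap CI on the AUC.

    The score is oriented so that higher means more likely unacceptable
    (similarity metrics are negated); the CI is the 2.5–97.5 percentile of
    AUCs over ``n_boot`` seeded resamples of the (value, label) pairs.
    Resamples that lose one of the classes are redrawn.
    """
    v = np.asarray(values, dtype=float)
    y = _encode_labels(labels)
    direction = direction or _infer_direction(v, y)
    score = -v if direction == "flag_if_below" else v

    fpr, tpr, _ = _roc_curve(y, score)
    point_auc = float(_trapezoid_auc(fpr, tpr))

    rng = np.random.default_rng(seed)
    n = len(v)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() != yb.max():
                break
        else:  # pragma: no cover - requires a pathological class imbalance
            raise RuntimeError("could not draw a two-class bootstrap resample")
        f, t, _ = _roc_curve(yb, score[idx])
        boot[i] = _trapezoid_auc(f, t)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    return ROCResult(fpr=fpr, tpr=tpr, auc=point_auc,
                     ci_low=float(ci_low), ci_high=float(ci_high),
                     n_boot=n_boot, boot_aucs=boot)
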