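"""Model/Results front end for contour QA, statsmodels-style.

:class:`ContourQA` is built from a tidy DataFrame of per-pair metric values
with acceptability labels; :meth:`ContourQA.fit` returns a
:class:`ContourQAResults` carrying the fitted decision rule, its
cross-validated accuracy/sensitivity/specificity, the ROC with a bootstrap
CI on the AUC, and a ``summary()`` table. The functional layer in
:mod:`contourqa.qa_classifier` does the actual work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import qa_classifier as qac
from .mask_io import ContourPair
from .surface_metrics import (
    DISTANCE_METRICS,
    METRIC_NAMES,
    MetricVector,
    compute_metric_vector,
)

__all__ = ["ContourQA", "ContourQAResults", "metrics_dataframe"]


def _grid_diagonal_mm(pair: ContourPair) -> float:
    shape = np.asarray(pair.reference.shape, dtype=float)
    spacing = np.asarray(pair.reference.spacing, dtype=float)
    return float(np.linalg.norm((shape - 1) * spacing))


def metrics_dataframe(pairs, cap_degenerate: bool = True) -> pd.DataFrame:
    """Compute the 11-metric table for a list of :class:`ContourPair`.

    Degenerate pairs (one empty mask) carry +inf distances; with
    ``cap_degenerate`` those are replaced by the grid diagonal — the largest
    distance realisable on the grid — so the table stays finite for SVM
    training while remaining maximally bad.
    """
    rows = []
    for i, pair in enumerate(pairs):
        vec = compute_metric_vector(pair)
        row = vec.as_dict()
        if cap_degenerate and vec.degenerate_flag:
            diag = _grid_diagonal_mm(pair)
            for m in DISTANCE_METRICS:
                row[m] = diag
        row["pair_id"] = pair.pair_id or f"pair_{i:04d}"
        row["structure"] = pair.structure_name
        row["label"] = pair.label
        row["source_set"] = pair.source_set
        rows.append(row)
    cols = ["pair_id", "structure", "label", "source_set",
            *METRIC_NAMES, "degenerate_flag"]
    return pd.DataFrame(rows)[cols]


class ContourQA:
    """A contour-QA decision-rule model over a labelled metric table.

    Parameters
    ----------
    data : DataFrame
        One row per contour pair with the metric columns plus ``label``
        (acceptable/unacceptable) and ``source_set``; typically produced by
        :func:`metrics_dataframe`.
    metric : str or sequence of str
        A single metric name, a named combination (e.g. ``"Three_SDSC"``),
        or an explicit list of metrics.
    kernel : str
        SVM kernel; single-metric rules are always linear.
    penalty_C : float
        SVM soft-margin penalty (the study reports results at C = 10).
    """

    def __init__(self, data: pd.DataFrame, metric="sdsc_2",
                 kernel: str = "linear", penalty_C: float = 10.0,
                 structure_name: str = ""):
        self.metric_set = qac.resolve_metric_set(metric)
        missing = [c for c in (*self.metric_set, "label") if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing columns {missing}")
        self.data = data.reset_index(drop=True)
        if "source_set" not in self.data.columns:
            self.data = self.data.assign(source_set="synthetic")
        self.kernel = kernel
        self.penalty_C = float(penalty_C)
        self.structure_name = structure_name or (
            str(data["structure"].iloc[0]) if "structure" in data.columns
            and data["structure"].nunique() == 1 else ""
        )

    @classmethod
    def from_pairs(cls, pairs, **kwargs) -> "ContourQA":
        """Build the model directly from contour pairs (computes the metrics)."""
        return cls(metrics_dataframe(pairs), **kwargs)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "ContourQA":
        """Alias constructor mirroring from_formula-style APIs."""
        return cls(data, **kwargs)

    def fit(self, n_folds: int = 3, seed: int = 0,
            n_boot: int = 2000) -> "ContourQAResults":
        """Cross-validate, then fit the final rule on all rows."""
        cv = qac.cross_validate(self.data, self.metric_set, kernel=self.kernel,
                                penalty_C=self.penalty_C, n_folds=n_folds,
                                seed=seed)
        labels = self.data["label"].to_numpy()
        if len(self.metric_set) == 1:
            m = self.metric_set[0]
            model = qac.fit_single_metric(self.data[m].to_numpy(dtype=float),
                                          labels, self.penalty_C, metric_name=m,
                                          structure_name=self.structure_name)
            roc = qac.roc_auc(self.data[m].to_numpy(dtype=float), labels,
                              n_boot=n_boot, seed=seed)
        else:
            model = qac.fit_multi_metric(self.data, labels, kernel=self.kernel,
                                         penalty_C=self.penalty_C,
                                         metric_set=self.metric_set,
                                         structure_name=self.structure_name)
            roc = None
        return ContourQAResults(model=self, qa_model=model, cv=cv, roc=roc,
                                seed=seed)


@dataclass
class ContourQAResults:
    """Fitted QA rule plus its cross-validated diagnostics."""

    model: ContourQA
    qa_model: qac.QAModel
    cv: qac.CVReport
    roc: qac.ROCResult | None
    seed: int

    @property
    def threshold(self) -> float | None:
        return self.qa_model.threshold

    @property
    def direction(self) -> str | None:
        return self.qa_model.direction

    @property
    def auc(self) -> float | None:
        return self.roc.auc if self.roc is not None else None

    def predict(self, vector) -> str:
        return self.qa_model.predict(vector)

    def operating_point(self, target_sensitivity: float) -> qac.OperatingPoint:
        """Re-threshold the single metric to guarantee a sensitivity floor."""
        if len(self.model.metric_set) != 1:
            raise ValueError("operating points are defined for single-metric rules")
        m = self.model.metric_set[0]
        return qac.fixed_sensitivity_threshold(
            self.model.data[m].to_numpy(dtype=float),
            self.model.data["label"].to_numpy(), target_sensitivity,
            direction=self.direction)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Contour QA decision rule",
            "=" * 58,
            f"structure:        {m.structure_name or '(pooled)'}",
            f"metrics:          {', '.join(m.metric_set)}",
            f"kernel:           {m.kernel}   C = {m.penalty_C:g}",
            f"n pairs:          {len(m.data)}  "
            f"({(m.data['label'] == 'unacceptable').sum()} unacceptable)",
        ]
        if self.threshold is not None:
            op = "<" if self.direction == "flag_if_below" else ">"
            lines.append(f"decision rule:    flag if {m.metric_set[0]} "
                         f"{op} {self.threshold:.4f}")
        lines += [
            "-" * 58,
            f"CV accuracy:      {self.cv.mean_accuracy:.3f} "
            f"± {self.cv.sd_accuracy:.3f}  ({self.cv.n_folds} folds)",
            f"CV sensitivity:   {self.cv.mean_sensitivity:.3f}",
            f"CV specificity:   {self.cv.mean_specificity:.3f}",
        ]
        if self.roc is not None:
            lines.append(f"AUC:              {self.roc.auc:.3f} "
                         f"(95% CI {self.roc.ci_low:.3f}–{self.roc.ci_high:.3f}, "
                         f"bootstrap n = {self.roc.n_boot})")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Plot the ROC curve (requires matplotlib)."""
        if self.roc is None:
            raise ValueError("ROC is only computed for single-metric rules")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc.fpr, self.roc.tpr,
                label=f"AUC = {self.roc.auc:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate (sensitivity)")
        ax.legend(loc="lower right")
        return ax
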