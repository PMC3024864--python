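"""Confusion-matrix metrics and outer 3-fold stratified cross-validation.

With a heavily imbalanced test set, accuracy alone hides failures on the
rare (real precursor) class, so sensitivity, specificity and their
geometric mean Gm = sqrt(SE·SP) are reported alongside it, all as
percentages.  The outer CV splits the data into three stratified folds;
scaling, feature selection and ensemble fitting all happen inside the
training folds, and the final report is the arithmetic mean of the three
fold-level reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .ensemble import GridConfig, train_ensemble
from .errors import UndefinedMetricError
from .features import FeatureMatrix
from .selection import rank_and_select


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


@dataclass(frozen=True)
class MetricsReport:
    """SE, SP, Gm, Acc as percentages in [0, 100]."""

    se: float
    sp: float
    gm: float
    acc: float

    def __str__(self) -> str:  # 2 dp, table style
        return (
            f"SE={self.se:.2f}% SP={self.sp:.2f}% "
            f"Gm={self.gm:.2f}% Acc={self.acc:.2f}%"
        )


def geometric_mean(se: float, sp: float) -> float:
    """Gm = sqrt(SE·SP) on the percentage scale."""
    return math.sqrt(se * sp)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """SE = TP/(TP+FN), SP = TN/(TN+FP), Acc over all, Gm = sqrt(SE·SP)."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise UndefinedMetricError("both classes must be present in the test set")
    se = 100.0 * cm.tp / (cm.tp + cm.fn)
    sp = 100.0 * cm.tn / (cm.tn + cm.fp)
    acc = 100.0 * (cm.tp + cm.tn) / (cm.tp + cm.tn + cm.fp + cm.fn)
    return MetricsReport(se, sp, geometric_mean(se, sp), acc)


def mean_report(reports: List[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of fold-level reports (not pooled confusion matrices)."""
    return MetricsReport(
        se=float(np.mean([r.se for r in reports])),
        sp=float(np.mean([r.sp for r in reports])),
        gm=float(np.mean([r.gm for r in reports])),
        acc=float(np.mean([r.acc for r in reports])),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the CV pipeline needs besides the data."""

    k: int = 3
    aggregation: str = "mean_distance"
    m: Optional[int] = None  # top-m F-score features; None = use all
    grid: GridConfig = field(default_factory=GridConfig)
    centroid_on: str = "subset"
    selection_mode: str = "per_fold"  # or "global"


def outer_3fold_cv(
    matrix: FeatureMatrix,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> Tuple[MetricsReport, List[MetricsReport]]:
    """Stratified outer 3-fold CV of the full pipeline.

    Per fold: (optional) F-score selection and ensemble training on the two
    training partitions, evaluation on the held-out partition.  With
    ``selection_mode="global"`` the feature subset is chosen once on the
    full matrix (the historical workflow; mildly optimistic).
    """
    if matrix.labels is None:
        raise UndefinedMetricError("cross-validation requires labels")
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed % (2**31))

    global_names = None
    if config.m is not None and config.selection_mode == "global":
        _, global_names = rank_and_select(matrix, config.m)

    fold_reports: List[MetricsReport] = []
    for fold_no, (train, test) in enumerate(skf.split(matrix.X, matrix.labels)):
        train_m = FeatureMatrix(
            [matrix.ids[i] for i in train],
            list(matrix.names),
            matrix.X[train],
            matrix.labels[train],
        )
        test_X = matrix.X[test]
        if config.m is not None:
            names = (
                global_names
                if global_names is not None
                else rank_and_select(train_m, config.m)[1]
            )
            train_m = train_m.subset_columns(names)
            cols = [matrix.names.index(n) for n in names]
            test_X = matrix.X[test][:, cols]
        model = train_ensemble(
            train_m,
            k=config.k,
            aggregation=config.aggregation,
            grid=config.grid,
            seed=seed + fold_no,
            centroid_on=config.centroid_on,
        )
        y_pred = model.predict(test_X)
        cm = ConfusionMatrix.from_predictions(matrix.labels[test], y_pred)
        fold_reports.append(compute_metrics(cm))
    return mean_report(fold_reports), fold_reports
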