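"""Imbalance-aware RBF-SVM ensemble.

With far more pseudo hairpins than real precursors, a single SVM drifts
toward the majority class.  Instead of under- or over-sampling, the
negatives are sorted by distance to the positive-class centroid (in scaled
feature space) and cut into k contiguous, near-equal partitions — partition
1 is the "closer set".  One RBF sub-classifier is trained per partition on
(all positives ∪ that partition), with an inner cross-validated grid search
over (C, gamma) selected by the geometric mean of sensitivity and
specificity.  Two aggregations are supported:

* majority vote — every sub-classifier votes; on an exact tie (even k) the
  latter half of sub-classifiers (trained on negatives far from the
  positives) takes priority over the half trained on closer sets, and if
  that half is itself tied the sub-classifier with the largest partition
  index decides;
* mean distance — each sample is dispatched to the single sub-classifier
  whose training-subset centroid is nearest (Euclidean, scaled space), so
  every sample is classified exactly once.

For k = 1 the two aggregations coincide with a single SVM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ModelFormatError, PremirclassError
from .features import FeatureMatrix

SCHEMA_VERSION = 1

AGGREGATIONS = ("majority_vote", "mean_distance")


@dataclass
class ScalingParams:
    """Per-feature min-max scaling to [-1, 1], fitted on training data only."""

    col_min: np.ndarray
    col_max: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "ScalingParams":
        return cls(X.min(axis=0), X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.col_max - self.col_min
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.where(span == 0, 0.0, -1.0 + 2.0 * (X - self.col_min) / span)
        return scaled


@dataclass(frozen=True)
class GridConfig:
    """Coarse log2 grid for the inner (C, gamma) search, Gm-selected."""

    c_exponents: Tuple[int, ...] = (-5, -1, 3, 7, 11, 15)
    gamma_exponents: Tuple[int, ...] = (-15, -11, -7, -3, 1, 3)
    inner_folds: int = 5


@dataclass
class SubModel:
    clf: SVC
    centroid: np.ndarray
    partition_index: int  # 1-based; 1 = trained on the closer set
    c: float
    gamma: float


@dataclass
class EnsembleModel:
    k: int
    submodels: List[SubModel]
    scaling: ScalingParams
    aggregation: str
    feature_names: List[str]
    schema_version: int = SCHEMA_VERSION

    def _scaled(self, X: np.ndarray) -> np.ndarray:
        return self.scaling.transform(np.asarray(X, dtype=float))

    def votes(self, X: np.ndarray) -> np.ndarray:
        """(n, k) matrix of ±1 votes, columns ordered by partition index."""
        Xs = self._scaled(X)
        return np.column_stack([sm.clf.predict(Xs) for sm in self.submodels])

    def dispatch_indices(self, X: np.ndarray) -> np.ndarray:
        """Nearest-centroid sub-classifier per sample (0-based; ties -> lowest)."""
        Xs = self._scaled(X)
        centroids = np.vstack([sm.centroid for sm in self.submodels])
        d2 = ((Xs[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.aggregation == "majority_vote":
            return predict_majority(self, X)
        return predict_mean_distance(self, X)


def aggregate_majority(votes: np.ndarray) -> np.ndarray:
    """Resolve a (n, k) ±1 vote matrix by majority with the even-k tie cascade.

    Ties (possible only for even k) go to the majority among the latter half
    of sub-classifiers (partition indices > k/2); a tie there falls through
    to the vote of the largest partition index.
    """
    votes = np.asarray(votes)
    if votes.ndim == 1:
        votes = votes[None, :]
    k = votes.shape[1]
    total = votes.sum(axis=1)
    out = np.sign(total)
    tied = total == 0
    if np.any(tied):
        latter = votes[:, k // 2 :].sum(axis=1)
        out[tied] = np.sign(latter[tied])
        still = tied & (latter == 0)
        out[still] = votes[still, -1]
    return out.astype(int)


def predict_majority(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    return aggregate_majority(model.votes(X))


def predict_mean_distance(
    model: EnsembleModel, X: np.ndarray, return_dispatch: bool = False
):
    """Label each sample with the nearest-centroid sub-classifier only."""
    Xs = model._scaled(X)
    idx = model.dispatch_indices(X)
    out = np.empty(len(Xs), dtype=int)
    for i in np.unique(idx):
        sel = idx == i
        out[sel] = model.submodels[i].clf.predict(Xs[sel])
    return (out, idx) if return_dispatch else out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def partition_negatives(X_scaled: np.ndarray, labels: np.ndarray, k: int) -> List[np.ndarray]:
    """Sort negatives by distance to the positive centroid and cut k blocks.

    Returns k arrays of row indices (into the full matrix); block 1 is the
    closer set, block sizes differ by at most 1.
    """
    neg_idx = np.flatnonzero(labels == -1)
    pos_idx = np.flatnonzero(labels == 1)
    if k < 1:
        raise PremirclassError("k must be >= 1")
    if k > len(neg_idx):
        raise PremirclassError(f"k={k} exceeds the {len(neg_idx)} negatives")
    pos_centroid = X_scaled[pos_idx].mean(axis=0)
    d2 = ((X_scaled[neg_idx] - pos_centroid) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")
    return [np.asarray(block) for block in np.array_split(neg_idx[order], k)]


def _gm_fraction(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == 1
    neg = y_true == -1
    se = (y_pred[pos] == 1).mean() if pos.any() else 0.0
    sp = (y_pred[neg] == -1).mean() if neg.any() else 0.0
    return float(np.sqrt(se * sp))


def _grid_search(
    X: np.ndarray, y: np.ndarray, grid: GridConfig, seed: int
) -> Tuple[float, float]:
    """Inner CV over the (C, gamma) grid, scored by Gm; ties keep grid order."""
    n_splits = min(grid.inner_folds, np.bincount((y == 1).astype(int)).min())
    n_splits = max(2, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31))
    folds = list(skf.split(X, y))
    best = (-1.0, 2.0**grid.c_exponents[0], 2.0**grid.gamma_exponents[0])
    for ce in grid.c_exponents:
        for ge in grid.gamma_exponents:
            c, gamma = 2.0**ce, 2.0**ge
            gms = []
            for train, test in folds:
                clf = SVC(C=c, gamma=gamma, kernel="rbf")
                clf.fit(X[train], y[train])
                gms.append(_gm_fraction(y[test], clf.predict(X[test])))
            score = float(np.mean(gms))
            if score > best[0]:
                best = (score, c, gamma)
    return best[1], best[2]


def train_ensemble(
    matrix: FeatureMatrix,
    k: int,
    aggregation: str = "mean_distance",
    grid: GridConfig = GridConfig(),
    seed: int = 0,
    centroid_on: str = "subset",
) -> EnsembleModel:
    """Fit the k-sub-classifier ensemble on a labelled feature matrix.

    ``centroid_on`` chooses whether dispatch centroids average the full
    training subset (positives + partition, the default) or the negative
    partition alone.
    """
    if aggregation not in AGGREGATIONS:
        raise PremirclassError(f"aggregation must be one of {AGGREGATIONS}")
    if matrix.labels is None:
        raise PremirclassError("training requires labels")
    if centroid_on not in ("subset", "negatives"):
        raise PremirclassError("centroid_on must be 'subset' or 'negatives'")
    labels = matrix.labels
    if not ((labels == 1).any() and (labels == -1).any()):
        raise PremirclassError("training needs both classes present")

    scaling = ScalingParams.fit(matrix.X)
    Xs = scaling.transform(matrix.X)
    pos_idx = np.flatnonzero(labels == 1)
    partitions = partition_negatives(Xs, labels, k)

    submodels: List[SubModel] = []
    for part_no, neg_block in enumerate(partitions, start=1):
        rows = np.concatenate([pos_idx, neg_block])
        Xi, yi = Xs[rows], labels[rows]
        c, gamma = _grid_search(Xi, yi, grid, seed + part_no)
        clf = SVC(C=c, gamma=gamma, kernel="rbf")
        clf.fit(Xi, yi)
        centroid_rows = Xi if centroid_on == "subset" else Xs[neg_block]
        submodels.append(
            SubModel(clf, centroid_rows.mean(axis=0), part_no, c, gamma)
        )
    return EnsembleModel(k, submodels, scaling, aggregation, list(matrix.names))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: EnsembleModel, path) -> None:
    """Write the model archive (scaling, feature names, submodels, schema)."""
    payload = {
        "schema_version": model.schema_version,
        "k": model.k,
        "aggregation": model.aggregation,
        "feature_names": model.feature_names,
        "scaling": {"col_min": model.scaling.col_min, "col_max": model.scaling.col_max},
        "submodels": [
            {
                "clf": sm.clf,
                "centroid": sm.centroid,
                "partition_index": sm.partition_index,
                "c": sm.c,
                "gamma": sm.gamma,
            }
            for sm in model.submodels
        ],
    }
    joblib.dump(payload, path)


def load_model(path) -> EnsembleModel:
    payload = joblib.load(path)
    try:
        if payload["schema_version"] != SCHEMA_VERSION:
            raise ModelFormatError(
                f"unsupported model schema {payload['schema_version']}"
            )
        scaling = ScalingParams(payload["scaling"]["col_min"], payload["scaling"]["col_max"])
        submodels = [
            SubModel(d["clf"], d["centroid"], d["partition_index"], d["c"], d["gamma"])
            for d in payload["submodels"]
        ]
        return EnsembleModel(
            payload["k"], submodels, scaling, payload["aggregation"], payload["feature_names"]
        )
    except KeyError as exc:
        raise ModelFormatError(f"model archive missing field {exc}") from None
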