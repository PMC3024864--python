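"""F-score feature ranking and top-m selection.

The F-score of feature i is the squared separation of the class means from
the overall mean, over the summed (n−1)-normalized within-class scatters:

    F_i = [(x̄_i⁺ − x̄_i)² + (x̄_i⁻ − x̄_i)²] /
          [ Σ_k (x⁺_{k,i} − x̄_i⁺)²/(n⁺−1) + Σ_k (x⁻_{k,i} − x̄_i⁻)²/(n⁻−1) ]

— the filter criterion shipped with libsvm's feature-selection tool.  A
feature constant within both classes has F = 0 by the zero-denominator
rule.  Larger F means more discriminative; selection keeps the top m with
ties broken by canonical feature order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .errors import InsufficientClassSizeError, PremirclassError
from .features import FEATURE_GROUPS, FeatureMatrix


@dataclass(frozen=True)
class FScoreRanking:
    scores: np.ndarray  # per-feature F, canonical column order
    ranking: np.ndarray  # column indices sorted by descending F (stable)
    n_plus: int
    n_minus: int


def _split_classes(matrix: FeatureMatrix) -> Tuple[np.ndarray, np.ndarray]:
    if matrix.labels is None:
        raise PremirclassError("F-score needs a labelled feature matrix")
    pos = matrix.X[matrix.labels == 1]
    neg = matrix.X[matrix.labels == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise InsufficientClassSizeError(
            f"need >= 2 instances per class, got {len(pos)} positive / {len(neg)} negative"
        )
    return pos, neg


def f_scores(matrix: FeatureMatrix) -> np.ndarray:
    """Vector of F-scores for every column of the matrix."""
    pos, neg = _split_classes(matrix)
    overall = matrix.X.mean(axis=0)
    mean_p, mean_n = pos.mean(axis=0), neg.mean(axis=0)
    num = (mean_p - overall) ** 2 + (mean_n - overall) ** 2
    den = ((pos - mean_p) ** 2).sum(axis=0) / (len(pos) - 1) + (
        (neg - mean_n) ** 2
    ).sum(axis=0) / (len(neg) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(den == 0, 0.0, num / den)
    return f


def f_score(matrix: FeatureMatrix, feature_index: int) -> float:
    """F-score of a single column (see module docstring for the formula)."""
    return float(f_scores(matrix)[feature_index])


def rank_features(matrix: FeatureMatrix) -> FScoreRanking:
    pos, neg = _split_classes(matrix)
    scores = f_scores(matrix)
    ranking = np.argsort(-scores, kind="stable")  # ties -> canonical order
    return FScoreRanking(scores, ranking, len(pos), len(neg))


def rank_and_select(matrix: FeatureMatrix, m: int) -> Tuple[FScoreRanking, List[str]]:
    """Rank all features and return the names of the m largest-F ones.

    The selected names are returned in canonical column order so that
    reduced matrices keep a stable layout.
    """
    if not 1 <= m <= len(matrix.names):
        raise PremirclassError(f"m must be in [1, {len(matrix.names)}], got {m}")
    ranking = rank_features(matrix)
    top = sorted(ranking.ranking[:m])
    return ranking, [matrix.names[i] for i in top]


def ranking_report(matrix: FeatureMatrix, ranking: FScoreRanking, m: int) -> pd.DataFrame:
    """TSV-ready report: feature, group, F-score, rank, selected flag."""
    rank_of = np.empty(len(matrix.names), dtype=int)
    rank_of[ranking.ranking] = np.arange(1, len(matrix.names) + 1)
    selected = set(ranking.ranking[:m])
    return pd.DataFrame(
        {
            "feature": matrix.names,
            "group": [FEATURE_GROUPS.get(n, "custom") for n in matrix.names],
            "f_score": ranking.scores,
            "rank": rank_of,
            "selected": [i in selected for i in range(len(matrix.names))],
        }
    ).sort_values("rank")
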