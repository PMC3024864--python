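"""The 65-feature representation of a hairpin candidate.

Three groups, in a frozen canonical order used for every table written or
read by the package:

* 32 *triplet* elements — for each window of 3 adjacent positions the
  pairing pattern (brackets collapsed to '(', so 8 patterns) combined with
  the middle nucleotide, normalized to frequencies over the L−2 windows;
* 15 *base-pair* features — pair-density and pair-composition ratios,
  including the four multi-loop features normalized by the number of
  hairpin loops (dP/n_loops and %(X−Y)/n_loops), which separate
  multi-branched pseudo hairpins from genuine single-stem precursors;
* 18 *thermodynamic* features — length- and composition-normalized folding
  energies (dG, MFEI_1..4, NEFE, Diff, Freq), duplex melting quantities
  (dH, dS, Tm and their per-length versions), and z-scores / empirical
  p-values of MFE and EFE against the dinucleotide-shuffle null.

Degenerate denominators (no stems, no loops, no pairs, no C, zero GC%)
resolve to 0 so every vector is finite.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, PremirclassError
from .fasta import SequenceRecord
from .folding import (
    EnergyModel,
    FoldingEngine,
    FoldResult,
    StructureStats,
    ToyEngine,
    structure_stats,
)
from .shuffle import ShuffleNull, null_statistics, z_and_p

# ---------------------------------------------------------------------------
# Canonical feature names
# ---------------------------------------------------------------------------

TRIPLET_PATTERNS: Tuple[str, ...] = (
    "(((", "((.", "(..", "(.(", ".((", ".(.", "..(", "...",
)

TRIPLET_NAMES: Tuple[str, ...] = tuple(
    f"{base}{pat}" for base in "ACGU" for pat in TRIPLET_PATTERNS
)

BASE_PAIR_NAMES: Tuple[str, ...] = (
    "G/C_ratio",
    "%C+G",
    "dP",
    "Avg_BP_Stem",
    "Diversity",
    "|A-U|/L",
    "|G-C|/L",
    "|G-U|/L",
    "(A-U)/n_stems",
    "(G-C)/n_stems",
    "(G-U)/n_stems",
    "dP/n_loops",
    "%(A-U)/n_loops",
    "%(G-C)/n_loops",
    "%(G-U)/n_loops",
)

THERMO_NAMES: Tuple[str, ...] = (
    "dG",
    "MFEI_1",
    "MFEI_2",
    "MFEI_3",
    "MFEI_4",
    "Freq",
    "NEFE",
    "Diff",
    "dH",
    "dS",
    "Tm",
    "dH/L",
    "dS/L",
    "Tm/L",
    "z-score_MFE",
    "z-score_EFE",
    "p-value_MFE",
    "p-value_EFE",
)

ALL_FEATURE_NAMES: Tuple[str, ...] = TRIPLET_NAMES + BASE_PAIR_NAMES + THERMO_NAMES

FEATURE_GROUPS: Mapping[str, str] = {
    **{n: "triplet" for n in TRIPLET_NAMES},
    **{n: "base_pair" for n in BASE_PAIR_NAMES},
    **{n: "thermodynamic" for n in THERMO_NAMES},
}

assert len(TRIPLET_NAMES) == 32 and len(BASE_PAIR_NAMES) == 15 and len(THERMO_NAMES) == 18


def _safe_div(num: float, den: float) -> float:
    """num/den with the degenerate-denominator convention (den == 0 -> 0)."""
    return 0.0 if den == 0 else num / den


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureVector:
    names: Tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


@dataclass
class FeatureMatrix:
    """Rows of feature vectors with ids and optional ±1 labels."""

    ids: List[str]
    names: List[str]
    X: np.ndarray
    labels: Optional[np.ndarray] = None  # +1 real, -1 pseudo

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.ids), len(self.names)):
            raise ValueError("matrix shape inconsistent with ids/names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.ids),):
                raise ValueError("labels length must match rows")
            if not set(np.unique(self.labels)) <= {-1, 1}:
                raise ValueError("labels must be +1 (real) or -1 (pseudo)")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def subset_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.names.index(n) for n in names]
        return FeatureMatrix(list(self.ids), list(names), self.X[:, idx], self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df.insert(0, "id", self.ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        if "id" not in df.columns:
            raise PremirclassError(f"{path}: missing mandatory 'id' column")
        labels = None
        cols = [c for c in df.columns if c != "id"]
        if "label" in df.columns:
            labels = df["label"].to_numpy(dtype=int)
            cols.remove("label")
        return cls(df["id"].astype(str).tolist(), cols, df[cols].to_numpy(dtype=float), labels)


# ---------------------------------------------------------------------------
# Triplet features
# ---------------------------------------------------------------------------


def triplet_features(record: SequenceRecord, structure: str) -> Dict[str, float]:
    """Frequencies of the 32 structure-sequence triplet categories.

    Both bracket characters are collapsed to '(' (paired vs unpaired is all
    that matters), each of the L−2 windows of 3 adjacent positions is
    classified by its pattern and middle nucleotide, and counts are
    normalized by L−2 so the 32 frequencies sum to 1.
    """
    L = len(record.seq)
    if L < 3:
        raise DegenerateInputError("triplet features need L >= 3")
    if len(structure) != L:
        raise PremirclassError("structure length must match sequence length")
    collapsed = structure.replace(")", "(")
    counts = dict.fromkeys(TRIPLET_NAMES, 0)
    for w in range(L - 2):
        name = record.seq[w + 1] + collapsed[w : w + 3]
        counts[name] += 1
    n_windows = L - 2
    return {name: counts[name] / n_windows for name in TRIPLET_NAMES}


# ---------------------------------------------------------------------------
# Base-pair features
# ---------------------------------------------------------------------------


def base_pair_features(
    record: SequenceRecord, stats: StructureStats, fold: FoldResult
) -> Dict[str, float]:
    """The 15 pair-composition features, including the 4 multi-loop features.

    %(X−Y) is the share of X−Y pairs among all base pairs; dividing it and
    dP by the hairpin-loop count yields the multi-loop features that shrink
    for multi-branched structures.
    """
    seq = record.seq
    L = len(seq)
    c = {nt: seq.count(nt) for nt in "ACGU"}
    n = stats.pair_type_counts
    n_bp, n_stems, n_loops = stats.n_bp, stats.n_stems, stats.n_loops
    dp = n_bp / L
    return {
        "G/C_ratio": _safe_div(c["G"], c["C"]),
        "%C+G": 100.0 * (c["C"] + c["G"]) / L,
        "dP": dp,
        "Avg_BP_Stem": _safe_div(n_bp, n_stems),
        "Diversity": fold.diversity,
        "|A-U|/L": n["AU"] / L,
        "|G-C|/L": n["GC"] / L,
        "|G-U|/L": n["GU"] / L,
        "(A-U)/n_stems": _safe_div(n["AU"], n_stems),
        "(G-C)/n_stems": _safe_div(n["GC"], n_stems),
        "(G-U)/n_stems": _safe_div(n["GU"], n_stems),
        "dP/n_loops": _safe_div(dp, n_loops),
        "%(A-U)/n_loops": _safe_div(_safe_div(n["AU"], n_bp), n_loops),
        "%(G-C)/n_loops": _safe_div(_safe_div(n["GC"], n_bp), n_loops),
        "%(G-U)/n_loops": _safe_div(_safe_div(n["GU"], n_bp), n_loops),
    }


# ---------------------------------------------------------------------------
# Thermodynamic features
# ---------------------------------------------------------------------------

# Watson-Crick stack enthalpies (kcal/mol), Xia et al. 1998 unified RNA
# nearest-neighbour set. Key: (outer pair, inner pair) reading the top
# strand 5'->3'. Stacks with a GU wobble fall back to a flat value.
_WC_STACK_DH: Dict[Tuple[Tuple[str, str], Tuple[str, str]], float] = {
    (("A", "U"), ("A", "U")): -6.82,
    (("A", "U"), ("U", "A")): -9.38,
    (("U", "A"), ("A", "U")): -7.69,
    (("C", "G"), ("U", "A")): -10.48,
    (("C", "G"), ("A", "U")): -10.44,
    (("G", "C"), ("U", "A")): -11.40,
    (("G", "C"), ("A", "U")): -12.44,
    (("C", "G"), ("G", "C")): -10.64,
    (("G", "C"), ("G", "C")): -13.39,
    (("G", "C"), ("C", "G")): -14.88,
}
# a stack read from the other strand is the same stack
for (_p1, _p2), _dh in list(_WC_STACK_DH.items()):
    _WC_STACK_DH.setdefault((_p2[::-1], _p1[::-1]), _dh)

_GU_STACK_DH = -7.5  # flat approximation for wobble-containing stacks


def stack_enthalpy(record: SequenceRecord, stats: StructureStats) -> float:
    """dH: summed nearest-neighbour enthalpies over consecutive stacked pairs."""
    seq = record.seq
    pair_set = set(stats.pairs)
    dh = 0.0
    for i, j in stats.pairs:
        if (i + 1, j - 1) not in pair_set:
            continue
        outer = (seq[i - 1], seq[j - 1])
        inner = (seq[i], seq[j - 2])
        dh += _WC_STACK_DH.get((outer, inner), _GU_STACK_DH)
    return dh


def thermo_features(
    record: SequenceRecord,
    stats: StructureStats,
    fold: FoldResult,
    null: ShuffleNull,
    model: EnergyModel = EnergyModel(),
    mfei34_swapped: bool = False,
) -> Dict[str, float]:
    """The 18 thermodynamic features.

    dG = MFE/L; MFEI_1 = dG/%(C+G); MFEI_2 = dG/n_stems; MFEI_3 = dG/n_loops;
    MFEI_4 = MFE/n_bp (``mfei34_swapped`` exchanges the MFEI_3/MFEI_4
    denominators); NEFE = EFE/L; Diff = |MFE−EFE|/L.  dS and Tm derive from
    dH and MFE through the two-state relations dS = (dH − dG°)·1000/T and
    Tm = 1000·dH/dS − 273.15.
    """
    L = len(record.seq)
    seq = record.seq
    pct_cg = 100.0 * (seq.count("C") + seq.count("G")) / L
    mfe, efe = fold.mfe, fold.efe
    dg = mfe / L
    dh = stack_enthalpy(record, stats)
    ds = (dh - mfe) * 1000.0 / model.temperature
    tm = _safe_div(1000.0 * dh, ds) - 273.15 if ds != 0 else 0.0

    mfei3 = _safe_div(dg, stats.n_loops)
    mfei4 = _safe_div(mfe, stats.n_bp)
    if mfei34_swapped:
        mfei3, mfei4 = mfei4, mfei3

    z_mfe, p_mfe = z_and_p(mfe, null.null_mfe)
    z_efe, p_efe = z_and_p(efe, null.null_efe)

    return {
        "dG": dg,
        "MFEI_1": _safe_div(dg, pct_cg),
        "MFEI_2": _safe_div(dg, stats.n_stems),
        "MFEI_3": mfei3,
        "MFEI_4": mfei4,
        "Freq": fold.freq,
        "NEFE": efe / L,
        "Diff": abs(mfe - efe) / L,
        "dH": dh,
        "dS": ds,
        "Tm": tm,
        "dH/L": dh / L,
        "dS/L": ds / L,
        "Tm/L": tm / L,
        "z-score_MFE": z_mfe,
        "z-score_EFE": z_efe,
        "p-value_MFE": p_mfe,
        "p-value_EFE": p_efe,
    }


# ---------------------------------------------------------------------------
# Full vector / matrix extraction
# ---------------------------------------------------------------------------


def _record_seed(seed: int, seq: str) -> int:
    """Per-record RNG stream: depends on sequence content, not record order."""
    return (seed * 1_000_003 + zlib.crc32(seq.encode())) % (2**31)


def extract_all(
    record: SequenceRecord,
    engine: Optional[FoldingEngine] = None,
    model: EnergyModel = EnergyModel(),
    n_shuffles: int = 300,
    seed: int = 0,
    mfei34_swapped: bool = False,
) -> FeatureVector:
    """Assemble the canonical 65-dimensional vector for one record.

    The shuffle null is folded with the same engine/model; its RNG stream
    derives from (seed, sequence), so vectors are invariant to record order.
    """
    engine = engine if engine is not None else ToyEngine(model)
    fold = engine.fold(record)
    stats = structure_stats(record, fold.structure)
    null = null_statistics(record, model, n=n_shuffles, seed=_record_seed(seed, record.seq))

    values = {}
    values.update(triplet_features(record, fold.structure))
    values.update(base_pair_features(record, stats, fold))
    values.update(
        thermo_features(record, stats, fold, null, model, mfei34_swapped=mfei34_swapped)
    )
    arr = np.array([values[name] for name in ALL_FEATURE_NAMES], dtype=float)
    return FeatureVector(ALL_FEATURE_NAMES, arr)


def extract_matrix(
    records: Sequence[SequenceRecord],
    labels: Optional[Sequence[int]] = None,
    engine: Optional[FoldingEngine] = None,
    model: EnergyModel = EnergyModel(),
    n_shuffles: int = 300,
    seed: int = 0,
    mfei34_swapped: bool = False,
) -> FeatureMatrix:
    """Extract the canonical feature matrix for a batch of records."""
    rows = [
        extract_all(
            rec,
            engine=engine,
            model=model,
            n_shuffles=n_shuffles,
            seed=seed,
            mfei34_swapped=mfei34_swapped,
        ).values
        for rec in records
    ]
    X = np.vstack(rows) if rows else np.empty((0, len(ALL_FEATURE_NAMES)))
    return FeatureMatrix(
        [r.id for r in records],
        list(ALL_FEATURE_NAMES),
        X,
        None if labels is None else np.asarray(labels, dtype=int),
    )
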