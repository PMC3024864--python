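"""Synthetic data with known structure for exercising every pipeline stage.

The generators target the package's additive energy model, not biological
realism: positives are GC-rich single stem-loops whose optimal structure is
one hairpin, negatives are (mostly) concatenations of short stem-loops that
fold with two or more hairpin loops — matching the two aggregates the real
training corpus is known for: a negative:positive ratio of 7.79:1 and
roughly 84% of pseudo hairpins folding with multi-loops.  Loop, bulge and
linker letters are drawn from {A, C}, which cannot pair with each other, so
the intended topology is also the optimal one.

``make_separable_table`` skips sequence space entirely and emits a labelled
feature matrix with class-shifted informative columns plus pure-noise
columns — the test bed for selection, ensemble and cross-validation
mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .fasta import SequenceRecord
from .features import FeatureMatrix

_PAIRS = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")]
_PAIR_P = [0.35, 0.35, 0.12, 0.12, 0.03, 0.03]  # GC-biased stems
_LOOP_ALPHABET = ["A", "C"]  # A and C cannot pair: loops stay unstructured

# Positives use disjoint arm alphabets: 5' arm from {G, A}, 3' arm from
# {C, U}.  No two left-arm (or two right-arm) letters can legally pair, so
# every pair of ANY structure spans the terminal loop and the optimal fold
# is necessarily a single hairpin.
_HAIRPIN_PAIRS = [("G", "C"), ("A", "U"), ("G", "U")]
_HAIRPIN_PAIR_P = [0.70, 0.25, 0.05]


@dataclass(frozen=True)
class FixtureConfig:
    """Generator settings; defaults are the documented study conditions."""

    n_pos: int = 50
    n_neg: Optional[int] = None  # None -> round(n_pos * imbalance_ratio)
    imbalance_ratio: float = 7.79
    stem_range: Tuple[int, int] = (30, 55)
    loop_range: Tuple[int, int] = (4, 8)
    bulge_prob: float = 0.05
    multi_branch_fraction: float = 0.84
    length_range: Tuple[int, int] = (70, 150)
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1:
            raise ValueError("n_pos must be >= 1")
        if not 0.0 <= self.multi_branch_fraction <= 1.0:
            raise ValueError("multi_branch_fraction must be in [0, 1]")
        if not 0.0 <= self.bulge_prob <= 1.0:
            raise ValueError("bulge_prob must be in [0, 1]")

    @property
    def resolved_n_neg(self) -> int:
        return self.n_neg if self.n_neg is not None else round(self.n_pos * self.imbalance_ratio)


def _stem_loop(
    rng: np.random.Generator,
    stem_len: int,
    loop_len: int,
    bulge_prob: float = 0.0,
    disjoint_arms: bool = False,
) -> Tuple[str, str]:
    """One stem-loop: sequence and its intended dot-bracket."""
    pairs, pair_p = (_HAIRPIN_PAIRS, _HAIRPIN_PAIR_P) if disjoint_arms else (_PAIRS, _PAIR_P)
    bulge_letters = ["A"] if disjoint_arms else _LOOP_ALPHABET
    left: List[str] = []
    right: List[str] = []
    struct_left: List[str] = []
    struct_right: List[str] = []
    for _ in range(stem_len):
        a, b = pairs[rng.choice(len(pairs), p=pair_p)]
        left.append(a)
        right.append(b)
        struct_left.append("(")
        struct_right.append(")")
        if rng.random() < bulge_prob:  # single-nucleotide bulge, 5' side
            left.append(str(rng.choice(bulge_letters)))
            struct_left.append(".")
    loop = [str(rng.choice(bulge_letters)) for _ in range(loop_len)]
    seq = "".join(left + loop + right[::-1])
    struct = "".join(struct_left + ["."] * loop_len + struct_right[::-1])
    return seq, struct


def make_hairpin(
    config: FixtureConfig, rng: np.random.Generator
) -> Tuple[SequenceRecord, str]:
    """A GC-biased single stem-loop positive with its expected structure."""
    stem = int(rng.integers(config.stem_range[0], config.stem_range[1] + 1))
    loop = int(rng.integers(config.loop_range[0], config.loop_range[1] + 1))
    seq, struct = _stem_loop(rng, stem, loop, config.bulge_prob, disjoint_arms=True)
    rec = SequenceRecord(f"hairpin_{rng.integers(10**9)}", seq)
    return rec, struct


def make_pseudo(config: FixtureConfig, rng: np.random.Generator) -> SequenceRecord:
    """A pseudo-hairpin negative.

    With probability ``multi_branch_fraction``: two or three short
    stem-loops joined by unpairable linkers (a multi-branched fold);
    otherwise an i.i.d. uniform sequence in the configured length range.
    """
    if rng.random() < config.multi_branch_fraction:
        n_branches = int(rng.integers(2, 4))
        parts = []
        for _ in range(n_branches):
            stem = int(rng.integers(6, 11))
            loop = int(rng.integers(4, 7))
            seq, _ = _stem_loop(rng, stem, loop)
            linker = "".join(str(rng.choice(_LOOP_ALPHABET)) for _ in range(int(rng.integers(2, 5))))
            parts.append(seq + linker)
        seq = "".join(parts)
        if len(seq) < config.length_range[0]:  # pad with unpairable tail
            pad = config.length_range[0] - len(seq)
            seq += "".join(str(rng.choice(_LOOP_ALPHABET)) for _ in range(pad))
    else:
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = "".join(str(c) for c in rng.choice(list("ACGU"), size=length))
    return SequenceRecord(f"pseudo_{rng.integers(10**9)}", seq)


def make_dataset(
    config: FixtureConfig,
) -> Tuple[List[SequenceRecord], List[int]]:
    """Positives then negatives, honouring the configured imbalance ratio."""
    rng = np.random.default_rng(config.seed)
    records: List[SequenceRecord] = []
    labels: List[int] = []
    for i in range(config.n_pos):
        rec, _ = make_hairpin(config, rng)
        records.append(SequenceRecord(f"real_{i:04d}", rec.seq))
        labels.append(1)
    for i in range(config.resolved_n_neg):
        rec = make_pseudo(config, rng)
        records.append(SequenceRecord(f"pseudo_{i:04d}", rec.seq))
        labels.append(-1)
    return records, labels


def make_separable_table(
    n_pos: int,
    n_neg: int,
    effect_size: float = 3.0,
    noise_features: int = 5,
    n_informative: int = 5,
    seed: int = 0,
) -> FeatureMatrix:
    """Labelled matrix with class-shifted informative and pure-noise columns.

    Informative columns: positives ~ N(effect_size, 1), negatives ~ N(0, 1)
    (shift = effect_size standard deviations); noise columns ~ N(0, 1) in
    both classes.
    """
    if n_pos < 4 or n_neg < 4:
        raise ValueError("need at least 4 samples per class")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    informative = rng.normal(0.0, 1.0, size=(n, n_informative))
    informative[:n_pos] += effect_size
    noise = rng.normal(0.0, 1.0, size=(n, noise_features))
    X = np.hstack([informative, noise])
    names = [f"inf_{i + 1}" for i in range(n_informative)] + [
        f"noise_{i + 1}" for i in range(noise_features)
    ]
    ids = [f"pos_{i:04d}" for i in range(n_pos)] + [f"neg_{i:04d}" for i in range(n_neg)]
    labels = np.array([1] * n_pos + [-1] * n_neg)
    return FeatureMatrix(ids, names, X, labels)
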