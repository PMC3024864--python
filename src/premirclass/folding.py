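"""Secondary-structure prediction for hairpin candidates.

The engine implements an additive pair-energy model: a structure's energy is
the sum of the energies of its base pairs (GC/AU/GU wobble allowed), with a
minimum hairpin-loop length and no stacking or loop terms.  On top of that
model it provides

* ``fold_mfe`` — Nussinov-style dynamic program for the minimum-free-energy
  structure, with a deterministic traceback;
* ``partition_function`` — McCaskill-style inside/outside recursions in log
  space for the ensemble free energy, MFE-structure frequency, base-pair
  probabilities and ensemble diversity;
* ``enumerate_structures`` — exhaustive enumeration of all legal structures
  (exponential; intended for small sequences, where it serves as an
  independent check on the dynamic programs);
* dot-bracket parsing and topology statistics (stems, hairpin loops,
  pair-type counts).

Everything downstream (features, shuffle nulls) consumes the ``FoldResult``
produced here, so any engine honouring the ``FoldingEngine`` protocol — for
instance an adapter around a full thermodynamic folder — can be substituted
and all features remain well defined relative to it.

Coordinates are 1-based throughout; dot-bracket is the only structure
exchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Protocol, Sequence, Tuple

import numpy as np

from .errors import InconsistentStructureError, StructureParseError
from .fasta import SequenceRecord

Pair = Tuple[int, int]

#: Unordered nucleotide sets that may pair, keyed by canonical pair-type name.
PAIR_TYPES: Mapping[str, frozenset] = {
    "GC": frozenset("GC"),
    "AU": frozenset("AU"),
    "GU": frozenset("GU"),
}


def pair_type(a: str, b: str) -> Optional[str]:
    """Canonical pair-type name ('GC', 'AU', 'GU') or None if illegal."""
    s = frozenset((a, b))
    for name, nts in PAIR_TYPES.items():
        if s == nts:
            return name
    return None


@dataclass(frozen=True)
class EnergyModel:
    """Additive pair-energy model.

    Parameters
    ----------
    pair_energies
        kcal/mol per pair type; defaults GC −3, AU −2, GU −1 (ordering by
        hydrogen-bond count). Must be ≤ 0.
    min_hairpin_loop
        Minimum number of unpaired bases enclosed by any pair (default 3,
        the standard folding convention).
    temperature
        Kelvin (default 310.15 K = 37 °C).
    gas_constant
        kcal/(mol·K).
    """

    pair_energies: Mapping[str, float] = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    min_hairpin_loop: int = 3
    temperature: float = 310.15
    gas_constant: float = 0.0019872

    def __post_init__(self):
        if any(e > 0 for e in self.pair_energies.values()):
            raise ValueError("pair energies must be <= 0 kcal/mol")
        if self.min_hairpin_loop < 1:
            raise ValueError("min_hairpin_loop must be >= 1")

    @property
    def rt(self) -> float:
        """Thermal energy RT in kcal/mol."""
        return self.gas_constant * self.temperature

    def pair_energy(self, a: str, b: str) -> Optional[float]:
        """Energy of pairing nucleotides ``a`` and ``b``, or None if illegal."""
        t = pair_type(a, b)
        return None if t is None else self.pair_energies[t]


@dataclass(frozen=True)
class FoldResult:
    """Structure plus ensemble thermodynamics for one sequence."""

    structure: str
    mfe: float
    efe: float  # ensemble free energy, -RT ln Z
    freq: float  # Boltzmann probability of the MFE structure
    diversity: float  # expected base-pair distance, 2 sum p(1-p)
    bp_probs: Dict[Pair, float] = field(repr=False, default_factory=dict)
    log_z: float = 0.0


@dataclass(frozen=True)
class StructureStats:
    """Topology counts derived from a dot-bracket structure."""

    pairs: Tuple[Pair, ...]
    n_bp: int
    n_stems: int
    n_loops: int  # hairpin (terminal) loops
    pair_type_counts: Mapping[str, int]


class FoldingEngine(Protocol):
    """Adapter contract: anything that turns a record into a FoldResult."""

    def fold(self, record: SequenceRecord) -> FoldResult: ...


# ---------------------------------------------------------------------------
# Pair-energy matrix helpers
# ---------------------------------------------------------------------------


def _energy_matrix(seq: str, model: EnergyModel) -> np.ndarray:
    """(L+2)x(L+2) matrix of pair energies, +inf where pairing is illegal.

    1-based indexing; entry [i, j] is defined only for j - i > min_hairpin_loop.
    """
    L = len(seq)
    E = np.full((L + 2, L + 2), np.inf)
    for i in range(1, L + 1):
        for j in range(i + model.min_hairpin_loop + 1, L + 1):
            e = model.pair_energy(seq[i - 1], seq[j - 1])
            if e is not None:
                E[i, j] = e
    return E


# ---------------------------------------------------------------------------
# Minimum free energy
# ---------------------------------------------------------------------------


def fold_mfe(record: SequenceRecord, model: EnergyModel = EnergyModel()) -> Tuple[str, float]:
    """Optimal structure and its energy under the additive pair model.

    The traceback is deterministic: at interval [i, j] it prefers pairing i
    over leaving it unpaired, and among co-optimal partners takes the
    smallest j.  An unpairable sequence yields all dots and MFE 0.
    """
    seq = record.seq
    L = len(seq)
    E = _energy_matrix(seq, model)
    W = np.zeros((L + 2, L + 2))
    span0 = model.min_hairpin_loop + 2  # shortest interval that can hold a pair
    for span in range(span0, L + 1):
        for i in range(1, L - span + 2):
            j = i + span - 1
            ks = np.arange(i + model.min_hairpin_loop + 1, j + 1)
            cand = E[i, ks] + W[i + 1, ks - 1] + W[ks + 1, j]
            W[i, j] = min(W[i + 1, j], cand.min()) if ks.size else W[i + 1, j]

    # deterministic traceback
    pairs: List[Pair] = []
    stack: List[Pair] = [(1, L)]
    eps = 1e-9
    while stack:
        i, j = stack.pop()
        if j - i < model.min_hairpin_loop + 1:
            continue
        target = W[i, j]
        paired = False
        for k in range(i + model.min_hairpin_loop + 1, j + 1):
            if np.isfinite(E[i, k]) and E[i, k] + W[i + 1, k - 1] + W[k + 1, j] <= target + eps:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))

    structure = ["."] * L
    for i, j in pairs:
        structure[i - 1] = "("
        structure[j - 1] = ")"
    return "".join(structure), float(W[1, L])


# ---------------------------------------------------------------------------
# Partition function (inside / outside, log space)
# ---------------------------------------------------------------------------


def _inside_log_z(seq: str, model: EnergyModel) -> Tuple[np.ndarray, np.ndarray]:
    """Inside log-partition table lZ[i, j] and log-Boltzmann pair factors."""
    L = len(seq)
    E = _energy_matrix(seq, model)
    lq = np.where(np.isfinite(E), -E / model.rt, -np.inf)
    # lZ[i, j] = log partition function over s[i..j]; empty intervals (j < i)
    # stay at log 1 = 0, which the recursions below rely on.
    lZ = np.zeros((L + 2, L + 2))
    for span in range(model.min_hairpin_loop + 2, L + 1):
        for i in range(1, L - span + 2):
            j = i + span - 1
            ks = np.arange(i + model.min_hairpin_loop + 1, j + 1)
            terms = lq[i, ks] + lZ[i + 1, ks - 1] + lZ[ks + 1, j]
            best = max(lZ[i + 1, j], terms.max()) if ks.size else lZ[i + 1, j]
            acc = np.exp(lZ[i + 1, j] - best) + np.exp(terms - best).sum()
            lZ[i, j] = best + np.log(acc)
    return lZ, lq


def log_partition(record: SequenceRecord, model: EnergyModel = EnergyModel()) -> float:
    """log Z without base-pair probabilities (cheap path for shuffle nulls)."""
    lZ, _ = _inside_log_z(record.seq, model)
    return float(lZ[1, len(record.seq)])


def ensemble_free_energy(record: SequenceRecord, model: EnergyModel = EnergyModel()) -> float:
    """EFE = −RT·ln Z in kcal/mol."""
    return -model.rt * log_partition(record, model)


def partition_function(record: SequenceRecord, model: EnergyModel = EnergyModel()) -> FoldResult:
    """Full ensemble computation: Z, EFE, Freq, base-pair probabilities, diversity.

    Inside recursion (unambiguous: condition on whether i pairs, and to whom):

        Z(i, j) = Z(i+1, j) + sum_k q(i, k) Z(i+1, k-1) Z(k+1, j)

    Outside values O(i, j) accumulate the weight of everything outside an
    interval rooted at a pair, giving p(i, k) = q·Z_in·O/Z; all accumulation
    is in log space to survive the large Boltzmann factors of long GC stems.
    """
    seq = record.seq
    L = len(seq)
    structure, mfe = fold_mfe(record, model)
    lZ, lq = _inside_log_z(seq, model)
    log_z = float(lZ[1, L])

    # outside pass
    lO = np.full((L + 2, L + 2), -np.inf)
    lO[1, L] = 0.0
    bp_probs: Dict[Pair, float] = {}
    for i in range(1, L + 1):
        for k in range(i + model.min_hairpin_loop + 1, L + 1):
            if not np.isfinite(lq[i, k]):
                continue
            js = np.arange(k, L + 1)
            terms = lO[i, js] + lZ[k + 1, js]
            m = terms.max()
            if not np.isfinite(m):
                continue
            l_ob = m + np.log(np.exp(terms - m).sum())
            l_zb = lq[i, k] + lZ[i + 1, k - 1]  # log weight of the paired block
            lp = l_zb + l_ob - log_z
            p = float(np.exp(lp))
            if p > 0.0:
                bp_probs[(i, k)] = min(p, 1.0)
            if k - 1 >= i + 1:
                lO[i + 1, k - 1] = np.logaddexp(lO[i + 1, k - 1], l_ob + lq[i, k])
            if k + 1 <= L:  # suffix child [k+1, j] of every context [i, j]
                js2 = np.arange(k + 1, L + 1)
                lO[k + 1, js2] = np.logaddexp(lO[k + 1, js2], lO[i, js2] + l_zb)
        if i + 1 <= L:
            sl = slice(i + 1, L + 1)
            lO[i + 1, sl] = np.logaddexp(lO[i + 1, sl], lO[i, sl])

    probs = np.fromiter(bp_probs.values(), dtype=float) if bp_probs else np.empty(0)
    diversity = float(2.0 * np.sum(probs * (1.0 - probs)))
    freq = float(np.exp(-mfe / model.rt - log_z))
    return FoldResult(
        structure=structure,
        mfe=mfe,
        efe=float(-model.rt * log_z),
        freq=min(freq, 1.0),
        diversity=diversity,
        bp_probs=bp_probs,
        log_z=log_z,
    )


@dataclass(frozen=True)
class ToyEngine:
    """Default engine: the additive pair-energy model defined in this module."""

    model: EnergyModel = EnergyModel()

    def fold(self, record: SequenceRecord) -> FoldResult:
        return partition_function(record, self.model)


# ---------------------------------------------------------------------------
# Exhaustive enumeration (independent of the dynamic programs)
# ---------------------------------------------------------------------------


def enumerate_structures(
    seq: str, model: EnergyModel = EnergyModel()
) -> Iterator[Tuple[Pair, ...]]:
    """Yield every legal nested structure of ``seq`` as a tuple of pairs.

    Recursive case split on the first position (unpaired, or paired with
    each legal partner) — deliberately naive and separate from the DP code
    so it can act as an oracle for small sequences.
    """
    L = len(seq)

    def _enum(i: int, j: int) -> Iterator[Tuple[Pair, ...]]:
        if i > j:
            yield ()
            return
        yield from _enum(i + 1, j)
        for k in range(i + model.min_hairpin_loop + 1, j + 1):
            if model.pair_energy(seq[i - 1], seq[k - 1]) is None:
                continue
            for left in _enum(i + 1, k - 1):
                for right in _enum(k + 1, j):
                    yield ((i, k),) + left + right

    yield from _enum(1, L)


def structure_energy(seq: str, pairs: Sequence[Pair], model: EnergyModel = EnergyModel()) -> float:
    """Additive energy of an explicit pair list (oracle helper)."""
    total = 0.0
    for i, j in pairs:
        e = model.pair_energy(seq[i - 1], seq[j - 1])
        if e is None:
            raise InconsistentStructureError(
                f"positions {i}-{j} ({seq[i - 1]}-{seq[j - 1]}) cannot pair"
            )
        total += e
    return total


# ---------------------------------------------------------------------------
# Dot-bracket parsing and topology statistics
# ---------------------------------------------------------------------------


def parse_dot_bracket(structure: str) -> List[Pair]:
    """Matched (i, j) pairs (1-based, i < j) from a dot-bracket string."""
    pairs: List[Pair] = []
    stack: List[int] = []
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureParseError(f"unmatched ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureParseError(f"illegal character {ch!r} at position {pos}")
    if stack:
        raise StructureParseError(
            f"{len(stack)} unclosed '(' at end of string (first at position {stack[0]})"
        )
    return sorted(pairs)


def structure_stats(record: SequenceRecord, structure: str) -> StructureStats:
    """Counts of base pairs, stems, hairpin loops and pair types.

    A stem is a maximal run of stacked pairs ((i, j) and (i+1, j-1) belong
    to the same stem); a hairpin loop is a pair enclosing no other paired
    position, so single-hairpin structures have n_loops = 1 and
    multi-branched ones n_loops >= 2.
    """
    if len(structure) != len(record.seq):
        raise StructureParseError(
            f"structure length {len(structure)} != sequence length {len(record.seq)}"
        )
    pairs = parse_dot_bracket(structure)
    type_counts = {"AU": 0, "GC": 0, "GU": 0}
    for i, j in pairs:
        t = pair_type(record.seq[i - 1], record.seq[j - 1])
        if t is None:
            raise InconsistentStructureError(
                f"positions {i}-{j} pair {record.seq[i - 1]}-{record.seq[j - 1]}, "
                "which is not a legal AU/GC/GU pair"
            )
        type_counts[t] += 1

    pair_set = set(pairs)
    n_stems = sum(1 for (i, j) in pairs if (i - 1, j + 1) not in pair_set)

    paired = np.zeros(len(record.seq) + 2, dtype=bool)
    for i, j in pairs:
        paired[i] = paired[j] = True
    csum = np.concatenate(([0], np.cumsum(paired[1:])))
    n_loops = sum(1 for (i, j) in pairs if csum[j - 1] - csum[i] == 0)

    return StructureStats(
        pairs=tuple(pairs),
        n_bp=len(pairs),
        n_stems=n_stems,
        n_loops=n_loops,
        pair_type_counts=type_counts,
    )
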