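"""Dinucleotide-preserving shuffles and shuffle-null folding statistics.

Real precursors fold with unusually low free energy for their dinucleotide
composition, so the null model must preserve that composition exactly: the
Euler-path shuffle of Altschul & Erickson keeps both the mononucleotide and
dinucleotide count multisets (and the first/last nucleotide) of the input.
z-scores and lower-tail add-one empirical p-values of MFE and EFE against
this null are the four "statistically significant" features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import DegenerateInputError
from .fasta import SequenceRecord
from .folding import EnergyModel, ensemble_free_energy, fold_mfe


@dataclass(frozen=True)
class ShuffleNull:
    """Null MFE / EFE distributions from dinucleotide shuffles."""

    n_shuffles: int
    null_mfe: Tuple[float, ...]
    null_efe: Tuple[float, ...]
    seed: int

    def __post_init__(self):
        if len(self.null_mfe) != self.n_shuffles or len(self.null_efe) != self.n_shuffles:
            raise ValueError("null distribution lengths must equal n_shuffles")


def dinuc_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its dinucleotide count multiset.

    Altschul–Erickson Euler-path construction: pick a random last out-edge
    per vertex until those edges form an arborescence into the final
    nucleotide, shuffle the remaining out-edges, then walk the Euler path.
    The first and last nucleotides are invariant.
    """
    if len(seq) < 2:
        raise DegenerateInputError("dinucleotide shuffle needs length >= 2")
    if len(set(seq)) == 1:
        return seq

    edges = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]

    sources = [v for v in edges if v != last]
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in sources}
        # every source must reach `last` by following chosen last edges
        ok = True
        for v in sources:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break

    walk_edges = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        walk_edges[v] = pool

    out: List[str] = [seq[0]]
    positions = {v: 0 for v in walk_edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_edges[cur][positions[cur]]
        positions[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def null_statistics(
    record: SequenceRecord,
    model: EnergyModel = EnergyModel(),
    n: int = 300,
    seed: int = 0,
) -> ShuffleNull:
    """Fold ``n`` dinucleotide shuffles with the same engine/model.

    The default n = 300 matches the size of the published null; smaller
    values (>= 2) are accepted for fast runs.
    """
    if n < 2:
        raise DegenerateInputError("null_statistics needs n >= 2 shuffles")
    rng = np.random.default_rng(seed)
    null_mfe: List[float] = []
    null_efe: List[float] = []
    for _ in range(n):
        shuffled = SequenceRecord(record.id + "|shuf", dinuc_shuffle(record.seq, rng))
        _, mfe = fold_mfe(shuffled, model)
        null_mfe.append(mfe)
        null_efe.append(ensemble_free_energy(shuffled, model))
    return ShuffleNull(n, tuple(null_mfe), tuple(null_efe), seed)


def z_and_p(observed: float, null: Sequence[float]) -> Tuple[float, float]:
    """Lower-tail z-score and add-one empirical p-value against a null sample.

    z uses the n−1 (sample) standard deviation and is 0 when the null is
    degenerate; p = (#{null <= observed} + 1) / (n + 1), so p is never 0 and
    equals 1 when the observation sits at or above every null value.
    """
    arr = np.asarray(null, dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("null distribution is empty")
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    z = 0.0 if sd == 0 else (observed - arr.mean()) / sd
    p = (np.count_nonzero(arr <= observed) + 1) / (arr.size + 1)
    return float(z), float(p)
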