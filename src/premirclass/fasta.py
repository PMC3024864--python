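"""FASTA input/output and RNA-alphabet normalization.

Sequences are stored RNA-side (T is mapped to U on read); IUPAC ambiguity
codes are rejected rather than resolved so that every downstream feature is
a deterministic function of the record.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, TextIO, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FastaParseError, InvalidAlphabetError

RNA_ALPHABET = frozenset("ACGU")

PathLike = Union[str, Path]


def normalize_sequence(raw: str) -> str:
    """Uppercase ``raw`` and map T/t to U; reject anything outside A/C/G/U.

    Idempotent: normalizing an already-normalized sequence is the identity.

    Raises
    ------
    InvalidAlphabetError
        Naming the offending character and its 1-based position.
    """
    out = raw.upper().replace("T", "U")
    for pos, ch in enumerate(out, start=1):
        if ch not in RNA_ALPHABET:
            raise InvalidAlphabetError(ch, pos)
    return out


@dataclass(frozen=True)
class SequenceRecord:
    """A FASTA record: identifier plus normalized RNA sequence."""

    id: str
    seq: str = field(repr=False)

    def __post_init__(self):
        if not self.seq:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in RNA_ALPHABET:
                raise InvalidAlphabetError(ch, pos)

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: PathLike) -> TextIO:
    """Open ``path`` as text, transparently decompressing gzip."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path: PathLike) -> List[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into normalized records.

    Order is preserved; one record per entry. A sequence line before any
    header or an entry with an empty body is a :class:`FastaParseError`.
    """
    with _open_text(path) as handle:
        text = handle.read()
    first = next((ln for ln in text.splitlines() if ln.strip()), None)
    if first is not None and not first.startswith(">"):
        raise FastaParseError(
            f"{path}: sequence data before any '>' header: {first[:40]!r}"
        )
    records: List[SequenceRecord] = []
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        header_token = title.split()[0] if title.split() else title
        if not seq:
            raise FastaParseError(f"{path}: record {header_token!r} has no sequence")
        try:
            records.append(SequenceRecord(header_token, normalize_sequence(seq)))
        except InvalidAlphabetError as exc:
            raise InvalidAlphabetError(exc.char, exc.position) from None
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 60) -> None:
    """Write records as multi-FASTA, wrapping sequence lines at ``width``."""
    with open(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for start in range(0, len(rec.seq), width):
                out.write(rec.seq[start : start + width] + "\n")
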