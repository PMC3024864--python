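"""Exception hierarchy for premirclass.

Every error raised by the package derives from :class:`PremirclassError`,
so callers (and the CLI) can catch one type and report a categorized
message.
"""


class PremirclassError(Exception):
    """Base class for all premirclass errors."""


class FastaParseError(PremirclassError):
    """Malformed FASTA input (sequence before header, empty body, ...)."""


class InvalidAlphabetError(PremirclassError):
    """A sequence character outside {A, C, G, U} (after T->U mapping)."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based
        super().__init__(
            f"invalid nucleotide {char!r} at position {position}; "
            "only A/C/G/U (or T, mapped to U) are accepted"
        )


class StructureParseError(PremirclassError):
    """Unbalanced or ill-formed dot-bracket string."""


class InconsistentStructureError(PremirclassError):
    """A dot-bracket pair whose nucleotides cannot legally pair."""


class DegenerateInputError(PremirclassError):
    """Input too short / empty for the requested operation."""


class InsufficientClassSizeError(PremirclassError):
    """A class has too few instances for the requested statistic."""


class UndefinedMetricError(PremirclassError):
    """Confusion-matrix metric requested with an empty class."""


class ModelFormatError(PremirclassError):
    """Model archive missing fields or with an unsupported schema version."""
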