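"""Degenerate IUPAC primers: validation, expansion, and end-trimming.

A degenerate primer is a single IUPAC string (e.g. ``GTGYCAGCMGCCGCGGTAA``)
standing for the pool of all fully resolved A/C/G/T oligonucleotides obtained
by substituting each ambiguity code with one of its nucleotides.  The classes
here model the parent primer, its resolved variants (with 5'/3' trim offsets
relative to the parent's locus-specific region), and the equimolar pool.

An optional 5' linker (a constant "common sequence" tag used for two-stage
Illumina library construction) is stored separately from the locus-specific
sequence: trimming and all thermodynamics operate on the locus-specific
region only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

__all__ = [
    "IUPAC_CODES",
    "InvalidSequenceError",
    "DegeneratePrimer",
    "PrimerVariant",
    "PrimerPool",
    "validate_iupac",
    "degeneracy",
    "degenerate_positions",
    "reverse_complement",
    "matches_pattern",
    "expand",
    "trim_variant",
]

#: IUPAC nucleotide codes mapped to their nucleotide sets (alphabetical order,
#: A < C < G < T, so that itertools.product over these tuples enumerates
#: variants in lexicographic order of the expansion choices).
IUPAC_CODES: dict[str, tuple[str, ...]] = {
    "A": ("A",),
    "C": ("C",),
    "G": ("G",),
    "T": ("T",),
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
    "B": ("C", "G", "T"),
    "D": ("A", "G", "T"),
    "H": ("A", "C", "T"),
    "V": ("A", "C", "G"),
    "N": ("A", "C", "G", "T"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains a character outside the IUPAC DNA alphabet."""

    def __init__(self, sequence: str, position: int, character: str):
        self.sequence = sequence
        self.position = position  # 1-based
        self.character = character
        super().__init__(
            f"invalid IUPAC DNA character {character!r} at position {position} "
            f"in sequence {sequence!r}"
        )


def validate_iupac(sequence: str) -> str:
    """Uppercase and validate a degenerate DNA sequence.

    Returns the uppercased sequence iff every character is an IUPAC
    nucleotide code; otherwise raises :class:`InvalidSequenceError` naming
    the first offending 1-based position and character.
    """
    if not isinstance(sequence, str):
        raise TypeError(f"sequence must be a string, got {type(sequence).__name__}")
    seq = sequence.upper()
    if not seq:
        raise InvalidSequenceError(sequence, 1, "")
    for i, ch in enumerate(seq):
        if ch not in IUPAC_CODES:
            raise InvalidSequenceError(sequence, i + 1, ch)
    return seq


def degeneracy(sequence: str) -> int:
    """Product over positions of the IUPAC code multiplicity (>= 1)."""
    seq = validate_iupac(sequence)
    d = 1
    for ch in seq:
        d *= len(IUPAC_CODES[ch])
    return d


def degenerate_positions(sequence: str) -> set[int]:
    """1-based positions whose code stands for more than one nucleotide."""
    seq = validate_iupac(sequence)
    return {i + 1 for i, ch in enumerate(seq) if len(IUPAC_CODES[ch]) > 1}


def reverse_complement(sequence: str) -> str:
    """IUPAC-aware reverse complement (an involution: R<->Y, B<->V, ...)."""
    seq = validate_iupac(sequence)
    return "".join(_IUPAC_COMPLEMENT[ch] for ch in reversed(seq))


def matches_pattern(sequence: str, iupac_pattern: str) -> bool:
    """True iff ``sequence`` is one resolution of ``iupac_pattern`` (equal lengths)."""
    if len(sequence) != len(iupac_pattern):
        return False
    return all(
        s in IUPAC_CODES[p] for s, p in zip(sequence.upper(), iupac_pattern.upper())
    )


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named degenerate primer: the design unit.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"515F"``.
    iupac_sequence : str
        Locus-specific region as an IUPAC string (linker excluded).
    orientation : {"forward", "reverse"}
        Priming orientation; informational for pairing and reporting.
    linker : str, optional
        Constant 5' common-sequence tag (A/C/G/T only).  Excluded from
        expansion, trimming, and thermodynamics.
    """

    name: str
    iupac_sequence: str
    orientation: Literal["forward", "reverse"] = "forward"
    linker: str | None = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("primer name must be non-empty")
        object.__setattr__(self, "iupac_sequence", validate_iupac(self.iupac_sequence))
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse, got {self.orientation!r}")
        if self.linker is not None:
            link = validate_iupac(self.linker)
            bad = [c for c in link if len(IUPAC_CODES[c]) > 1]
            if bad:
                raise ValueError(
                    f"linker of primer {self.name!r} contains degenerate code(s) {bad}"
                )
            object.__setattr__(self, "linker", link)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.iupac_sequence)

    @property
    def degenerate_positions(self) -> set[int]:
        return degenerate_positions(self.iupac_sequence)

    def __len__(self) -> int:
        return len(self.iupac_sequence)


@dataclass(frozen=True)
class PrimerVariant:
    """One fully resolved expansion of a degenerate primer.

    ``trim5``/``trim3`` count bases removed from the 5'/3' ends of the
    parent's locus-specific region; ``sequence`` is the retained window.
    """

    parent: str
    index: int
    sequence: str
    trim5: int = 0
    trim3: int = 0

    def __post_init__(self):
        seq = validate_iupac(self.sequence)
        bad = [c for c in seq if len(IUPAC_CODES[c]) > 1]
        if bad:
            raise ValueError(f"variant sequence must be non-degenerate, found {bad}")
        object.__setattr__(self, "sequence", seq)
        if self.trim5 < 0 or self.trim3 < 0:
            raise ValueError("trim offsets must be non-negative")

    @property
    def label(self) -> str:
        return f"{self.parent}_{self.index}_t5-{self.trim5}_t3-{self.trim3}"

    def __len__(self) -> int:
        return len(self.sequence)


def trim_variant(variant: PrimerVariant, a: int, b: int) -> PrimerVariant:
    """Remove ``a`` bases from the 5' end and ``b`` from the 3' end.

    Trim offsets accumulate, so trimming (a, b) then (c, d) equals trimming
    (a + c, b + d) in one step.  Raises ``ValueError`` if nothing would remain.
    """
    if a < 0 or b < 0:
        raise ValueError("trim amounts must be non-negative")
    if a + b >= len(variant.sequence):
        raise ValueError(
            f"over-trim: removing {a}+{b} bases from {len(variant.sequence)}-base "
            f"variant {variant.label} would leave nothing"
        )
    if a == 0 and b == 0:
        return variant
    new_seq = variant.sequence[a: len(variant.sequence) - b]
    return replace(variant, sequence=new_seq, trim5=variant.trim5 + a, trim3=variant.trim3 + b)


@dataclass(frozen=True)
class PrimerPool:
    """An ordered pool of resolved variants with per-variant molar weights.

    Weights default to equimolar and are normalized to sum to 1.
    """

    name: str
    variants: tuple[PrimerVariant, ...]
    weights: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if not self.variants:
            raise ValueError(f"pool {self.name!r} must contain at least one variant")
        object.__setattr__(self, "variants", tuple(self.variants))
        w = tuple(self.weights)
        if not w:
            w = tuple(1.0 / len(self.variants) for _ in self.variants)
        if len(w) != len(self.variants):
            raise ValueError("weights and variants must have equal length")
        if any(x < 0 for x in w):
            raise ValueError("weights must be non-negative")
        total = sum(w)
        if total <= 0:
            raise ValueError("weights must not all be zero")
        object.__setattr__(self, "weights", tuple(x / total for x in w))

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[PrimerVariant]:
        return iter(self.variants)

    def sequences(self) -> list[str]:
        return [v.sequence for v in self.variants]


def expand(primer: DegeneratePrimer) -> PrimerPool:
    """Expand a degenerate primer into its equimolar pool of variants.

    Variants are ordered lexicographically over the expansion choices at each
    position (A < C < G < T), which is deterministic and stable; every variant
    is distinct and untrimmed.
    """
    choices = [IUPAC_CODES[ch] for ch in primer.iupac_sequence]
    variants = tuple(
        PrimerVariant(parent=primer.name, index=i, sequence="".join(combo))
        for i, combo in enumerate(itertools.product(*choices))
    )
    return PrimerPool(name=primer.name, variants=variants)
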