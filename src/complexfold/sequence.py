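"""Effective one-strand representation of a two-strand RNA complex.

Two strands are joined by a three-nucleotide *phantom linker*: an unpairable
spacer that turns the complex into a single chain so one folding engine can
treat both intra- and inter-molecular base pairs.  Loops that contain linker
positions are not physical loops and carry no free energy; the linker itself
can never pair.

Internally all positions are 0-based; every public report and file format uses
1-based coordinates (the conversion happens at the I/O boundary only).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: Number of phantom-linker nucleotides inserted between the strands.
LINKER_LENGTH = 3

#: Placeholder letter used for linker positions in the effective sequence.
LINKER_BASE = "N"

#: Canonical pairs: Watson-Crick plus the GU wobble.
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: Minimum number of unpaired nucleotides in a physical hairpin loop.
MIN_HAIRPIN_LOOP = 3

_VALID = set("ACGU")


def clean_sequence(raw: str, *, name: str = "sequence") -> str:
    """Uppercase an RNA string, map T to U, and validate the alphabet.

    Raises :class:`ValidationError` naming the 1-based position of the first
    offending character.
    """
    s = raw.strip().upper().replace("T", "U")
    if not s:
        raise ValidationError(f"{name} is empty")
    for pos, ch in enumerate(s, start=1):
        if ch not in _VALID:
            raise ValidationError(
                f"{name}: invalid character {ch!r} at position {pos}"
            )
    return s


def is_canonical(x: str, y: str) -> bool:
    return (x, y) in CANONICAL_PAIRS


@dataclass(frozen=True)
class EffectiveSequence:
    """Strand A + phantom linker + strand B as one chain.

    Attributes
    ----------
    bases:
        The concatenated sequence; linker positions hold :data:`LINKER_BASE`.
    linker_mask:
        ``linker_mask[i]`` is True iff position ``i`` (0-based) is a linker
        nucleotide.
    strand_boundary:
        0-based index of the first strand-B position.
    """

    bases: str
    linker_mask: tuple
    strand_boundary: int

    @property
    def n(self) -> int:
        return len(self.bases)

    @property
    def len_a(self) -> int:
        return self.strand_boundary - sum(self.linker_mask)

    @property
    def len_b(self) -> int:
        return self.n - self.strand_boundary

    @property
    def l_tot(self) -> int:
        """Total physical length: both strands, linker excluded."""
        return self.n - sum(self.linker_mask)

    def is_linker(self, i: int) -> bool:
        return bool(self.linker_mask[i])

    def linker_in(self, lo: int, hi: int) -> bool:
        """True iff any linker position lies in the closed interval [lo, hi]."""
        return any(self.linker_mask[i] for i in range(max(lo, 0), min(hi + 1, self.n)))

    def can_pair(self, i: int, j: int) -> bool:
        """Conformational pairing rule for positions ``i < j`` (0-based).

        Requires a canonical pair of non-linker bases, and either at least
        :data:`MIN_HAIRPIN_LOOP` nucleotides between them or a linker inside
        the span (a linker-containing loop has no minimum size because it is
        not a physical loop).
        """
        if not (0 <= i < j < self.n):
            return False
        if self.linker_mask[i] or self.linker_mask[j]:
            return False
        if not is_canonical(self.bases[i], self.bases[j]):
            return False
        if j - i - 1 < MIN_HAIRPIN_LOOP and not self.linker_in(i + 1, j - 1):
            return False
        return True

    def is_intermolecular(self, i: int, j: int) -> bool:
        return i < self.strand_boundary - LINKER_LENGTH <= self.strand_boundary <= j

    def to_local(self, i: int) -> tuple:
        """Map a 0-based effective index to (strand, 0-based local index)."""
        if self.linker_mask[i]:
            raise ValidationError(f"position {i} is a linker position")
        if i < self.strand_boundary:
            return ("A", i)
        return ("B", i - self.strand_boundary)

    @classmethod
    def single(cls, seq: str) -> "EffectiveSequence":
        """Wrap a single strand (no linker) — used for plain folding."""
        s = clean_sequence(seq)
        return cls(bases=s, linker_mask=(False,) * len(s), strand_boundary=len(s))


def concat_with_linker(seq_a: str, seq_b: str) -> EffectiveSequence:
    """Join two strands with the three-nucleotide phantom linker.

    The effective length is ``len(A) + 3 + len(B)``; the linker positions can
    never pair and L_tot (the physical length) excludes them.
    """
    a = clean_sequence(seq_a, name="strand A")
    b = clean_sequence(seq_b, name="strand B")
    bases = a + LINKER_BASE * LINKER_LENGTH + b
    mask = (False,) * len(a) + (True,) * LINKER_LENGTH + (False,) * len(b)
    return EffectiveSequence(
        bases=bases, linker_mask=mask, strand_boundary=len(a) + LINKER_LENGTH
    )
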