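"""Coordinate system and cut-geometry algebra for staggered dsRNA cleavage.

Mini-III RNases (class 4 of the RNase III superfamily) cut perfect RNA
duplexes with a 2-nt stagger, leaving 3' overhangs on both products, like the
orthodox RNase III.  Everything downstream of the sequencing and scanning
stages rests on the small algebra defined here, so the conventions are spelled
out once and used everywhere:

* Coordinates are **1-based and residue-inclusive**.  The *top* strand of a
  duplex segment is stored 5'->3'; the bottom strand is always its exact
  reverse complement (perfect duplex, no bulges).
* A **bond** is named by the residue immediately 5' of it *on the named
  strand, in that strand's own 5'->3' numbering*.  "Cut between the 14th and
  15th residues" of a strand is bond index 14 of that strand.
* Bottom-strand positions convert to reference (top-strand) coordinates via
  ``ref = L - pos + 1`` where ``L`` is the duplex length.
* The **overhang** is signed: positive values are 3' overhangs (2 for
  Mini-III), negative values 5' overhangs, zero a blunt cut.

With these conventions, a top-strand cut at bond ``i`` paired with a
bottom-strand cut at bond ``b`` (bottom numbering) on a duplex of length
``L`` satisfies the closed form ``b = L - i + overhang``; the worked example
is a 30-bp duplex cut at top bond 14 and bottom bond 18, i.e. a 2-nt 3'
overhang.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_OVERHANG",
    "AlphabetError",
    "GeometryError",
    "DsSegment",
    "BondCoordinate",
    "DuplexCutSite",
    "SiteWindow",
    "reverse_complement",
    "complement_base",
    "bottom_bond_from_top",
    "top_bond_from_bottom",
    "infer_overhang",
    "site_window",
    "termination_to_bond",
    "bottom_ref_bond",
    "bottom_end_position",
]

#: Overhang left by Mini-III / RNase III-family staggered cleavage (nt, 3').
DEFAULT_OVERHANG = 2

RNA_BASES = "ACGU"

#: Complements for the RNA alphabet plus IUPAC degeneracy codes.
_COMPLEMENT = {
    "A": "U", "C": "G", "G": "C", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class AlphabetError(ValueError):
    """A sequence contains a character outside the accepted alphabet."""


class GeometryError(ValueError):
    """A cut position is impossible for the stated duplex length / overhang."""


def complement_base(base: str, *, allow_iupac: bool = False) -> str:
    """Complement of a single RNA base (IUPAC codes behind a flag)."""
    if not allow_iupac and base not in RNA_BASES:
        raise AlphabetError(f"not an RNA base: {base!r}")
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise AlphabetError(f"not an IUPAC RNA code: {base!r}") from None


def reverse_complement(seq: str, *, allow_iupac: bool = False) -> str:
    """Reverse complement of an RNA string (5'->3' in, 5'->3' out).

    Strict {A,C,G,U} by default; ``allow_iupac=True`` additionally maps the
    degeneracy codes to their complements (R<->Y, K<->M, ...), which is what
    motif scanning needs.  Non-alphabet characters are rejected with the
    offending position reported.
    """
    alphabet = _COMPLEMENT if allow_iupac else {b: _COMPLEMENT[b] for b in RNA_BASES}
    out = []
    for pos, ch in enumerate(reversed(seq)):
        try:
            out.append(alphabet[ch])
        except KeyError:
            bad = len(seq) - pos  # 1-based position in the input orientation
            raise AlphabetError(
                f"invalid character {ch!r} at position {bad} of sequence"
            ) from None
    return "".join(out)


@dataclass(frozen=True)
class DsSegment:
    """A linear double-stranded RNA reference segment.

    Only the top strand is stored; the bottom strand is implied (exact
    reverse complement — the model assumes a perfect duplex).
    """

    id: str
    top_sequence: str

    def __post_init__(self) -> None:
        for pos, ch in enumerate(self.top_sequence, start=1):
            if ch not in RNA_BASES:
                raise AlphabetError(
                    f"segment {self.id!r}: invalid character {ch!r} at position {pos}"
                )

    @property
    def length(self) -> int:
        return len(self.top_sequence)

    @property
    def bottom_sequence(self) -> str:
        """Bottom strand, 5'->3' (reverse complement of the top strand)."""
        return reverse_complement(self.top_sequence)

    def reverse_complemented(self) -> "DsSegment":
        """The same duplex flipped: old bottom strand becomes the new top."""
        return DsSegment(id=self.id, top_sequence=self.bottom_sequence)


@dataclass(frozen=True)
class BondCoordinate:
    """A scissile bond on one strand: the residue 5' of the bond, 1-based,
    in that strand's own 5'->3' numbering."""

    strand: str  # "top" | "bottom"
    index: int
    segment_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise ValueError(f"strand must be 'top' or 'bottom', got {self.strand!r}")
        if self.index < 1:
            raise GeometryError(f"bond index must be >= 1, got {self.index}")


def bottom_bond_from_top(i_top: int, length: int, overhang: int = DEFAULT_OVERHANG) -> int:
    """Bottom-strand bond index paired with a top-strand cut.

    For a duplex of ``length`` bp cut at top bond ``i_top`` with the given
    signed overhang, the partner cut on the bottom strand (bottom numbering)
    is ``length - i_top + overhang``.  E.g. a 30-bp duplex cut between top
    residues 14|15 with a 2-nt 3' overhang is cut between bottom residues
    18|19.
    """
    if not 1 <= i_top <= length - 1:
        raise GeometryError(f"top bond {i_top} outside [1, {length - 1}]")
    b = length - i_top + overhang
    if not 1 <= b <= length - 1:
        raise GeometryError(
            f"cut at top bond {i_top} with overhang {overhang} falls outside the "
            f"{length}-bp duplex (bottom bond {b})"
        )
    return b


def top_bond_from_bottom(b_bottom: int, length: int, overhang: int = DEFAULT_OVERHANG) -> int:
    """Inverse of :func:`bottom_bond_from_top` (the formula is an involution)."""
    return bottom_bond_from_top(b_bottom, length, overhang)


def infer_overhang(i_top: int, b_bottom: int, length: int) -> int:
    """Signed overhang implied by a pair of cut positions.

    ``i_top + b_bottom - length``; positive = 3' overhang, negative = 5',
    zero = blunt.  The Mini-III worked example (14, 18, 30) gives +2.
    """
    for name, idx in (("top", i_top), ("bottom", b_bottom)):
        if not 1 <= idx <= length - 1:
            raise GeometryError(f"{name} bond {idx} outside [1, {length - 1}]")
    return i_top + b_bottom - length


def bottom_ref_bond(i_top: int, overhang: int = DEFAULT_OVERHANG) -> int:
    """Reference-coordinate bond severed on the bottom strand.

    A duplex cut at top bond ``i`` with a 3' overhang ``v`` severs the bottom
    strand between reference positions ``i - v`` and ``i - v + 1``, i.e. at
    reference bond ``i - v``.
    """
    return i_top - overhang


def bottom_end_position(i_top: int, overhang: int = DEFAULT_OVERHANG) -> int:
    """Reference position of the bottom-strand 3' end created by a cut.

    The bottom strand runs 3'->5' in reference coordinates, so the fragment
    on the high-coordinate side of the severed bond exposes its new 3' end
    at reference position ``i - v + 1`` — for the 2-nt overhang, position
    ``i - 1``, which is exactly the X / X'+1 strand-pairing offset used by
    site calling.
    """
    return i_top - overhang + 1


@dataclass(frozen=True)
class DuplexCutSite:
    """A double-strand cut, canonically indexed by its top-strand bond."""

    segment_id: str
    i_top: int
    overhang: int = DEFAULT_OVERHANG

    def bottom_bond(self, length: int) -> int:
        """Partner bond on the bottom strand, bottom-strand numbering."""
        return bottom_bond_from_top(self.i_top, length, self.overhang)


@dataclass(frozen=True)
class SiteWindow:
    """Sequence window centred on a scissile bond.

    ``bond_offset`` is the number of residues of the window that lie 5' of
    the bond (on the window's own strand), so the bond sits between window
    positions ``bond_offset`` and ``bond_offset + 1``.  A full-width window
    of 14 has ``bond_offset == 7`` (7 nt each side); windows nearer than
    half a width to a segment end are truncated and flagged.
    """

    sequence: str
    bond_offset: int
    truncated_left: bool = False
    truncated_right: bool = False
    weight: int = 1
    segment_id: str | None = None
    i_top: int | None = None

    @property
    def width(self) -> int:
        return len(self.sequence)


def site_window(segment: DsSegment, i_top: int, width: int = 14) -> SiteWindow:
    """Window of ``width`` nt centred on top-strand bond ``i_top``.

    Covers reference positions ``i_top - (width/2 - 1) .. i_top + width/2``
    (even widths only: half the window on each side of the bond), truncated
    at segment ends with flags set and ``bond_offset`` adjusted.
    """
    if width < 4 or width % 2 != 0:
        raise ValueError(f"window width must be even and >= 4, got {width}")
    L = segment.length
    if not 1 <= i_top <= L - 1:
        raise GeometryError(f"bond {i_top} outside [1, {L - 1}]")
    half = width // 2
    start = i_top - (half - 1)
    end = i_top + half
    truncated_left = start < 1
    truncated_right = end > L
    start = max(start, 1)
    end = min(end, L)
    return SiteWindow(
        sequence=segment.top_sequence[start - 1 : end],
        bond_offset=i_top - start + 1,
        truncated_left=truncated_left,
        truncated_right=truncated_right,
        segment_id=segment.id,
        i_top=i_top,
    )


def termination_to_bond(
    template_strand: str, strong_termination_pos: int, segment_id: str | None = None
) -> BondCoordinate:
    """Convert a strong primer-extension stop into a scissile-bond call.

    Reverse transcription of a cleaved template terminates when the enzyme
    runs off the cleavage-generated 5' end, so the strong stop marks the
    template's 5'-terminal residue and the bond lies immediately 5' of it:
    ``bond = stop - 1`` in the template strand's own numbering.  Weaker
    bands one residue beyond arise from non-templated nucleotide addition by
    the reverse transcriptase and are deliberately ignored.
    """
    if strong_termination_pos < 2:
        raise GeometryError(
            f"termination position must be >= 2, got {strong_termination_pos}"
        )
    return BondCoordinate(
        strand=template_strand, index=strong_termination_pos - 1, segment_id=segment_id
    )
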