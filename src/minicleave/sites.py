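"""Cleavage-site calling from strand-paired fragment-end counts.

End-capture sequencing ligates adapters to the 3' ends of cleavage products,
so mapped read termini mark cleavage-generated fragment ends.  A genuine
double-strand cut by a staggered nuclease leaves a signature on *both*
strands: with a 2-nt 3' overhang, the top-strand 3' end falls at reference
position ``i`` (the scissile bond) and the bottom-strand 3' end at ``i - 1``.
A site is called only when both strands carry at least ``min_support`` ends
at the paired positions, and its weight is the sum of the two supports —
single-strand nicks and random breaks rarely produce the paired offset, so
the pairing rule doubles as the noise filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import DEFAULT_OVERHANG, DsSegment, SiteWindow, site_window

__all__ = [
    "EndCountTrack",
    "CalledSite",
    "call_sites",
    "terminus_fraction",
    "weighted_instances",
]


@dataclass
class EndCountTrack:
    """Per-segment, per-strand counts of mapped fragment 3'-end positions.

    Positions are reference (top-strand) coordinates, 1-based, marking the
    3'-terminal residue of fragments on that strand.  Sparse: absent
    positions have count zero.
    """

    segment_id: str
    strand: str  # "top" | "bottom"
    length: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise ValueError(f"strand must be 'top' or 'bottom': {self.strand!r}")
        for pos, c in self.counts.items():
            if not 1 <= pos <= self.length:
                raise ValueError(
                    f"track {self.segment_id}/{self.strand}: position {pos} "
                    f"outside [1, {self.length}]"
                )
            if c < 0:
                raise ValueError(f"negative count at position {pos}")

    def add(self, pos: int, n: int = 1) -> None:
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside [1, {self.length}]")
        self.counts[pos] = self.counts.get(pos, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def terminal_position(self) -> int:
        """The segment-terminal 3'-end position on this strand.

        The intact top strand ends at reference position L, the intact
        bottom strand at reference position 1.
        """
        return self.length if self.strand == "top" else 1


@dataclass(frozen=True)
class CalledSite:
    """A canonical cleavage site indexed by its top-strand scissile bond."""

    segment_id: str
    i_top: int
    top_support: int
    bottom_support: int

    @property
    def weight(self) -> int:
        return self.top_support + self.bottom_support


def call_sites(
    top_track: EndCountTrack,
    bottom_track: EndCountTrack,
    min_support: int = 1,
    overhang: int = DEFAULT_OVERHANG,
) -> list[CalledSite]:
    """Pair strand-specific end counts into double-strand cleavage calls.

    A site at top-strand bond ``i`` is emitted iff the top track holds
    >= ``min_support`` ends at ``i`` and the bottom track >= ``min_support``
    ends at ``i - overhang + 1`` (``i - 1`` for the canonical 2-nt 3'
    overhang); its weight is the sum of the two supports.  Segment-terminal
    end positions (top at L, bottom at 1) are library features of intact
    molecule ends, not cleavage evidence, and are excluded.  Sites are
    returned sorted by coordinate.
    """
    if top_track.segment_id != bottom_track.segment_id:
        raise ValueError(
            f"track segment mismatch: {top_track.segment_id!r} vs "
            f"{bottom_track.segment_id!r}"
        )
    if top_track.length != bottom_track.length:
        raise ValueError("track length mismatch")
    if top_track.strand != "top" or bottom_track.strand != "bottom":
        raise ValueError("call_sites expects (top, bottom) tracks in that order")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")

    L = top_track.length
    sites = []
    for i in sorted(top_track.counts):
        if i >= L:  # terminal top end, or out of bond range
            continue
        j = i - overhang + 1
        if j <= 1:  # below range, or the terminal bottom end at position 1
            continue
        top_n = top_track.counts[i]
        bot_n = bottom_track.counts.get(j, 0)
        if top_n >= min_support and bot_n >= min_support:
            sites.append(
                CalledSite(
                    segment_id=top_track.segment_id,
                    i_top=i,
                    top_support=top_n,
                    bottom_support=bot_n,
                )
            )
    return sites


def terminus_fraction(tracks: list[EndCountTrack]) -> float:
    """Fraction of all end counts that fall on segment-terminal positions.

    A 3-segment genome has 6 terminal 3'-end positions (top at L, bottom at
    1 for each segment).  An uncleaved library concentrates essentially all
    of its ends there; a digested library moves mass to internal positions,
    so this statistic is the library-level control for cleavage.
    """
    total = sum(t.total for t in tracks)
    if total == 0:
        raise ValueError("terminus_fraction undefined: tracks hold zero counts")
    terminal = sum(t.counts.get(t.terminal_position, 0) for t in tracks)
    return terminal / total


def weighted_instances(
    sites: list[CalledSite],
    segments: dict[str, DsSegment] | list[DsSegment],
    width: int = 14,
) -> list[SiteWindow]:
    """One sequence window per called site, carrying the site's read weight.

    The windows are the positive set for motif discovery; weighting by read
    count makes heavily cleaved sites contribute proportionally.  Total
    window weight equals total site weight (conservation).
    """
    if not isinstance(segments, dict):
        segments = {s.id: s for s in segments}
    out = []
    for s in sites:
        seg = segments[s.segment_id]
        w = site_window(seg, s.i_top, width=width)
        out.append(
            SiteWindow(
                sequence=w.sequence,
                bond_offset=w.bond_offset,
                truncated_left=w.truncated_left,
                truncated_right=w.truncated_right,
                weight=s.weight,
                segment_id=s.segment_id,
                i_top=s.i_top,
            )
        )
    return out
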