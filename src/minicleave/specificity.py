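"""Saturation-mutagenesis consensus, duplex scanning and in-silico digestion.

The enrichment and EM routes derive a motif from sequencing; the orthogonal
wet-lab route substitutes every position of a 14-nt window around a known
cleavage site (3 substitutions x 14 positions = 42 variants), measures each
variant's cleavage rate relative to the wild type, and renders the tolerated
base sets as a consensus such as (G/A/U)(A/U)CC^(U/A)(C/A/U)(G/A/U).  This
module implements that derivation plus the uses a consensus is put to:
scanning duplexes for predicted sites and predicting digestion products and
their gel banding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DEFAULT_OVERHANG,
    DsSegment,
    DuplexCutSite,
    GeometryError,
    reverse_complement,
)
from .motifs import IUPAC_SETS, IupacMotif, Pwm

__all__ = [
    "VariantRateRecord",
    "ConsensusSpec",
    "SaturationVariant",
    "ScanHit",
    "DigestProduct",
    "design_saturation",
    "derive_consensus",
    "scan_duplex",
    "insilico_digest",
    "banding_table",
]

_BASES = "ACGU"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class VariantRateRecord:
    """Relative cleavage rate of a single-substitution variant (wt = 1)."""

    position: int  # 1..window width
    base: str
    relative_rate: float
    label: str | None = None  # optional substrate coordinate, e.g. "87"

    def __post_init__(self) -> None:
        if self.base not in _BASES:
            raise ValueError(f"invalid base {self.base!r}")
        if self.relative_rate < 0:
            raise ValueError("relative_rate must be >= 0")


@dataclass(frozen=True)
class SaturationVariant:
    position: int
    base: str
    sequence: str


@dataclass
class ConsensusSpec:
    """Per-position tolerated base sets with a preferred base each.

    ``preferred`` is a concrete window string (the best-cleaved base per
    position); ``tolerated[i]`` always contains ``preferred[i]``.
    ``bond_offset`` marks the scissile bond (residues 5' of it).
    """

    tolerated: list[frozenset[str]]
    preferred: str
    bond_offset: int
    rates: dict[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.tolerated) != len(self.preferred):
            raise ValueError("tolerated/preferred length mismatch")
        for i, (tol, pref) in enumerate(zip(self.tolerated, self.preferred), start=1):
            if not tol:
                raise ValueError(f"position {i}: empty tolerated set")
            if pref not in tol:
                raise ValueError(f"position {i}: preferred {pref!r} not tolerated")

    @property
    def width(self) -> int:
        return len(self.preferred)

    def _ordered_bases(self, pos: int) -> list[str]:
        """Preferred first, then by relative rate (desc), then alphabetical."""
        pref = self.preferred[pos]
        rest = sorted(
            (b for b in self.tolerated[pos] if b != pref),
            key=lambda b: (-self.rates.get((pos + 1, b), 0.0), b),
        )
        return [pref] + rest

    def render(self, trim: bool = True) -> str:
        """Printable consensus, e.g. ``(G/A/U)(A/U)CC^(U/A)(C/A/U)(G/A/U)``.

        Fully unconstrained positions render as N and, when ``trim`` is on,
        are dropped from the flanks.
        """
        parts = []
        for pos in range(self.width):
            bases = self._ordered_bases(pos)
            if len(self.tolerated[pos]) == 4:
                parts.append("N")
            elif len(bases) == 1:
                parts.append(bases[0])
            else:
                parts.append("(" + "/".join(bases) + ")")
        lo, hi = 0, self.width
        if trim:
            while lo < hi and parts[lo] == "N":
                lo += 1
            while hi > lo and parts[hi - 1] == "N":
                hi -= 1
        rendered = parts[lo:hi]
        caret_at = self.bond_offset - lo
        if 0 <= caret_at <= len(rendered):
            rendered = rendered[:caret_at] + ["^"] + rendered[caret_at:]
        return "".join(rendered)

    def to_iupac(self) -> IupacMotif:
        from .motifs import SET_TO_IUPAC

        letters = "".join(SET_TO_IUPAC[s] for s in self.tolerated)
        return IupacMotif(letters=letters, cut_offset=self.bond_offset)


def design_saturation(window: str) -> list[SaturationVariant]:
    """All single-substitution variants of a 14-nt site window.

    Exactly 3 variants per position (every non-wild-type base), 42 in total;
    together with the wild type they saturate all 4 bases at all positions.
    """
    if len(window) != 14:
        raise ValueError(f"saturation window must be 14 nt, got {len(window)}")
    for ch in window:
        if ch not in _BASES:
            raise ValueError(f"invalid base {ch!r} in window")
    out = []
    for pos, wt in enumerate(window, start=1):
        for base in _BASES:
            if base == wt:
                continue
            seq = window[: pos - 1] + base + window[pos:]
            out.append(SaturationVariant(position=pos, base=base, sequence=seq))
    return out


def derive_consensus(
    records: list[VariantRateRecord],
    wild_type_window: str,
    tolerance: float = 0.5,
    bond_offset: int = 7,
) -> ConsensusSpec:
    """Consensus from a complete saturation-mutagenesis rate table.

    Per position, the tolerated set is the wild-type base plus every
    substitution whose relative rate is >= ``tolerance``; the preferred base
    is the one with the maximal rate (wild type = 1 by definition).  All
    3 x width records must be present.
    """
    width = len(wild_type_window)
    expected = {
        (pos, b)
        for pos, wt in enumerate(wild_type_window, start=1)
        for b in _BASES
        if b != wt
    }
    got = {(r.position, r.base) for r in records}
    missing = sorted(expected - got)
    if missing:
        raise ValueError(f"missing variant records: {missing}")
    extra = got - expected
    if extra:
        raise ValueError(f"unexpected variant records (wild-type base?): {sorted(extra)}")

    rate = {(r.position, r.base): r.relative_rate for r in records}
    tolerated: list[frozenset[str]] = []
    preferred = []
    for pos, wt in enumerate(wild_type_window, start=1):
        tol = {wt} | {b for b in _BASES if b != wt and rate[(pos, b)] >= tolerance}
        tolerated.append(frozenset(tol))
        best = max(tol, key=lambda b: (1.0 if b == wt else rate[(pos, b)], b == wt))
        preferred.append(best)
    rates = dict(rate)
    for pos, wt in enumerate(wild_type_window, start=1):
        rates[(pos, wt)] = 1.0
    return ConsensusSpec(
        tolerated=tolerated,
        preferred="".join(preferred),
        bond_offset=bond_offset,
        rates=rates,
    )


@dataclass(frozen=True)
class ScanHit:
    """A motif/PWM match on a duplex, canonicalized to a top-strand bond."""

    site: DuplexCutSite
    strand: str  # strand carrying the motif in its given orientation
    start: int  # 1-based start of the match on that strand (own numbering)
    score: float


def _iupac_match(seq: str, letters: str, start0: int) -> bool:
    return all(seq[start0 + p] in IUPAC_SETS[ch] for p, ch in enumerate(letters))


def _pwm_scores(seq: str, pwm: Pwm) -> np.ndarray:
    enc = np.array([_BASE_IDX[ch] for ch in seq], dtype=np.int64)
    lo = pwm.log_odds()
    w = pwm.width
    n = len(seq) - w + 1
    scores = np.empty(n)
    for off in range(n):
        scores[off] = lo[np.arange(w), enc[off : off + w]].sum()
    return scores


def scan_duplex(
    segment: DsSegment,
    motif: IupacMotif | Pwm,
    overhang: int = DEFAULT_OVERHANG,
    score_threshold: float | str | None = "auto",
) -> list[ScanHit]:
    """Find all predicted cleavage sites for a motif on both strands.

    The motif is matched against the top strand and against the bottom
    strand (5'->3'); a bottom-strand match at bottom bond ``b`` is reported
    as the canonical top-strand bond ``i_top = L - b + overhang``.
    Overlapping matches are all reported.  For a PWM the score is the sum of
    log-odds against a uniform background; ``score_threshold="auto"`` uses
    80% of the maximal achievable score, and an explicit ``None`` raises.
    """
    if isinstance(motif, Pwm):
        if motif.cut_offset is None:
            raise ValueError("PWM needs a cut_offset to place the scissile bond")
        if score_threshold is None:
            raise ValueError("PWM scanning requires a score threshold")
        if score_threshold == "auto":
            score_threshold = 0.8 * float(motif.log_odds().max(axis=1).sum())
        width, cut_offset = motif.width, motif.cut_offset
    else:
        if motif.cut_offset is None:
            raise ValueError("motif needs a cut_offset (use e.g. 'ACC^U')")
        width, cut_offset = motif.width, motif.cut_offset

    L = segment.length
    hits: list[ScanHit] = []
    for strand, seq in (("top", segment.top_sequence), ("bottom", segment.bottom_sequence)):
        if isinstance(motif, Pwm):
            scores = _pwm_scores(seq, motif)
            starts = [
                (off + 1, float(scores[off]))
                for off in range(len(scores))
                if scores[off] >= score_threshold
            ]
        else:
            starts = [
                (off + 1, 0.0)
                for off in range(L - width + 1)
                if _iupac_match(seq, motif.letters, off)
            ]
        for start, score in starts:
            bond = start + cut_offset - 1  # bond on the matched strand
            if strand == "top":
                i_top = bond
            else:
                i_top = L - bond + overhang
            if not 1 <= i_top <= L - 1:
                continue
            if not 1 <= i_top - overhang <= L - 1:
                continue  # partner cut would fall off the duplex
            hits.append(
                ScanHit(
                    site=DuplexCutSite(segment_id=segment.id, i_top=i_top, overhang=overhang),
                    strand=strand,
                    start=start,
                    score=score,
                )
            )
    hits.sort(key=lambda h: (h.site.i_top, h.strand, h.start))
    return hits


@dataclass(frozen=True)
class DigestProduct:
    """A maximal uncut duplex span between cleavage sites.

    Spans are reference-coordinate, residue-inclusive.  The apparent gel
    size of a staggered-ended product is the longer strand's length
    (overhanging ends migrate approximately with the total span).
    """

    index: int
    top_span: tuple[int, int]
    bottom_span: tuple[int, int]

    @property
    def top_length(self) -> int:
        return self.top_span[1] - self.top_span[0] + 1

    @property
    def bottom_length(self) -> int:
        return self.bottom_span[1] - self.bottom_span[0] + 1

    @property
    def apparent_size(self) -> int:
        return max(self.top_length, self.bottom_length)


def insilico_digest(
    segment: DsSegment, sites: list[DuplexCutSite] | list[int], overhang: int | None = None
) -> list[DigestProduct]:
    """Complete-digestion products of a duplex for a set of cut sites.

    ``k`` sites produce ``k + 1`` products; per strand the product lengths
    sum to the segment length.  Sites may be given as DuplexCutSite objects
    or bare top-strand bond indices (then ``overhang`` applies to all,
    defaulting to 2).
    """
    L = segment.length
    parsed: list[tuple[int, int]] = []
    for s in sites:
        if isinstance(s, DuplexCutSite):
            parsed.append((s.i_top, s.overhang if overhang is None else overhang))
        else:
            parsed.append((int(s), DEFAULT_OVERHANG if overhang is None else overhang))
    tops = [i for i, _ in parsed]
    if len(set(tops)) != len(tops):
        raise ValueError("duplicate cut sites")
    for i, v in parsed:
        if not 1 <= i <= L - 1:
            raise GeometryError(f"cut {i} outside [1, {L - 1}]")
        if not 1 <= i - v <= L - 1:
            raise GeometryError(
                f"cut at bond {i} with overhang {v}: bottom cut falls off the duplex"
            )
    parsed.sort()
    top_cuts = [i for i, _ in parsed]
    bottom_cuts = [i - v for i, v in parsed]  # reference bonds on the bottom strand
    top_bounds = [0] + top_cuts + [L]
    bottom_bounds = [0] + bottom_cuts + [L]
    products = []
    for k in range(len(parsed) + 1):
        products.append(
            DigestProduct(
                index=k,
                top_span=(top_bounds[k] + 1, top_bounds[k + 1]),
                bottom_span=(bottom_bounds[k] + 1, bottom_bounds[k + 1]),
            )
        )
    return products


def banding_table(products: list[DigestProduct], min_visible: int = 20) -> list[int]:
    """Apparent product sizes in gel order (largest first).

    Products smaller than ``min_visible`` nt run off the gel and are
    dropped; equal sizes are listed with multiplicity (they co-migrate but
    both exist).
    """
    sizes = [p.apparent_size for p in products if p.apparent_size >= min_visible]
    return sorted(sizes, reverse=True)
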