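"""Synthetic end-capture experiments on a Φ6-like segmented dsRNA genome.

Every input the analysis pipeline consumes can be generated here with known
ground truth: a 3-segment linear dsRNA genome (default lengths 6374, 4063
and 2948 bp, matching the bacteriophage Φ6 L/M/S segments), a planted
positional preference model centred on the ACC^U core, time-limited
digestion with first-order per-site kinetics, multinomial end-capture
sampling with a uniform random-breakage background, noisy cleavage time
courses, and saturation-mutagenesis rate tables.

The digestion model is deliberately the simplest memoryless one: each bond
``i`` is severed within time ``t`` with probability ``1 - exp(-k_i t)``
where ``k_i = k_specific * score_i + k_nonspecific`` and ``score_i`` is the
product of per-position multipliers of the preference model over the 14-nt
window around the bond.  Sites cut independently; cuts follow the 2-nt 3'
overhang geometry.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import DEFAULT_OVERHANG, DsSegment, bottom_end_position
from .sites import EndCountTrack
from .specificity import ConsensusSpec, VariantRateRecord
from .kinetics import TimeCourse

__all__ = [
    "PreferenceModel",
    "SimConfig",
    "GroundTruthSite",
    "FragmentPopulation",
    "SimResult",
    "make_genome",
    "score_all_bonds",
    "simulate_limited_digest",
    "simulate_end_capture",
    "simulate_experiment",
    "simulate_timecourse",
    "simulate_satmut_rates",
]

_BASES = "ACGU"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

#: Φ6 bacteriophage genome: three linear dsRNA segments L, M and S.
PHI6_SEGMENT_LENGTHS = (6374, 4063, 2948)
PHI6_SEGMENT_IDS = ("L", "M", "S")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class PreferenceModel:
    """Per-position, per-base cleavage-rate multipliers around the bond.

    A width-14 table anchored so that the scissile bond falls between window
    positions ``bond_offset`` and ``bond_offset + 1``.  The wild-type
    (preferred) base at every position has multiplier 1; the default model
    encodes the (G/A/U)(A/U)CC^(U/A)(C/A/U)(G/A/U) consensus: preferred
    bases multiply by 1, tolerated-but-not-preferred bases by 0.5 (they are
    cleaved, just less efficiently than the preferred variant), disallowed
    flank bases by 0.05, and the obligate CC core by 0 — substitutions
    there are not tolerated at all.
    """

    multipliers: np.ndarray  # (width, 4)
    preferred: str
    bond_offset: int = 7

    def __post_init__(self) -> None:
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        if self.multipliers.ndim != 2 or self.multipliers.shape[1] != 4:
            raise ValueError("multipliers must be (width, 4)")
        if np.any(self.multipliers < 0):
            raise ValueError("multipliers must be >= 0")
        if len(self.preferred) != self.multipliers.shape[0]:
            raise ValueError("preferred string must match the table width")
        for p, ch in enumerate(self.preferred):
            if not math.isclose(self.multipliers[p, _BASE_IDX[ch]], 1.0):
                raise ValueError(f"preferred base at position {p + 1} must have multiplier 1")

    @property
    def width(self) -> int:
        return self.multipliers.shape[0]

    @classmethod
    def default(cls) -> "PreferenceModel":
        """Consensus-derived default, strongest at the ACC^U core.

        The obligate CC (window positions 6-7) admits no substitution; the
        core-adjacent positions 5 and 8 (the A and U of ACC^U) are strongly
        graded (preferred 1, the other tolerated base 0.38 — the measured
        relative rate of a substituted-core substrate — and disallowed
        0.05); the outer consensus positions 4, 9 and 10 tolerate three
        bases and are only mildly graded (preferred 1, tolerated 0.7,
        disallowed 0.2) — flank constraints in the measured consensus are
        much weaker than the core.
        """
        mult = np.ones((14, 4))
        preferred = list("AAAGACCUCGAAAA")

        def set_pos(pos: int, pref: str, tolerated: str, tol_mult: float, off_mult: float) -> None:
            for b in _BASES:
                if b == pref:
                    mult[pos - 1, _BASE_IDX[b]] = 1.0
                elif b in tolerated:
                    mult[pos - 1, _BASE_IDX[b]] = tol_mult
                else:
                    mult[pos - 1, _BASE_IDX[b]] = off_mult
            preferred[pos - 1] = pref

        set_pos(4, "G", "AU", 0.7, 0.2)
        set_pos(5, "A", "U", 0.38, 0.05)
        set_pos(6, "C", "", 0.0, 0.0)
        set_pos(7, "C", "", 0.0, 0.0)
        set_pos(8, "U", "A", 0.38, 0.05)
        set_pos(9, "C", "AU", 0.7, 0.2)
        set_pos(10, "G", "AU", 0.7, 0.2)
        return cls(multipliers=mult, preferred="".join(preferred), bond_offset=7)

    def constrained_positions(self) -> list[int]:
        """1-based window positions carrying any multiplier below 1."""
        return [
            p + 1
            for p in range(self.width)
            if np.any(self.multipliers[p] < 1.0)
        ]

    def tolerated(self, position: int, threshold: float = 0.3) -> list[str]:
        """Bases with multiplier >= threshold at a 1-based window position."""
        row = self.multipliers[position - 1]
        return [b for b in _BASES if row[_BASE_IDX[b]] >= threshold]

    def score(self, window: str) -> float:
        if len(window) != self.width:
            raise ValueError(f"window must be {self.width} nt")
        s = 1.0
        for p, ch in enumerate(window):
            s *= self.multipliers[p, _BASE_IDX[ch]]
        return s


@dataclass
class SimConfig:
    """Study conditions for one synthetic end-capture experiment.

    Defaults emulate the published experiment: the three Φ6 segment
    lengths, a 10-min limited digest, a sequencing depth equal to the
    uniquely mapped read count of the real library, and a 7% uniform
    background-breakage fraction (the uncleaved control retains ~93% of its
    ends at the six segment termini).
    """

    segment_lengths: tuple[int, ...] = PHI6_SEGMENT_LENGTHS
    segment_ids: tuple[str, ...] | None = None
    seed: int = 0
    planted_model: PreferenceModel = field(default_factory=PreferenceModel.default)
    k_specific: float = 0.12  # per minute, score-1 sites
    k_nonspecific: float = 2e-6  # per bond per minute
    digestion_time: float = 10.0  # minutes
    n_molecules: int = 20
    read_depth: int = 236_860
    background_break_fraction: float = 0.07
    control_mode: bool = False
    n_planted_per_segment: int = 10
    planted_positions: dict[str, list[int]] | None = None
    ground_truth_threshold: float = 0.5
    overhang: int = DEFAULT_OVERHANG
    read_length: int = 8

    def __post_init__(self) -> None:
        if any(L < 100 for L in self.segment_lengths):
            raise ValueError("segment lengths must be >= 100")
        for name in ("k_specific", "k_nonspecific", "digestion_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.background_break_fraction <= 1.0:
            raise ValueError("background_break_fraction must be in [0, 1]")
        if self.segment_ids is None:
            if len(self.segment_lengths) == 3 and tuple(self.segment_lengths) == PHI6_SEGMENT_LENGTHS:
                self.segment_ids = PHI6_SEGMENT_IDS
            else:
                self.segment_ids = tuple(f"seg{i + 1}" for i in range(len(self.segment_lengths)))
        if len(self.segment_ids) != len(self.segment_lengths):
            raise ValueError("segment_ids/segment_lengths length mismatch")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_model"] = {
            "multipliers": self.planted_model.multipliers.tolist(),
            "preferred": self.planted_model.preferred,
            "bond_offset": self.planted_model.bond_offset,
        }
        return d


@dataclass(frozen=True)
class GroundTruthSite:
    segment_id: str
    i_top: int
    score: float
    planted: bool


@dataclass
class FragmentPopulation:
    """Multiset of per-strand fragment intervals (reference coordinates).

    Each of the ``n_molecules`` digested duplex copies contributes one exact
    tiling of the segment per strand; intervals accumulate across copies.
    """

    segment_id: str
    length: int
    n_molecules: int
    top: Counter = field(default_factory=Counter)  # (start, end) -> count
    bottom: Counter = field(default_factory=Counter)
    cuts: Counter = field(default_factory=Counter)  # i_top -> molecules cut there


def make_genome(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> tuple[list[DsSegment], list[GroundTruthSite]]:
    """Random genome with planted preference-model sites, plus ground truth.

    Sequences are uniform over {A,C,G,U} except at planted windows, where
    each constrained model position receives a base drawn in proportion to
    its rate multiplier.  Ground truth contains every planted position
    plus, by *scanning*, every bond whose window score reaches
    ``ground_truth_threshold`` — chance occurrences of the consensus count
    as real sites, because the simulated enzyme cannot tell them from
    planted ones.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    model = config.planted_model
    half = model.bond_offset
    segments: list[DsSegment] = []
    planted_map: dict[str, set[int]] = {}

    for seg_id, L in zip(config.segment_ids, config.segment_lengths):
        seq = rng.integers(0, 4, size=L)
        if config.planted_positions is not None:
            positions = sorted(config.planted_positions.get(seg_id, []))
            for i in positions:
                if not (half + 1 <= i <= L - (model.width - half) + 0):
                    raise ValueError(
                        f"planted site {seg_id}:{i} overlaps a segment end "
                        f"(needs the full {model.width}-nt window)"
                    )
        else:
            lo, hi = half + 1, L - (model.width - half)
            positions = []
            tries = 0
            while len(positions) < config.n_planted_per_segment and tries < 10_000:
                cand = int(rng.integers(lo, hi + 1))
                if all(abs(cand - p) >= model.width for p in positions):
                    positions.append(cand)
                tries += 1
            positions.sort()
        for i in positions:
            # window position p sits at reference i - bond_offset + p,
            # i.e. 0-based index i - bond_offset + p - 1
            for p in model.constrained_positions():
                # planted bases are drawn in proportion to their rate
                # multipliers: preferred bases dominate, tolerated ones
                # appear at reduced frequency, disallowed ones rarely
                row = model.multipliers[p - 1]
                seq[i - half + p - 1] = rng.choice(4, p=row / row.sum())
        top = "".join(_BASES[b] for b in seq)
        segments.append(DsSegment(id=seg_id, top_sequence=top))
        planted_map[seg_id] = set(positions)

    ground_truth: list[GroundTruthSite] = []
    for seg in segments:
        scores = score_all_bonds(seg, model)
        L = seg.length
        for i in range(half + 1, L - (model.width - half) + 1):
            s = scores[i - 1]
            planted = i in planted_map[seg.id]
            # every planted site is truth by construction; beyond those,
            # chance windows reaching the threshold are real sites too and
            # must be reported, not ignored
            if planted or s >= config.ground_truth_threshold:
                ground_truth.append(
                    GroundTruthSite(
                        segment_id=seg.id, i_top=i, score=float(s), planted=planted
                    )
                )
    return segments, ground_truth


def score_all_bonds(segment: DsSegment, model: PreferenceModel) -> np.ndarray:
    """Preference score of every top-strand bond (index i at array slot i-1).

    Window positions falling outside the segment contribute multiplier 1
    (an absent flank neither helps nor hurts).
    """
    L = segment.length
    enc = np.array([_BASE_IDX[ch] for ch in segment.top_sequence], dtype=np.int64)
    bonds = np.arange(1, L)
    scores = np.ones(L - 1)
    for p in range(1, model.width + 1):
        ref = bonds - model.bond_offset + p
        valid = (ref >= 1) & (ref <= L)
        scores[valid] *= model.multipliers[p - 1, enc[ref[valid] - 1]]
    return scores


def simulate_limited_digest(
    segments: list[DsSegment],
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> dict[str, FragmentPopulation]:
    """Time-limited digestion of ``n_molecules`` copies of each segment.

    Each bond is severed independently with probability
    ``1 - exp(-(k_specific * score + k_nonspecific) * t)``; cuts follow the
    configured overhang geometry, and the resulting per-strand intervals
    tile each molecule exactly.
    """
    if config.digestion_time <= 0:
        raise ValueError("digestion_time must be > 0 for a digest")
    rng = _as_rng(config.seed if rng is None else rng)
    model = config.planted_model
    v = config.overhang
    t = config.digestion_time
    out: dict[str, FragmentPopulation] = {}
    for seg in segments:
        L = seg.length
        scores = score_all_bonds(seg, model)
        rates = config.k_specific * scores + config.k_nonspecific
        p_cut = 1.0 - np.exp(-rates * t)
        # a cut needs both strand scissions inside the duplex
        bonds = np.arange(1, L)
        valid = (bonds - v >= 1) & (bonds - v <= L - 1) & (bonds <= L - 1)
        p_cut = np.where(valid, p_cut, 0.0)
        pop = FragmentPopulation(segment_id=seg.id, length=L, n_molecules=config.n_molecules)
        for _ in range(config.n_molecules):
            cuts = bonds[rng.random(L - 1) < p_cut]
            for i in cuts.tolist():
                pop.cuts[int(i)] += 1
            top_bounds = [0, *cuts.tolist(), L]
            bot_bounds = [0, *(cuts - v).tolist(), L]
            for a, b in zip(top_bounds[:-1], top_bounds[1:]):
                pop.top[(a + 1, b)] += 1
            for a, b in zip(bot_bounds[:-1], bot_bounds[1:]):
                pop.bottom[(a + 1, b)] += 1
        out[seg.id] = pop
    return out


def intact_fragments(segments: list[DsSegment], n_molecules: int) -> dict[str, FragmentPopulation]:
    """Undigested fragment populations (the uncleaved control library)."""
    return {
        seg.id: FragmentPopulation(
            segment_id=seg.id,
            length=seg.length,
            n_molecules=n_molecules,
            top=Counter({(1, seg.length): n_molecules}),
            bottom=Counter({(1, seg.length): n_molecules}),
        )
        for seg in segments
    }


def simulate_end_capture(
    fragments: dict[str, FragmentPopulation],
    segments: list[DsSegment],
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[tuple[str, str], EndCountTrack], Counter]:
    """Sample sequenced fragment 3' ends into per-strand count tracks.

    A top-strand fragment spanning reference ``(s, e)`` exposes its 3' end
    at ``e``; a bottom-strand fragment at ``s`` (the bottom strand runs
    3'->5' in reference coordinates).  ``read_depth`` ends are sampled
    multinomially in proportion to fragment multiplicity; a
    ``background_break_fraction`` share is drawn uniformly over all
    positions and strands instead, emulating random breakage.

    Also returns a counter of reference-oriented ``read_length``-mers
    centred on the scissile bond implied by each sampled internal end (the
    mapped-read context used by the MEME-style route); ends whose context
    window would run off the segment — including the intact termini — emit
    no read.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    if not fragments or all(
        not pop.top and not pop.bottom for pop in fragments.values()
    ):
        raise ValueError("empty fragment set")
    seg_by_id = {s.id: s for s in segments}

    end_keys: list[tuple[str, str, int]] = []
    end_weights: list[int] = []
    for seg_id in sorted(fragments):
        pop = fragments[seg_id]
        for (s, e), c in sorted(pop.top.items()):
            end_keys.append((seg_id, "top", e))
            end_weights.append(c)
        for (s, e), c in sorted(pop.bottom.items()):
            end_keys.append((seg_id, "bottom", s))
            end_weights.append(c)
    weights = np.array(end_weights, dtype=float)

    tracks: dict[tuple[str, str], EndCountTrack] = {
        (seg.id, strand): EndCountTrack(
            segment_id=seg.id, strand=strand, length=seg.length
        )
        for seg in segments
        for strand in ("top", "bottom")
    }

    depth = config.read_depth
    n_bg = int(rng.binomial(depth, config.background_break_fraction))
    n_sig = depth - n_bg

    reads: Counter[str] = Counter()
    v = config.overhang
    rl = config.read_length
    half_left = rl // 2 - 1  # bond-centred: rl/2 - 1 left of the bond residue

    def emit(seg_id: str, strand: str, pos: int, count: int) -> None:
        tracks[(seg_id, strand)].add(pos, count)
        bond = pos if strand == "top" else pos + v - 1
        seg = seg_by_id[seg_id]
        start = bond - half_left
        end = bond + (rl - half_left - 1)
        if start >= 1 and end <= seg.length:
            reads[seg.top_sequence[start - 1 : end]] += count

    if n_sig > 0:
        counts = rng.multinomial(n_sig, weights / weights.sum())
        for (seg_id, strand, pos), c in zip(end_keys, counts):
            if c > 0:
                emit(seg_id, strand, pos, int(c))
    if n_bg > 0:
        sizes = np.array([seg_by_id[s].length for s in sorted(seg_by_id)], dtype=float)
        seg_ids_sorted = sorted(seg_by_id)
        per_slot = np.repeat(sizes, 2)  # top and bottom per segment
        slot_counts = rng.multinomial(n_bg, per_slot / per_slot.sum())
        slot = 0
        for seg_id, size in zip(seg_ids_sorted, sizes):
            for strand in ("top", "bottom"):
                k = int(slot_counts[slot])
                slot += 1
                if k == 0:
                    continue
                positions = rng.integers(1, int(size) + 1, size=k)
                for pos, c in Counter(positions.tolist()).items():
                    emit(seg_id, strand, int(pos), c)
    return tracks, reads


@dataclass
class SimResult:
    """Everything one synthetic experiment produced, with ground truth."""

    config: SimConfig
    segments: list[DsSegment]
    ground_truth: list[GroundTruthSite]
    fragments: dict[str, FragmentPopulation]
    tracks: dict[tuple[str, str], EndCountTrack]
    reads: Counter


def simulate_experiment(config: SimConfig) -> SimResult:
    """Run the full generator: genome -> digest -> end capture.

    In ``control_mode`` the digest is skipped (intact molecules only), so
    all non-background ends fall on the six segment termini.
    """
    rng = np.random.default_rng(config.seed)
    segments, ground_truth = make_genome(config, rng)
    if config.control_mode:
        fragments = intact_fragments(segments, config.n_molecules)
    else:
        fragments = simulate_limited_digest(segments, config, rng)
    tracks, reads = simulate_end_capture(fragments, segments, config, rng)
    return SimResult(
        config=config,
        segments=segments,
        ground_truth=ground_truth,
        fragments=fragments,
        tracks=tracks,
        reads=reads,
    )


def simulate_timecourse(
    slopes: dict[str, float],
    times: list[float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    enzyme_id: str = "wt",
    enzyme_amount: float = 1.0,
) -> list[TimeCourse]:
    """Noisy linear cleavage time courses, one per substrate.

    ``fraction(t) = clip(slope * t + Normal(0, noise_sd), 0, 1)``.
    """
    rng = _as_rng(rng)
    out = []
    for substrate_id in sorted(slopes):
        slope = slopes[substrate_id]
        fracs = []
        for t in times:
            y = slope * t
            if noise_sd > 0:
                y += rng.normal(0.0, noise_sd)
            fracs.append(min(1.0, max(0.0, y)))
        out.append(
            TimeCourse(
                substrate_id=substrate_id,
                enzyme_id=enzyme_id,
                enzyme_amount=enzyme_amount,
                times=list(times),
                fractions=fracs,
            )
        )
    return out


def simulate_satmut_rates(
    true_consensus: ConsensusSpec,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    tolerated_rate: float = 0.8,
    disallowed_rate: float = 0.05,
) -> list[VariantRateRecord]:
    """Relative-rate table of all single substitutions of a consensus window.

    The wild-type window is the consensus's preferred string; tolerated
    substitutions cleave at ``tolerated_rate`` and disallowed ones at
    ``disallowed_rate`` (0 for an obligate core), plus optional Gaussian
    noise clipped at zero.  With zero noise, :func:`derive_consensus`
    recovers the planted consensus exactly.
    """
    rng = _as_rng(rng)
    wt = true_consensus.preferred
    records = []
    for pos, wt_base in enumerate(wt, start=1):
        tol = true_consensus.tolerated[pos - 1]
        for base in _BASES:
            if base == wt_base:
                continue
            if base in tol:
                r = tolerated_rate
            elif len(tol) == 1:
                r = 0.0  # obligate position: substitutions not tolerated at all
            else:
                r = disallowed_rate
            if noise_sd > 0:
                r += rng.normal(0.0, noise_sd)
            records.append(
                VariantRateRecord(position=pos, base=base, relative_rate=max(0.0, r))
            )
    return records
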