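"""Discriminative motif discovery for cleavage-site consensus derivation.

Two complementary routes, mirroring how discriminative motif finders are used
on end-capture data:

* **Enrichment route** (DREME-style): weighted site windows form the positive
  set; every sliding window of the substrate genome forms the background.
  Exact w-mer seeds are scored with a one-sided hypergeometric (Fisher) tail
  and greedily generalized one position at a time to IUPAC degeneracy codes,
  accepting a generalization only when the p-value strictly improves.  Run
  incrementally over widths 4..14, the longest width that does not cause a
  dramatic drop in motif presence and sub-word diversity is selected.
* **PFM/EM route** (MEME-style): the most frequent unique 8-nt end-proximal
  reads are fit with a one-occurrence-per-sequence EM to yield a position
  weight matrix.

Both routes report a consensus string; on Mini-III data they converge on the
ACC^U core.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .geometry import DsSegment, SiteWindow, reverse_complement

__all__ = [
    "IUPAC_SETS",
    "SET_TO_IUPAC",
    "IupacMotif",
    "EnrichmentResult",
    "Pwm",
    "WidthSelectionTrace",
    "WidthTraceEntry",
    "WindowSet",
    "hypergeom_tail",
    "build_background",
    "discover_motif",
    "select_width",
    "top_unique_reads",
    "em_pwm",
    "consensus_string",
]

_BASES = "ACGU"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "U": frozenset("U"),
    "R": frozenset("AG"), "Y": frozenset("CU"), "S": frozenset("CG"),
    "W": frozenset("AU"), "K": frozenset("GU"), "M": frozenset("AC"),
    "B": frozenset("CGU"), "D": frozenset("AGU"), "H": frozenset("ACU"),
    "V": frozenset("ACG"), "N": frozenset("ACGU"),
}
SET_TO_IUPAC = {v: k for k, v in IUPAC_SETS.items()}

# All 15 non-empty base sets, used when enumerating generalizations.
_ALL_SETS = list(IUPAC_SETS.values())


@dataclass(frozen=True)
class IupacMotif:
    """A degenerate motif with an optional scissile-bond annotation.

    ``cut_offset`` is the number of motif positions 5' of the bond, so
    ``ACCU`` with ``cut_offset=3`` renders as ``ACC^U``.
    """

    letters: str
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        for ch in self.letters:
            if ch not in IUPAC_SETS:
                raise ValueError(f"not an IUPAC RNA code: {ch!r}")
        if self.cut_offset is not None and not 0 <= self.cut_offset <= len(self.letters):
            raise ValueError(f"cut_offset {self.cut_offset} outside [0, {len(self.letters)}]")

    @property
    def width(self) -> int:
        return len(self.letters)

    @classmethod
    def from_string(cls, text: str) -> "IupacMotif":
        """Parse ``ACC^U`` notation; the caret marks the scissile bond."""
        if "^" in text:
            off = text.index("^")
            return cls(letters=text.replace("^", ""), cut_offset=off)
        return cls(letters=text)

    def __str__(self) -> str:
        if self.cut_offset is None:
            return self.letters
        return self.letters[: self.cut_offset] + "^" + self.letters[self.cut_offset :]

    def reverse_complement(self) -> "IupacMotif":
        rc = reverse_complement(self.letters, allow_iupac=True)
        off = None if self.cut_offset is None else self.width - self.cut_offset
        return IupacMotif(letters=rc, cut_offset=off)

    def mask(self) -> np.ndarray:
        """(width, 4) boolean match table over the A/C/G/U base indices."""
        m = np.zeros((self.width, 4), dtype=bool)
        for p, ch in enumerate(self.letters):
            for b in IUPAC_SETS[ch]:
                m[p, _BASE_IDX[b]] = True
        return m

    def n_degenerate(self) -> int:
        """Total degeneracy beyond a concrete word (0 for an exact word)."""
        return sum(len(IUPAC_SETS[ch]) - 1 for ch in self.letters)


def _mask_to_letters(sets: list[frozenset[str]]) -> str:
    return "".join(SET_TO_IUPAC[s] for s in sets)


def _rc_mask(mask: np.ndarray) -> np.ndarray:
    # complement of base index i is 3 - i under the A,C,G,U ordering
    return mask[::-1, ::-1]


class WindowSet:
    """A weighted multiset of sequence windows, matrix-encoded for scanning.

    Windows of differing lengths (edge-truncated sites) are grouped by
    length so motif matching stays vectorized.
    """

    def __init__(self, windows: list[tuple[str, int]]):
        self.sequences = [w for w, _ in windows]
        self.weights = np.array([c for _, c in windows], dtype=np.int64)
        if np.any(self.weights < 0):
            raise ValueError("window weights must be non-negative")
        self._groups: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        by_len: dict[int, tuple[list[list[int]], list[int]]] = {}
        for idx, seq in enumerate(self.sequences):
            enc = [_BASE_IDX[ch] for ch in seq]
            by_len.setdefault(len(seq), ([], []))[0].append(enc)
            by_len[len(seq)][1].append(idx)
        for length, (rows, idxs) in by_len.items():
            self._groups[length] = (
                np.array(rows, dtype=np.int8),
                np.array(idxs, dtype=np.int64),
            )

    @classmethod
    def from_site_windows(cls, windows: list[SiteWindow]) -> "WindowSet":
        return cls([(w.sequence, w.weight) for w in windows])

    @classmethod
    def from_counter(cls, counter: Counter[str]) -> "WindowSet":
        return cls(sorted(counter.items()))

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def total_weight(self) -> int:
        return int(self.weights.sum())

    def match_any(self, masks: list[np.ndarray]) -> np.ndarray:
        """Boolean per-window: does any mask match at any offset?"""
        hit = np.zeros(len(self.sequences), dtype=bool)
        for length, (mat, idxs) in self._groups.items():
            group_hit = np.zeros(mat.shape[0], dtype=bool)
            for mask in masks:
                w = mask.shape[0]
                if w > length:
                    continue
                for off in range(length - w + 1):
                    sub = mat[:, off : off + w]  # (n, w)
                    ok = mask[np.arange(w), sub].all(axis=1)
                    group_hit |= ok
                if group_hit.all():
                    break
            hit[idxs] = group_hit
        return hit

    def hit_weight(self, masks: list[np.ndarray]) -> int:
        return int(self.weights[self.match_any(masks)].sum())

    def distinct_words(self, width: int) -> Counter[str]:
        """Distinct exact sub-words of the given width, with total weights."""
        words: Counter[str] = Counter()
        for seq, wt in zip(self.sequences, self.weights):
            seen = set()
            for off in range(len(seq) - width + 1):
                seen.add(seq[off : off + width])
            for word in seen:
                words[word] += int(wt)
        return words


def hypergeom_log_tail(k: int, K: int, n: int, N: int) -> float:
    """Natural log of the one-sided upper hypergeometric tail P(X >= k).

    Drawing ``K`` windows without replacement from a population of ``N``
    containing ``n`` motif matches, the probability of observing ``k`` or
    more matches.  This is the Fisher-exact enrichment core of the
    discriminative search; enrichment p-values at sequencing depth underflow
    the probability scale, so the log value is what ranking uses.
    """
    if not (0 <= k <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 0.0
    upper = min(K, n)
    xs = np.arange(k, upper + 1)
    logs = hypergeom.logpmf(xs, N, n, K)
    return float(min(0.0, logsumexp(logs)))


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """One-sided upper hypergeometric tail P(X >= k) (probability scale)."""
    return math.exp(hypergeom_log_tail(k, K, n, N))


def build_background(
    segments: list[DsSegment] | dict[str, DsSegment], width: int = 14
) -> WindowSet:
    """All sliding windows (step 1) of every segment: the background set.

    A genome of segment lengths L_s yields sum(L_s - width + 1) windows.
    """
    if isinstance(segments, dict):
        segments = list(segments.values())
    counter: Counter[str] = Counter()
    for seg in segments:
        seq = seg.top_sequence
        for off in range(len(seq) - width + 1):
            counter[seq[off : off + width]] += 1
    if not counter:
        raise ValueError("no segment long enough for the background window width")
    return WindowSet.from_counter(counter)


@dataclass
class EnrichmentResult:
    """Weighted enrichment of a motif in positives vs background windows.

    ``log_p`` is the natural-log hypergeometric tail (always finite);
    ``p_value`` is its probability-scale counterpart and may underflow to
    0.0 for strong enrichments.
    """

    motif: IupacMotif
    seed: str
    positive_hits: int
    positive_total: int
    background_hits: int
    background_total: int
    log_p: float
    e_value: float | None = None
    #: heaviest exact word among the positives matching the motif (either
    #: orientation when RC search is on) — the motif's concrete core
    core: str | None = None

    @property
    def p_value(self) -> float:
        return math.exp(self.log_p)

    @property
    def fold_enrichment(self) -> float:
        pos_rate = self.positive_hits / self.positive_total
        bg_rate = self.background_hits / self.background_total
        if bg_rate == 0:
            return math.inf if pos_rate > 0 else 1.0
        return pos_rate / bg_rate


def _as_window_set(obj) -> WindowSet:
    if isinstance(obj, WindowSet):
        return obj
    if obj and isinstance(obj[0], SiteWindow):
        return WindowSet.from_site_windows(obj)
    return WindowSet(list(obj))


def _motif_masks(sets: list[frozenset[str]], search_rc: bool) -> list[np.ndarray]:
    mask = np.zeros((len(sets), 4), dtype=bool)
    for p, s in enumerate(sets):
        for b in s:
            mask[p, _BASE_IDX[b]] = True
    masks = [mask]
    if search_rc:
        masks.append(_rc_mask(mask))
    return masks


def discover_motif(
    positives,
    background,
    width: int,
    search_rc: bool = True,
    n_generalize: int = 20,
    max_results: int = 50,
) -> list[EnrichmentResult]:
    """Rank discriminative IUPAC motifs of one width.

    Seeds are all exact ``width``-mers occurring in the positive windows
    (counted in forward and reverse-complement orientation when
    ``search_rc``; a seed and its reverse complement are the same motif and
    are de-duplicated to the lexicographically smaller representative).  The
    ``n_generalize`` best seeds are greedily generalized one position at a
    time to IUPAC codes, a step being accepted only if the hypergeometric
    p-value strictly improves.  Results are ranked by p-value, ties broken
    by fewer degenerate letters then lexicographically.
    """
    if not 4 <= width <= 14:
        raise ValueError(f"motif width must be in [4, 14], got {width}")
    pos = _as_window_set(positives)
    bg = _as_window_set(background)
    if len(pos) == 0:
        raise ValueError("positive window set is empty")

    K = pos.total_weight
    N = K + bg.total_weight

    seeds = pos.distinct_words(width)
    if not seeds:
        return []
    canon: dict[str, int] = {}
    for word, wt in seeds.items():
        rep = min(word, reverse_complement(word)) if search_rc else word
        canon[rep] = canon.get(rep, 0) + wt

    def evaluate(sets: list[frozenset[str]]) -> tuple[int, int, float]:
        masks = _motif_masks(sets, search_rc)
        k = pos.hit_weight(masks)
        bh = bg.hit_weight(masks)
        logp = hypergeom_log_tail(k, K, k + bh, N)
        return k, bh, logp

    scored: list[tuple[float, str, int, int]] = []
    for word in canon:
        sets = [IUPAC_SETS[ch] for ch in word]
        k, bh, p = evaluate(sets)
        scored.append((p, word, k, bh))
    scored.sort(key=lambda t: (t[0], t[1]))

    n_seeds_tested = len(scored)
    results: dict[str, EnrichmentResult] = {}
    for rank, (p0, word, k0, bh0) in enumerate(scored):
        if rank < n_generalize:
            sets = [IUPAC_SETS[ch] for ch in word]
            best = (p0, k0, bh0)
            improved = True
            while improved:
                improved = False
                candidate = None
                for ppos in range(width):
                    current = sets[ppos]
                    # a position generalized all the way to N carries no
                    # information; capping at 3 bases keeps every motif
                    # position informative, which is what lets the width
                    # search detect when a width exceeds the signal
                    if len(current) >= 3:
                        continue
                    for extra in "ACGU":
                        if extra in current:
                            continue
                        trial = sets[:ppos] + [current | {extra}] + sets[ppos + 1 :]
                        k, bh, p = evaluate(trial)
                        if p < best[0]:
                            best = (p, k, bh)
                            candidate = trial
                if candidate is not None:
                    sets = candidate
                    improved = True
            letters = _mask_to_letters(sets)
            p, k, bh = best
        else:
            letters, p, k, bh = word, p0, k0, bh0
        if letters not in results or p < results[letters].log_p:
            results[letters] = EnrichmentResult(
                motif=IupacMotif(letters=letters),
                seed=word,
                positive_hits=k,
                positive_total=K,
                background_hits=bh,
                background_total=bg.total_weight,
                log_p=p,
                e_value=math.exp(p) * n_seeds_tested,
            )
    ranked = sorted(
        results.values(),
        key=lambda r: (r.log_p, r.motif.n_degenerate(), r.motif.letters),
    )[:max_results]

    # annotate each motif with its concrete core: the heaviest exact word
    # among the positives that the motif matches
    word_weights = pos.distinct_words(width)
    if word_weights:
        word_list = sorted(word_weights)
        word_ws = WindowSet([(w, word_weights[w]) for w in word_list])
        for r in ranked:
            masks = _motif_masks([IUPAC_SETS[ch] for ch in r.motif.letters], search_rc)
            matched = word_ws.match_any(masks)
            best_i = None
            for i in np.flatnonzero(matched):
                # first max in lexicographic word order wins ties
                if best_i is None or word_ws.weights[i] > word_ws.weights[best_i]:
                    best_i = i
            if best_i is not None:
                r.core = word_list[int(best_i)]
    return ranked


@dataclass
class WidthTraceEntry:
    width: int
    motif: str
    seed: str
    core: str | None
    log_p: float
    presence: float
    diversity: int

    @property
    def p_value(self) -> float:
        return math.exp(self.log_p)


@dataclass
class WidthSelectionTrace:
    """Record of the incremental width search, one entry per width tried."""

    entries: list[WidthTraceEntry] = field(default_factory=list)
    chosen_width: int | None = None

    def entry(self, width: int) -> WidthTraceEntry:
        for e in self.entries:
            if e.width == width:
                return e
        raise KeyError(width)

    def to_dict(self) -> dict:
        return {
            "chosen_width": self.chosen_width,
            "trace": [vars(e) for e in self.entries],
        }


def _diversity(pos: WindowSet, motif: IupacMotif, search_rc: bool) -> int:
    """Number of distinct exact words in the positives matching the motif."""
    masks = _motif_masks([IUPAC_SETS[ch] for ch in motif.letters], search_rc)
    words = pos.distinct_words(motif.width)
    if not words:
        return 0
    single = WindowSet([(w, 1) for w in sorted(words)])
    return int(single.match_any(masks).sum())


def select_width(
    positives,
    background,
    w_min: int = 4,
    w_max: int = 14,
    presence_ratio: float = 0.5,
    diversity_ratio: float = 0.5,
    search_rc: bool = True,
    n_generalize: int = 20,
) -> tuple[int, WidthSelectionTrace]:
    """Incremental motif-width search with a drop-off stopping rule.

    Discovery is run at each width from ``w_min`` upward; per width the best
    motif's *presence* (weighted fraction of positives matched) and
    *diversity* (distinct exact words matching it) are recorded.  The chosen
    width is the largest consecutive width whose presence stays >=
    ``presence_ratio`` x presence(w_min) and whose diversity stays >=
    ``diversity_ratio`` x diversity(previous width) — an operational form of
    "no dramatic drop in motif presence and sub-motif diversity".  The full
    trace is returned for inspection.
    """
    pos = _as_window_set(positives)
    bg = _as_window_set(background)
    if len(pos) == 0:
        raise ValueError("positive window set is empty")

    trace = WidthSelectionTrace()
    base_presence = None
    prev_diversity = None
    chosen = None
    for w in range(w_min, w_max + 1):
        if not any(len(s) >= w for s in pos.sequences):
            break
        ranked = discover_motif(
            pos, bg, width=w, search_rc=search_rc, n_generalize=n_generalize
        )
        if not ranked:
            break
        best = ranked[0]
        presence = best.positive_hits / best.positive_total
        diversity = _diversity(pos, best.motif, search_rc)
        trace.entries.append(
            WidthTraceEntry(
                width=w,
                motif=best.motif.letters,
                seed=best.seed,
                core=best.core,
                log_p=best.log_p,
                presence=presence,
                diversity=diversity,
            )
        )
        if base_presence is None:
            base_presence = presence
            chosen = w
        else:
            ok_presence = presence >= presence_ratio * base_presence
            ok_diversity = diversity >= diversity_ratio * prev_diversity
            if not (ok_presence and ok_diversity):
                break
            chosen = w
        prev_diversity = diversity
    if chosen is None:
        raise ValueError("no width could be evaluated on the positive set")
    trace.chosen_width = chosen
    return chosen, trace


def top_unique_reads(
    reads: Counter[str] | dict[str, int] | list[str], n: int = 200
) -> list[tuple[str, int]]:
    """The ``n`` most frequent unique read sequences, with their counts.

    Ties are broken lexicographically; fewer than ``n`` unique inputs are
    all returned.
    """
    counter = Counter(reads) if not isinstance(reads, (Counter, dict)) else Counter(dict(reads))
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


@dataclass
class Pwm:
    """Position weight matrix over A/C/G/U with a cut-offset annotation."""

    probs: np.ndarray  # (width, 4), rows sum to 1
    pseudocount: float = 0.25
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits, in [0, 2]."""
        p = np.clip(self.probs, 1e-12, 1.0)
        return 2.0 + (p * np.log2(p)).sum(axis=1)

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        return np.log2(np.clip(self.probs, 1e-12, 1.0) / background)

    def consensus(self, majority: float = 0.5, pair: float = 0.8) -> str:
        return consensus_string(self.probs, majority=majority, pair=pair)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_IDX[ch] for ch in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence {seq!r}") from None


def em_pwm(
    sequences: list[str],
    width: int = 8,
    weights: list[int] | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
    n_restarts: int = 5,
    pseudocount: float = 0.25,
) -> tuple[Pwm, list[float]]:
    """One-occurrence-per-sequence EM estimation of a PWM.

    Each sequence is assumed to contain exactly one motif occurrence at an
    unknown start; non-motif positions follow a uniform 0.25 background.
    E-step: posterior over start positions under the current PWM; M-step:
    pseudocounted re-estimation (MAP under a Dirichlet(pseudocount) prior).
    The reported objective — data log-likelihood plus the log prior, i.e.
    the log posterior up to a constant — is non-decreasing each iteration;
    iteration stops when the gain falls below ``tol``.  The first start is
    deterministic (initialized from the most frequent exact word); the
    remaining ``n_restarts - 1`` use seeded random initializations and the
    best final objective is kept.

    Returns the fitted PWM and the per-iteration objective trace of the
    winning restart.
    """
    if not sequences:
        raise ValueError("no sequences given")
    for s in sequences:
        if len(s) < width:
            raise ValueError(f"sequence shorter than motif width {width}: {s!r}")
    wts = np.ones(len(sequences)) if weights is None else np.asarray(weights, dtype=float)
    encoded = [_encode(s) for s in sequences]

    # deterministic init: most frequent exact word of the target width
    word_counts: Counter[str] = Counter()
    for s, wt in zip(sequences, wts):
        for off in range(len(s) - width + 1):
            word_counts[s[off : off + width]] += wt
    top_word = min(
        (w for w, c in word_counts.items() if c == max(word_counts.values())),
    )

    rng = np.random.default_rng(seed)

    def run(init: np.ndarray) -> tuple[np.ndarray, list[float]]:
        pwm = init.copy()
        trace: list[float] = []
        prev = -math.inf
        for _ in range(max_iter):
            logp = np.log(np.clip(pwm, 1e-300, 1.0))
            counts = np.full((width, 4), pseudocount)
            # Dirichlet(pseudocount) log-prior term: makes the traced
            # objective the monotone MAP functional
            ll = float(pseudocount * logp.sum())
            for enc, wt in zip(encoded, wts):
                L = len(enc)
                n_off = L - width + 1
                scores = np.empty(n_off)
                for off in range(n_off):
                    sub = enc[off : off + width]
                    # motif positions under the PWM, the rest under uniform bg
                    scores[off] = logp[np.arange(width), sub].sum() + (
                        (L - width) * math.log(0.25)
                    )
                m = scores.max()
                probs = np.exp(scores - m)
                z = probs.sum()
                ll += wt * (m + math.log(z) - math.log(n_off))
                gamma = probs / z
                for off in range(n_off):
                    sub = enc[off : off + width]
                    counts[np.arange(width), sub] += wt * gamma[off]
            trace.append(ll)
            pwm = counts / counts.sum(axis=1, keepdims=True)
            if ll - prev < tol and len(trace) > 1:
                break
            prev = ll
        return pwm, trace

    inits = []
    seeded = np.full((width, 4), 0.1)
    for p, ch in enumerate(top_word):
        seeded[p, _BASE_IDX[ch]] = 0.7
    inits.append(seeded)
    for _ in range(max(0, n_restarts - 1)):
        inits.append(rng.dirichlet(np.ones(4), size=width))

    best_pwm, best_trace = None, None
    for init in inits:
        pwm, trace = run(init)
        if best_trace is None or trace[-1] > best_trace[-1]:
            best_pwm, best_trace = pwm, trace
    return Pwm(probs=best_pwm, pseudocount=pseudocount), best_trace


def consensus_string(
    matrix, majority: float = 0.5, pair: float = 0.8
) -> str:
    """Render per-column base frequencies as an IUPAC consensus.

    Per column: a single letter if the top base reaches ``majority`` and at
    least twice the runner-up; the two-base IUPAC code if the top two bases
    jointly reach ``pair``; otherwise N.
    """
    if isinstance(matrix, Pwm):
        matrix = matrix.probs
    matrix = np.asarray(matrix, dtype=float)
    sums = matrix.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("consensus column with zero total")
    freqs = matrix / sums
    out = []
    for row in freqs:
        order = np.argsort(-row, kind="stable")
        top, second = row[order[0]], row[order[1]]
        if top >= majority and top >= 2 * second:
            out.append(_BASES[order[0]])
        elif top + second >= pair:
            pair_set = frozenset({_BASES[order[0]], _BASES[order[1]]})
            out.append(SET_TO_IUPAC[pair_set])
        else:
            out.append("N")
    return "".join(out)
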