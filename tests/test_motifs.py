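"""Discriminative motif discovery: enrichment, width selection, EM."""

import math
from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from minicleave import (
    DsSegment,
    IupacMotif,
    WindowSet,
    build_background,
    consensus_string,
    discover_motif,
    em_pwm,
    hypergeom_tail,
    select_width,
    top_unique_reads,
)
from minicleave.motifs import hypergeom_log_tail


def exact_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Independent oracle: exhaustive hypergeometric tail as a rational."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(n, x) * math.comb(N - n, K - x), math.comb(N, K))
    return total


class TestHypergeomTail:
    def test_small_worked_example(self):
        # (C(4,2)C(6,1) + C(4,3)C(6,0)) / C(10,3) = 40/120
        assert hypergeom_tail(2, 3, 4, 10) == pytest.approx(1 / 3, rel=1e-12)

    def test_zero_hits_is_certain(self):
        assert hypergeom_tail(0, 5, 3, 10) == 1.0

    def test_matches_exhaustive_enumeration_for_all_small_populations(self):
        for N in range(1, 13):
            for n in range(N + 1):
                for K in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = exact_tail(k, K, n, N)
                        got = hypergeom_tail(k, K, n, N)
                        assert got == pytest.approx(float(expected), rel=1e-9, abs=1e-12), (
                            k, K, n, N,
                        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(5, 3, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_tail(2, 3, 12, 10)

    def test_log_tail_finite_at_depth(self):
        # probability-scale p underflows here; the log tail must stay finite
        lp = hypergeom_log_tail(2000, 3000, 2300, 16000)
        assert np.isfinite(lp) and lp < -500


class TestBackground:
    def test_sliding_window_count(self):
        seg = DsSegment("s", "ACGU" * 5)  # 20 nt -> L - 13 = 7 windows
        assert build_background([seg]).total_weight == 7

    def test_counts_sum_over_segments(self):
        segs = [DsSegment("a", "ACGU" * 10), DsSegment("b", "GGCC" * 10)]
        ws = build_background(segs)
        assert ws.total_weight == (40 - 13) * 2

    def test_invariant_under_segment_order(self):
        segs = [DsSegment("a", "ACGU" * 10), DsSegment("b", "AGCUUGCA" * 5)]
        a = build_background(segs)
        b = build_background(segs[::-1])
        assert Counter(dict(zip(a.sequences, a.weights))) == Counter(
            dict(zip(b.sequences, b.weights))
        )


class TestDiscover:
    def test_positives_equal_to_background_are_unenriched(self, random_segment):
        bg = build_background([random_segment])
        positives = WindowSet(list(zip(bg.sequences, (int(w) for w in bg.weights))))
        ranked = discover_motif(positives, bg, width=4, n_generalize=5)
        assert all(r.log_p > math.log(0.05) for r in ranked)

    def test_single_window_recovers_itself(self, random_segment):
        bg = build_background([random_segment])
        word = "ACGUACGUACGUAC"[:14]
        positives = WindowSet([(word, 1)])
        ranked = discover_motif(positives, bg, width=14, search_rc=False, n_generalize=0)
        top = ranked[0]
        assert top.seed == word
        assert top.log_p == pytest.approx(
            hypergeom_log_tail(1, 1, 1 + top.background_hits, 1 + bg.total_weight)
        )

    def test_planted_word_dominates(self, rng):
        """A word planted into half the positives beats every other seed."""
        flanks = ["".join("ACGU"[i] for i in rng.integers(0, 4, 14)) for _ in range(60)]
        positives = []
        for j, f in enumerate(flanks):
            if j % 2 == 0:
                f = f[:5] + "ACCU" + f[9:]
            positives.append((f, 10))
        genome = DsSegment("g", "".join("ACGU"[i] for i in rng.integers(0, 4, 2000)))
        ranked = discover_motif(WindowSet(positives), build_background([genome]), width=4)
        assert ranked[0].core in ("ACCU", "AGGU")

    def test_doubling_weights_doubles_hits_and_keeps_ranking(self, rng):
        flanks = ["".join("ACGU"[i] for i in rng.integers(0, 4, 14)) for _ in range(40)]
        positives = [(f[:5] + "ACCU" + f[9:] if j % 3 else f, 7) for j, f in enumerate(flanks)]
        doubled = [(s, 2 * w) for s, w in positives]
        genome = DsSegment("g", "".join("ACGU"[i] for i in rng.integers(0, 4, 1500)))
        bg = build_background([genome])
        a = discover_motif(WindowSet(positives), bg, width=4, n_generalize=3)
        b = discover_motif(WindowSet(doubled), bg, width=4, n_generalize=3)
        assert [r.motif.letters for r in a[:3]] == [r.motif.letters for r in b[:3]]
        lookup = {r.motif.letters: r for r in b}
        for r in a[:3]:
            assert lookup[r.motif.letters].positive_hits == 2 * r.positive_hits

    def test_reverse_complement_symmetry(self, rng):
        """Discovery on the flipped duplex finds the same enrichment."""
        from minicleave import reverse_complement

        flanks = ["".join("ACGU"[i] for i in rng.integers(0, 4, 14)) for _ in range(40)]
        positives = [(f[:5] + "ACCU" + f[9:] if j % 2 else f, 5) for j, f in enumerate(flanks)]
        genome = DsSegment("g", "".join("ACGU"[i] for i in rng.integers(0, 4, 1500)))
        a = discover_motif(WindowSet(positives), build_background([genome]), width=4)

        flipped = [(reverse_complement(s), w) for s, w in positives]
        genome_rc = genome.reverse_complemented()
        b = discover_motif(WindowSet(flipped), build_background([genome_rc]), width=4)
        assert a[0].log_p == pytest.approx(b[0].log_p)
        assert b[0].core in (a[0].core, reverse_complement(a[0].core))

    def test_width_out_of_range_rejected(self, random_segment):
        bg = build_background([random_segment])
        with pytest.raises(ValueError):
            discover_motif(WindowSet([("ACGUACGUACGUAC", 1)]), bg, width=3)


class TestWidthSelection:
    def test_identical_positives_never_drop(self, random_segment):
        word = "GACCUCGAUGCAUG"
        positives = WindowSet([(word, 50)])
        bg = build_background([random_segment])
        width, trace = select_width(positives, bg, n_generalize=0)
        assert width == 14
        assert all(e.presence == 1.0 and e.diversity == 1 for e in trace.entries)

    def test_thresholds_disabled_selects_max_width(self, rng, random_segment):
        wins = ["".join("ACGU"[i] for i in rng.integers(0, 4, 14)) for _ in range(20)]
        positives = WindowSet([(w, 3) for w in wins])
        bg = build_background([random_segment])
        width, _ = select_width(
            positives, bg, presence_ratio=0.0, diversity_ratio=0.0, n_generalize=0
        )
        assert width == 14

    def test_few_informative_positions_select_short_width(self, rng):
        """Only 4 planted positions are informative; the drop rule should
        stop the search at a short motif."""
        wins = []
        for j in range(60):
            f = "".join("ACGU"[i] for i in rng.integers(0, 4, 14))
            if j % 10 < 7:  # ~70% of instances carry the exact core
                f = f[:5] + "ACCU" + f[9:]
            wins.append((f, 5))
        genome = DsSegment("g", "".join("ACGU"[i] for i in rng.integers(0, 4, 3000)))
        width, trace = select_width(
            WindowSet(wins), build_background([genome]), n_generalize=4
        )
        assert width <= 6
        assert trace.chosen_width == width


class TestTopUniqueReads:
    def test_top_n_of_many(self):
        # 500 distinct 8-mers (base-4 encodings) with distinct counts
        reads = {
            "".join("ACGU"[(i >> (2 * p)) & 3] for p in range(8)): i + 1
            for i in range(500)
        }
        top = top_unique_reads(reads, n=200)
        assert len(top) == 200
        counts = [c for _, c in top]
        assert counts == sorted(counts, reverse=True)

    def test_fewer_than_n(self):
        assert len(top_unique_reads({"ACGUACGU": 3, "GGGGCCCC": 1}, n=200)) == 2

    def test_ties_break_lexicographically(self):
        top = top_unique_reads({"UUUUUUUU": 5, "AAAAAAAA": 5, "CCCCCCCC": 5}, n=2)
        assert [s for s, _ in top] == ["AAAAAAAA", "CCCCCCCC"]


class TestEmPwm:
    def test_identical_sequences_give_indicator_pwm(self):
        pwm, _ = em_pwm(["GACCUCGA"] * 20, width=8, seed=0)
        consensus = pwm.consensus()
        assert consensus == "GACCUCGA"
        assert pwm.probs.max(axis=1).min() > 0.9

    def test_loglikelihood_monotone_on_random_input(self, rng):
        seqs = ["".join("ACGU"[i] for i in rng.integers(0, 4, 12)) for _ in range(30)]
        _, trace = em_pwm(seqs, width=8, seed=1, n_restarts=2)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_short_sequence_named_in_error(self):
        with pytest.raises(ValueError, match="ACGU"):
            em_pwm(["GACCUCGA", "ACGU"], width=8)

    def test_information_content_bounds(self, rng):
        seqs = ["".join("ACGU"[i] for i in rng.integers(0, 4, 8)) for _ in range(30)]
        pwm, _ = em_pwm(seqs, width=8, seed=2, n_restarts=2)
        ic = pwm.information_content()
        assert np.all(ic >= -1e-9) and np.all(ic <= 2 + 1e-9)


class TestConsensusString:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ((1, 0, 0, 0), "A"),
            ((0.45, 0.45, 0.05, 0.05), "M"),  # A+C
            ((0.25, 0.25, 0.25, 0.25), "N"),
            ((0.0, 0.1, 0.1, 0.8), "U"),
            ((0.1, 0.1, 0.4, 0.4), "K"),  # G+U
        ],
    )
    def test_column_rules(self, column, expected):
        assert consensus_string(np.array([column])) == expected

    def test_motif_caret_rendering(self):
        m = IupacMotif.from_string("ACC^U")
        assert m.letters == "ACCU" and m.cut_offset == 3
        assert str(m) == "ACC^U"
        assert str(m.reverse_complement()) == "A^GGU"
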