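"""Synthetic-data generator: genome planting, digestion, end capture."""

from collections import Counter

import numpy as np
import pytest

from minicleave import (
    PreferenceModel,
    SimConfig,
    call_sites,
    derive_consensus,
    simulate_end_capture,
    simulate_experiment,
    simulate_limited_digest,
    simulate_satmut_rates,
    simulate_timecourse,
    terminus_fraction,
)
from minicleave.simulate import (
    FragmentPopulation,
    intact_fragments,
    make_genome,
    score_all_bonds,
)
from minicleave.specificity import ConsensusSpec
from tests.conftest import make_single_site_segment


def small_config(**kw):
    defaults = dict(
        segment_lengths=(400,), seed=0, read_depth=2000,
        background_break_fraction=0.0, n_planted_per_segment=3,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestMakeGenome:
    def test_planting_contract(self):
        cfg = SimConfig(
            segment_lengths=(100,), seed=3, planted_positions={"seg1": [50]},
            background_break_fraction=0.0,
        )
        segments, gt = make_genome(cfg)
        assert segments[0].length == 100
        assert any(s.i_top == 50 and s.planted for s in gt)

    def test_planting_near_end_rejected(self):
        cfg = SimConfig(segment_lengths=(100,), planted_positions={"seg1": [3]})
        with pytest.raises(ValueError, match="segment end"):
            make_genome(cfg)

    def test_determinism(self):
        cfg = small_config(seed=11)
        a, gta = make_genome(cfg)
        b, gtb = make_genome(SimConfig(**{**cfg.to_dict(), "planted_model": cfg.planted_model}))
        assert a[0].top_sequence == b[0].top_sequence
        assert gta == gtb

    def test_chance_core_occurrences_match_binomial_expectation(self):
        """Uniform sequence contains ACCU at ~(N-3)/256 positions."""
        N = 40_000
        counts = []
        for seed in range(5):
            cfg = SimConfig(
                segment_lengths=(N,), seed=seed, n_planted_per_segment=0,
            )
            (seg,), _ = make_genome(cfg)
            counts.append(
                sum(1 for i in range(N - 3) if seg.top_sequence[i : i + 4] == "ACCU")
            )
        expected = (N - 3) / 256
        sd_of_mean = np.sqrt(expected) / np.sqrt(5)
        assert abs(np.mean(counts) - expected) < 5 * sd_of_mean

    def test_chance_consensus_windows_reported_as_ground_truth(self):
        # with no planting, any reported site must come from scanning
        cfg = SimConfig(segment_lengths=(30_000,), seed=4, n_planted_per_segment=0)
        (seg,), gt = make_genome(cfg)
        assert len(gt) > 0
        assert all(not s.planted for s in gt)
        model = cfg.planted_model
        scores = score_all_bonds(seg, model)
        for s in gt:
            assert scores[s.i_top - 1] >= cfg.ground_truth_threshold


class TestLimitedDigest:
    def test_no_activity_leaves_segments_intact(self):
        cfg = small_config(k_specific=0.0, k_nonspecific=0.0, n_molecules=5)
        segments, _ = make_genome(cfg)
        frags = simulate_limited_digest(segments, cfg)
        pop = frags[segments[0].id]
        assert pop.top == Counter({(1, 400): 5})
        assert pop.bottom == Counter({(1, 400): 5})
        assert not pop.cuts

    def test_saturating_single_site_gives_two_products(self):
        seg = make_single_site_segment(100, 50)
        cfg = SimConfig(
            segment_lengths=(100,), segment_ids=(seg.id,), seed=0,
            k_specific=1e3, k_nonspecific=0.0, n_molecules=4,
        )
        pop = simulate_limited_digest([seg], cfg)[seg.id]
        assert pop.top == Counter({(1, 50): 4, (51, 100): 4})
        assert pop.bottom == Counter({(1, 48): 4, (49, 100): 4})
        assert pop.cuts == Counter({50: 4})

    def test_fragments_tile_each_molecule(self):
        cfg = small_config(n_molecules=1, k_specific=5.0, k_nonspecific=1e-4, seed=7)
        segments, _ = make_genome(cfg)
        pop = simulate_limited_digest(segments, cfg)[segments[0].id]
        for strand in (pop.top, pop.bottom):
            ivals = sorted(strand.elements())
            assert ivals[0][0] == 1 and ivals[-1][1] == 400
            for (a, b), (c, d) in zip(ivals, ivals[1:]):
                assert c == b + 1  # no gaps, no overlaps

    def test_strand_length_conservation(self):
        cfg = small_config(n_molecules=6, k_specific=5.0, seed=2)
        segments, _ = make_genome(cfg)
        pop = simulate_limited_digest(segments, cfg)[segments[0].id]
        for strand in (pop.top, pop.bottom):
            total = sum((e - s + 1) * c for (s, e), c in strand.items())
            assert total == 6 * 400

    def test_relative_cut_rates_follow_multiplier_ratio(self):
        """First-order kinetics: at small k*t the cut fraction ratio of a
        0.38-multiplier site to a preferred site approaches 0.38."""
        pref = make_single_site_segment(100, 50, seg_id="pref")
        # UCC^U: tolerated substitution at the core-adjacent position
        sub_seq = list(pref.top_sequence)
        sub_seq[47] = "U"
        from minicleave import DsSegment

        sub = DsSegment(id="sub", top_sequence="".join(sub_seq))
        model = PreferenceModel.default()
        assert score_all_bonds(sub, model)[49] == pytest.approx(0.38)
        n = 30_000
        cfg = SimConfig(
            segment_lengths=(100, 100), segment_ids=("pref", "sub"), seed=9,
            k_specific=0.001, k_nonspecific=0.0, digestion_time=10.0, n_molecules=n,
        )
        frags = simulate_limited_digest([pref, sub], cfg)
        ratio = frags["sub"].cuts[50] / frags["pref"].cuts[50]
        assert ratio == pytest.approx(0.38, abs=0.13)


class TestEndCapture:
    def test_single_cut_end_geometry(self):
        """A cut at bond 14 puts top ends at 14 and bottom ends at 13."""
        seg = make_single_site_segment(100, 14)
        pop = FragmentPopulation(
            segment_id=seg.id, length=100, n_molecules=1,
            top=Counter({(1, 14): 1, (15, 100): 1}),
            bottom=Counter({(1, 12): 1, (13, 100): 1}),
            cuts=Counter({14: 1}),
        )
        cfg = SimConfig(
            segment_lengths=(100,), segment_ids=(seg.id,), read_depth=4000,
            background_break_fraction=0.0, seed=1,
        )
        tracks, _ = simulate_end_capture({seg.id: pop}, [seg], cfg)
        top, bottom = tracks[(seg.id, "top")], tracks[(seg.id, "bottom")]
        assert set(top.counts) == {14, 100}
        assert set(bottom.counts) == {13, 1}

    def test_internal_ends_all_correspond_to_recorded_cuts(self):
        cfg = small_config(seed=5, k_specific=2.0, n_molecules=10)
        res = simulate_experiment(cfg)
        seg = res.segments[0]
        pop = res.fragments[seg.id]
        top = res.tracks[(seg.id, "top")]
        bottom = res.tracks[(seg.id, "bottom")]
        for p in top.counts:
            assert p == seg.length or p in pop.cuts
        for p in bottom.counts:
            assert p == 1 or (p + 1) in pop.cuts

    def test_control_mode_without_background_is_all_terminal(self):
        cfg = SimConfig(
            segment_lengths=(500, 400, 300), seed=0, control_mode=True,
            background_break_fraction=0.0, read_depth=6000,
        )
        res = simulate_experiment(cfg)
        assert terminus_fraction(list(res.tracks.values())) == 1.0

    def test_control_mode_background_fraction_matches_published_contrast(self):
        """7% uniform breakage leaves ~93% of control ends at the termini."""
        fractions = []
        for seed in range(3):
            cfg = SimConfig(seed=seed, control_mode=True, read_depth=100_000)
            res = simulate_experiment(cfg)
            fractions.append(terminus_fraction(list(res.tracks.values())))
        assert np.mean(fractions) == pytest.approx(0.93, abs=0.005)

    def test_empty_fragments_rejected(self):
        cfg = small_config()
        segments, _ = make_genome(cfg)
        empty = {segments[0].id: FragmentPopulation(segments[0].id, 400, 0)}
        with pytest.raises(ValueError, match="empty"):
            simulate_end_capture(empty, segments, cfg)

    def test_experiment_is_seed_deterministic(self):
        a = simulate_experiment(small_config(seed=42, k_specific=1.0))
        b = simulate_experiment(small_config(seed=42, k_specific=1.0))
        assert a.reads == b.reads
        assert all(
            a.tracks[k].counts == b.tracks[k].counts for k in a.tracks
        )

    def test_reads_are_bond_centred_context(self):
        """Each emitted read is the reference window around a sampled end's
        implied bond, so planted site reads carry the full ACC^U context."""
        seg = make_single_site_segment(100, 50)
        cfg = SimConfig(
            segment_lengths=(100,), segment_ids=(seg.id,), seed=0,
            k_specific=1e3, k_nonspecific=0.0, n_molecules=2,
            background_break_fraction=0.0, read_depth=600,
        )
        frags = simulate_limited_digest([seg], cfg)
        _, reads = simulate_end_capture(frags, [seg], cfg)
        expected = seg.top_sequence[46:54]  # bonds 50: residues 47..54
        assert set(reads) == {expected}
        assert "ACCU" in expected


class TestTimecourse:
    def test_exact_line_without_noise(self):
        (tc,) = simulate_timecourse({"s": 0.01}, [15, 30, 45], noise_sd=0.0)
        assert tc.fractions == [0.15, 0.30, 0.45]

    def test_zero_slope_is_flat(self):
        (tc,) = simulate_timecourse({"s": 0.0}, [15, 30, 45], noise_sd=0.0)
        assert tc.fractions == [0.0, 0.0, 0.0]

    def test_noise_is_clamped_to_unit_interval(self):
        courses = simulate_timecourse(
            {"s": 0.03}, [10, 20, 30, 40], noise_sd=0.5, rng=1
        )
        assert all(0.0 <= f <= 1.0 for f in courses[0].fractions)


class TestSatmutSimulation:
    def test_noise_free_round_trip(self):
        spec = ConsensusSpec(
            tolerated=[frozenset("GAU"), frozenset("AU"), frozenset("C"),
                       frozenset("C"), frozenset("UA"), frozenset("CAU"),
                       frozenset("GAU")] + [frozenset("ACGU")] * 7,
            preferred="GACCUCG" + "A" * 7,
            bond_offset=4,
        )
        records = simulate_satmut_rates(spec, noise_sd=0.0, rng=0)
        assert len(records) == 3 * 14
        got = derive_consensus(records, spec.preferred, bond_offset=4)
        assert got.tolerated == spec.tolerated
        assert got.preferred == spec.preferred

    def test_obligate_core_rates_are_zero(self):
        spec = ConsensusSpec(
            tolerated=[frozenset("ACGU")] * 5 + [frozenset("C"), frozenset("C")]
            + [frozenset("ACGU")] * 7,
            preferred="AAAAACCAAAAAAA",
            bond_offset=7,
        )
        records = simulate_satmut_rates(spec, noise_sd=0.0)
        core = [r for r in records if r.position in (6, 7)]
        assert len(core) == 6 and all(r.relative_rate == 0.0 for r in core)
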