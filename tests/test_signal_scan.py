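"""Unit and property tests for the prophage evidence-track stage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgrscan.signal_scan import (
    RegionCallConfig,
    call_candidate_regions,
    call_transposable_termini,
    contamination_filter,
    coverage_ratio,
    depth_breadth_tracks,
    enumerate_windows,
    nucleotide_content_track,
    orf_organization_track,
)
from dgrscan.types import (
    BACTERIAL_WINDOWS,
    DepthProfile,
    GenomeRecord,
    InputError,
    Interval,
    OrfRecord,
    PHAGE_WINDOWS,
    WindowSpec,
    WindowTrack,
)
from dgrscan import simulate as sim

from conftest import random_genome


class TestEnumerateWindows:
    @pytest.mark.parametrize(
        "length,spec,expected",
        [
            (4000, (3001, 500, 1500), [(1, 3001), (501, 4000)]),
            (101, (101, 20, 50), [(1, 101)]),
            (50, (101, 20, 50), [(1, 50)]),
        ],
    )
    def test_stated_examples(self, length, spec, expected):
        windows = enumerate_windows(length, WindowSpec(*spec))
        assert [(w.start, w.end) for w in windows] == expected

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InputError):
            enumerate_windows(0, PHAGE_WINDOWS)

    @settings(max_examples=200, deadline=None)
    @given(
        length=st.integers(1, 30_000),
        spec=st.sampled_from([BACTERIAL_WINDOWS, PHAGE_WINDOWS]),
    )
    def test_windows_tile_the_sequence(self, length, spec):
        """Union of windows covers [1, length]; consecutive starts differ
        by exactly the step (for the two standard conventions the tail is
        always absorbed by the terminal extension)."""
        windows = enumerate_windows(length, spec)
        assert windows[0].start == 1
        assert windows[-1].end == length
        for a, b in zip(windows, windows[1:]):
            assert b.start - a.start == spec.step
            assert b.start <= a.end + 1  # no uncovered gap


class TestNucleotideContent:
    def test_homogeneous_windows(self):
        track = nucleotide_content_track(GenomeRecord("g", "A" * 200), PHAGE_WINDOWS)
        assert np.allclose(track.values["frac_a"], 1.0)
        for col in ("frac_c", "frac_g", "frac_t"):
            assert np.allclose(track.values[col], 0.0)

    def test_half_a_half_t(self):
        g = GenomeRecord("g", "A" * 50 + "T" * 50)
        track = nucleotide_content_track(g, WindowSpec(100, 100, 0))
        assert track.values["frac_a"][0] == 0.5
        assert track.values["frac_t"][0] == 0.5
        assert track.values["frac_c"][0] == 0.0

    def test_all_n_window_missing(self):
        track = nucleotide_content_track(
            GenomeRecord("g", "N" * 101), PHAGE_WINDOWS
        )
        assert np.isnan(track.values["frac_a"][0])

    def test_invalid_character_named(self):
        with pytest.raises(InputError, match="position 3"):
            nucleotide_content_track(GenomeRecord("g", "ACXGT" * 30), PHAGE_WINDOWS)


class TestOrfOrganization:
    def test_two_orfs_in_one_window(self):
        orfs = [OrfRecord("c", 1, 300, "+"), OrfRecord("c", 401, 700, "+")]
        track = orf_organization_track(orfs, 700, WindowSpec(700, 700, 0), "c")
        assert track.values["orf_median_len"][0] == 300
        assert track.values["orf_median_gap"][0] == 100
        assert track.values["orf_strand_switches"][0] == 0

    def test_alternating_strands_count_switches(self):
        orfs = [
            OrfRecord("c", 1 + 200 * i, 150 + 200 * i, "+-+-"[i]) for i in range(4)
        ]
        track = orf_organization_track(orfs, 800, WindowSpec(800, 800, 0), "c")
        assert track.values["orf_strand_switches"][0] == 3

    def test_sparse_windows_missing(self):
        orfs = [OrfRecord("c", 10, 60, "+")]
        track = orf_organization_track(orfs, 200, WindowSpec(200, 200, 0), "c")
        assert np.isnan(track.values["orf_median_len"][0])
        assert track.values["coding_density"][0] == pytest.approx(51 / 200)

    def test_out_of_bounds_orf_rejected(self):
        with pytest.raises(InputError):
            orf_organization_track([OrfRecord("c", 10, 300, "+")], 200, PHAGE_WINDOWS)

    def test_prophage_windows_have_shorter_genes(self):
        """Prophage-region windows show smaller median ORF length than
        host-region windows in nearly all seeded simulations."""
        wins = 0
        runs = 15
        for seed in range(runs):
            genome, orfs, truth = sim.simulate_host_with_prophage(
                seed, host_len=60_000, prophage_len=20_000
            )
            track = orf_organization_track(
                orfs, genome.length, BACTERIAL_WINDOWS, genome.id
            )
            pro = truth.prophage
            inside, outside = [], []
            for i, w in enumerate(track.windows):
                v = track.values["orf_median_len"][i]
                if np.isnan(v):
                    continue
                if w.start >= pro.start and w.end <= pro.end:
                    inside.append(v)
                elif w.end < pro.start or w.start > pro.end:
                    outside.append(v)
            if np.median(inside) < np.median(outside):
                wins += 1
        assert wins >= runs - 1


class TestDepthBreadth:
    def test_constant_depth(self):
        profile = DepthProfile("c", "s", np.full(500, 7))
        track = depth_breadth_tracks(profile, 500, PHAGE_WINDOWS)
        assert np.allclose(track.values["depth_mean"], 7.0)
        assert np.allclose(track.values["breadth"], 1.0)

    def test_zero_depth(self):
        track = depth_breadth_tracks(DepthProfile("c", "s", np.zeros(300)), 300, PHAGE_WINDOWS)
        assert np.allclose(track.values["depth_mean"], 0.0)
        assert np.allclose(track.values["breadth"], 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            depth_breadth_tracks(DepthProfile("c", "s", np.zeros(100)), 200, PHAGE_WINDOWS)


class TestContaminationFilter:
    def _profiles(self, covered, total):
        depth = np.zeros(total, dtype=int)
        depth[:covered] = 3
        return {"s1": [DepthProfile("c1", "s1", depth)]}

    def test_breadth_above_quarter_excluded(self):
        (d,) = contamination_filter(self._profiles(3000, 10_000))
        assert d.excluded and d.breadth == pytest.approx(0.30)

    def test_exact_quarter_included(self):
        (d,) = contamination_filter(self._profiles(2500, 10_000))
        assert not d.excluded

    def test_zero_breadth_included(self):
        (d,) = contamination_filter(self._profiles(0, 10_000))
        assert not d.excluded

    def test_invariant_under_contig_reordering(self, rng):
        a = DepthProfile("c1", "s", rng.poisson(1, 4000))
        b = DepthProfile("c2", "s", rng.poisson(0.1, 6000))
        d1 = contamination_filter({"s": [a, b]})[0]
        d2 = contamination_filter({"s": [b, a]})[0]
        assert d1.breadth == d2.breadth and d1.excluded == d2.excluded


class TestCoverageRatio:
    def test_step_profile(self):
        depth = np.ones(1000)
        depth[99:200] = 200
        r = coverage_ratio(DepthProfile("c", "s", depth), Interval("c", 100, 200))
        assert r.ratio == pytest.approx(200.0)

    def test_uniform_depth_is_unity(self):
        r = coverage_ratio(
            DepthProfile("c", "s", np.full(1000, 13)), Interval("c", 100, 200)
        )
        assert r.ratio == pytest.approx(1.0)

    def test_zero_background_flagged_infinite(self):
        depth = np.zeros(1000)
        depth[99:200] = 50
        r = coverage_ratio(DepthProfile("c", "s", depth), Interval("c", 100, 200))
        assert r.infinite and np.isinf(r.ratio)

    def test_whole_contig_rejected(self):
        with pytest.raises(InputError):
            coverage_ratio(DepthProfile("c", "s", np.ones(100)), Interval("c", 1, 100))


def _sim_tracks(seed, host_len=60_000, prophage_len=20_000, ratio=50.0):
    genome, orfs, truth = sim.simulate_host_with_prophage(
        seed, host_len=host_len, prophage_len=prophage_len
    )
    depth, _ = sim.simulate_depth_profile(
        seed + 1, genome.length, truth.prophage, base_depth=5.0, ratio=ratio,
        contig_id=genome.id,
    )
    tracks = [
        nucleotide_content_track(genome, BACTERIAL_WINDOWS),
        orf_organization_track(orfs, genome.length, BACTERIAL_WINDOWS, genome.id),
        depth_breadth_tracks(depth, genome.length, BACTERIAL_WINDOWS),
    ]
    return tracks, truth.prophage


class TestCandidateRegions:
    def test_flat_signals_yield_no_regions(self):
        windows = enumerate_windows(60_000, BACTERIAL_WINDOWS, "c")
        n = len(windows)
        tracks = [
            WindowTrack("c", BACTERIAL_WINDOWS, windows, {"depth_mean": np.full(n, 5.0)}),
            WindowTrack("c", BACTERIAL_WINDOWS, windows, {"breadth": np.ones(n)}),
        ]
        assert call_candidate_regions(tracks) == []

    def test_planted_prophage_recovered(self):
        hits = 0
        runs = 10
        for seed in range(runs):
            tracks, pro = _sim_tracks(seed)
            regions = call_candidate_regions(tracks)
            if len(regions) == 1 and regions[0].interval.overlap_len(pro) >= 0.8 * pro.length:
                hits += 1
        assert hits >= runs - 1

    def test_two_informative_signals_at_lower_cutoff(self):
        genome, orfs, truth = sim.simulate_host_with_prophage(
            7, host_len=60_000, prophage_len=20_000, prophage_gc=0.56,
            prophage_gene_mean=900.0, prophage_gene_sd=300.0,
            prophage_gap_mean=120.0, prophage_switch_p=0.35,
        )
        depth, _ = sim.simulate_depth_profile(
            8, genome.length, truth.prophage, base_depth=5.0, ratio=50.0,
            contig_id=genome.id,
        )
        tracks = [
            nucleotide_content_track(genome, BACTERIAL_WINDOWS),
            orf_organization_track(orfs, genome.length, BACTERIAL_WINDOWS, genome.id),
            depth_breadth_tracks(depth, genome.length, BACTERIAL_WINDOWS),
        ]
        regions = call_candidate_regions(tracks, config=RegionCallConfig(z_cutoff=2.0))
        assert any(
            r.interval.overlap_len(truth.prophage) >= 0.8 * truth.prophage.length
            for r in regions
        )

    def test_mismatched_contigs_rejected(self):
        w1 = enumerate_windows(5000, BACTERIAL_WINDOWS, "c1")
        w2 = enumerate_windows(5000, BACTERIAL_WINDOWS, "c2")
        t1 = WindowTrack("c1", BACTERIAL_WINDOWS, w1, {"depth_mean": np.zeros(len(w1))})
        t2 = WindowTrack("c2", BACTERIAL_WINDOWS, w2, {"breadth": np.zeros(len(w2))})
        with pytest.raises(InputError):
            call_candidate_regions([t1, t2])

    def test_shuffled_tracks_rarely_call_regions(self):
        """Exchangeably shuffling every track destroys the spatial signal;
        the empirical false-positive rate stays at or below 5%."""
        tracks, _ = _sim_tracks(3)
        rng = np.random.default_rng(0)
        false_positives = 0
        n_shuffles = 100
        for _ in range(n_shuffles):
            shuffled = []
            for t in tracks:
                vals = {}
                for name, col in t.values.items():
                    perm = rng.permutation(len(col))
                    vals[name] = col[perm]
                shuffled.append(WindowTrack(t.contig_id, t.spec, t.windows, vals))
            if call_candidate_regions(shuffled):
                false_positives += 1
        assert false_positives <= 5


class TestTransposableTermini:
    def test_modal_positions_reported(self):
        call = call_transposable_termini([(100, 50), (101, 3), (5000, 40)])
        assert (call.left, call.right) == (100, 5000)
        assert (call.support_left, call.support_right) == (50, 40)
        assert call.explained_fraction == pytest.approx(90 / 93)

    def test_single_position_degenerate(self):
        call = call_transposable_termini([(250, 10)])
        assert call.left == 250 and call.right is None
        assert call.support_left == 10

    def test_tie_breaks_toward_smaller_coordinate(self):
        call = call_transposable_termini([(300, 5), (100, 5), (200, 5)])
        assert (call.left, call.right) == (100, 200)

    def test_permutation_invariance(self, rng):
        records = [(int(p), 1) for p in rng.integers(1, 1000, size=200)]
        base = call_transposable_termini(records)
        for _ in range(5):
            perm = [records[i] for i in rng.permutation(len(records))]
            assert call_transposable_termini(perm) == base

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            call_transposable_termini([])
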