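"""RD caller: GC correction, normalisation, segmentation, recovery."""

from __future__ import annotations

import numpy as np
import pytest

from yakcnv.rd_caller import (
    DEL,
    DUP,
    CallerParams,
    CNVCall,
    DepthProfile,
    RatioTrack,
    call_sample,
    gc_correct,
    normalize,
    segment_calls,
)
from yakcnv.synthetic import PlantedCNV, gc_factor, make_genome, simulate_depth


def profile(counts, gc=None, bin_size=500, sample="s1", chrom="chr1"):
    counts = np.asarray(counts, dtype=float)
    if gc is None:
        gc = np.full(len(counts), 0.45)
    return DepthProfile(sample_id=sample, chrom=chrom, bin_size=bin_size,
                        counts=counts, gc=np.asarray(gc, dtype=float))


def track(ratios, bin_size=500, sample="s1", chrom="chr1"):
    return RatioTrack(sample_id=sample, chrom=chrom, bin_size=bin_size,
                      ratios=np.asarray(ratios, dtype=float), diploid_mean=40.0)


class TestGcCorrect:
    def test_single_stratum_unchanged(self, flat_profile):
        out = gc_correct(flat_profile)
        np.testing.assert_allclose(out.counts, flat_profile.counts)

    def test_exact_inversion_of_planted_bias(self):
        """A noise-free multiplicative GC effect is removed exactly."""
        rng = np.random.default_rng(0)
        gc = rng.choice([0.35, 0.45, 0.55], size=600)
        base = 40.0
        biased = base * gc_factor(gc, strength=4.0)
        out = gc_correct(profile(biased, gc=gc))
        assert np.ptp(out.counts) == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_profile_returned_with_warning(self):
        p = profile(np.zeros(200))
        with pytest.warns(UserWarning, match="all-zero"):
            out = gc_correct(p)
        assert out.counts.sum() == 0

    def test_sparse_stratum_left_alone(self):
        gc = np.full(300, 0.45)
        gc[:3] = 0.30  # stratum below the 5-bin minimum
        counts = np.full(300, 40.0)
        counts[:3] = 10.0
        out = gc_correct(profile(counts, gc=gc))
        np.testing.assert_allclose(out.counts[:3], 10.0)


class TestNormalize:
    def test_constant_depth_gives_unit_ratio(self, flat_profile):
        t = normalize(flat_profile)
        np.testing.assert_allclose(t.ratios, 1.0)
        assert t.diploid_mean == 40.0

    def test_isolated_double_bin(self):
        counts = np.full(200, 30.0)
        counts[17] = 60.0
        t = normalize(profile(counts))
        assert t.ratios[17] == pytest.approx(2.0)

    def test_noisy_flat_profile_median_ratio_near_one(self):
        rng = np.random.default_rng(5)
        mu, disp = 37.5, 0.02
        n = 1.0 / disp
        counts = rng.negative_binomial(n, n / (n + mu), size=2000)
        t = normalize(profile(counts))
        assert 0.95 <= np.median(t.ratios) <= 1.05

    def test_degenerate_profile_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize(profile(np.zeros(100)))


class TestSegmentCalls:
    def test_flat_track_yields_no_calls(self):
        assert segment_calls(track(np.ones(100))) == []

    def test_hand_traced_deletion_run(self):
        """10 consecutive zero-ratio bins -> one 5 kb DEL at copy number 0."""
        r = np.ones(50)
        r[10:20] = 0.0
        calls = segment_calls(track(r))
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end, c.svtype, c.copy_number) == (5_000, 10_000, DEL, 0)

    def test_single_bin_event_removed_by_size_filter(self):
        """One 500 bp bin is not 'larger than 0.5 kb' and must be dropped."""
        r = np.ones(50)
        r[25] = 0.0
        assert segment_calls(track(r)) == []

    def test_gap_tolerance_bridges_single_bin(self):
        r = np.ones(60)
        r[10:14] = 0.0
        r[14] = 1.0  # interior non-qualifying bin
        r[15:20] = 0.0
        calls = segment_calls(track(r))
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (5_000, 10_000)

    def test_stitching_bridges_same_leaning_gap(self):
        """Two deletion runs split by a short dip-leaning gap become one call."""
        r = np.ones(60)
        r[10:15] = 0.4
        r[15:17] = 0.9  # non-qualifying but still below 1
        r[17:21] = 0.4
        calls = segment_calls(track(r))
        assert [(c.start, c.end) for c in calls] == [(5_000, 10_500)]

    def test_two_bin_gap_splits_runs(self):
        r = np.ones(60)
        r[10:14] = 0.0
        r[16:20] = 0.0
        calls = segment_calls(track(r))
        assert [(c.start, c.end) for c in calls] == [(5_000, 7_000), (8_000, 10_000)]

    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError, match="del_thresh"):
            segment_calls(track(np.ones(10)), CallerParams(del_thresh=1.5))

    def test_empty_track(self):
        assert segment_calls(track(np.array([]))) == []


@pytest.fixture(scope="module")
def genome():
    return make_genome(n_chrom=1, chrom_length=500_000, seed=21)


class TestCallSample:
    def test_flat_sample_has_no_calls(self, genome):
        profs = simulate_depth(genome, [], "s1", dispersion=0.02, seed=22)
        assert call_sample(profs) == []

    def test_recovers_planted_homozygous_deletion(self, genome):
        """10 kb CN=0 deletion at 7.5x: one DEL call, >= 90% reciprocal overlap."""
        cnv = PlantedCNV("s1", "chr1", 200_000, 210_000, 0)
        profs = simulate_depth(genome, [cnv], "s1", dispersion=0.02, seed=23)
        calls = call_sample(profs)
        dels = [c for c in calls if c.svtype == DEL]
        assert len(dels) == 1
        c = dels[0]
        inter = min(c.end, 210_000) - max(c.start, 200_000)
        assert inter / max(c.length, 10_000) >= 0.9
        assert c.copy_number == 0

    def test_recovers_planted_duplication(self, genome):
        cnv = PlantedCNV("s1", "chr1", 300_000, 320_000, 4)
        profs = simulate_depth(genome, [cnv], "s1", dispersion=0.02, seed=24)
        dups = [c for c in call_sample(profs) if c.svtype == DUP]
        assert len(dups) == 1
        assert abs(dups[0].copy_number - 4) <= 1

    def test_scale_invariance(self, genome):
        """Multiplying all counts by a constant leaves the calls unchanged."""
        cnv = PlantedCNV("s1", "chr1", 100_000, 115_000, 0)
        profs = simulate_depth(genome, [cnv], "s1", dispersion=0.02, seed=25)
        calls = call_sample(profs)
        scaled = [
            DepthProfile(p.sample_id, p.chrom, p.bin_size, p.counts * 7.0, p.gc)
            for p in profs
        ]
        calls2 = call_sample(scaled)
        assert [(c.start, c.end, c.svtype) for c in calls] == [
            (c.start, c.end, c.svtype) for c in calls2
        ]

    def test_calls_disjoint_and_in_bounds(self, genome):
        planted = [
            PlantedCNV("s1", "chr1", 50_000, 60_000, 0),
            PlantedCNV("s1", "chr1", 200_000, 215_000, 4),
            PlantedCNV("s1", "chr1", 400_000, 408_000, 1),
        ]
        profs = simulate_depth(genome, planted, "s1", dispersion=0.02, seed=26)
        calls = sorted(call_sample(profs), key=lambda c: c.start)
        for c in calls:
            assert 0 <= c.start < c.end <= 500_000
        for a, b in zip(calls, calls[1:]):
            assert b.start >= a.end

    def test_lowering_del_threshold_never_creates_new_regions(self, genome):
        """DEL calls at a stricter (lower) threshold lie within looser-threshold calls."""
        planted = [PlantedCNV("s1", "chr1", 150_000, 165_000, 0)]
        profs = simulate_depth(genome, planted, "s1", dispersion=0.02, seed=27)
        loose = call_sample(profs, CallerParams(del_thresh=0.75))
        strict = call_sample(profs, CallerParams(del_thresh=0.5))
        loose_dels = [(c.start, c.end) for c in loose if c.svtype == DEL]
        for c in strict:
            if c.svtype == DEL:
                assert any(s <= c.start and c.end <= e for s, e in loose_dels)


class TestCNVCallInvariants:
    def test_direction_consistency_enforced(self):
        with pytest.raises(ValueError, match="DEL"):
            CNVCall("s", "chr1", 0, 1000, DEL, rd_ratio=1.2)
        with pytest.raises(ValueError, match="DUP"):
            CNVCall("s", "chr1", 0, 1000, DUP, rd_ratio=0.8)

    @pytest.mark.parametrize(
        "ratio,cn", [(0.1, 0), (0.5, 1), (0.74, 1), (1.26, 3), (1.75, 4), (2.3, 5)]
    )
    def test_copy_number_rounds_half_away(self, ratio, cn):
        svtype = DEL if ratio < 1 else DUP
        assert CNVCall("s", "chr1", 0, 1000, svtype, ratio).copy_number == cn
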