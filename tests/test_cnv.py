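"""Bin-based read-depth copy-number calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from embryomito import (
    AlignmentSummary,
    BinCountVector,
    BinGrid,
    EmbryoRecord,
    call_profile,
    copy_number_per_bin,
    count_reads_per_bin,
    filter_alignments,
    gc_normalize,
    simulate_bin_counts,
    sliding_median,
    smooth_copy_number,
)

def make_grid(chroms_bins, gc=0.45, weight=1.0):
    rows = []
    for chrom, n in chroms_bins:
        for j in range(n):
            rows.append(
                {
                    "chrom": chrom,
                    "start": j * 1000,
                    "end": (j + 1) * 1000,
                    "gc_fraction": gc if np.isscalar(gc) else gc[len(rows)],
                    "mappable_36mers": 100,
                    "reference_weight": weight if np.isscalar(weight) else weight[len(rows)],
                }
            )
    return BinGrid(pd.DataFrame(rows))


class TestFilterAlignments:
    def test_more_than_one_mismatch_removed(self):
        recs = [AlignmentSummary("chr1", 0, mismatches=2)]
        assert list(filter_alignments(recs)) == []

    def test_clean_records_pass_through(self):
        recs = [AlignmentSummary("chr1", i, mapping_score=60) for i in range(10)]
        assert len(list(filter_alignments(recs, min_mapping_score=20))) == 10

    def test_duplicates_dropped_by_count(self):
        recs = [AlignmentSummary("chr1", i, duplicate=(i < 40)) for i in range(100)]
        assert len(list(filter_alignments(recs))) == 60

    def test_unmapped_and_low_score_dropped(self):
        recs = [
            AlignmentSummary("chr1", 0, mapped=False),
            AlignmentSummary("chr1", 1, mapping_score=5),
            AlignmentSummary("chr1", 2),
        ]
        kept = list(filter_alignments(recs, min_mapping_score=20))
        assert [r.position for r in kept] == [2]


class TestCountReadsPerBin:
    def test_half_open_boundaries(self):
        grid = make_grid([("chr1", 2)])
        at_start = AlignmentSummary("chr1", 0)
        at_end_of_first = AlignmentSummary("chr1", 1000)  # start of second bin
        counts = count_reads_per_bin([at_start, at_end_of_first], grid)
        assert counts.raw_count.tolist() == [1, 1]

    def test_reads_outside_grid_dropped_not_fatal(self):
        grid = make_grid([("chr1", 2)])
        recs = [AlignmentSummary("chr2", 0), AlignmentSummary("chr1", 99999)]
        counts = count_reads_per_bin(recs, grid)
        assert counts.raw_count.sum() == 0

    def test_uniform_reads_spread_poisson(self):
        grid = make_grid([("chr1", 10)])
        rng = np.random.default_rng(5)
        recs = [AlignmentSummary("chr1", int(p)) for p in rng.integers(0, 10_000, 1000)]
        counts = count_reads_per_bin(recs, grid)
        assert counts.raw_count.sum() == 1000
        # each bin 100 +- well within 5 sigma of Poisson error
        assert np.all(np.abs(counts.raw_count - 100) < 5 * np.sqrt(100))


class TestGcNormalize:
    def test_no_bias_is_near_identity(self):
        grid = make_grid([("chr1", 100)])
        counts = BinCountVector("e", np.full(100, 50))
        out = gc_normalize(counts, grid)
        assert np.allclose(out.normalized_count, 50.0)

    def test_reference_weight_divides(self):
        weight = np.ones(100)
        weight[7] = 2.0
        grid = make_grid([("chr1", 100)], weight=weight)
        counts = BinCountVector("e", np.full(100, 50))
        out = gc_normalize(counts, grid)
        assert out.normalized_count[7] == pytest.approx(25.0, rel=0.02)

    def test_planted_quadratic_bias_removed(self):
        from embryomito.simulate import gc_bias_curve

        rng = np.random.default_rng(0)
        gc = rng.uniform(0.3, 0.6, 10_000)
        grid = make_grid([("chr1", 10_000)], gc=gc)
        mu = 200 * gc_bias_curve(gc, (0.2, 4.0, -5.0))
        counts = BinCountVector("e", rng.poisson(mu))
        raw_r = np.corrcoef(gc, counts.raw_count)[0, 1]
        out = gc_normalize(counts, grid)
        post_r = np.corrcoef(gc, out.normalized_count)[0, 1]
        assert abs(raw_r) > 0.3  # bias was real
        assert abs(post_r) < 0.05

    def test_all_zero_counts_is_an_error(self):
        grid = make_grid([("chr1", 30)])
        with pytest.raises(ValueError, match="zero"):
            gc_normalize(BinCountVector("e", np.zeros(30, dtype=int)), grid)


class TestCopyNumberPerBin:
    def test_flat_counts_give_cn_two(self):
        grid = make_grid([("chr1", 50)])
        profile = copy_number_per_bin(BinCountVector("e", np.full(50, 80)), grid)
        assert np.allclose(profile.cn, 2.0)

    def test_elevated_chromosome_scales_to_three(self):
        grid = make_grid([("chr1", 200), ("chr2", 40)])
        counts = np.full(240, 100.0)
        counts[200:] = 150.0
        profile = copy_number_per_bin(
            BinCountVector("e", raw_count=np.zeros(240), normalized_count=counts), grid
        )
        assert np.allclose(profile.cn[:200], 2.0)
        assert np.allclose(profile.cn[200:], 3.0)

    def test_zero_count_bin_reports_cn_zero(self):
        grid = make_grid([("chr1", 51)])
        counts = np.full(51, 60)
        counts[13] = 0
        profile = copy_number_per_bin(BinCountVector("e", counts), grid)
        assert profile.cn[13] == 0.0

    def test_autosomal_median_is_two_for_any_sample(self, small_grid, default_config):
        rec = EmbryoRecord("e", 38)
        counts = simulate_bin_counts(rec, small_grid, default_config)
        profile = copy_number_per_bin(gc_normalize(counts, small_grid), small_grid)
        auto = small_grid.autosomal_mask
        assert np.median(profile.cn[auto]) == pytest.approx(2.0, abs=1e-9)


class TestSlidingMedian:
    def test_constant_input(self):
        assert np.all(sliding_median(np.full(40, 2.0), 13) == 2.0)

    def test_single_outlier_rejected(self):
        values = np.full(40, 2.0)
        values[20] = 10.0
        assert sliding_median(values, 13)[20] == 2.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            values = rng.uniform(0, 4, n)
            window = 13
            got = sliding_median(values, window)
            half = window // 2
            for i in range(n):
                h = min(half, i, n - 1 - i)
                assert got[i] == np.median(values[i - h : i + h + 1])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_median(np.ones(5), 4)

    def test_never_crosses_chromosome_boundary(self):
        grid = make_grid([("chr1", 20), ("chr2", 20)])
        cn = np.concatenate([np.full(20, 2.0), np.full(20, 3.0)])
        profile = copy_number_per_bin(
            BinCountVector("e", raw_count=np.zeros(40), normalized_count=cn), grid
        )
        smoothed = smooth_copy_number(profile, 13).smoothed_cn
        # values near the junction keep their chromosome's level
        assert np.allclose(smoothed[:20], smoothed[0])
        assert np.allclose(smoothed[20:], smoothed[-1])


class TestCallChromosomes:
    def test_flat_profile_is_euploid(self, small_grid):
        counts = BinCountVector("e", np.full(len(small_grid), 50))
        profile = call_profile(counts, small_grid, normalize=False)
        assert profile.verdict == "euploid"

    @pytest.mark.parametrize("state, expected", [(3, "gain"), (1, "loss")])
    def test_planted_whole_chromosome_events_recovered(
        self, small_grid, default_config, state, expected
    ):
        rec = EmbryoRecord(
            "e", 38, ploidy="aneuploid", aneuploid_chromosomes=[("chr7", state)]
        )
        counts = simulate_bin_counts(rec, small_grid, default_config)
        profile = call_profile(counts, small_grid)
        calls = {c.chrom: c.state for c in profile.calls}
        assert calls["chr7"] == expected
        assert profile.verdict == "aneuploid"

    def test_sex_chromosomes_called_against_declared_sex(self):
        grid = make_grid([("chr1", 100), ("chrX", 40), ("chrY", 40)])
        counts = np.full(180, 100.0)
        counts[100:140] = 50.0  # one X
        counts[140:] = 50.0  # one Y
        vec = BinCountVector("e", raw_count=np.zeros(180), normalized_count=counts)
        male = call_profile(vec, grid, sample_sex="XY", normalize=False)
        states = {c.chrom: c.state for c in male.calls}
        assert states == {"chr1": "neutral", "chrX": "neutral", "chrY": "neutral"}
        female = call_profile(vec, grid, sample_sex="XX", normalize=False)
        states = {c.chrom: c.state for c in female.calls}
        assert states["chrX"] == "loss"
        undeclared = call_profile(vec, grid, normalize=False)
        states = {c.chrom: c.state for c in undeclared.calls}
        assert states["chrX"] == "not_called"
        assert undeclared.verdict == "euploid"


class TestPipelineInvariants:
    @given(factor=st.integers(min_value=2, max_value=50))
    @settings(derandomize=True, max_examples=10)
    def test_scale_equivariance(self, small_grid, factor):
        """Multiplying all raw counts by a constant changes no cn or call."""
        rng = np.random.default_rng(23)
        base = rng.poisson(60, len(small_grid)).astype(np.int64)
        p1 = call_profile(BinCountVector("e", base), small_grid)
        p2 = call_profile(BinCountVector("e", base * factor), small_grid)
        assert np.allclose(p1.cn, p2.cn)
        assert np.allclose(p1.smoothed_cn, p2.smoothed_cn)
        assert [c.state for c in p1.calls] == [c.state for c in p2.calls]
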