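"""Depth windowing, dosage binning, masking, RLE and collapse validation."""

import numpy as np
import pytest

import polyarch as pa
from polyarch.dosage import (
    DEFAULT_BINS, MASK_OUTLIER, MASK_REPEAT, DepthWindow,
    estimate_single_copy_depth,
)
from polyarch.intervals import GenomicInterval
from polyarch.io import PafRecord


def paf(tname, tstart, tend, qname="r", tags=None):
    L = tend - tstart
    return PafRecord(qname, L, 0, L, "+", tname, 100_000, tstart, tend,
                     L, L, 60, tags or {"tp": "P"})


def mkwin(depths, chrom="c", size=10_000):
    return [
        DepthWindow(GenomicInterval(chrom, i * size, (i + 1) * size), float(d))
        for i, d in enumerate(depths)
    ]


class TestWindowDepth:
    def test_exact_overlap_arithmetic(self):
        alns = [paf("c", 0, 10_000, qname=f"r{i}") for i in range(10)]
        wins = pa.window_depth(alns, {"c": 10_000}, window=10_000)
        assert len(wins) == 1 and wins[0].raw_depth == 10.0

    def test_empty_paf_gives_zero_depth(self):
        wins = pa.window_depth([], {"c": 30_000}, window=10_000)
        assert [w.raw_depth for w in wins] == [0.0, 0.0, 0.0]

    def test_partial_overlap_split_across_windows(self):
        wins = pa.window_depth([paf("c", 5_000, 25_000)], {"c": 30_000})
        assert [w.raw_depth for w in wins] == [0.5, 1.0, 0.5]

    def test_secondary_records_excluded(self):
        alns = [paf("c", 0, 10_000), paf("c", 0, 10_000, tags={"tp": "S"})]
        wins = pa.window_depth(alns, {"c": 10_000})
        assert wins[0].raw_depth == 1.0
        wins = pa.window_depth(alns, {"c": 10_000}, unique_only=False)
        assert wins[0].raw_depth == 2.0

    def test_unknown_chromosome_listed(self):
        with pytest.raises(ValueError, match="ghost"):
            pa.window_depth([paf("ghost", 0, 100)], {"c": 1000})

    def test_collapsed_region_depth_additive(self, truth, oracle_paf,
                                             chrom_lengths):
        wins = pa.window_depth(oracle_paf, chrom_lengths)
        g4 = [w.raw_depth for w in wins if w.interval.chrom == "chr2_g4"]
        assert abs(np.mean(g4) - 90.0 * truth.copy_number["chr2_g4"] / 3) < 9.0


class TestClassifyDepth:
    @pytest.mark.parametrize("rel,expected", [
        (0.0, 0), (0.24, 0),
        (0.25, 1), (1.0, 1), (1.39, 1),
        (1.4, 2), (2.29, 2),
        (2.3, 3), (3.49, 3),
        (3.5, 4), (5.0, 4),
        (5.01, MASK_REPEAT), (5.5, MASK_REPEAT),
    ])
    def test_bin_boundaries_half_open(self, rel, expected):
        wins = mkwin([rel])
        pa.classify_depth(wins, median_override=1.0)
        assert wins[0].cls == expected

    def test_scale_invariance(self):
        depths = [10, 20, 30, 40, 120, 7]
        w1 = pa.classify_depth(mkwin(depths))
        w2 = pa.classify_depth(mkwin([d * 7.3 for d in depths]))
        assert [w.cls for w in w1] == [w.cls for w in w2]

    def test_all_zero_without_override_rejected(self):
        with pytest.raises(ValueError, match="median"):
            pa.classify_depth(mkwin([0, 0, 0]))

    def test_zero_coverage_genome_all_class_zero_with_override(self):
        wins = pa.classify_depth(mkwin([0, 0, 0]), median_override=30.0)
        assert [w.cls for w in wins] == [0, 0, 0]

    def test_anchor_recenters_on_single_copy_peak(self):
        # 60% of windows near 30, the rest collapsed at 60-120: plain
        # median overshoots 30, the refined anchor does not
        rng = np.random.default_rng(0)
        depths = list(30 + 4 * rng.standard_normal(60))
        depths += list(60 + 6 * rng.standard_normal(20))
        depths += list(120 + 9 * rng.standard_normal(20))
        wins = mkwin(depths)
        assert np.median(depths) > 31.5
        assert abs(estimate_single_copy_depth(wins) - 30.0) < 1.5


class TestExclusionMask:
    def test_retrotransposon_window_masked(self):
        wins = mkwin([10, 10, 10])
        retro = [GenomicInterval("c", 10_000, 20_000)]
        pa.exclusion_mask(wins, retro_annotation=retro)
        assert [w.cls for w in wins] == [None, MASK_REPEAT, None]

    def test_repeat_fraction_threshold(self):
        wins = mkwin([10, 10])
        repeat = [GenomicInterval("c", 0, 9_500), GenomicInterval("c", 10_000, 19_000)]
        pa.exclusion_mask(wins, repeat_mask=repeat)
        assert wins[0].cls == MASK_REPEAT      # 95% covered
        assert wins[1].cls is None             # 90% < 95%

    def test_uniform_depths_not_outlier_masked(self):
        wins = mkwin([10.0] * 20)
        pa.exclusion_mask(wins, depth_percentiles=(10, 90))
        assert all(w.cls is None for w in wins)

    def test_extreme_depth_window_masked(self):
        depths = [10.0] * 99 + [500.0]
        wins = mkwin(depths)
        pa.exclusion_mask(wins, depth_percentiles=(10, 90))
        lo, hi = np.percentile(depths, [10, 90])
        expect = [not (lo <= d <= hi) for d in depths]
        assert [w.cls == MASK_OUTLIER for w in wins] == expect
        assert wins[-1].cls == MASK_OUTLIER


class TestRleSegments:
    def test_rle_definition(self):
        wins = mkwin([1, 1, 2, 2, 2, 0])
        for w, c in zip(wins, [1, 1, 2, 2, 2, 0]):
            w.cls = c
        segs = pa.rle_segments(wins)
        assert [(s.cls, s.n_windows) for s in segs] == [(1, 2), (2, 3), (0, 1)]
        # conservation: segment lengths cover the chromosome
        assert sum(s.interval.length for s in segs) == 60_000

    def test_single_window_single_segment(self):
        wins = mkwin([1])
        wins[0].cls = 1
        segs = pa.rle_segments(wins)
        assert len(segs) == 1 and segs[0].n_windows == 1

    def test_chromosome_boundary_breaks_runs(self):
        wins = mkwin([1, 1], chrom="c1") + mkwin([1], chrom="c2")
        for w in wins:
            w.cls = 1
        segs = pa.rle_segments(wins)
        assert [(s.interval.chrom, s.n_windows) for s in segs] == [("c1", 2), ("c2", 1)]

    def test_unsorted_windows_rejected(self):
        wins = mkwin([1, 1])
        wins.reverse()
        with pytest.raises(ValueError, match="sorted"):
            pa.rle_segments(wins)

    def test_fixture_segments_match_truth_breakpoints(self, depth_windows, truth):
        segs = pa.rle_segments(depth_windows)
        # each emitted sequence has constant truth dosage; the dominant
        # segment must carry the truth class over >= 90% of its length
        for name, copies in truth.copy_number.items():
            here = [s for s in segs if s.interval.chrom == name]
            covered = sum(s.interval.length for s in here if s.cls == copies)
            assert covered >= 0.9 * len(truth.assembly[name])


class TestValidateCollapse:
    def _mini(self, n_reads, alt_every=None):
        """Reads over one 2 kb sequence; optionally an alternate allele at
        position 1000 in a fraction of reads."""
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        reads, alns = {}, []
        for i in range(n_reads):
            r = seq
            if alt_every and i % alt_every == 0:
                base = "A" if seq[1000] != "A" else "C"
                r = seq[:1000] + base + seq[1001:]
            reads[f"r{i}"] = r
            alns.append(paf("c", 0, 2000, qname=f"r{i}"))
        return seq, reads, alns

    def test_alt_fraction_above_threshold_flagged(self):
        # 10 of 30 reads carry the alternate base: 33% > 20%
        seq, reads, alns = self._mini(30, alt_every=3)
        reports = pa.validate_collapse(
            reads, alns, [GenomicInterval("c", 0, 2000)], {"c": 2000})
        assert reports[0].evaluable
        assert reports[0].n_sites_flagged == 1
        assert reports[0].flagged_runs[0].start == 1000

    def test_alt_fraction_below_threshold_not_flagged(self):
        # 5 of 30 reads: 16.7% < 20%
        seq, reads, alns = self._mini(30, alt_every=6)
        reports = pa.validate_collapse(
            reads, alns, [GenomicInterval("c", 0, 2000)], {"c": 2000})
        assert reports[0].n_sites_flagged == 0

    def test_exact_threshold_not_flagged(self):
        # 6 of 30 reads = exactly 20%: rule is strictly greater
        seq, reads, alns = self._mini(30, alt_every=5)
        reports = pa.validate_collapse(
            reads, alns, [GenomicInterval("c", 0, 2000)], {"c": 2000})
        assert reports[0].n_sites_flagged == 0

    def test_zero_coverage_region_unevaluable(self):
        seq, reads, alns = self._mini(5)
        reports = pa.validate_collapse(
            reads, alns, [GenomicInterval("other", 0, 100)], {"c": 2000, "other": 100})
        assert not reports[0].evaluable and not reports[0].flagged_runs
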