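"""Interval intersection, feature assignment, Fisher enrichment and
genome-composition summaries."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polyarch as pa
from polyarch.intervals import GenomicInterval


def brute_force_intersect(a, b):
    out = []
    for ia in sorted(a, key=lambda x: (x.chrom, x.start, x.end)):
        for ib in b:
            if ia.overlaps(ib):
                out.append((ia, ib, max(ia.start, ib.start), min(ia.end, ib.end)))
    return out


def random_intervals(rng, n, chroms=("c1", "c2"), span=100_000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span - 1))
        e = int(rng.integers(s + 1, min(s + 5000, span) + 1))
        out.append(GenomicInterval(str(rng.choice(chroms)), s, e))
    return out


class TestIntersect:
    def test_basic_overlap(self):
        a = [GenomicInterval("c", 0, 100)]
        b = [GenomicInterval("c", 50, 150)]
        out = pa.intersect(a, b)
        assert len(out) == 1
        assert (out[0].overlap.start, out[0].overlap.end, out[0].length) == (50, 100, 50)

    def test_disjoint_empty(self):
        out = pa.intersect([GenomicInterval("c", 0, 10)],
                           [GenomicInterval("c", 10, 20)])
        assert out == []

    def test_matches_quadratic_oracle_on_random_sets(self):
        rng = np.random.default_rng(17)
        a = random_intervals(rng, 1000)
        b = random_intervals(rng, 1000)
        mine = {(x.a, x.b, x.overlap.start, x.overlap.end) for x in pa.intersect(a, b)}
        oracle = set(brute_force_intersect(a, b))
        assert mine == oracle

    def test_commutative_total_overlap(self):
        rng = np.random.default_rng(3)
        a = random_intervals(rng, 200)
        b = random_intervals(rng, 200)
        fwd = sum(x.length for x in pa.intersect(a, b))
        rev = sum(x.length for x in pa.intersect(b, a))
        assert fwd == rev


class TestAssignFeatures:
    BLOCKS = [
        GenomicInterval("c", 0, 1000, name="A"),
        GenomicInterval("c", 1000, 2000, name="B"),
    ]

    def test_majority_rule(self):
        feat = GenomicInterval("c", 800, 1050)  # 200 bp in A, 50 in B
        assert pa.assign_features([feat], self.BLOCKS)[feat] == "A"

    def test_tie_unassigned(self):
        feat = GenomicInterval("c", 900, 1100)
        assert pa.assign_features([feat], self.BLOCKS)[feat] == "unassigned"

    def test_no_overlap_unassigned(self):
        feat = GenomicInterval("other", 0, 100)
        assert pa.assign_features([feat], self.BLOCKS)[feat] == "unassigned"

    def test_overlapping_blocks_rejected(self):
        blocks = [GenomicInterval("c", 0, 100, name="A"),
                  GenomicInterval("c", 50, 150, name="B")]
        with pytest.raises(ValueError, match="overlap"):
            pa.assign_features([GenomicInterval("c", 0, 10)], blocks)

    def test_planted_marker_density_ratio_recovered(self, truth):
        markers = pa.plant_markers(truth, density_a=1e-4, density_b=3e-4,
                                   marker_len=200, seed=99)
        assigned = pa.assign_features(markers, truth.progenitor_blocks)
        bp = {"A": 0, "B": 0}
        for blk in truth.progenitor_blocks:
            bp[blk.name] += blk.length
        dens = {
            lab: sum(1 for v in assigned.values() if v == lab) / bp[lab]
            for lab in ("A", "B")
        }
        ratio = dens["B"] / dens["A"]
        assert abs(ratio - 3.0) <= 0.2 * 3.0


def fisher_oracle_p(a, b, c, d):
    """Exact two-sided Fisher p by exhaustive table enumeration with
    rational hypergeometric probabilities."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p <= p_obs:
            total += p
    return float(total)


class TestFisherEnrichment:
    def test_cross_product_odds_ratio(self):
        res = pa.fisher_enrichment(10, 90, 5, 195)
        assert res.odds_ratio == pytest.approx(10 * 195 / (90 * 5), abs=1e-9)
        assert res.odds_ratio == pytest.approx(4.33, abs=0.01)

    def test_identical_rows_null(self):
        res = pa.fisher_enrichment(10, 90, 10, 90)
        assert res.odds_ratio == 1.0
        assert res.p_value == pytest.approx(1.0)
        assert res.fold_enrichment == 1.0

    def test_haldane_correction_on_zero_cell(self):
        res = pa.fisher_enrichment(5, 0, 3, 7)
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pa.fisher_enrichment(-1, 2, 3, 4)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.tuples(st.integers(1, 15), st.integers(0, 15),
                     st.integers(0, 15), st.integers(1, 15)))
    def test_p_matches_enumeration_oracle_small_tables(self, table):
        a, b, c, d = table
        res = pa.fisher_enrichment(a, b, c, d)
        assert res.p_value == pytest.approx(fisher_oracle_p(a, b, c, d), abs=1e-9)

    def test_p_invariant_under_row_and_column_swap(self):
        p0 = pa.fisher_enrichment(3, 11, 7, 2).p_value
        assert pa.fisher_enrichment(7, 2, 3, 11).p_value == pytest.approx(p0)
        assert pa.fisher_enrichment(11, 3, 2, 7).p_value == pytest.approx(p0)


class TestCompositionSummary:
    def test_progenitor_split_arithmetic(self):
        blocks = [GenomicInterval("c", 0, 73_000, name="A"),
                  GenomicInterval("c", 73_000, 100_000, name="B")]
        segs = [GenomicInterval("c", 0, 100_000, name="1")]
        comp = pa.composition_summary(blocks, segs, {"c": 100_000})
        assert comp.progenitor_frac == {"A": 0.73, "B": 0.27}
        assert comp.collapsed_fraction == 0.0

    def test_collapsed_fraction(self):
        blocks = [GenomicInterval("c", 0, 100, name="A")]
        segs = [GenomicInterval("c", 0, 40, name="1"),
                GenomicInterval("c", 40, 100, name="3")]
        comp = pa.composition_summary(blocks, segs, {"c": 100})
        assert comp.collapsed_fraction == pytest.approx(0.6)

    def test_track_past_chromosome_end_rejected(self):
        with pytest.raises(ValueError, match="past"):
            pa.composition_summary(
                [GenomicInterval("c", 0, 200, name="A")], [], {"c": 100})

    def test_fixture_collapsed_fraction_near_truth(self, truth, depth_windows,
                                                   chrom_lengths):
        segs = [s.as_interval() for s in pa.rle_segments(depth_windows)]
        comp = pa.composition_summary(truth.progenitor_blocks, segs, chrom_lengths)
        truth_collapsed = sum(
            len(truth.assembly[n]) for n, c in truth.copy_number.items() if c >= 2
        ) / sum(chrom_lengths.values())
        assert abs(comp.collapsed_fraction - truth_collapsed) <= 0.05

    def test_lengths_conserved_across_cross_tab(self, truth, chrom_lengths):
        segs = truth.dosage
        comp = pa.composition_summary(truth.progenitor_blocks, segs, chrom_lengths)
        assert sum(comp.cross_bp.values()) == sum(chrom_lengths.values())


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        p = [0.001, 0.01, 0.02, 0.8]
        q = pa.benjamini_hochberg(p)
        assert all(qi >= pi for qi, pi in zip(q, p))
        assert all(0 <= qi <= 1 for qi in q)
        assert q == sorted(q)
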