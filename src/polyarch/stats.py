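"""Interval bookkeeping and enrichment statistics.

Intersects feature sets (genes, markers, resistance-gene-analogue motifs)
with progenitor blocks and dosage segments, assigns features by majority
overlap, computes Fisher exact enrichment, and summarises genome
composition (progenitor split, collapsed fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .intervals import GenomicInterval, sorted_intervals

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Intersection:
    a: GenomicInterval
    b: GenomicInterval
    overlap: GenomicInterval

    @property
    def length(self) -> int:
        return self.overlap.length


def _trees(ivs: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in ivs:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[Intersection]:
    """All pairwise overlapping spans between two interval sets
    (BEDtools-intersect semantics), sorted by the A interval."""
    trees = _trees(b)
    out: list[Intersection] = []
    for iv in sorted_intervals(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(iv.start, iv.end)):
            other: GenomicInterval = hit.data
            out.append(Intersection(iv, other, iv.intersection(other)))
    return out


def _check_non_overlapping(blocks: Sequence[GenomicInterval]) -> None:
    prev_end: dict[str, int] = {}
    for iv in sorted_intervals(blocks):
        if iv.start < prev_end.get(iv.chrom, 0):
            raise ValueError(f"blocks overlap on {iv.chrom} at {iv.start}")
        prev_end[iv.chrom] = iv.end


def assign_features(
    features: Sequence[GenomicInterval],
    blocks: Sequence[GenomicInterval],
    rule: str = "majority",
) -> dict[GenomicInterval, str]:
    """Label each feature by the block class covering most of its length.

    Block classes come from the block ``name`` field. With the default
    ``majority`` rule a strict plurality of overlapped length wins; ties
    and zero overlap yield ``unassigned``. With ``any``, a single
    overlapping class suffices (multiple distinct classes -> tie rule).
    """
    if rule not in ("majority", "any"):
        raise ValueError(f"unknown assignment rule {rule!r}")
    _check_non_overlapping(blocks)
    trees = _trees(blocks)
    out: dict[GenomicInterval, str] = {}
    for f in features:
        cover: dict[str, int] = {}
        tree = trees.get(f.chrom)
        if tree is not None:
            for hit in tree.overlap(f.start, f.end):
                blk: GenomicInterval = hit.data
                ov = blk.intersection(f)
                cover[blk.name] = cover.get(blk.name, 0) + ov.length
        if not cover:
            out[f] = UNASSIGNED
            continue
        if rule == "any" and len(cover) == 1:
            out[f] = next(iter(cover))
            continue
        ranked = sorted(cover.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out[f] = UNASSIGNED
        else:
            out[f] = ranked[0][0]
    return out


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    fold_enrichment: float
    haldane_corrected: bool = False


def fisher_enrichment(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Odds ratio is the cross-product (a d)/(b c), with a 0.5 Haldane
    correction on every cell when any cell is zero (flagged). The
    two-sided p sums hypergeometric tables whose probability does not
    exceed the observed one. Fold enrichment compares the rate in the
    first row with the first-column rate overall.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("contingency counts must be non-negative")
    if a + b == 0 or a + c == 0 or a + b + c + d == 0:
        raise ValueError("contingency table margins must be positive")
    haldane = 0 in (a, b, c, d)
    if haldane:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    odds = (aa * dd) / (bb * cc)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    fold = (a / (a + b)) / ((a + c) / (a + b + c + d))
    return EnrichmentResult(odds, float(p), fold, haldane)


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH-adjusted q-values (helper; raw p-values are reported by default)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, pvalues[i] * m / rank)
        q[i] = prev
    return q


@dataclass
class CompositionSummary:
    progenitor_bp: dict[str, int]
    progenitor_frac: dict[str, float]     # over assigned length
    dosage_bp: dict[object, int]
    collapsed_fraction: float             # class >= 2 over classified length
    cross_bp: dict[tuple[str, object], int]
    total_bp: int


def composition_summary(
    progenitor_blocks: Sequence[GenomicInterval],
    dosage_segments: Sequence[GenomicInterval],
    chrom_lengths: dict[str, int],
) -> CompositionSummary:
    """Per-progenitor and per-dosage-class genome composition.

    Progenitor blocks carry labels in ``name``; dosage segments carry the
    class (integer or mask string) in ``name``. The collapsed fraction is
    the classified length at class >= 2 over all integer-classified
    length. Tracks must stay within the chromosome bounds.
    """
    for track in (progenitor_blocks, dosage_segments):
        for iv in track:
            L = chrom_lengths.get(iv.chrom)
            if L is None:
                raise ValueError(f"track names unknown chromosome {iv.chrom}")
            if iv.end > L:
                raise ValueError(f"interval {iv} extends past chromosome end {L}")
    prog_bp: dict[str, int] = {}
    for iv in progenitor_blocks:
        prog_bp[iv.name] = prog_bp.get(iv.name, 0) + iv.length
    assigned = sum(prog_bp.values())
    prog_frac = {k: v / assigned for k, v in prog_bp.items()} if assigned else {}

    dose_bp: dict[object, int] = {}
    for iv in dosage_segments:
        try:
            key: object = int(iv.name)
        except (TypeError, ValueError):
            key = iv.name
        dose_bp[key] = dose_bp.get(key, 0) + iv.length
    classified = sum(v for k, v in dose_bp.items() if isinstance(k, int))
    collapsed = sum(v for k, v in dose_bp.items() if isinstance(k, int) and k >= 2)
    collapsed_frac = collapsed / classified if classified else 0.0

    cross: dict[tuple[str, object], int] = {}
    for ix in intersect(progenitor_blocks, dosage_segments):
        try:
            dkey: object = int(ix.b.name)
        except (TypeError, ValueError):
            dkey = ix.b.name
        key = (ix.a.name, dkey)
        cross[key] = cross.get(key, 0) + ix.length
    total = sum(chrom_lengths.values())
    return CompositionSummary(
        prog_bp, prog_frac, dose_bp, collapsed_frac, cross, total
    )
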