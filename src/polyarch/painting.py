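"""Progenitor-of-origin painting with diagnostic k-mers.

A k-mer is diagnostic for progenitor A if its canonical form occurs in
the A genome and never in the B genome (and symmetrically for B). Tiling
windows of the hybrid assembly are labelled by which diagnostic set they
hit more often; same-label windows are then merged into progenitor
blocks. Default k is 27 bp.

K-mers are handled as 2-bit-packed integer codes (A=0, C=1, G=2, T=3),
so the lexicographic minimum of a k-mer and its reverse complement
coincides with the numeric minimum of their codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .intervals import GenomicInterval
from .simulate import encode, decode

UNASSIGNED = "unassigned"

MAX_K = 31  # 2-bit codes must fit a 64-bit integer


def canonical_kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical integer codes of every k-mer of ``seq``.

    Returns (codes, starts); k-mers spanning a non-ACGT symbol are skipped.
    """
    if not 3 <= k <= MAX_K or k % 2 == 0:
        raise ValueError(f"k must be odd and in [3, {MAX_K}], got {k}")
    b = encode(seq)
    if b.size < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    win = sliding_window_view(b, k)
    valid = (win != 255).all(axis=1)
    win = win[valid].astype(np.uint64)
    pow_desc = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    pow_asc = pow_desc[::-1]
    fwd = (win * pow_desc).sum(axis=1)
    rev = ((np.uint64(3) - win) * pow_asc).sum(axis=1)
    canon = np.minimum(fwd, rev)
    starts = np.flatnonzero(valid).astype(np.int64)
    return canon, starts


def decode_kmer(code: int, k: int) -> str:
    digits = np.empty(k, dtype=np.uint8)
    c = int(code)
    for i in range(k - 1, -1, -1):
        digits[i] = c & 3
        c >>= 2
    return decode(digits)


@dataclass
class DiagnosticKmerSets:
    """Canonical k-mer sets exclusive to each progenitor.

    ``codes_a``/``codes_b`` are sorted arrays of canonical codes;
    ``n_shared`` counts canonical k-mers present in both genomes (and
    therefore discarded as non-diagnostic).
    """

    k: int
    codes_a: np.ndarray
    codes_b: np.ndarray
    n_shared: int

    def kmers(self, which: str) -> frozenset[str]:
        codes = self.codes_a if which == "A" else self.codes_b
        return frozenset(decode_kmer(c, self.k) for c in codes)

    def swap(self) -> "DiagnosticKmerSets":
        return DiagnosticKmerSets(self.k, self.codes_b, self.codes_a, self.n_shared)


def _genome_kmer_codes(seqs: Iterable[str], k: int) -> np.ndarray:
    parts = [canonical_kmer_codes(s, k)[0] for s in seqs]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def extract_diagnostic_kmers(
    progenitor_a: Mapping[str, str] | Sequence[str],
    progenitor_b: Mapping[str, str] | Sequence[str],
    k: int = 27,
) -> DiagnosticKmerSets:
    """Canonical k-mers exclusive to each progenitor genome."""
    seqs_a = list(progenitor_a.values() if isinstance(progenitor_a, Mapping) else progenitor_a)
    seqs_b = list(progenitor_b.values() if isinstance(progenitor_b, Mapping) else progenitor_b)
    if not any(seqs_a) or not any(seqs_b):
        raise ValueError("progenitor input sequences are empty")
    all_a = _genome_kmer_codes(seqs_a, k)
    all_b = _genome_kmer_codes(seqs_b, k)
    only_a = np.setdiff1d(all_a, all_b, assume_unique=True)
    only_b = np.setdiff1d(all_b, all_a, assume_unique=True)
    n_shared = all_a.size - only_a.size
    return DiagnosticKmerSets(k, only_a, only_b, int(n_shared))


@dataclass
class WindowPaint:
    """Diagnostic-hit counts and progenitor label for one tiling window."""

    interval: GenomicInterval
    hits_a: int
    hits_b: int
    label: str  # 'A' | 'B' | 'unassigned'


def _label(hits_a: int, hits_b: int, min_hits: int) -> str:
    if hits_a == hits_b or max(hits_a, hits_b) < min_hits:
        return UNASSIGNED
    return "A" if hits_a > hits_b else "B"


def paint_windows(
    assembly: Mapping[str, str],
    kmers: DiagnosticKmerSets,
    window: int = 10_000,
    min_hits: int = 2,
) -> list[WindowPaint]:
    """Count diagnostic k-mer hits per tiling window and label each window.

    A k-mer belongs to the window containing its start position. The label
    is the argmax of the two hit counts when the larger count reaches
    ``min_hits`` and the counts differ; otherwise the window is unassigned.
    """
    if window < kmers.k:
        raise ValueError(f"window {window} smaller than k={kmers.k}")
    paints: list[WindowPaint] = []
    for chrom, seq in assembly.items():
        codes, starts = canonical_kmer_codes(seq, kmers.k)
        in_a = _member(codes, kmers.codes_a)
        in_b = _member(codes, kmers.codes_b)
        widx = starts // window
        n_win = (len(seq) + window - 1) // window
        hits_a = np.bincount(widx[in_a], minlength=n_win)
        hits_b = np.bincount(widx[in_b], minlength=n_win)
        for w in range(n_win):
            iv = GenomicInterval(chrom, w * window, min((w + 1) * window, len(seq)))
            ha, hb = int(hits_a[w]), int(hits_b[w])
            paints.append(WindowPaint(iv, ha, hb, _label(ha, hb, min_hits)))
    return paints


def _member(codes: np.ndarray, sorted_set: np.ndarray) -> np.ndarray:
    if sorted_set.size == 0 or codes.size == 0:
        return np.zeros(codes.size, dtype=bool)
    idx = np.searchsorted(sorted_set, codes)
    idx[idx == sorted_set.size] = 0
    return sorted_set[idx] == codes


@dataclass
class ProgenitorBlock:
    """A merged run of same-label windows."""

    interval: GenomicInterval
    progenitor: str
    n_windows: int
    hit_density: float  # supporting diagnostic hits per kb

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.interval.chrom, self.interval.start, self.interval.end,
            name=self.progenitor, score=round(self.hit_density, 4),
        )


def segment_blocks(
    paints: Sequence[WindowPaint],
    min_block: int = 20_000,
    max_gap: int = 2,
) -> list[ProgenitorBlock]:
    """Merge consecutive same-label windows into progenitor blocks.

    Runs of at most ``max_gap`` unassigned windows flanked on both sides
    by the same label are absorbed into that label; merged blocks shorter
    than ``min_block`` are dropped. Input must be position-sorted within
    each chromosome.
    """
    by_chrom: dict[str, list[WindowPaint]] = {}
    for p in paints:
        lst = by_chrom.setdefault(p.interval.chrom, [])
        if lst and p.interval.start < lst[-1].interval.start:
            raise ValueError(f"window paints not sorted on {p.interval.chrom}")
        lst.append(p)
    blocks: list[ProgenitorBlock] = []
    for chrom, wins in by_chrom.items():
        labels = [w.label for w in wins]
        labels = _absorb_gaps(labels, max_gap)
        i = 0
        while i < len(wins):
            lab = labels[i]
            j = i
            while j < len(wins) and labels[j] == lab:
                j += 1
            if lab != UNASSIGNED:
                start = wins[i].interval.start
                end = wins[j - 1].interval.end
                if end - start >= min_block:
                    hits = sum(
                        w.hits_a if lab == "A" else w.hits_b for w in wins[i:j]
                    )
                    blocks.append(
                        ProgenitorBlock(
                            GenomicInterval(chrom, start, end),
                            lab, j - i, hits / ((end - start) / 1000.0),
                        )
                    )
            i = j
    return blocks


def _absorb_gaps(labels: list[str], max_gap: int) -> list[str]:
    out = list(labels)
    i = 0
    while i < len(out):
        if out[i] == UNASSIGNED:
            j = i
            while j < len(out) and out[j] == UNASSIGNED:
                j += 1
            if (
                0 < i and j < len(out)
                and out[i - 1] == out[j] != UNASSIGNED
                and j - i <= max_gap
            ):
                for t in range(i, j):
                    out[t] = out[i - 1]
            i = j
        else:
            i += 1
    return out


def painting_accuracy(
    paints: Sequence[WindowPaint], truth_label, skip_unassigned: bool = True
) -> float:
    """Fraction of labelled windows whose label matches the truth track.

    ``truth_label`` maps a window interval to 'A'/'B' (e.g. the bound
    method ``TruthSet.truth_label_of_window``).
    """
    n = hit = 0
    for p in paints:
        if skip_unassigned and p.label == UNASSIGNED:
            continue
        t = truth_label(p.interval)
        if t is None:
            continue
        n += 1
        hit += p.label == t
    if n == 0:
        raise ValueError("no labelled windows to score")
    return hit / n
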