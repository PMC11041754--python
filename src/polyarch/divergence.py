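"""Ortholog divergence: PID2, codon alignment, NG86 Ka/Ks, Ks-peak dating.

Peptide pairs are globally aligned (Needleman-Wunsch, BLOSUM62, affine
gaps) and identity is scored as PID2 = exact-match columns / total
alignment columns (gaps count in the denominator). The peptide alignment
is back-translated onto the CDS pair codon by codon, and synonymous and
nonsynonymous distances are estimated with the Nei-Gojobori (1986)
pathway-counting method under a Jukes-Cantor multiple-hit correction:

    d = -3/4 ln(1 - 4/3 p)

The mode of the Ks distribution over many ortholog pairs, divided by
twice the neutral substitution rate, dates the progenitor split:
T = Ks_peak / (2 mu).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

# ---------------------------------------------------------------------------
# Peptide alignment / PID2

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _make_aligner(open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    return aligner


def global_align_pid2(
    peptide_a: str,
    peptide_b: str,
    open_gap: float = 10.0,
    extend_gap: float = 1.0,
) -> tuple[str, str, float]:
    """Global peptide alignment and PID2.

    PID2 counts exact-match columns over all alignment columns, terminal
    gaps included; 'X' is tolerated in the input but never scores as a
    match. Among co-optimal alignments the aligner's first is used.
    """
    for name, pep in (("A", peptide_a), ("B", peptide_b)):
        if not pep:
            raise ValueError(f"peptide {name} is empty")
        bad = set(pep.upper()) - _AA - {"X"}
        if bad:
            raise ValueError(f"peptide {name} contains invalid letters {sorted(bad)}")
    aligner = _make_aligner(open_gap, extend_gap)
    aln = aligner.align(peptide_a.upper(), peptide_b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x not in ("-", "X")
    )
    return row_a, row_b, matches / len(row_a)


# ---------------------------------------------------------------------------
# Back-translation

_STOPS = set(standard_dna_table.stop_codons)


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return standard_dna_table.forward_table.get(codon, "X")


def backtranslate(
    aligned_a: str, aligned_b: str, cds_a: str, cds_b: str
) -> tuple[str, str]:
    """Expand a gapped peptide alignment into a codon alignment.

    Each peptide column becomes one codon column; a peptide gap becomes
    '---'. Terminal stop codons on the CDS are trimmed. Translation must
    reproduce the (ungapped) peptides.
    """
    out = []
    for row, cds, which in ((aligned_a, cds_a, "A"), (aligned_b, cds_b, "B")):
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS {which} length {len(cds)} is not a multiple of 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in _STOPS:
            codons = codons[:-1]
        pep = row.replace("-", "")
        if len(codons) != len(pep):
            raise ValueError(
                f"CDS {which}: {len(codons)} codons do not match peptide "
                f"length {len(pep)}"
            )
        for i, (codon, aa) in enumerate(zip(codons, pep)):
            trans = _translate_codon(codon)
            if trans == "*":
                raise ValueError(f"CDS {which}: internal stop codon {codon} at codon {i}")
            if aa != "X" and trans != aa:
                raise ValueError(
                    f"CDS {which}: codon {i} ({codon}) translates to {trans}, "
                    f"peptide has {aa}"
                )
        it = iter(codons)
        out.append("".join("---" if c == "-" else next(it) for c in row))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# NG86

_NT = "ACGT"


@lru_cache(maxsize=None)
def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one codon.

    Each of the nine single-base changes counts 1/3 of a site; changes
    that create a stop codon count as nonsynonymous.
    """
    aa = _translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in _STOPS and _translate_codon(alt) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pairwise_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over minimal mutation paths.

    Paths passing through a stop codon are excluded; if every path does,
    all paths are averaged as a fallback.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
            if _translate_codon(nxt) == _translate_codon(cur) and nxt not in _STOPS and cur not in _STOPS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((ok, sd, nd))
    valid = [(s, n) for ok, s, n in paths if ok]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance; NaN at or beyond saturation (p >= 3/4)."""
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsResult:
    ka: float
    ks: float
    syn_sites: float       # S, averaged over the two sequences
    nonsyn_sites: float    # N
    sd: float
    nd: float
    n_codons: int          # gap-free, unambiguous codon columns counted


def kaks_ng86(codon_a: str, codon_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Only gap-free codon columns with unambiguous bases are counted.
    Saturated distances (p >= 3/4) are returned as NaN, not raised.
    """
    if len(codon_a) != len(codon_b) or len(codon_a) % 3 != 0:
        raise ValueError("codon alignment rows must be equal length multiples of 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(codon_a), 3):
        ca, cb = codon_a[i:i + 3].upper(), codon_b[i:i + 3].upper()
        if "-" in ca or "-" in cb:
            continue
        if set(ca + cb) - set(_NT):
            continue  # ambiguous nucleotides: codon excluded
        if ca in _STOPS or cb in _STOPS:
            raise ValueError(f"stop codon in alignment at codon column {i // 3}")
        s1, n1 = _codon_site_counts(ca)
        s2, n2 = _codon_site_counts(cb)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _pairwise_path_counts(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no countable codon columns")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return KaKsResult(
        ka=jukes_cantor(pn), ks=jukes_cantor(ps),
        syn_sites=S, nonsyn_sites=N, sd=Sd, nd=Nd, n_codons=n_codons,
    )


# ---------------------------------------------------------------------------
# Pair container and batch analysis

@dataclass
class OrthologPair:
    id_a: str
    id_b: str
    peptide_a: str
    peptide_b: str
    cds_a: str
    cds_b: str
    progenitor_a: str = "A"
    progenitor_b: str = "B"
    pid2: Optional[float] = None
    ka: Optional[float] = None
    ks: Optional[float] = None


def analyze_pair(pair: OrthologPair) -> OrthologPair:
    """Align, back-translate and estimate Ka/Ks for one ortholog pair."""
    row_a, row_b, pid2 = global_align_pid2(pair.peptide_a, pair.peptide_b)
    cod_a, cod_b = backtranslate(row_a, row_b, pair.cds_a, pair.cds_b)
    res = kaks_ng86(cod_a, cod_b)
    pair.pid2, pair.ka, pair.ks = pid2, res.ka, res.ks
    return pair


def ks_from_cds_pairs(pairs: Sequence[tuple[str, str, str, str]]) -> list[float]:
    """Ks per (id_a, id_b, cds_a, cds_b) tuple, skipping the aligner when
    the CDS pair is already codon-aligned (equal length, no gaps)."""
    out = []
    for _, _, ca, cb in pairs:
        out.append(kaks_ng86(ca, cb).ks)
    return out


# ---------------------------------------------------------------------------
# Ks distribution and dating

@dataclass
class KsDistribution:
    values: np.ndarray
    peak: float
    bin_width: float


def ks_peak(values: Sequence[float], bin_width: float = 0.002) -> KsDistribution:
    """Histogram mode of a Ks sample, as the midpoint of the modal bin.

    Missing (NaN) values are dropped; at least 30 finite values are
    required. Ties between modal bins resolve to the lowest bin.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 30:
        raise ValueError(f"need >= 30 finite Ks values, got {arr.size}")
    hi = max(arr.max(), bin_width)
    # bins centred on multiples of bin_width, so a sample concentrated at
    # such a value reports that value as its peak
    edges = np.arange(-bin_width / 2.0, hi + 2 * bin_width, bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    mode = int(np.argmax(counts))
    peak = float((edges[mode] + edges[mode + 1]) / 2.0)
    return KsDistribution(arr, peak, bin_width)


@dataclass
class DivergenceEstimate:
    ks_peak: float
    mu: float          # substitutions / site / year
    time_years: float


def divergence_time(ks_peak_value: float, mu: float) -> DivergenceEstimate:
    """Molecular date of a split: T = Ks_peak / (2 mu) years."""
    if mu <= 0:
        raise ValueError("neutral rate mu must be positive")
    if ks_peak_value < 0:
        raise ValueError("Ks peak must be non-negative")
    return DivergenceEstimate(ks_peak_value, mu, ks_peak_value / (2.0 * mu))
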