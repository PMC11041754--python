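"""Synthetic hybrid-polyploid generator.

Emulates the genome structure the downstream analyses assume: two
progenitor genomes diverged at neutral sites (the "domesticated" A and
"wild" B species), a hybrid assembly whose chromosome copies carry
per-progenitor dosage 0-4 including byte-identical (IBD, collapsed)
copies and interspecific recombinant chromosomes, and long reads whose
depth over a collapsed region is the sum over the underlying copies.
Every stage emits machine-readable truth so recovery can be scored.

The generator is deliberately idealised: substitution-only divergence
(no indels), forward-strand error-free-by-default reads, and an oracle
PAF in which every read is placed at its true (collapsed) location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .intervals import GenomicInterval
from .io import PafRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A=0, C=1, G=2, T=3; other=255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Substitute each site with probability ``rate``; returns (new, positions)."""
    out = codes.copy()
    if rate <= 0:
        return out, np.empty(0, dtype=np.int64)
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        # shift by 1..3 in base space: always a different base
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out, hit


# ---------------------------------------------------------------------------
# Progenitors

@dataclass
class ProgenitorPair:
    """Two progenitor genomes differing only by substitutions.

    ``substitutions`` lists (chromosome index, position, base in A, base in B).
    """

    seq_a: list[str]
    seq_b: list[str]
    substitutions: list[tuple[int, int, str, str]]
    divergence: float

    @property
    def n_chrom(self) -> int:
        return len(self.seq_a)

    def chrom_length(self, i: int) -> int:
        return len(self.seq_a[i])


def simulate_progenitors(
    n_chrom: int, chrom_len: int, divergence: float, seed: int
) -> ProgenitorPair:
    """Draw a random ancestor and derive progenitor B by substitutions.

    Substitutions are placed independently and uniformly at rate
    ``divergence`` per site; no indels, so coordinates are shared.
    """
    if not 0.0 <= divergence <= 0.2:
        raise ValueError(f"divergence {divergence} outside [0, 0.2]")
    if chrom_len < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    seq_a, seq_b, subs = [], [], []
    for ci in range(n_chrom):
        a = rng.integers(0, 4, size=chrom_len, dtype=np.uint8)
        b, hit = _mutate(a, divergence, rng)
        seq_a.append(decode(a))
        seq_b.append(decode(b))
        for pos in hit:
            subs.append((ci, int(pos), decode(a[pos:pos + 1]), decode(b[pos:pos + 1])))
    return ProgenitorPair(seq_a, seq_b, subs, divergence)


# ---------------------------------------------------------------------------
# Hybrid assembly

@dataclass(frozen=True)
class CopySpec:
    """One chromosome copy of the hybrid.

    ``progenitor`` is the source at the chromosome start; each breakpoint
    switches the source (A<->B), modelling an interspecific recombinant.
    Copies sharing an ``ibd_group`` are byte-identical and emitted once
    (the collapsed representation); ``None`` means a unique copy.
    """

    progenitor: str
    ibd_group: Optional[str] = None
    breakpoints: tuple[int, ...] = ()
    private_mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.progenitor not in ("A", "B"):
            raise ValueError(f"progenitor must be 'A' or 'B', got {self.progenitor!r}")
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")
        if not 0.0 <= self.private_mutation_rate <= 0.1:
            raise ValueError("private mutation rate outside [0, 0.1]")

    def source_blocks(self, length: int) -> list[tuple[int, int, str]]:
        """(start, end, progenitor) blocks implied by the breakpoints."""
        for bp in self.breakpoints:
            if not 0 < bp < length:
                raise ValueError(f"breakpoint {bp} outside chromosome of length {length}")
        bounds = [0, *self.breakpoints, length]
        labels = ["A", "B"] if self.progenitor == "A" else ["B", "A"]
        return [
            (bounds[i], bounds[i + 1], labels[i % 2]) for i in range(len(bounds) - 1)
        ]


class DosageSpec:
    """Per basic chromosome, the list of copies making up the hybrid."""

    def __init__(self, copies: dict[int, list[CopySpec]]):
        self.copies = copies
        for ci, specs in copies.items():
            groups: dict[str, CopySpec] = {}
            for cs in specs:
                if cs.ibd_group is None:
                    continue
                if cs.ibd_group in groups and groups[cs.ibd_group] != cs:
                    raise ValueError(
                        f"chromosome {ci}: copies in IBD group {cs.ibd_group!r} "
                        "must share one descriptor"
                    )
                groups[cs.ibd_group] = cs

    def emitted(self, ci: int) -> list[tuple[str, CopySpec, int]]:
        """(emitted name, descriptor, collapsed copy number) per sequence."""
        out: list[tuple[str, CopySpec, int]] = []
        seen: dict[str, int] = {}
        uniq = 0
        counts: dict[str, int] = {}
        for cs in self.copies[ci]:
            if cs.ibd_group is not None:
                counts[cs.ibd_group] = counts.get(cs.ibd_group, 0) + 1
        for cs in self.copies[ci]:
            if cs.ibd_group is None:
                out.append((f"chr{ci}_u{uniq}", cs, 1))
                uniq += 1
            elif cs.ibd_group not in seen:
                seen[cs.ibd_group] = 1
                out.append((f"chr{ci}_{cs.ibd_group}", cs, counts[cs.ibd_group]))
        return out


@dataclass
class TruthSet:
    """Machine-readable truth for every downstream stage."""

    assembly: dict[str, str]
    progenitor_blocks: list[GenomicInterval]          # name = 'A' | 'B'
    dosage: list[GenomicInterval]                     # name = str(copy number)
    copy_number: dict[str, int]                       # emitted name -> copies
    basic_chromosome: dict[str, int]                  # emitted name -> index
    read_origins: list[tuple[str, str, int, int]] = field(default_factory=list)
    markers: list[GenomicInterval] = field(default_factory=list)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)

    def truth_label_of_window(self, iv: GenomicInterval) -> Optional[str]:
        """Majority truth progenitor over a window (for scoring painters)."""
        best: dict[str, int] = {}
        for blk in self.progenitor_blocks:
            ov = blk.intersection(iv)
            if ov is not None:
                best[blk.name] = best.get(blk.name, 0) + ov.length
        if not best:
            return None
        return max(best, key=lambda k: (best[k], k))


def build_hybrid_assembly(
    pair: ProgenitorPair, spec: DosageSpec, seed: int
) -> TruthSet:
    """Emit one sequence per IBD group and per unique copy, with truth tracks.

    Private mutations are drawn once per emitted sequence, so copies in an
    IBD group are byte-identical by construction.
    """
    rng = np.random.default_rng(seed)
    assembly: dict[str, str] = {}
    prog_blocks: list[GenomicInterval] = []
    dosage: list[GenomicInterval] = []
    copy_number: dict[str, int] = {}
    basic: dict[str, int] = {}
    src = {"A": [encode(s) for s in pair.seq_a], "B": [encode(s) for s in pair.seq_b]}
    for ci in sorted(spec.copies):
        if ci >= pair.n_chrom:
            raise ValueError(f"dosage spec names chromosome {ci}, pair has {pair.n_chrom}")
        length = pair.chrom_length(ci)
        for name, cs, count in spec.emitted(ci):
            blocks = cs.source_blocks(length)
            parts = [src[lab][ci][s:e] for s, e, lab in blocks]
            codes = np.concatenate(parts)
            codes, _ = _mutate(codes, cs.private_mutation_rate, rng)
            assembly[name] = decode(codes)
            copy_number[name] = count
            basic[name] = ci
            for s, e, lab in blocks:
                prog_blocks.append(GenomicInterval(name, s, e, name=lab))
            dosage.append(GenomicInterval(name, 0, length, name=str(count)))
    return TruthSet(assembly, prog_blocks, dosage, copy_number, basic)


# ---------------------------------------------------------------------------
# Reads

def sample_reads(
    seq: str,
    source_name: str,
    target_name: str,
    target_len: int,
    coverage: float,
    read_len: int,
    error_rate: float,
    rng: np.random.Generator,
    read_prefix: str,
) -> tuple[dict[str, str], list[PafRecord], list[tuple[str, str, int, int]]]:
    """Draw reads from one underlying copy, with oracle placements.

    Fragment starts are uniform over ``[-(read_len-1), L)`` and reads are
    clipped at the sequence ends, keeping expected depth uniform along the
    chromosome. Returns (reads, oracle PAF records, origin rows).
    """
    L = len(seq)
    if read_len > L:
        raise ValueError(f"read length {read_len} exceeds sequence length {L}")
    window = L + read_len - 1
    n = int(round(coverage * window / read_len))
    starts = rng.integers(-(read_len - 1), L, size=n)
    codes = encode(seq)
    reads: dict[str, str] = {}
    paf: list[PafRecord] = []
    origins: list[tuple[str, str, int, int]] = []
    for i, s in enumerate(starts):
        b = max(int(s), 0)
        e = min(int(s) + read_len, L)
        if e - b < 1:
            continue
        sub, nerr = codes[b:e], 0
        if error_rate > 0:
            sub, hit = _mutate(sub, error_rate, rng)
            nerr = hit.size
        rid = f"{read_prefix}_r{i}"
        reads[rid] = decode(sub)
        rlen = e - b
        paf.append(
            PafRecord(
                qname=rid, qlen=rlen, qstart=0, qend=rlen, strand="+",
                tname=target_name, tlen=target_len, tstart=b, tend=e,
                nmatch=rlen - nerr, alnlen=rlen, mapq=60, tags={"tp": "P"},
            )
        )
        origins.append((rid, source_name, b, e))
    return reads, paf, origins


def simulate_reads(
    truth: TruthSet,
    coverage_per_copy: float,
    read_len: int,
    error_rate: float,
    seed: int,
) -> tuple[dict[str, str], list[PafRecord]]:
    """Simulate long reads per *underlying* copy of each emitted sequence.

    A sequence collapsed from ``c`` identical copies receives ``c`` times
    ``coverage_per_copy``. The oracle PAF places each read at its true span
    on its emitted sequence, tagged as a primary alignment. Origins are
    recorded in ``truth.read_origins``.
    """
    if coverage_per_copy <= 0:
        raise ValueError("coverage_per_copy must be positive")
    rng = np.random.default_rng(seed)
    reads: dict[str, str] = {}
    paf: list[PafRecord] = []
    truth.read_origins = []
    for name in truth.assembly:
        seq = truth.assembly[name]
        for copy_i in range(truth.copy_number[name]):
            r, p, o = sample_reads(
                seq,
                source_name=f"{name}/copy{copy_i}",
                target_name=name,
                target_len=len(seq),
                coverage=coverage_per_copy,
                read_len=read_len,
                error_rate=error_rate,
                rng=rng,
                read_prefix=f"{name}_c{copy_i}",
            )
            reads.update(r)
            paf.extend(p)
            truth.read_origins.extend(o)
    return reads, paf


# ---------------------------------------------------------------------------
# Markers, segregation, ortholog pairs

def plant_markers(
    truth: TruthSet,
    density_a: float,
    density_b: float,
    marker_len: int,
    seed: int,
) -> list[GenomicInterval]:
    """Scatter marker intervals with progenitor-dependent density.

    Marker starts follow a Poisson process at ``density_a`` (resp. ``_b``)
    per bp inside truth A (resp. B) blocks; each marker interval carries
    its truth label in ``strand``-free ``name`` as ``m<N>|<label>``.
    """
    rng = np.random.default_rng(seed)
    out: list[GenomicInterval] = []
    n = 0
    density = {"A": density_a, "B": density_b}
    for blk in truth.progenitor_blocks:
        lam = density[blk.name] * blk.length
        k = rng.poisson(lam)
        starts = np.sort(rng.integers(blk.start, blk.end, size=k))
        for s in starts:
            e = min(int(s) + marker_len, blk.end)
            if e <= s:
                continue
            out.append(GenomicInterval(blk.chrom, int(s), e, name=f"m{n}|{blk.name}"))
            n += 1
    truth.markers = out
    return out


def simulate_selfed_progeny(
    dose: int, ploidy: int, n_progeny: int, seed: int
) -> np.ndarray:
    """Marker presence among selfed progeny of an autopolyploid.

    Each progeny unites two independent gametes; each gamete is a uniform
    draw of ``ploidy/2`` of the ``ploidy`` homologous copies without
    replacement (random bivalent pairing, no double reduction). The marker
    is present if at least one inherited copy carries it.
    """
    if ploidy % 2 != 0 or ploidy <= 0:
        raise ValueError("ploidy must be a positive even number")
    if not 0 <= dose <= ploidy:
        raise ValueError("dose must lie in [0, ploidy]")
    rng = np.random.default_rng(seed)
    carried = rng.hypergeometric(dose, ploidy - dose, ploidy // 2, size=(n_progeny, 2))
    return carried.sum(axis=1) > 0


# Codon families whose third position is fully synonymous and whose first
# two positions admit no synonymous change: each codon contributes exactly
# one synonymous site under NG86 counting.
_FOURFOLD_FAMILIES = ("GG", "GC", "CC", "AC", "GT")
_NT = "ACGT"


def simulate_ortholog_pairs(
    n_pairs: int, n_codons: int, ks_true: float, seed: int
) -> list[tuple[str, str, str, str]]:
    """Simulate CDS pairs diverged only at synonymous sites.

    Third positions of fourfold-degenerate codons mutate with probability
    p = 3/4 (1 - exp(-4 d / 3)), so the Jukes-Cantor-corrected synonymous
    distance has expectation ``ks_true``. Returns (id_A, id_B, cds_A, cds_B).
    """
    if not 0 <= ks_true < 0.5:
        raise ValueError("ks_true outside [0, 0.5)")
    rng = np.random.default_rng(seed)
    p = 0.75 * (1.0 - math.exp(-4.0 * ks_true / 3.0))
    out = []
    fam = np.array([list(f) for f in _FOURFOLD_FAMILIES])
    for i in range(n_pairs):
        fi = rng.integers(0, len(_FOURFOLD_FAMILIES), size=n_codons)
        third_a = rng.integers(0, 4, size=n_codons)
        shift = np.where(rng.random(n_codons) < p, rng.integers(1, 4, size=n_codons), 0)
        third_b = (third_a + shift) % 4
        stems = fam[fi]
        cds_a = "".join(
            s0 + s1 + _NT[t] for (s0, s1), t in zip(stems, third_a)
        )
        cds_b = "".join(
            s0 + s1 + _NT[t] for (s0, s1), t in zip(stems, third_b)
        )
        out.append((f"orthoA_{i}", f"orthoB_{i}", cds_a, cds_b))
    return out


# ---------------------------------------------------------------------------
# Default fixture

DEFAULT_N_CHROM = 3
DEFAULT_CHROM_LEN = 200_000
DEFAULT_DIVERGENCE = 0.012
DEFAULT_READ_LEN = 15_000
DEFAULT_COVERAGE = 30.0
DEFAULT_PRIVATE_RATE = 0.01


def default_fixture_spec(chrom_len: int = DEFAULT_CHROM_LEN) -> DosageSpec:
    """The standard test genome: dosage classes 1-4, IBD groups, and one
    interspecific recombinant chromosome copy with a mid-chromosome
    breakpoint. Single-copy sequence dominates so the genome-wide median
    window depth corresponds to one copy, as in real partially inbred
    polyploids.
    """
    r = DEFAULT_PRIVATE_RATE
    g2 = CopySpec("A", ibd_group="g2", private_mutation_rate=r)
    g3 = CopySpec("B", ibd_group="g3", private_mutation_rate=r)
    g4 = CopySpec("B", ibd_group="g4", private_mutation_rate=r)
    return DosageSpec({
        0: [
            CopySpec("A", private_mutation_rate=r),
            CopySpec("B", private_mutation_rate=r),
            g2, g2,
        ],
        1: [
            CopySpec("A", private_mutation_rate=r),
            g3, g3, g3,
        ],
        2: [
            CopySpec("A", private_mutation_rate=r),
            CopySpec("A", breakpoints=(chrom_len // 2,), private_mutation_rate=r),
            g4, g4, g4, g4,
        ],
    })


def default_fixture(seed: int) -> tuple[ProgenitorPair, TruthSet, dict[str, str], list[PafRecord]]:
    """Progenitors, hybrid truth, reads and oracle PAF at the default scale."""
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    pair = simulate_progenitors(
        DEFAULT_N_CHROM, DEFAULT_CHROM_LEN, DEFAULT_DIVERGENCE, seed=s1
    )
    truth = build_hybrid_assembly(pair, default_fixture_spec(), seed=s2)
    reads, paf = simulate_reads(
        truth, DEFAULT_COVERAGE, DEFAULT_READ_LEN, error_rate=0.0, seed=s3
    )
    return pair, truth, reads, paf
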