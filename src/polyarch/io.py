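"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA goes through Biopython; PAF, BED and GFF3 are line-oriented TSV
dialects parsed here directly so that malformed input can be reported
with a ``file:line`` location, which the contract requires.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

logger = logging.getLogger("polyarch")

PathLike = Union[str, os.PathLike]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict.

    Sequences are stored uppercase; duplicate identifiers are an error;
    an empty file yields an empty dict with a logged warning.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA identifier {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: Mapping[str, str], path: PathLike, width: int = 60) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def softmask_bed(records: Mapping[str, str]) -> list[GenomicInterval]:
    """Runs of lowercase (soft-masked) sequence as BED intervals."""
    out = []
    for name, seq in records.items():
        start = None
        for i, c in enumerate(seq):
            if c.islower():
                if start is None:
                    start = i
            elif start is not None:
                out.append(GenomicInterval(name, start, i, name="softmask"))
                start = None
        if start is not None:
            out.append(GenomicInterval(name, start, len(seq), name="softmask"))
    return out


# ---------------------------------------------------------------------------
# PAF

@dataclass
class PafRecord:
    """One line of a PAF alignment (12 mandatory columns + optional tags)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def is_primary(self) -> bool:
        # tp:A:P marks a primary alignment; an untagged record is treated as
        # primary (one record per read); tp:A:S / tp:A:I are excluded.
        return self.tags.get("tp", "P") == "P"

    def to_line(self) -> str:
        cols = [
            self.qname, self.qlen, self.qstart, self.qend, self.strand,
            self.tname, self.tlen, self.tstart, self.tend,
            self.nmatch, self.alnlen, self.mapq,
        ]
        tagcols = [f"{k}:A:{v}" if k == "tp" else f"{k}:Z:{v}"
                   for k, v in self.tags.items()]
        return "\t".join(str(c) for c in cols + tagcols)


def _parse_paf_line(line: str, where: str) -> PafRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise ValueError(f"{where}: PAF line has {len(cols)} columns, expected >= 12")
    try:
        rec = PafRecord(
            qname=cols[0], qlen=int(cols[1]), qstart=int(cols[2]), qend=int(cols[3]),
            strand=cols[4],
            tname=cols[5], tlen=int(cols[6]), tstart=int(cols[7]), tend=int(cols[8]),
            nmatch=int(cols[9]), alnlen=int(cols[10]), mapq=int(cols[11]),
        )
    except ValueError as exc:
        raise ValueError(f"{where}: malformed PAF numeric field ({exc})") from None
    if rec.strand not in "+-":
        raise ValueError(f"{where}: invalid PAF strand {rec.strand!r}")
    for tag in cols[12:]:
        parts = tag.split(":", 2)
        if len(parts) != 3:
            raise ValueError(f"{where}: malformed PAF tag {tag!r}")
        rec.tags[parts[0]] = parts[2]
    return rec


def read_paf(path: PathLike) -> list[PafRecord]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.strip():
                out.append(_parse_paf_line(line, f"{path}:{i}"))
    return out


def write_paf(records: Iterable[PafRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3-BED6 into intervals (sorted order is the caller's concern)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{i}: BED line has fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ValueError(f"{path}:{i}: non-integer BED coordinates") from None
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score: Optional[float] = None
            if len(cols) > 4 and cols[4] != ".":
                try:
                    score = float(cols[4])
                except ValueError:
                    raise ValueError(f"{path}:{i}: non-numeric BED score") from None
            strand = cols[5] if len(cols) > 5 and cols[5] != "." else None
            try:
                out.append(GenomicInterval(cols[0], start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: {exc}") from None
    return out


def _fmt_score(score: Optional[float]) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return f"{score:.6g}"


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                "\t".join([
                    iv.chrom, str(iv.start), str(iv.end),
                    iv.name if iv.name is not None else ".",
                    _fmt_score(iv.score),
                    iv.strand if iv.strand is not None else ".",
                ]) + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(
    path: PathLike, feature_types: Sequence[str] = ("gene",)
) -> list[GenomicInterval]:
    """Extract features of the given types as 0-based half-open intervals.

    GFF3 is 1-based closed; conversion is ``(start-1, end)``. The feature
    name is the ID attribute when present.
    """
    wanted = set(feature_types)
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{i}: GFF3 line has {len(cols)} columns, expected 9")
            if cols[2] not in wanted:
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ValueError(f"{path}:{i}: non-integer GFF3 coordinates") from None
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            try:
                out.append(
                    GenomicInterval(
                        cols[0], start - 1, end,
                        name=attrs.get("ID"),
                        strand=cols[6] if cols[6] in "+-" else None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: {exc}") from None
    return out


# ---------------------------------------------------------------------------
# Tables and manifests

def read_pair_table(path: PathLike) -> list[tuple[str, str, str, str]]:
    """Ortholog pair table: id_A, id_B, progenitor_A, progenitor_B (TSV)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{i}: pair table needs at least 2 columns")
            prog_a = cols[2] if len(cols) > 2 else "A"
            prog_b = cols[3] if len(cols) > 3 else "B"
            out.append((cols[0], cols[1], prog_a, prog_b))
    return out


def sha256_of(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: PathLike,
    command: str,
    config: Mapping,
    inputs: Sequence[PathLike] = (),
) -> str:
    """Write a machine-readable run manifest (config + input checksums)."""
    manifest = {
        "command": command,
        "config": dict(config),
        "inputs": {str(p): sha256_of(p) for p in inputs},
    }
    os.makedirs(outdir, exist_ok=True)
    path = os.path.join(str(outdir), "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
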