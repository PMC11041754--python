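"""Pedigree and autopolyploid segregation expectations.

Wright path-counting inbreeding coefficients over a tabular pedigree,
the expected amount of exactly duplicated (IBD) sequence F x genome
size, and closed-form selfed-progeny segregation ratios for a marker at
a given dose in an autopolyploid under random bivalent pairing (no
double reduction). Ratios use exact rational arithmetic so that the
textbook 3:1 (simplex) and 143:1 (triplex in a 10-copy homology group)
values are reproduced literally.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Optional

UNKNOWN = "0"


class Pedigree:
    """Directed acyclic parent map; founders have no recorded parents."""

    def __init__(self, parents: dict[str, tuple[Optional[str], Optional[str]]]):
        self.parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
        for ind, (sire, dam) in parents.items():
            sire = None if sire in (None, UNKNOWN, "") else sire
            dam = None if dam in (None, UNKNOWN, "") else dam
            if (sire is None) != (dam is None):
                raise ValueError(
                    f"{ind}: non-founders need both parents recorded (use '0' for founders)"
                )
            self.parents[ind] = (sire, dam)
        for ind, (sire, dam) in self.parents.items():
            for p in (sire, dam):
                if p is not None and p not in self.parents:
                    self.parents[p] = (None, None)
        self._check_acyclic()

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        """3-column TSV: individual, sire, dam ('0' = unknown/founder)."""
        parents = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 3:
                    raise ValueError(f"{path}:{i}: pedigree rows need 3 columns")
                parents[cols[0]] = (cols[1], cols[2])
        return cls(parents)

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {ind: WHITE for ind in self.parents}

        def visit(node: str) -> None:
            colour[node] = GREY
            for p in self.parents[node]:
                if p is None:
                    continue
                if colour[p] == GREY:
                    raise ValueError(f"pedigree contains a cycle through {p!r}")
                if colour[p] == WHITE:
                    visit(p)
            colour[node] = BLACK

        for ind in list(self.parents):
            if colour[ind] == WHITE:
                visit(ind)

    def _ancestor_paths(self, start: str) -> list[tuple[str, ...]]:
        """Every upward path from ``start`` (inclusive) to each ancestor."""
        paths: list[tuple[str, ...]] = []

        def rec(node: str, path: tuple[str, ...]) -> None:
            paths.append(path)
            for p in self.parents[node]:
                if p is not None:
                    rec(p, path + (p,))

        rec(start, (start,))
        return paths


def inbreeding_coefficient(ped: Pedigree, individual: str) -> float:
    """Wright's path-counting inbreeding coefficient F.

    F = sum over common ancestors A and over pairs of ancestor paths
    (sire -> A, dam -> A) sharing no individual but A, of
    (1/2)^(n1 + n2 + 1) (1 + F_A). Founders have F = 0.
    """
    if individual not in ped.parents:
        raise ValueError(f"individual {individual!r} not in pedigree")

    @lru_cache(maxsize=None)
    def F(ind: str) -> float:
        sire, dam = ped.parents[ind]
        if sire is None or dam is None:
            return 0.0
        total = 0.0
        for p1 in ped._ancestor_paths(sire):
            for p2 in ped._ancestor_paths(dam):
                if p1[-1] != p2[-1]:
                    continue
                if set(p1) & set(p2) != {p1[-1]}:
                    continue
                n1, n2 = len(p1) - 1, len(p2) - 1
                total += 0.5 ** (n1 + n2 + 1) * (1.0 + F(p1[-1]))
        return total

    return F(individual)


def expected_identical_length(F: float, genome_size: float) -> float:
    """Expected exactly duplicated (IBD-collapsed) sequence, F x genome size."""
    if not 0.0 <= F <= 1.0:
        raise ValueError("inbreeding coefficient must lie in [0, 1]")
    if genome_size < 0:
        raise ValueError("genome size must be non-negative")
    return F * genome_size


@dataclass
class SegregationRatio:
    dose: int
    ploidy: int
    null_gamete_freq: Fraction     # gametes carrying no marker copy
    selfed_absence: Fraction       # q^2
    ratio: Optional[Fraction]      # presence : absence, as X in X:1; None
                                   # when every gamete carries the marker

    @property
    def ratio_str(self) -> str:
        r = self.ratio
        if r is None:
            return "all-present"
        if r.denominator == 1:
            return f"{r.numerator}:1"
        return f"{r.numerator}/{r.denominator}:1"


def segregation_ratio(dose: int, ploidy: int) -> SegregationRatio:
    """Selfed-progeny presence:absence ratio for a marker at ``dose``.

    Under random bivalent pairing a gamete is a uniform draw of
    ploidy/2 of the ploidy copies without replacement, so the
    null-gamete frequency is hypergeometric:
    q = C(ploidy - dose, ploidy/2) / C(ploidy, ploidy/2);
    selfed absence is q^2 and the ratio (1 - q^2)/q^2.
    """
    if ploidy <= 0 or ploidy % 2 != 0:
        raise ValueError("ploidy must be a positive even number")
    if not 0 <= dose <= ploidy:
        raise ValueError("dose must lie in [0, ploidy]")
    half = ploidy // 2
    q = Fraction(comb(ploidy - dose, half), comb(ploidy, half))
    q2 = q * q
    ratio = (1 - q2) / q2 if q2 > 0 else None
    return SegregationRatio(dose, ploidy, q, q2, ratio)


def enumerate_null_gamete_freq(dose: int, ploidy: int) -> Fraction:
    """Exhaustive-gamete oracle for the null-gamete frequency.

    Enumerates all C(ploidy, ploidy/2) gametes and counts those carrying
    none of the first ``dose`` copies. Exact, independent of the closed
    form; intended for cross-checks and small ploidy.
    """
    if ploidy <= 0 or ploidy % 2 != 0:
        raise ValueError("ploidy must be a positive even number")
    if not 0 <= dose <= ploidy:
        raise ValueError("dose must lie in [0, ploidy]")
    marker = set(range(dose))
    total = null = 0
    for gamete in itertools.combinations(range(ploidy), ploidy // 2):
        total += 1
        if not marker & set(gamete):
            null += 1
    return Fraction(null, total)
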