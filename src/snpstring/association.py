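"""Case-control association statistics for haplotypes and single SNPs.

Subjects are grouped by copies (0/1/2) of a target allele or haplotype.
Odds ratios are computed separately for heterozygous and homozygous
carriers with non-carriers as the reference class; significance uses the
1-df Pearson chi-square on the corresponding carrier-vs-non-carrier 2x2
table, without continuity correction.  Allelic frequencies, a weighted
Pearson correlation between two copy-number variables, and conditional
(carrier-excluded) re-analysis complete the toolkit.

A zero divisor anywhere yields NaN, rendered "na" in summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeCountTable",
    "AssociationResult",
    "genotype_counts",
    "odds_ratios",
    "chi_square_1df",
    "allelic_frequency",
    "status_correlation",
    "associate",
    "conditional_association",
]


@dataclass(frozen=True)
class GenotypeCountTable:
    """3x2 table of copy-class counts (0/1/2 copies x case/control)."""

    target: str
    cases: tuple[int, int, int]
    controls: tuple[int, int, int]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.cases + self.controls):
            raise ValueError("counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return sum(self.cases)

    @property
    def n_controls(self) -> int:
        return sum(self.controls)


def _copies(pair: tuple[str, str], target: str) -> int:
    return sum(1 for h in pair if h == target)


def genotype_counts(
    subjects: Mapping[str, tuple[str, str] | int | None],
    phenotype: Mapping[str, str],
    target: str,
) -> GenotypeCountTable:
    """Count 0/1/2-copy carriers of a target per phenotype group.

    ``subjects`` maps subject -> unordered haplotype pair (phased), or
    directly to a dosage code in {0,1,2} for single-SNP targets; None
    marks an unresolved subject, excluded from the table but counted.
    """
    cases = [0, 0, 0]
    controls = [0, 0, 0]
    n_excluded = 0
    for sid, value in subjects.items():
        if value is None:
            n_excluded += 1
            continue
        copies = value if isinstance(value, int) else _copies(value, target)
        group = phenotype[sid]
        if group == "case":
            cases[copies] += 1
        elif group == "control":
            controls[copies] += 1
        else:
            raise ValueError(f"unknown phenotype {group!r} for subject {sid!r}")
    return GenotypeCountTable(target, tuple(cases), tuple(controls), n_excluded)


def odds_ratios(table: GenotypeCountTable) -> tuple[float, float]:
    """Heterozygote and homozygote odds ratios vs non-carriers.

    OR_het = (case1/case0) / (ctrl1/ctrl0), OR_hom likewise with the
    2-copy class.  A zero divisor yields NaN ("na").
    """
    ca0, ca1, ca2 = table.cases
    co0, co1, co2 = table.controls

    def ratio(ca_k: int, co_k: int) -> float:
        if ca0 == 0 or co0 == 0 or co_k == 0:
            return math.nan
        return (ca_k / ca0) / (co_k / co0)

    return ratio(ca1, co1), ratio(ca2, co2)


def chi_square_1df(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square (1 df) on a 2x2 table, no continuity correction.

    Layout: a,b = case carrier/non-carrier; c,d = control
    carrier/non-carrier.  X^2 = N(ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)];
    NaN when any margin is zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    return n * (a * d - b * c) ** 2 / denom


def allelic_frequency(table: GenotypeCountTable) -> tuple[float, float]:
    """Allele frequency (count1 + 2*count2) / (2*total) per phenotype."""
    out = []
    for counts in (table.cases, table.controls):
        total = sum(counts)
        if total == 0:
            raise ValueError("empty phenotype group")
        out.append((counts[1] + 2 * counts[2]) / (2 * total))
    return tuple(out)


def status_correlation(table3x3: Sequence[Sequence[int]]) -> float:
    """Weighted Pearson correlation of two 0/1/2 copy-number variables.

    ``table3x3[i][j]`` counts subjects with i copies of one allele and j
    of the other.  Raises on zero variance in either margin.
    """
    t = np.asarray(table3x3, dtype=float)
    if t.shape != (3, 3) or (t < 0).any():
        raise ValueError("expected a non-negative 3x3 count table")
    n = t.sum()
    if n == 0:
        raise ValueError("empty table")
    i = np.arange(3)
    px = t.sum(axis=1) / n
    py = t.sum(axis=0) / n
    mx, my = px @ i, py @ i
    vx = px @ (i - mx) ** 2
    vy = py @ (i - my) ** 2
    if vx == 0 or vy == 0:
        raise ValueError("zero variance in a margin")
    cov = sum(
        t[x, y] * (x - mx) * (y - my) for x in range(3) for y in range(3)
    ) / n
    return cov / math.sqrt(vx * vy)


@dataclass(frozen=True)
class AssociationResult:
    """Carrier-category association statistics for one target."""

    table: GenotypeCountTable
    or_het: float
    or_hom: float
    chi2_het: float
    chi2_hom: float
    freq_cases: float
    freq_controls: float
    correlation: float | None = None

    @staticmethod
    def _fmt(x: float | None) -> str:
        if x is None:
            return ""
        return "na" if isinstance(x, float) and math.isnan(x) else f"{x:.2f}"

    def summary(self) -> str:
        t = self.table
        lines = [
            f"Target: {t.target}",
            f"  copies      cases  controls",
            f"  0-copies  {t.cases[0]:7d}  {t.controls[0]:8d}",
            f"  1-copy    {t.cases[1]:7d}  {t.controls[1]:8d}",
            f"  2-copies  {t.cases[2]:7d}  {t.controls[2]:8d}",
            f"  OR 1 allele   {self._fmt(self.or_het)}",
            f"  OR 2 alleles  {self._fmt(self.or_hom)}",
            f"  X2 (1 df) 1 allele   {self._fmt(self.chi2_het)}",
            f"  X2 (1 df) 2 alleles  {self._fmt(self.chi2_hom)}",
            f"  allelic frequency cases={self.freq_cases:.3f} controls={self.freq_controls:.3f}",
        ]
        if self.correlation is not None:
            lines.append(f"  reference-status correlation r={self.correlation:.3f}")
        if t.n_excluded:
            lines.append(f"  ({t.n_excluded} unresolved subjects excluded)")
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "target": self.table.target,
            "cases_0": self.table.cases[0],
            "cases_1": self.table.cases[1],
            "cases_2": self.table.cases[2],
            "controls_0": self.table.controls[0],
            "controls_1": self.table.controls[1],
            "controls_2": self.table.controls[2],
            "or_het": self.or_het,
            "or_hom": self.or_hom,
            "chi2_het": self.chi2_het,
            "chi2_hom": self.chi2_hom,
            "freq_cases": self.freq_cases,
            "freq_controls": self.freq_controls,
        }


def associate(table: GenotypeCountTable, correlation: float | None = None) -> AssociationResult:
    """Compute the full carrier-category statistics for one count table."""
    or_het, or_hom = odds_ratios(table)
    ca0, ca1, ca2 = table.cases
    co0, co1, co2 = table.controls
    chi2_het = chi_square_1df(ca1, ca0, co1, co0)
    chi2_hom = chi_square_1df(ca2, ca0, co2, co0)
    freq_cases, freq_controls = allelic_frequency(table)
    return AssociationResult(
        table, or_het, or_hom, chi2_het, chi2_hom, freq_cases, freq_controls, correlation
    )


def conditional_association(
    subjects: Mapping[str, tuple[str, str] | None],
    phenotype: Mapping[str, str],
    target: str,
    excluded: str,
) -> AssociationResult:
    """Re-test a target after removing all carriers of another haplotype.

    Exposes synthetic "protective" signals: a haplotype that merely
    co-occurs less often with a true risk haplotype loses its apparent
    effect once risk-haplotype carriers are excluded.  Excluding the
    target itself is a degenerate request and raises.
    """
    if excluded == target:
        raise ValueError("cannot condition a target on itself")
    kept = {
        sid: pair
        for sid, pair in subjects.items()
        if pair is None or excluded not in pair
    }
    if not any(pair is not None for pair in kept.values()):
        raise ValueError("no subjects remain after exclusion")
    return associate(genotype_counts(kept, phenotype, target))
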