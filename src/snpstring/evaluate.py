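"""Concordance between two phasings, per subject and along sliding windows.

A subject is concordant when the two unordered haplotype pairs are
identical; there is no partial or switch-error credit.  Subjects phased
by only one input are excluded from the denominator and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .phasing import Pair

__all__ = [
    "ConcordanceReport",
    "phasing_concordance",
    "sliding_concordance",
    "likelihood_compare",
]

Phasing = Mapping[str, Pair | None]


@dataclass(frozen=True)
class ConcordanceReport:
    """Per-subject and overall concordance of two phasings."""

    concordant: dict[str, bool]
    fraction: float
    n_compared: int
    n_only_a: int
    n_only_b: int


def _norm(pair: Pair) -> Pair:
    return pair if pair[0] <= pair[1] else (pair[1], pair[0])


def phasing_concordance(phasing_a: Phasing, phasing_b: Phasing) -> ConcordanceReport:
    """Fraction of commonly-phased subjects with identical unordered pairs."""
    resolved_a = {s for s, p in phasing_a.items() if p is not None}
    resolved_b = {s for s, p in phasing_b.items() if p is not None}
    common = resolved_a & resolved_b
    if not common:
        raise ValueError("no subjects phased by both inputs")
    flags = {
        s: _norm(phasing_a[s]) == _norm(phasing_b[s]) for s in sorted(common)
    }
    return ConcordanceReport(
        concordant=flags,
        fraction=sum(flags.values()) / len(flags),
        n_compared=len(flags),
        n_only_a=len(resolved_a - common),
        n_only_b=len(resolved_b - common),
    )


def sliding_concordance(
    phasing_a: Phasing,
    phasing_b: Phasing,
    window_length: int,
    step: int = 1,
) -> list[tuple[int, float]]:
    """Concordance profile over sliding windows of a multi-SNP span.

    Both phasings must carry full-span haplotypes of one common length.
    For each window start (0-based, stepped), pairs are restricted to the
    window and compared as unordered pairs.  Returns (start, fraction)
    points; identical inputs give a flat profile at 1.0.
    """
    lengths = {
        len(p[0])
        for ph in (phasing_a, phasing_b)
        for p in ph.values()
        if p is not None
    }
    if len(lengths) != 1:
        raise ValueError("phasings must share one haplotype span length")
    span = lengths.pop()
    if window_length > span:
        raise ValueError(f"window of {window_length} exceeds span of {span}")
    profile = []
    for start in range(0, span - window_length + 1, step):
        end = start + window_length
        a_win = {
            s: (p[0][start:end], p[1][start:end]) if p is not None else None
            for s, p in phasing_a.items()
        }
        b_win = {
            s: (p[0][start:end], p[1][start:end]) if p is not None else None
            for s, p in phasing_b.items()
        }
        profile.append((start, phasing_concordance(a_win, b_win).fraction))
    return profile


def likelihood_compare(
    pair_a: Pair,
    pair_b: Pair,
    frequencies: Mapping[str, float],
) -> float:
    """Likelihood ratio f(A1)f(A2) / f(B1)f(B2) of two candidate pairs.

    NaN when the denominator pair has a zero-frequency member; the ratio
    of (A,B) and (B,A) are reciprocals.
    """
    num = frequencies.get(pair_a[0], 0.0) * frequencies.get(pair_a[1], 0.0)
    den = frequencies.get(pair_b[0], 0.0) * frequencies.get(pair_b[1], 0.0)
    if den == 0.0:
        return math.nan
    return num / den
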