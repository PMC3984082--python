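"""Structural analyses of identified haplotype strings.

Families of related haplotypes are the connected components of the graph
joining strings at Hamming distance exactly 1 (single-SNP mutational
neighbours).  Homozygote counts give a phasing-independent frequency
estimate under Hardy-Weinberg equilibrium (f = sqrt(homozygote fraction)).
Adjacent phased windows are merged into longer haplotypes through an
overlapping bridge window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .phasing import Pair, het_count

__all__ = [
    "FamilyPartition",
    "WindowPhasing",
    "MergeOutcome",
    "hamming",
    "cluster_families",
    "freq_from_homozygotes",
    "merge_windows",
]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("strings differ in length")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class FamilyPartition:
    """Disjoint families of strings plus a distance-1 witness per member."""

    families: tuple[tuple[str, ...], ...]
    witnesses: Mapping[str, str | None]

    def family_of(self, s: str) -> tuple[str, ...]:
        for fam in self.families:
            if s in fam:
                return fam
        raise KeyError(s)

    def __len__(self) -> int:
        return len(self.families)


def cluster_families(strings: Iterable[str]) -> FamilyPartition:
    """Partition strings into Hamming-1 connected components.

    Families are ordered by their lexicographically smallest member and
    listed sorted; each non-singleton member gets its smallest distance-1
    neighbour as witness.
    """
    strs = sorted(set(strings))
    if len({len(s) for s in strs}) > 1:
        raise ValueError("strings differ in length")
    graph = nx.Graph()
    graph.add_nodes_from(strs)
    for i, a in enumerate(strs):
        for b in strs[i + 1 :]:
            if hamming(a, b) == 1:
                graph.add_edge(a, b)
    comps = sorted((tuple(sorted(c)) for c in nx.connected_components(graph)), key=lambda c: c[0])
    witnesses = {
        s: (min(graph.neighbors(s)) if graph.degree(s) else None) for s in strs
    }
    return FamilyPartition(families=tuple(comps), witnesses=witnesses)


def freq_from_homozygotes(vectors: Iterable[str]) -> dict[str, dict[str, float]]:
    """Estimate haplotype frequencies from homozygote counts.

    Under HWE a haplotype of frequency f is homozygous in a fraction f^2
    of subjects, so f is estimated as sqrt(count / n).  Only fully
    homozygous vectors (no heterozygous site) contribute.  Returns
    ``{string: {"count": c, "frequency": sqrt(c / n)}}``.
    """
    vectors = list(vectors)
    n = len(vectors)
    counts: dict[str, int] = {}
    for v in vectors:
        if het_count(v) == 0:
            h = "".join("1" if ch == "2" else "0" for ch in v)
            counts[h] = counts.get(h, 0) + 1
    return {
        h: {"count": c, "frequency": math.sqrt(c / n)}
        for h, c in sorted(counts.items())
    }


@dataclass
class WindowPhasing:
    """Per-subject unordered haplotype pairs for one SNP window.

    ``span`` is the (start, end) pair of 1-based manifest indices the
    window covers, inclusive.
    """

    window_id: str
    pairs: dict[str, Pair]
    span: tuple[int, int]

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


@dataclass(frozen=True)
class MergeOutcome:
    """Result of merging one subject across two windows."""

    subject_id: str
    status: str  # 'unique' | 'ambiguous' | 'inconsistent'
    merged: Pair | None = None


def _linkages(
    pair1: Pair, pair2: Pair, overlap: Pair, tail_len: int, head_len: int
) -> set[Pair]:
    """All merged pairs consistent with the bridge window.

    A bridge string links window-1 haplotype A to window-2 haplotype B
    when its first ``tail_len`` characters equal A's tail and its last
    ``head_len`` characters equal B's head.  A valid linkage uses both
    bridge strings to connect both members of each window pair exactly
    once.
    """
    a1, a2 = pair1
    merged: set[Pair] = set()

    def links(o: str, a: str, b: str) -> bool:
        return o[:tail_len] == a[-tail_len:] and o[tail_len : tail_len + head_len] == b[:head_len]

    for b_for_a1, b_for_a2 in ((pair2[0], pair2[1]), (pair2[1], pair2[0])):
        for o_for_a1, o_for_a2 in ((overlap[0], overlap[1]), (overlap[1], overlap[0])):
            if links(o_for_a1, a1, b_for_a1) and links(o_for_a2, a2, b_for_a2):
                m1, m2 = a1 + b_for_a1, a2 + b_for_a2
                merged.add((m1, m2) if m1 <= m2 else (m2, m1))
    return merged


def merge_windows(
    phasing1: WindowPhasing,
    phasing2: WindowPhasing,
    overlap_phasing: WindowPhasing,
) -> list[MergeOutcome]:
    """Link adjacent phased windows through an overlapping bridge window.

    The two windows must be contiguous and the bridge must cover the tail
    of window 1 and the head of window 2.  For each subject phased in all
    three inputs: exactly one consistent linkage emits the concatenated
    pair; several distinct linkages flag 'ambiguous'; none flag
    'inconsistent'.
    """
    if phasing2.span[0] != phasing1.span[1] + 1:
        raise ValueError("windows are not adjacent (window 2 must start right after window 1)")
    o_start, o_end = overlap_phasing.span
    if not (phasing1.span[0] < o_start <= phasing1.span[1]):
        raise ValueError("bridge window must start inside window 1")
    if not (phasing2.span[0] <= o_end <= phasing2.span[1]):
        raise ValueError("bridge window must end inside window 2")
    tail_len = phasing1.span[1] - o_start + 1
    head_len = o_end - phasing2.span[0] + 1
    if tail_len + head_len != overlap_phasing.length:
        raise ValueError("bridge span does not tile the two windows")

    outcomes = []
    common = sorted(
        set(phasing1.pairs) & set(phasing2.pairs) & set(overlap_phasing.pairs)
    )
    for sid in common:
        merged = _linkages(
            phasing1.pairs[sid],
            phasing2.pairs[sid],
            overlap_phasing.pairs[sid],
            tail_len,
            head_len,
        )
        if len(merged) == 1:
            outcomes.append(MergeOutcome(sid, "unique", next(iter(merged))))
        elif merged:
            outcomes.append(MergeOutcome(sid, "ambiguous"))
        else:
            outcomes.append(MergeOutcome(sid, "inconsistent"))
    return outcomes
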