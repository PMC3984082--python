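"""Deterministic, frequency-guided haplotype phasing over short SNP windows.

The algorithm extends Clark's haplotype subtraction idea.  A subject's
genotype over a window of L biallelic SNPs is an ordered ternary vector
(0/1/2 copies of the counted allele per site); a haplotype ("SNP-string")
is an ordered binary vector, and every genotype is the elementwise sum of
two haplotypes.  Phasing proceeds in deterministic, whole-cohort passes:

1.  Subjects that are fully homozygous, or heterozygous at exactly one
    site, have a forced haplotype pair; these seed the *unambiguous*
    inventory.
2.  Remaining genotypes are decomposed against the inventory.  A genotype
    whose only legitimate completion requires a single new string promotes
    that string to *identified* status; passes repeat to a fixed point or
    an iteration cap.
3.  Haplotype frequencies are estimated from non-conflicted decompositions
    only; genotypes explainable by several listed pairs ("conflicted") are
    resolved in favour of the pair maximizing the product of the two
    haplotype frequencies.
4.  A *complete* list (identified strings plus every legitimate novel
    complement) is pruned of never-selected strings until every remaining
    string is selected at least once, and subjects carrying strings seen in
    fewer than ``rare_threshold`` individuals are re-assessed against
    commoner alternatives.

Because every pass consumes the whole cohort through set/count semantics,
the output is independent of subject order.

Haplotypes and genotype vectors are plain strings over {'0','1'} and
{'0','1','2'} respectively; an unordered pair is a lexicographically
sorted 2-tuple.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AlgorithmConfig",
    "DecompositionRecord",
    "HaplotypeInventory",
    "PhasingResult",
    "complement",
    "enumerate_pairs_bruteforce",
    "find_unambiguous",
    "decompose",
    "iterate_identification",
    "estimate_frequencies",
    "resolve_conflicts",
    "build_complete_and_prune",
    "reassess_rare",
    "phase_vectors",
    "phase_cohort",
]

Pair = tuple[str, str]

# Classification labels
UNAMBIGUOUS = "unambiguous"
UNIQUE = "unique"
CONFLICTED = "conflicted"
INDET_UNIQUE = "indeterminate-unique"
INDET_CONFLICTED = "indeterminate-conflicted"
UNRESOLVED = "unresolved"

NON_CONFLICTED = frozenset({UNAMBIGUOUS, UNIQUE, INDET_UNIQUE})

# Inventory status labels
STATUS_UNAMBIGUOUS = "unambiguous"
STATUS_IDENTIFIED = "identified"
STATUS_NOVEL = "novel"


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunable parameters of the phasing procedure.

    iteration_cap
        Maximum number of promotion rounds during iterative identification
        (the initial decomposition is not counted).
    rare_threshold
        Strings selected in fewer than this many individuals trigger the
        final re-assessment pass (``m``).
    promotion_threshold
        A novel string carrying more than this share of the non-conflicted
        identifications is promoted to identified status (``tau``).
    seed
        Recorded for provenance; the phasing itself is deterministic and
        never draws random numbers.
    """

    iteration_cap: int = 4
    rare_threshold: int = 9
    promotion_threshold: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.iteration_cap < 1:
            raise ValueError("iteration_cap must be >= 1")
        if self.rare_threshold < 1:
            raise ValueError("rare_threshold must be >= 1")
        if not 0.0 < self.promotion_threshold < 1.0:
            raise ValueError("promotion_threshold must be in (0, 1)")


@dataclass
class HaplotypeInventory:
    """Evolving list of haplotype strings with provenance and frequencies.

    ``status`` maps each string to unambiguous / identified / novel.
    ``frequencies`` holds the estimates used for conflict resolution
    (from non-conflicted identifications; never-observed strings carry the
    nominal floor ``f0``).  ``n_observations`` is H, the number of
    haplotype observations behind the estimates (2 per non-conflicted
    subject), so ``f0 = 0.5 / H``.
    """

    status: dict[str, str] = field(default_factory=dict)
    frequencies: dict[str, float] = field(default_factory=dict)
    n_observations: int = 0

    @property
    def strings(self) -> frozenset[str]:
        return frozenset(self.status)

    @property
    def nominal_frequency(self) -> float:
        if self.n_observations <= 0:
            raise ValueError("no non-conflicted observations (H = 0)")
        return 0.5 / self.n_observations

    def frequency(self, hap: str) -> float:
        return self.frequencies.get(hap, 0.0)

    def identified_strings(self) -> frozenset[str]:
        return frozenset(
            h for h, s in self.status.items()
            if s in (STATUS_UNAMBIGUOUS, STATUS_IDENTIFIED)
        )


@dataclass
class DecompositionRecord:
    """Outcome of decomposing one subject's genotype vector."""

    subject_id: str
    vector: str
    classification: str
    candidates: tuple[Pair, ...] = ()
    selected: Pair | None = None
    likelihood: float | None = None

    def is_non_conflicted(self) -> bool:
        return self.classification in NON_CONFLICTED


@dataclass
class PhasingResult:
    """Phased cohort: per-subject records, final inventory, diagnostics."""

    records: list[DecompositionRecord]
    inventory: HaplotypeInventory
    final_frequencies: dict[str, float]
    classification_counts: dict[str, int]
    n_identification_iterations: int
    config: AlgorithmConfig

    @property
    def pairs(self) -> dict[str, Pair | None]:
        return {r.subject_id: r.selected for r in self.records}


def _check_lengths(vector: str, hap: str) -> None:
    if len(vector) != len(hap):
        raise ValueError(
            f"length mismatch: vector has {len(vector)} sites, "
            f"haplotype has {len(hap)}"
        )


def complement(vector: str, hap: str) -> str | None:
    """Subtract haplotype from genotype vector; None if not legitimate.

    The complement c = v - h is legitimate when every entry lies in {0,1},
    i.e. when h combined with c reproduces v exactly.
    """
    _check_lengths(vector, hap)
    out = []
    for v_ch, h_ch in zip(vector, hap):
        c = ord(v_ch) - ord(h_ch)
        if c not in (0, 1):
            return None
        out.append(chr(c + 48))
    return "".join(out)


def _sorted_pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def het_count(vector: str) -> int:
    return vector.count("1")


def enumerate_pairs_bruteforce(vector: str, max_het: int = 20) -> set[Pair]:
    """All unordered binary haplotype pairs summing to the vector.

    Exhaustive over the 2^k assignments of the k heterozygous sites
    (2^(k-1) unordered pairs for k >= 1, a single homozygous pair for
    k = 0).  Used as the independent oracle for the decomposition search;
    refuses k > ``max_het`` as a combinatorial guard.
    """
    k = het_count(vector)
    if k > max_het:
        raise ValueError(f"refusing brute-force enumeration for {k} > {max_het} het sites")
    het_idx = [i for i, ch in enumerate(vector) if ch == "1"]
    base = [ch if ch != "2" else "1" for ch in vector]
    for i in het_idx:
        base[i] = "0"
    pairs: set[Pair] = set()
    for bits in itertools.product("01", repeat=k):
        h1 = list(base)
        for i, b in zip(het_idx, bits):
            h1[i] = b
        h1s = "".join(h1)
        h2s = complement(vector, h1s)
        assert h2s is not None
        pairs.add(_sorted_pair(h1s, h2s))
    return pairs


def _forced_pair(vector: str) -> Pair:
    """The single possible pair of a homozygous or single-het vector."""
    pairs = enumerate_pairs_bruteforce(vector, max_het=1)
    assert len(pairs) == 1
    return next(iter(pairs))


def find_unambiguous(vectors: Iterable[str]) -> HaplotypeInventory:
    """Seed inventory from homozygotes and single-site heterozygotes.

    A vector of only 0s and 2s forces two copies of its halved string; a
    vector with exactly one 1 forces two strings differing only at that
    site.  Both members of each forced pair enter with unambiguous status.
    """
    inv = HaplotypeInventory()
    for v in sorted(set(vectors)):
        if het_count(v) <= 1:
            for h in _forced_pair(v):
                inv.status[h] = STATUS_UNAMBIGUOUS
    return inv


def _candidate_pairs(vector: str, strings: frozenset[str]) -> tuple[Pair, ...]:
    pairs = set()
    for h in strings:
        c = complement(vector, h)
        if c is not None and c in strings:
            pairs.add(_sorted_pair(h, c))
    return tuple(sorted(pairs))


def _novel_pairs(vector: str, strings: frozenset[str]) -> tuple[Pair, ...]:
    pairs = set()
    for h in strings:
        c = complement(vector, h)
        if c is not None and c not in strings:
            pairs.add(_sorted_pair(h, c))
    return tuple(sorted(pairs))


def decompose(
    vector: str,
    inventory: HaplotypeInventory | frozenset[str],
    subject_id: str = "",
) -> DecompositionRecord:
    """Classify one genotype vector against a haplotype list.

    Candidates are all unordered pairs of listed strings summing to the
    vector: one candidate is *unique*, several are *conflicted*.  With no
    listed pair, each listed string whose complement is legitimate but
    unlisted proposes a novel string: exactly one proposal is
    *indeterminate-unique*, several *indeterminate-conflicted*, none
    *unresolved*.
    """
    strings = inventory if isinstance(inventory, frozenset) else inventory.strings
    cands = _candidate_pairs(vector, strings)
    if cands:
        cls = UNIQUE if len(cands) == 1 else CONFLICTED
        return DecompositionRecord(subject_id, vector, cls, cands)
    novel = _novel_pairs(vector, strings)
    if not novel:
        return DecompositionRecord(subject_id, vector, UNRESOLVED)
    cls = INDET_UNIQUE if len(novel) == 1 else INDET_CONFLICTED
    return DecompositionRecord(subject_id, vector, cls, novel)


def iterate_identification(
    vectors: Iterable[str],
    config: AlgorithmConfig = AlgorithmConfig(),
) -> tuple[HaplotypeInventory, int]:
    """Grow the identified list by promoting unique novel complements.

    Each round decomposes every distinct vector against the current list
    and promotes, as a set, all strings discovered through
    indeterminate-unique decompositions.  Stops at a fixed point or after
    ``iteration_cap`` promotion rounds.  Returns the inventory and the
    number of rounds that added strings.
    """
    distinct = sorted(set(vectors))
    inv = find_unambiguous(distinct)
    rounds = 0
    for _ in range(config.iteration_cap):
        strings = inv.strings
        promoted: set[str] = set()
        for v in distinct:
            if het_count(v) <= 1:
                continue
            rec = decompose(v, strings)
            if rec.classification == INDET_UNIQUE:
                (pair,) = rec.candidates
                promoted.update(h for h in pair if h not in strings)
        if not promoted:
            break
        rounds += 1
        for h in sorted(promoted):
            inv.status[h] = STATUS_IDENTIFIED
    return inv, rounds


def _classify_with_unambiguous(vector: str, strings: frozenset[str], subject_id: str = "") -> DecompositionRecord:
    """Decompose, labelling homozygous/single-het vectors unambiguous."""
    if het_count(vector) <= 1:
        pair = _forced_pair(vector)
        return DecompositionRecord(subject_id, vector, UNAMBIGUOUS, (pair,), selected=pair)
    return decompose(vector, strings, subject_id)


def estimate_frequencies(
    records: Iterable[DecompositionRecord],
    inventory: HaplotypeInventory,
    weights: Mapping[str, int] | None = None,
) -> HaplotypeInventory:
    """Estimate haplotype frequencies from non-conflicted records.

    Counts both haplotypes of every unambiguous, unique or
    indeterminate-unique record (H = 2 x number of such records) and
    assigns each counted string frequency count/H.  Listed strings never
    seen non-conflicted receive the nominal floor f0 = 0.5/H, half the
    smallest observable frequency.  ``weights`` optionally multiplies each
    record (used internally to weight distinct vectors by the number of
    subjects sharing them).
    """
    counts: Counter[str] = Counter()
    n_records = 0
    for rec in records:
        if not rec.is_non_conflicted():
            continue
        w = 1 if weights is None else weights.get(rec.subject_id or rec.vector, 1)
        pair = rec.selected if rec.selected is not None else rec.candidates[0]
        for h in pair:
            counts[h] += w
        n_records += w
    if n_records == 0:
        raise ValueError("no non-conflicted records; cannot estimate frequencies (H = 0)")
    H = 2 * n_records
    f0 = 0.5 / H
    freqs = {h: counts[h] / H for h in counts}
    for h in inventory.status:
        freqs.setdefault(h, f0)
    inventory.frequencies = freqs
    inventory.n_observations = H
    return inventory


def pair_likelihood(pair: Pair, frequencies: Mapping[str, float]) -> float:
    """Product of the two haplotype frequencies (f^2 for homozygous pairs)."""
    return frequencies.get(pair[0], 0.0) * frequencies.get(pair[1], 0.0)


def resolve_conflicts(
    record: DecompositionRecord,
    inventory: HaplotypeInventory,
) -> DecompositionRecord:
    """Select the most likely candidate pair for a record.

    Maximizes the product of the two haplotype frequencies; exact ties
    break on the lexicographic order of the concatenated pair text, so the
    outcome is deterministic.
    """
    if not record.candidates:
        return record
    best = min(
        record.candidates,
        key=lambda p: (-pair_likelihood(p, inventory.frequencies), p[0] + p[1]),
    )
    return replace(
        record,
        selected=best,
        likelihood=pair_likelihood(best, inventory.frequencies),
    )


def _decompose_and_resolve(
    distinct: Sequence[str],
    inventory: HaplotypeInventory,
    counts: Mapping[str, int],
) -> dict[str, DecompositionRecord]:
    """One full pass: classify, re-estimate frequencies, resolve.

    Against a complete list an indeterminate decomposition would require a
    second never-implicated novel string, so it is reported unresolved.
    """
    strings = inventory.strings
    recs: dict[str, DecompositionRecord] = {}
    for v in distinct:
        rec = _classify_with_unambiguous(v, strings)
        if rec.classification in (INDET_UNIQUE, INDET_CONFLICTED):
            rec = replace(rec, classification=UNRESOLVED, candidates=(), selected=None)
        recs[v] = rec
    estimate_frequencies(
        (replace(r, subject_id=v) for v, r in recs.items()),
        inventory,
        weights=counts,
    )
    for v, rec in recs.items():
        if rec.classification in (UNIQUE, CONFLICTED):
            recs[v] = resolve_conflicts(rec, inventory)
        elif rec.classification == UNAMBIGUOUS:
            recs[v] = replace(
                rec, likelihood=pair_likelihood(rec.selected, inventory.frequencies)
            )
    return recs


def _prune_loop(
    distinct: Sequence[str],
    inventory: HaplotypeInventory,
    counts: Mapping[str, int],
) -> dict[str, DecompositionRecord]:
    """Iterate decompose/resolve, dropping never-selected strings."""
    while True:
        recs = _decompose_and_resolve(distinct, inventory, counts)
        selected: set[str] = set()
        for rec in recs.values():
            if rec.selected is not None:
                selected.update(rec.selected)
        never = set(inventory.status) - selected
        if not never:
            return recs
        for h in never:
            del inventory.status[h]
            inventory.frequencies.pop(h, None)


def build_complete_and_prune(
    vectors: Iterable[str],
    inventory: HaplotypeInventory,
    config: AlgorithmConfig = AlgorithmConfig(),
    counts: Mapping[str, int] | None = None,
) -> tuple[HaplotypeInventory, dict[str, DecompositionRecord]]:
    """Extend the identified list to a complete list and prune it.

    The complete list adds every legitimate novel complement proposed by
    indeterminate decompositions against the identified list.  Decompose /
    resolve passes then drop strings never selected, until every remaining
    string is selected at least once.  Novel strings carrying more than
    ``promotion_threshold`` of the non-conflicted identifications are
    promoted to identified status.
    """
    distinct = sorted(set(vectors))
    if counts is None:
        counts = Counter(vectors) or Counter(distinct)
    identified = inventory.strings
    for v in distinct:
        if het_count(v) <= 1:
            continue
        rec = decompose(v, identified)
        if rec.classification in (INDET_UNIQUE, INDET_CONFLICTED):
            for pair in rec.candidates:
                for h in pair:
                    if h not in inventory.status:
                        inventory.status[h] = STATUS_NOVEL
    recs = _prune_loop(distinct, inventory, counts)
    _promote_frequent_novels(inventory, config)
    return inventory, recs


def _promote_frequent_novels(inventory: HaplotypeInventory, config: AlgorithmConfig) -> None:
    f0 = inventory.nominal_frequency
    for h, status in inventory.status.items():
        if status == STATUS_NOVEL:
            freq = inventory.frequencies.get(h, 0.0)
            if freq > f0 and freq > config.promotion_threshold:
                inventory.status[h] = STATUS_IDENTIFIED


def reassess_rare(
    vectors: Iterable[str],
    inventory: HaplotypeInventory,
    recs: Mapping[str, DecompositionRecord],
    config: AlgorithmConfig = AlgorithmConfig(),
    counts: Mapping[str, int] | None = None,
) -> tuple[HaplotypeInventory, dict[str, DecompositionRecord]]:
    """Re-assess subjects carrying strings selected in few individuals.

    For each string selected in fewer than ``rare_threshold`` individuals,
    every legitimate alternative complement of the carrying vectors against
    identified strings joins the complete list, and the prune loop re-runs,
    until the list stabilizes.  With an expected count of 9 carriers a
    truly present haplotype would have been observed with probability
    1 - e^-9 > 99.9%, so commoner alternatives are preferred when they
    exist.
    """
    distinct = sorted(set(vectors))
    if counts is None:
        counts = Counter(vectors) or Counter(distinct)
    recs = dict(recs)
    for _ in range(max(config.iteration_cap, 4)):
        carrier_counts: Counter[str] = Counter()
        for v, rec in recs.items():
            if rec.selected is not None:
                for h in set(rec.selected):
                    carrier_counts[h] += counts.get(v, 1)
        rare = {h for h, n in carrier_counts.items() if n < config.rare_threshold}
        if not rare:
            break
        identified = inventory.identified_strings()
        additions: set[str] = set()
        for v, rec in recs.items():
            if rec.selected is None or not rare.intersection(rec.selected):
                continue
            for h in identified:
                c = complement(v, h)
                if c is not None and c not in inventory.status:
                    additions.add(c)
        if not additions:
            break
        before = inventory.strings
        for h in sorted(additions):
            inventory.status[h] = STATUS_NOVEL
        recs = _prune_loop(distinct, inventory, counts)
        if inventory.strings == before:
            break
    return inventory, recs


def phase_vectors(
    vectors: Sequence[str],
    subject_ids: Sequence[str] | None = None,
    config: AlgorithmConfig = AlgorithmConfig(),
) -> PhasingResult:
    """Phase a cohort of genotype vectors end to end.

    Runs unambiguous seeding, iterative identification, frequency
    estimation, complete-list construction with pruning, and the
    rare-carrier re-assessment.  All passes work on distinct vectors
    weighted by multiplicity, so output is independent of subject order.
    """
    if subject_ids is None:
        subject_ids = [f"S{i + 1}" for i in range(len(vectors))]
    if len(subject_ids) != len(vectors):
        raise ValueError("subject_ids and vectors differ in length")
    if not vectors:
        raise ValueError("no vectors to phase")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("vectors differ in length")

    counts = Counter(vectors)
    distinct = sorted(counts)

    inventory, n_rounds = iterate_identification(distinct, config)
    inventory, recs = build_complete_and_prune(distinct, inventory, config, counts)
    inventory, recs = reassess_rare(distinct, inventory, recs, config, counts)

    # Final reported frequencies come from all selected pairs.
    final_counts: Counter[str] = Counter()
    n_obs = 0
    for v, rec in recs.items():
        if rec.selected is not None:
            for h in rec.selected:
                final_counts[h] += counts[v]
            n_obs += 2 * counts[v]
    final_frequencies = (
        {h: c / n_obs for h, c in sorted(final_counts.items())} if n_obs else {}
    )

    records = [
        replace(recs[v], subject_id=sid)
        for sid, v in zip(subject_ids, vectors)
    ]
    cls_counts = Counter(r.classification for r in records)
    return PhasingResult(
        records=records,
        inventory=inventory,
        final_frequencies=final_frequencies,
        classification_counts=dict(cls_counts),
        n_identification_iterations=n_rounds,
        config=config,
    )


def phase_cohort(matrix, manifest=None, config: AlgorithmConfig = AlgorithmConfig()):
    """Phase a validated genotype matrix (see :mod:`snpstring.genotype_io`).

    Orients codes to the minor allele in controls when phenotypes are
    available, builds subject vectors (excluding subjects with missing
    calls), and runs :func:`phase_vectors`.  Returns the
    :class:`PhasingResult` together with the exclusion report.
    """
    from . import genotype_io

    if manifest is not None and matrix.phenotype is not None and (matrix.phenotype == "control").any():
        matrix, manifest = genotype_io.orient_to_minor_allele(matrix, manifest)
    subject_vectors, excluded = genotype_io.build_subject_vectors(matrix)
    result = phase_vectors(
        [sv.codes for sv in subject_vectors],
        [sv.subject_id for sv in subject_vectors],
        config,
    )
    return result, excluded
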