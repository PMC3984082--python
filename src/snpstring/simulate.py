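"""Synthetic case-control cohorts with known haplotype phase.

Controls are independent Hardy-Weinberg draws of two haplotypes from a
fixed pool.  Cases are drawn from the same pool by rejection against
genotype relative risks for a designated risk haplotype: geometric
weights (1, w, w^2) for 0/1/2 copies (allelic / co-dominant, which keeps
cases in HWE), or recessive weights (1, 1, w_hom).  Ground-truth
diplotypes are retained for every subject so downstream phasing can be
scored exactly; missing data are injected per call after the truth is
fixed.

The default pool is the identified-haplotype frequency spectrum of the
HLA-DRB1 window in a published northern-European MS case-control cohort
(control arm, non-conflicted identifications), with the DRB1*1501-tagging
haplotype as the risk allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SnpManifest

__all__ = [
    "SimulationSpec",
    "SimulatedCohort",
    "DRB1_CONTROL_POOL",
    "DRB1_RISK_HAPLOTYPE",
    "drb1_spec",
    "simulate_cohort",
    "inject_missing",
    "poisson_detection_prob",
]

# Control-arm haplotype frequency spectrum of the DRB1 window
# (non-conflicted identifications; percentages normalized to sum to 1).
_DRB1_CONTROL_PCT = {
    "00000000000": 10,  # a1
    "01101100000": 13,  # a2 (tags DRB1*1501)
    "10000100000": 22,  # a3
    "01011000000": 10,  # a4
    "01010000000": 1,   # a5
    "10000011111": 2,   # a6
    "10000011110": 16,  # a7
    "01111000000": 6,   # a8
    "10011100000": 2,   # a9
    "01001000000": 1,   # a11
    "01111001110": 2,   # a13
    "10000010010": 1,   # a19
    "10000010000": 1,   # a20
    "10000011101": 9,   # a21
    "00000011101": 2,   # a22
}
_TOTAL = sum(_DRB1_CONTROL_PCT.values())
DRB1_CONTROL_POOL: dict[str, float] = {
    h: p / _TOTAL for h, p in _DRB1_CONTROL_PCT.items()
}
DRB1_RISK_HAPLOTYPE = "01101100000"  # a2


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic cohort.

    ``risk_model`` is 'geometric' (weights 1, w, w^2) or 'recessive'
    (weights 1, 1, w); ``w = 1`` gives a null cohort where both arms are
    plain HWE draws from the pool.
    """

    pool: Mapping[str, float]
    n_cases: int
    n_controls: int
    risk_haplotype: str | None = None
    risk_model: str = "geometric"
    w: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.pool.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool frequencies sum to {total}, not 1")
        if any(f <= 0 for f in self.pool.values()):
            raise ValueError("pool frequencies must be positive")
        if len({len(h) for h in self.pool}) > 1:
            raise ValueError("pool haplotypes differ in length")
        if self.risk_model not in ("geometric", "recessive"):
            raise ValueError(f"unknown risk model {self.risk_model!r}")
        if self.w <= 0:
            raise ValueError("w must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")
        if self.risk_haplotype is not None and self.risk_haplotype not in self.pool:
            raise ValueError("risk haplotype not in pool")

    def weights(self) -> tuple[float, float, float]:
        """Genotype relative risks for 0/1/2 copies of the risk haplotype."""
        if self.risk_model == "geometric":
            return (1.0, self.w, self.w**2)
        return (1.0, 1.0, self.w)


@dataclass
class SimulatedCohort:
    """Genotype matrix with phenotypes and ground-truth diplotypes."""

    matrix: GenotypeMatrix
    manifest: SnpManifest
    truth: dict[str, tuple[str, str]]
    spec: SimulationSpec


def drb1_spec(
    n_cases: int = 975,
    n_controls: int = 882,
    w: float = 3.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SimulationSpec:
    """Study-like spec: DRB1 control pool, a2 risk haplotype, geometric w."""
    return SimulationSpec(
        pool=DRB1_CONTROL_POOL,
        n_cases=n_cases,
        n_controls=n_controls,
        risk_haplotype=DRB1_RISK_HAPLOTYPE,
        risk_model="geometric",
        w=w,
        missing_rate=missing_rate,
        seed=seed,
    )


def _draw_pairs(
    rng: np.random.Generator,
    haps: Sequence[str],
    probs: np.ndarray,
    n: int,
) -> list[tuple[str, str]]:
    idx = rng.choice(len(haps), size=(n, 2), p=probs)
    return [tuple(sorted((haps[i], haps[j]))) for i, j in idx]


def _draw_case_pairs(
    rng: np.random.Generator,
    haps: Sequence[str],
    probs: np.ndarray,
    n: int,
    risk: str | None,
    weights: tuple[float, float, float],
) -> list[tuple[str, str]]:
    """Rejection-sample case diplotypes against genotype relative risks."""
    if risk is None or weights == (1.0, 1.0, 1.0):
        return _draw_pairs(rng, haps, probs, n)
    wmax = max(weights)
    out: list[tuple[str, str]] = []
    while len(out) < n:
        batch = max(n - len(out), 64)
        idx = rng.choice(len(haps), size=(batch, 2), p=probs)
        u = rng.random(batch)
        for (i, j), ui in zip(idx, u):
            pair = tuple(sorted((haps[i], haps[j])))
            copies = (pair[0] == risk) + (pair[1] == risk)
            if ui * wmax < weights[copies]:
                out.append(pair)
                if len(out) == n:
                    break
    return out


def _synthetic_manifest(length: int) -> SnpManifest:
    table = pd.DataFrame(
        {
            "label": [f"n{i + 1}" for i in range(length)],
            "rsid": [f"rs{1000 + i}" for i in range(length)],
            "chromosome": ["1"] * length,
            "position": [1000 * (i + 1) for i in range(length)],
            "counted_allele": ["A"] * length,
            "other_allele": ["G"] * length,
        }
    )
    return SnpManifest(table)


def simulate_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Draw a phased cohort under the spec; fully determined by the seed.

    Sub-streams for controls, cases and missing-data injection are spawned
    deterministically from the seed so each stage is independently
    reproducible.
    """
    ss = np.random.SeedSequence(spec.seed)
    control_rng, case_rng, missing_rng = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )
    haps = sorted(spec.pool)
    probs = np.array([spec.pool[h] for h in haps])
    probs = probs / probs.sum()

    control_pairs = _draw_pairs(control_rng, haps, probs, spec.n_controls)
    case_pairs = _draw_case_pairs(
        case_rng, haps, probs, spec.n_cases, spec.risk_haplotype, spec.weights()
    )

    ids, phen, truth, rows = [], [], {}, []
    for k, pair in enumerate(case_pairs):
        sid = f"case{k + 1}"
        ids.append(sid)
        phen.append("case")
        truth[sid] = pair
        rows.append([int(a) + int(b) for a, b in zip(*pair)])
    for k, pair in enumerate(control_pairs):
        sid = f"ctrl{k + 1}"
        ids.append(sid)
        phen.append("control")
        truth[sid] = pair
        rows.append([int(a) + int(b) for a, b in zip(*pair)])

    length = len(haps[0])
    manifest = _synthetic_manifest(length)
    codes = pd.DataFrame(
        rows, index=pd.Index(ids, name="subject_id"), columns=manifest.rsids, dtype="Int64"
    )
    matrix = GenotypeMatrix(codes=codes, phenotype=pd.Series(phen, index=codes.index, name="phenotype"))
    cohort = SimulatedCohort(matrix=matrix, manifest=manifest, truth=truth, spec=spec)
    if spec.missing_rate > 0:
        cohort = inject_missing(cohort, spec.missing_rate, rng=missing_rng)
    return cohort


def inject_missing(
    cohort: SimulatedCohort,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Mask each genotype call independently with the given probability.

    Ground truth is retained; rate 0 is the identity, rate -> 1 leaves no
    constructible vectors.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return cohort
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = cohort.matrix.codes.copy()
    mask = rng.random(codes.shape) < rate
    codes = codes.mask(pd.DataFrame(mask, index=codes.index, columns=codes.columns))
    matrix = GenotypeMatrix(codes=codes, phenotype=cohort.matrix.phenotype)
    return SimulatedCohort(
        matrix=matrix, manifest=cohort.manifest, truth=cohort.truth, spec=cohort.spec
    )


def poisson_detection_prob(lam: float) -> float:
    """P(at least one observation) = 1 - exp(-lambda) for a Poisson count.

    Rationale for the rare-carrier re-assessment threshold: a haplotype
    expected in 9 carriers is seen at least once with probability
    1 - e^-9 > 99.9%.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return 1.0 - math.exp(-lam)
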