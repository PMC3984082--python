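"""Model/Results interface over the SNP-string phasing engine.

`SnpStringModel` holds validated data (genotype matrix, SNP manifest,
algorithm configuration); `fit()` runs the deterministic phasing passes
and returns a `PhasingResults` object carrying per-subject diplotype
assignments, the haplotype inventory with frequency estimates, and
diagnostics, with `summary()`, family clustering, association testing and
TSV/VCF export hanging off it.

Example
-------
>>> from snpstring import SnpStringModel, simulate
>>> cohort = simulate.simulate_cohort(simulate.drb1_spec(seed=7))
>>> res = SnpStringModel(cohort.matrix, cohort.manifest).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import association as assoc
from . import evaluate as ev
from . import genotype_io as gio
from . import structure
from .phasing import (
    AlgorithmConfig,
    DecompositionRecord,
    HaplotypeInventory,
    Pair,
    PhasingResult,
    phase_vectors,
)

__all__ = ["SnpStringModel", "PhasingResults"]


class SnpStringModel:
    """Frequency-guided haplotype phasing model for one SNP window.

    Parameters
    ----------
    matrix
        Validated :class:`~snpstring.genotype_io.GenotypeMatrix`.
    manifest
        Optional :class:`~snpstring.genotype_io.SnpManifest`; required for
        allele orientation and VCF export.
    config
        :class:`~snpstring.phasing.AlgorithmConfig` (iteration cap, rare
        threshold m, promotion threshold tau).
    orient
        When True (default) and controls are present, codes are flipped so
        every SNP counts its minor allele in controls before phasing.
    """

    def __init__(
        self,
        matrix: gio.GenotypeMatrix,
        manifest: gio.SnpManifest | None = None,
        config: AlgorithmConfig = AlgorithmConfig(),
        orient: bool = True,
    ):
        self.config = config
        self.manifest = manifest
        if (
            orient
            and manifest is not None
            and (matrix.phenotype == "control").any()
        ):
            matrix, self.manifest = gio.orient_to_minor_allele(matrix, manifest)
        self.matrix = matrix

    @classmethod
    def from_dataframe(
        cls,
        codes: pd.DataFrame,
        phenotype: pd.Series | Mapping[str, str],
        manifest: gio.SnpManifest | None = None,
        **kwargs,
    ) -> "SnpStringModel":
        """Build from a subjects x rsIDs dosage DataFrame (<NA> = missing)."""
        phen = pd.Series(phenotype, name="phenotype").reindex(codes.index)
        matrix = gio.GenotypeMatrix(codes=codes.astype("Int64"), phenotype=phen)
        return cls(matrix, manifest, **kwargs)

    @classmethod
    def from_files(cls, genotypes, manifest, **kwargs) -> "SnpStringModel":
        """Build from genotype TSV + manifest TSV paths."""
        matrix, mani = gio.read_genotypes(genotypes, manifest)
        return cls(matrix, mani, **kwargs)

    def fit(self) -> "PhasingResults":
        vectors, excluded = gio.build_subject_vectors(self.matrix)
        result = phase_vectors(
            [sv.codes for sv in vectors],
            [sv.subject_id for sv in vectors],
            self.config,
        )
        return PhasingResults(self, result, excluded)


@dataclass
class PhasingResults:
    """Fitted phasing: assignments, inventory, diagnostics, reporting."""

    model: SnpStringModel
    result: PhasingResult
    excluded_subjects: list[str]

    # -- assignments ----------------------------------------------------
    @property
    def pairs(self) -> dict[str, Pair | None]:
        """Subject -> unordered haplotype pair (None when unresolved)."""
        return self.result.pairs

    @property
    def records(self) -> list[DecompositionRecord]:
        return self.result.records

    @property
    def inventory(self) -> HaplotypeInventory:
        return self.result.inventory

    def frequencies(self) -> pd.DataFrame:
        """Inventory with status, non-conflicted and final frequencies."""
        inv = self.inventory
        rows = [
            {
                "string": h,
                "status": inv.status[h],
                "freq_nonconflicted": inv.frequencies.get(h, 0.0),
                "freq_final": self.result.final_frequencies.get(h, 0.0),
            }
            for h in sorted(inv.status)
        ]
        return pd.DataFrame(rows).sort_values(
            "freq_final", ascending=False, kind="stable"
        ).reset_index(drop=True)

    # -- downstream analyses -------------------------------------------
    def families(self) -> structure.FamilyPartition:
        """Hamming-1 families of the identified strings."""
        return structure.cluster_families(self.inventory.identified_strings())

    def association(self, target: str) -> assoc.AssociationResult:
        """Carrier-category case-control statistics for one haplotype."""
        phen = self.model.matrix.phenotype.to_dict()
        table = assoc.genotype_counts(self.pairs, phen, target)
        return assoc.associate(table)

    def conditional_association(self, target: str, excluded: str) -> assoc.AssociationResult:
        phen = self.model.matrix.phenotype.to_dict()
        return assoc.conditional_association(self.pairs, phen, target, excluded)

    def concordance_with(self, other: Mapping[str, Pair | None]) -> ev.ConcordanceReport:
        """Per-subject concordance against another phasing (e.g. truth)."""
        return ev.phasing_concordance(self.pairs, other)

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        res = self.result
        inv = self.inventory
        n_total = len(res.records) + len(self.excluded_subjects)
        status_counts: dict[str, int] = {}
        for s in inv.status.values():
            status_counts[s] = status_counts.get(s, 0) + 1
        lines = [
            "SNP-string phasing results",
            "==========================",
            f"subjects:             {n_total}",
            f"  phased:             {len(res.records)}",
            f"  excluded (missing): {len(self.excluded_subjects)}",
            f"identification rounds: {res.n_identification_iterations}",
            "classification counts:",
        ]
        for cls in (
            "unambiguous",
            "unique",
            "conflicted",
            "unresolved",
        ):
            if cls in res.classification_counts:
                lines.append(f"  {cls:<12} {res.classification_counts[cls]}")
        lines.append(
            "inventory: "
            + ", ".join(f"{n} {s}" for s, n in sorted(status_counts.items()))
            + f" (H = {inv.n_observations}, f0 = {inv.nominal_frequency:.2e})"
        )
        lines.append("top haplotypes (final frequency):")
        freq = self.frequencies().head(8)
        for _, row in freq.iterrows():
            lines.append(
                f"  {row['string']}  {row['freq_final']:6.3f}  ({row['status']})"
            )
        lines.append(
            f"config: iteration_cap={res.config.iteration_cap}, "
            f"m={res.config.rare_threshold}, tau={res.config.promotion_threshold}"
        )
        return "\n".join(lines)

    def save(self, destination) -> tuple:
        """Write phasing.tsv + inventory.tsv into a directory."""
        return gio.write_phasing(self.result, destination)
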