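"""Genotype matrix / SNP manifest I/O and subject-vector construction.

Formats
-------
Genotype TSV
    Header ``subject_id<TAB>phenotype<TAB><rsID_1>...<rsID_L>``; one row
    per subject with allele-dosage codes 0/1/2 and ``.`` for missing.
Manifest TSV
    Columns ``label  rsid  chromosome  position  counted_allele``
    (optionally ``other_allele``); one row per SNP, positions 1-based and
    strictly increasing within the window.
VCF
    Unphased biallelic records read via pysam; the dosage code counts the
    ALT allele.  A phased writer emits ``|``-separated genotypes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .phasing import PhasingResult

__all__ = [
    "SnpManifest",
    "GenotypeMatrix",
    "SubjectVector",
    "read_genotypes",
    "read_genotype_tsv",
    "read_manifest_tsv",
    "read_vcf",
    "orient_to_minor_allele",
    "build_subject_vectors",
    "write_phasing",
    "read_phasing",
    "write_phased_vcf",
]

_VALID_BASES = frozenset("ACGT")
_PHENOTYPES = frozenset({"case", "control"})


@dataclass(frozen=True)
class SnpManifest:
    """Per-SNP records for one genomic window."""

    table: pd.DataFrame  # columns: label, rsid, chromosome, position, counted_allele[, other_allele]

    def __post_init__(self) -> None:
        required = {"label", "rsid", "chromosome", "position", "counted_allele"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        pos = self.table["position"].to_numpy()
        by_chrom = self.table.groupby("chromosome", sort=False)["position"]
        if not all(g.is_monotonic_increasing and g.is_unique for _, g in by_chrom):
            raise ValueError("manifest positions must be strictly increasing")
        bad = ~self.table["counted_allele"].isin(list(_VALID_BASES))
        if bad.any():
            raise ValueError(
                f"illegal counted_allele values: {sorted(self.table.loc[bad, 'counted_allele'])}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()


@dataclass
class GenotypeMatrix:
    """Allele-dosage codes for N subjects x L SNPs, with phenotypes.

    ``codes`` is a subjects x rsIDs DataFrame of nullable integers in
    {0, 1, 2} with <NA> marking missing calls; ``phenotype`` is a Series
    of 'case' / 'control' indexed by subject.
    """

    codes: pd.DataFrame
    phenotype: pd.Series

    def __post_init__(self) -> None:
        if self.codes.index.has_duplicates:
            dups = self.codes.index[self.codes.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject IDs: {dups}")
        vals = self.codes.to_numpy(dtype="float64", na_value=np.nan)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = sorted(set(vals[~ok].tolist()))
            raise ValueError(f"illegal genotype codes: {bad}")
        if not self.phenotype.index.equals(self.codes.index):
            raise ValueError("phenotype must be defined for every subject")
        unknown = set(self.phenotype.unique()) - _PHENOTYPES
        if unknown:
            raise ValueError(f"unknown phenotype labels: {sorted(unknown)}")

    @property
    def subjects(self) -> list[str]:
        return self.codes.index.tolist()

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]


@dataclass(frozen=True)
class SubjectVector:
    """One subject's complete ternary dosage vector over the window."""

    subject_id: str
    codes: str

    @property
    def het_sites(self) -> int:
        return self.codes.count("1")


def read_manifest_tsv(source) -> SnpManifest:
    table = pd.read_csv(source, sep="\t", dtype={"chromosome": str})
    return SnpManifest(table)


def read_genotype_tsv(source) -> GenotypeMatrix:
    df = pd.read_csv(source, sep="\t", dtype=str)
    if df.columns[0] != "subject_id" or df.columns[1] != "phenotype":
        raise ValueError("genotype TSV must start with subject_id and phenotype columns")
    df = df.set_index("subject_id")
    phenotype = df["phenotype"]
    codes = df.drop(columns="phenotype").replace(".", pd.NA)
    try:
        codes = codes.astype("Int64")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"illegal genotype codes in {source}: {exc}") from exc
    return GenotypeMatrix(codes=codes, phenotype=phenotype)


def read_genotypes(matrix_source, manifest_source) -> tuple[GenotypeMatrix, SnpManifest]:
    """Read and cross-validate a genotype matrix and its SNP manifest."""
    matrix = read_genotype_tsv(matrix_source)
    manifest = read_manifest_tsv(manifest_source)
    if matrix.n_snps != len(manifest):
        raise ValueError(
            f"matrix has {matrix.n_snps} SNP columns but manifest lists {len(manifest)}"
        )
    if matrix.codes.columns.tolist() != manifest.rsids:
        raise ValueError("matrix column rsIDs do not match manifest rsIDs (order matters)")
    return matrix, manifest


def read_vcf(path, phenotypes: pd.Series | dict) -> tuple[GenotypeMatrix, SnpManifest]:
    """Build matrix + manifest from an unphased biallelic VCF.

    The counted allele is ALT; a genotype's code is its ALT-allele count.
    Any partial or missing call becomes <NA>.  Multi-allelic records are
    rejected.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        rows = []
        code_cols: dict[str, list] = {}
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic or ALT-less record at {rec.chrom}:{rec.pos}; "
                    "only biallelic SNPs are supported"
                )
            rsid = rec.id or f"{rec.chrom}:{rec.pos}"
            rows.append(
                {
                    "label": f"n{len(rows) + 1}",
                    "rsid": rsid,
                    "chromosome": str(rec.chrom),
                    "position": rec.pos,
                    "counted_allele": rec.alts[0],
                    "other_allele": rec.ref,
                }
            )
            col = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt) or len(gt) != 2:
                    col.append(pd.NA)
                else:
                    col.append(sum(1 for a in gt if a == 1))
            code_cols[rsid] = col
    manifest = SnpManifest(pd.DataFrame(rows))
    codes = pd.DataFrame(code_cols, index=pd.Index(samples, name="subject_id"), dtype="Int64")
    phenotype = pd.Series(phenotypes, name="phenotype").reindex(codes.index)
    if phenotype.isna().any():
        raise ValueError("phenotype missing for some VCF samples")
    return GenotypeMatrix(codes=codes, phenotype=phenotype), manifest


def orient_to_minor_allele(
    matrix: GenotypeMatrix,
    manifest: SnpManifest,
    controls_only: bool = True,
) -> tuple[GenotypeMatrix, SnpManifest]:
    """Flip codes so each SNP counts its minor allele (in controls).

    A SNP whose counted-allele frequency exceeds 0.5 in the reference
    group has codes complemented (c -> 2 - c) and its manifest annotation
    swapped.  Frequency exactly 0.5 keeps the original orientation.  The
    operation is an involution on the SNPs it flips.
    """
    if controls_only:
        mask = matrix.phenotype == "control"
        if not mask.any():
            raise ValueError("no control subjects available for allele orientation")
        ref = matrix.codes.loc[mask]
    else:
        ref = matrix.codes
    counts = ref.sum(skipna=True)
    n_called = ref.notna().sum()
    freq = counts / (2 * n_called)
    flip = (freq > 0.5).fillna(False).to_numpy()

    codes = matrix.codes.copy()
    flip_cols = codes.columns[flip]
    for col in flip_cols:
        codes[col] = 2 - codes[col]
    table = manifest.table.copy()
    if "flipped" not in table.columns:
        table["flipped"] = False
    table.loc[flip, "flipped"] = ~table.loc[flip, "flipped"].astype(bool)
    if "other_allele" in table.columns:
        cur = table.loc[flip, "counted_allele"].copy()
        table.loc[flip, "counted_allele"] = table.loc[flip, "other_allele"]
        table.loc[flip, "other_allele"] = cur
    return (
        GenotypeMatrix(codes=codes, phenotype=matrix.phenotype),
        SnpManifest(table),
    )


def build_subject_vectors(
    matrix: GenotypeMatrix,
) -> tuple[list[SubjectVector], list[str]]:
    """Turn complete rows into ternary vectors; report excluded subjects.

    Subjects with one or more missing calls in the window cannot have a
    vector constructed and are listed (never silently dropped).
    """
    vectors: list[SubjectVector] = []
    excluded: list[str] = []
    arr = matrix.codes.to_numpy(dtype="float64", na_value=np.nan)
    for sid, row in zip(matrix.subjects, arr):
        if np.isnan(row).any():
            excluded.append(sid)
        else:
            vectors.append(SubjectVector(sid, "".join(str(int(c)) for c in row)))
    return vectors, excluded


def write_phasing(result: PhasingResult, destination) -> tuple[Path, Path]:
    """Write per-subject assignments and the haplotype inventory as TSV.

    Returns (subjects_path, inventory_path).  ``destination`` is a
    directory; files are ``phasing.tsv`` and ``inventory.tsv``.
    Unresolved subjects keep empty haplotype fields.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    subj_path = dest / "phasing.tsv"
    inv_path = dest / "inventory.tsv"

    rows = []
    for rec in result.records:
        h1, h2 = rec.selected if rec.selected is not None else ("", "")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "haplotype1": h1,
                "haplotype2": h2,
                "classification": rec.classification,
                "likelihood": "" if rec.likelihood is None else repr(rec.likelihood),
            }
        )
    pd.DataFrame(rows).to_csv(subj_path, sep="\t", index=False)

    inv = result.inventory
    inv_rows = [
        {
            "string": h,
            "status": inv.status[h],
            "frequency_nonconflicted": repr(inv.frequencies.get(h, 0.0)),
            "frequency_final": repr(result.final_frequencies.get(h, 0.0)),
        }
        for h in sorted(inv.status)
    ]
    pd.DataFrame(inv_rows).to_csv(inv_path, sep="\t", index=False)
    return subj_path, inv_path


def read_phasing(source) -> dict[str, tuple[str, str] | None]:
    """Read a per-subject phasing TSV back into subject -> pair."""
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    out: dict[str, tuple[str, str] | None] = {}
    for _, row in df.iterrows():
        if row["haplotype1"] == "" or row["haplotype2"] == "":
            out[row["subject_id"]] = None
        else:
            pair = (row["haplotype1"], row["haplotype2"])
            out[row["subject_id"]] = tuple(sorted(pair))  # type: ignore[assignment]
    return out


def write_phased_vcf(
    result: PhasingResult,
    manifest: SnpManifest,
    path,
) -> Path:
    """Emit phased genotypes as a VCF with '|'-separated GT fields.

    REF is the counted allele and ALT the other allele when known (else
    'N'); allele index 0 marks presence of the counted allele, so a
    haplotype character '1' maps to allele 0.
    """
    import pysam

    path = Path(path)
    phased = [r for r in result.records if r.selected is not None]
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(manifest.table["chromosome"]):
        header.contigs.add(str(chrom))
    for rec in phased:
        header.add_sample(rec.subject_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, row in manifest.table.reset_index(drop=True).iterrows():
            ref = row["counted_allele"]
            alt = row.get("other_allele", "N") if "other_allele" in manifest.table.columns else "N"
            vrec = out.new_record(
                contig=str(row["chromosome"]),
                start=int(row["position"]) - 1,
                alleles=(ref, alt),
                id=row["rsid"],
            )
            for rec in phased:
                h1, h2 = rec.selected
                vrec.samples[rec.subject_id]["GT"] = (1 - int(h1[i]), 1 - int(h2[i]))
                vrec.samples[rec.subject_id].phased = True
            out.write(vrec)
    return path
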