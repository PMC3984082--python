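"""Published example data: the DRB1 and MMEL1 windows of an MS cohort.

Haplotype inventories, control-arm frequency spectra and carrier-category
count tables for two 11-SNP windows (around HLA-DRB1 on chromosome 6 and
MMEL1 on chromosome 1) from a published northern-European multiple
sclerosis case-control study.  These small tables serve as worked
examples and regression anchors for the statistics in
:mod:`snpstring.association` and :mod:`snpstring.structure`; they carry
aggregate counts only.
"""

from __future__ import annotations

from .association import GenotypeCountTable

__all__ = [
    "DRB1_IDENTIFIED",
    "MMEL1_IDENTIFIED",
    "DRB1_FAMILIES",
    "DRB1_CONTROL_FREQ",
    "DRB1_COUNTS",
    "MMEL1_COUNTS",
    "HLA_DRB1_1501_COUNTS",
    "A2_VS_HLA_3X3",
    "MERGE_EXAMPLE",
]

# Identified haplotype strings of the DRB1 window, labelled a1..a22.
DRB1_IDENTIFIED: dict[str, str] = {
    "a1": "00000000000",
    "a2": "01101100000",
    "a3": "10000100000",
    "a4": "01011000000",
    "a5": "01010000000",
    "a6": "10000011111",
    "a7": "10000011110",
    "a8": "01111000000",
    "a9": "10011100000",
    "a10": "10001100000",
    "a11": "01001000000",
    "a12": "01011100000",
    "a13": "01111001110",
    "a14": "00000010000",
    "a15": "01100100000",
    "a16": "00000011110",
    "a17": "01101000000",
    "a18": "10000000000",
    "a19": "10000010010",
    "a20": "10000010000",
    "a21": "10000011101",
    "a22": "00000011101",
}

# Identified haplotype strings of the MMEL1 window, labelled a1..a24.
MMEL1_IDENTIFIED: dict[str, str] = {
    "a1": "01110110101",
    "a2": "01110010101",
    "a3": "00000000010",
    "a4": "11100001001",
    "a5": "01111010101",
    "a6": "00000101001",
    "a7": "00000001001",
    "a8": "00000000011",
    "a9": "11100001000",
    "a10": "01110110100",
    "a11": "01100001001",
    "a12": "01111010100",
    "a13": "11100000010",
    "a14": "01010000000",
    "a15": "01100000010",
    "a16": "00100000010",
    "a17": "00000101000",
    "a18": "01111010001",
    "a19": "01010000001",
    "a20": "00000001000",
    "a21": "11000000010",
    "a22": "00010110101",
    "a23": "01110000011",
    "a24": "11110010101",
}

# Published family memberships of the DRB1 strings (Hamming-1 families).
DRB1_FAMILIES: tuple[frozenset[str], ...] = (
    frozenset({"a6", "a7", "a16", "a21", "a22"}),
    frozenset({"a2", "a4", "a5", "a8", "a11", "a12", "a15", "a17"}),
    frozenset({"a1", "a3", "a9", "a10", "a14", "a18", "a19", "a20"}),
    frozenset({"a13"}),
)

# Control-arm non-conflicted frequency estimates (%), DRB1 window.
DRB1_CONTROL_FREQ: dict[str, float] = {
    "a1": 10, "a2": 13, "a3": 22, "a4": 10, "a5": 1, "a6": 2, "a7": 16,
    "a8": 6, "a9": 2, "a11": 1, "a13": 2, "a19": 1, "a20": 1, "a21": 9,
    "a22": 2,
}

# Carrier-category counts (0/1/2 copies x case/control), DRB1 window.
DRB1_COUNTS: dict[str, GenotypeCountTable] = {
    label: GenotypeCountTable(label, cases, controls)
    for label, cases, controls in [
        ("a1", (810, 138, 5), (645, 197, 8)),
        ("a2", (483, 404, 66), (660, 177, 13)),
        ("a3", (677, 250, 26), (549, 261, 40)),
        ("a4", (695, 235, 23), (616, 219, 15)),
        ("a7", (735, 209, 9), (601, 226, 22)),
        ("a8", (848, 101, 4), (733, 111, 6)),
        ("a9", (917, 36, 0), (817, 32, 1)),
    ]
}

# Carrier-category counts for the MMEL1 window.
MMEL1_COUNTS: dict[str, GenotypeCountTable] = {
    label: GenotypeCountTable(label, cases, controls)
    for label, cases, controls in [
        ("a1", (734, 219, 17), (637, 226, 14)),
        ("a3", (288, 470, 212), (289, 425, 163)),
        ("a4", (762, 182, 26), (686, 183, 8)),
        ("a5", (732, 219, 19), (668, 191, 18)),
        ("a6", (935, 35, 0), (845, 31, 1)),
        ("a7", (881, 84, 5), (792, 83, 2)),
        ("a14", (955, 14, 1), (859, 17, 1)),
    ]
}

# DRB1*1501 allele status in the US sub-population (TaqMan typing).
HLA_DRB1_1501_COUNTS = GenotypeCountTable(
    "DRB1*1501", cases=(262, 189, 35), controls=(346, 80, 5)
)

# Cross-tabulation of (a2)-haplotype copies (rows) vs DRB1*1501 copies
# (columns) in the US sub-population, after the single re-typed subject.
A2_VS_HLA_3X3: tuple[tuple[int, int, int], ...] = (
    (573, 6, 0),
    (5, 264, 0),
    (0, 0, 39),
)

# Worked window-merge example: two adjacent 11-SNP windows bridged by an
# overlap window starting at position 6 of the first.
MERGE_EXAMPLE = {
    "window1_pair": ("01101100000", "01011010000"),
    "window2_pair": ("01010000000", "10000011111"),
    "overlap_pair": ("10000001010", "01000010000"),
    "overlap_start": 6,  # 1-based position within window 1
    # The unique overlap-consistent 22-SNP haplotypes (sorted pair):
    "merged_pair": (
        "0101101000010000011111",
        "0110110000001010000000",
    ),
}
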