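"""Bundled published summary data for the MdnCNV cohort.

Two small tables travel with the package as analysis inputs: the
per-family de novo substitution counts of the five MdnCNV and five
control trios (with parental ages at conception and Ti:Tv ratios), and
the GRCh38 coordinates of the de novo CNVs of the three genotyped
MdnCNV probands, including the eight ~1 Mb tandem duplications of
proband BAB9637. They drive the cohort statistics, the duplication
geometry and the breakpoint-clustering analyses without any external
download.
"""

from __future__ import annotations

import pandas as pd

from .records import CnvEvent

_COHORT_ROWS = [
    # family, individual, group, mother_age, father_age, germline, post_zygotic, titv
    ("HOU1209", "BAB3097", "MdnCNV", 29.4, 29.7, 75, 9, 1.8),
    ("HOU1404", "BAB3596", "MdnCNV", 37.0, 41.7, 94, 5, 2.1),
    ("HOU3425", "mCNV3/BAB9484", "MdnCNV", 37.8, 41.6, 102, 9, 1.6),
    ("HOU3579", "BAB9637", "MdnCNV", 36.9, 35.9, 74, 4, 2.0),
    ("mCNV7", "mCNV7", "MdnCNV", 35.0, 37.0, 89, 9, 2.3),
    ("Fam1", "P1", "control", 17.2, 19.2, 47, 1, 2.4),
    ("Fam2", "P2", "control", 30.3, 29.9, 69, 3, 2.4),
    ("Fam3", "P3", "control", 41.0, 46.1, 98, 2, 1.1),
    ("Fam4", "P4", "control", 28.4, 27.7, 64, 2, 3.1),
    ("Fam5", "P5", "control", 32.3, 34.2, 72, 3, 2.0),
]

_DNCNV_ROWS = [
    # sample, locus, chrom, start (1-based), end (inclusive), type
    ("BAB9637", "4q31.22q31.23", "chr4", 147494740, 148399180, "DUP"),
    ("BAB9637", "5q35.2q35.3", "chr5", 176449583, 177376826, "DUP"),
    ("BAB9637", "6p24.2p24.1", "chr6", 11481309, 12522879, "DUP"),
    ("BAB9637", "10q26.13q26.2", "chr10", 124920875, 125841697, "DUP"),
    ("BAB9637", "12q13.2q13.3", "chr12", 55986511, 56885590, "DUP"),
    ("BAB9637", "13q33.3q34", "chr13", 109406834, 110341135, "DUP"),
    ("BAB9637", "14q21.1", "chr14", 40568596, 41479705, "DUP"),
    ("BAB9637", "21q21.3", "chr21", 28158347, 29192300, "DUP"),
    ("BAB3097", "1p36.22p36.13", "chr1", 10115497, 16283149, "DUP"),
    ("BAB3097", "3q13.33q21.1", "chr3", 122157406, 123113479, "DUP"),
    ("BAB3097", "5p12", "chr5", 44375961, 44815730, "DUP"),
    ("BAB3097", "5q33.3q34", "chr5", 158887731, 164722046, "DUP"),
    ("BAB3097", "9p13.3", "chr9", 33492358, 34725916, "TRP"),
    ("BAB3097", "17p12p11.2", "chr17", 11915997, 17892664, "DUP"),
    ("BAB3097", "22q13.31p13.32", "chr22", 47979382, 48288823, "DUP"),
    ("mCNV3/BAB9484", "1p31.3p31.1", "chr1", 66885559, 77949895, "DUP"),
    ("mCNV3/BAB9484", "1q42.2q42.3", "chr1", 233450789, 235471180, "DUP"),
    ("mCNV3/BAB9484", "2p13.3", "chr2", 69512973, 71153026, "DUP"),
    ("mCNV3/BAB9484", "3q26.32", "chr3", 176661565, 177473432, "DUP"),
    ("mCNV3/BAB9484", "9q22.2", "chr9", 89241202, 90787598, "DUP"),
    ("mCNV3/BAB9484", "11p12p11.2", "chr11", 42871836, 44852545, "DUP"),
    ("mCNV3/BAB9484", "16q22.2", "chr16", 71219688, 71768356, "DUP"),
    ("mCNV3/BAB9484", "20q13.33", "chr20", 61800345, 63644611, "DUP"),
]

#: GRCh38 chromosome lengths for the chromosomes appearing above
GRCH38_CHROM_LENGTHS = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
}

#: genome-wide de novo mutation counts of proband BAB9637 (short-read
#: trio sequencing): 91 DNMs = 79 SNVs + 12 indels; 50 phased, 80% paternal
BAB9637_TOTAL_DNM = 91
BAB9637_SNV = 79
BAB9637_INDEL = 12
BAB9637_PHASED = 50
BAB9637_PHASED_PATERNAL_FRACTION = 0.8


def load_cohort_counts() -> pd.DataFrame:
    """Per-family de novo substitution counts of the MdnCNV and control
    cohorts, with parental ages at conception and Ti:Tv ratios."""
    df = pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "family",
            "individual",
            "group",
            "mother_age",
            "father_age",
            "germline",
            "post_zygotic",
            "titv",
        ],
    )
    df["total"] = df["germline"] + df["post_zygotic"]
    return df


def load_dncnv_coordinates(sample: str | None = None) -> pd.DataFrame:
    """GRCh38 de novo CNV coordinates of the genotyped MdnCNV probands
    (1-based inclusive, as published)."""
    df = pd.DataFrame(
        _DNCNV_ROWS, columns=["sample", "locus", "chrom", "start", "end", "cnv_type"]
    )
    if sample is not None:
        df = df[df["sample"] == sample].reset_index(drop=True)
    df["size"] = df["end"] - df["start"]
    return df


def bab9637_duplications() -> list[CnvEvent]:
    """The eight BAB9637 tandem duplications as 0-based half-open
    :class:`CnvEvent` records (size preserved: end - start of the
    published 1-based inclusive pair)."""
    df = load_dncnv_coordinates("BAB9637")
    return [
        CnvEvent(chrom=r.chrom, start=r.start, end=r.end, cnv_type=r.cnv_type)
        for r in df.itertuples(index=False)
    ]
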