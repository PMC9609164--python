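"""Core record types shared across the pipeline stages.

Coordinate conventions: all in-memory coordinates are 0-based half-open.
VCF emission converts to 1-based positions; BED output stays 0-based
half-open. ``TrioVariantRecord.pos`` is the one deliberate exception: it
mirrors the VCF field and is 1-based, because trio variant tables are
read from and written to VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

GERMLINE = "germline"
POST_ZYGOTIC = "post_zygotic"
PATERNAL = "paternal"
MATERNAL = "maternal"
UNPHASED = "unphased"
UNASSIGNED = "unassigned"

#: Pyrimidine-collapsed substitution categories; C>T is split by CpG context.
MUTATION_CATEGORIES = (
    "C>A",
    "C>G",
    "C>T at CpG",
    "C>T at non-CpG",
    "T>A",
    "T>C",
    "T>G",
)


@dataclass
class CnvEvent:
    """A copy-number event. ``start``/``end`` are 0-based half-open reference
    coordinates of the duplicated (or deleted) segment; for a tandem
    duplication the junction joins the distal breakpoint (``end``) back to
    the proximal one (``start``)."""

    chrom: str
    start: int
    end: int
    cnv_type: str = "DUP"
    parent_of_origin: Optional[str] = None
    mh_len: Optional[int] = None
    mh_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid CNV interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def breakpoints(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TrioVariantRecord:
    """One biallelic site with proband/father/mother evidence.

    ``pos`` is 1-based (VCF convention). Genotypes are unphased strings
    ("0/0", "0/1", "1/1"). ``child_adf``/``child_adr`` are the proband's
    forward/reverse alt-supporting read counts.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    child_gt: str
    father_gt: str
    mother_gt: str
    child_ad: tuple[int, int]
    father_ad: tuple[int, int]
    mother_ad: tuple[int, int]
    child_gq: int
    father_gq: int
    mother_gq: int
    child_adf: int = 0
    child_adr: int = 0
    repeat_masked: bool = False
    near_indel: bool = False

    def __post_init__(self) -> None:
        for ad in (self.child_ad, self.father_ad, self.mother_ad):
            if min(ad) < 0:
                raise ValueError("allelic depths must be non-negative")
        if min(self.child_gq, self.father_gq, self.mother_gq) < 0:
            raise ValueError("GQ must be non-negative")
        if self.child_adf + self.child_adr != self.child_ad[1]:
            raise ValueError("strand counts must sum to the proband alt depth")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    @property
    def vaf(self) -> float:
        total = sum(self.child_ad)
        if total == 0:
            raise ZeroDivisionError(
                f"VAF undefined at {self.chrom}:{self.pos} (zero proband depth)"
            )
        return self.child_ad[1] / total


@dataclass
class DnmCall:
    """A validated de novo mutation with its VAF-based zygosity class,
    7-way substitution category and (optionally) parental phase."""

    record: TrioVariantRecord
    zygosity: str
    category: Optional[str] = None
    phase: str = UNPHASED

    def __post_init__(self) -> None:
        if self.zygosity not in (GERMLINE, POST_ZYGOTIC):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.category is not None and self.category not in MUTATION_CATEGORIES:
            raise ValueError(f"unknown mutation category {self.category!r}")

    @property
    def vaf(self) -> float:
        return self.record.vaf

    @property
    def variant_class(self) -> str:
        return "SNV" if self.record.is_snv else "indel"
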