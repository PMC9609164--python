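"""Parent-of-origin assignment of haplotype blocks, de novo SNVs and CNVs.

Read-backed physical phasing (haplotype blocks with a hapA/hapB allele
per child-het site) is consumed as input; this module adds the pedigree
layer. Pedigree-informative sites are biallelic sites where the child
is heterozygous and exactly one assignment of its two alleles to the
parents is Mendelian-consistent, which pins the transmitted alt allele
to one parent. A block is assigned a parental origin only when it
covers >= 20 informative sites and >= 90% of them vote for a single
origin of hapA; ties and thin blocks stay unassigned. De novo SNVs
inherit the origin of the haplotype that carries them; de novo tandem
duplications are phased through intra-duplication allele ratios, where
the duplicated haplotype's allele sits at an expected allele fraction
of 2/3 (copy number 2 of 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .records import CnvEvent, MATERNAL, PATERNAL, UNASSIGNED, UNPHASED

MIN_INFORMATIVE_SITES = 20
MIN_CONSISTENCY = 0.9


@dataclass
class PhaseAssignment:
    block_id: int
    hap_a_origin: str  # paternal | maternal | unassigned
    n_informative: int
    consistency: float

    def origin_of(self, hap: str) -> str:
        """Origin of haplotype "A" or "B" under this assignment."""
        if self.hap_a_origin == UNASSIGNED:
            return UNPHASED
        if hap == "A":
            return self.hap_a_origin
        return MATERNAL if self.hap_a_origin == PATERNAL else PATERNAL


def _has_allele(gt: str, allele: str) -> bool:
    return allele in gt.replace("|", "/").split("/")


def informative_sites(trio: pd.DataFrame) -> pd.DataFrame:
    """Sites where the transmitted alt allele has a forced parental origin.

    Requires a child-heterozygous genotype and exactly one
    Mendelian-consistent assignment of ref/alt to the parents:
    ``alt_origin`` is paternal iff (father carries alt and mother
    carries ref) is consistent while the converse is not. Sites with no
    consistent assignment are Mendelian violations and are excluded
    (flagged in the ``mendelian_violation`` frame attribute).
    """
    child = trio["child_gt"].str.replace("|", "/", regex=False)
    het = child.isin(["0/1", "1/0"])
    sub = trio.loc[het]
    alt_pat = sub["father_gt"].map(lambda g: _has_allele(g, "1")) & sub[
        "mother_gt"
    ].map(lambda g: _has_allele(g, "0"))
    alt_mat = sub["mother_gt"].map(lambda g: _has_allele(g, "1")) & sub[
        "father_gt"
    ].map(lambda g: _has_allele(g, "0"))
    forced = alt_pat ^ alt_mat
    violations = sub.loc[~alt_pat & ~alt_mat, ["chrom", "pos"]]
    out = sub.loc[forced, ["chrom", "pos"]].copy()
    out["alt_origin"] = np.where(alt_pat[forced], PATERNAL, MATERNAL)
    out = out.reset_index(drop=True)
    out.attrs["mendelian_violations"] = violations.reset_index(drop=True)
    return out


def assign_block_origin(
    block_sites: pd.DataFrame,
    informative: pd.DataFrame,
    block_id: int = 0,
    min_sites: int = MIN_INFORMATIVE_SITES,
    min_consistency: float = MIN_CONSISTENCY,
) -> PhaseAssignment:
    """Vote the origin of hapA over the informative sites in one block.

    ``block_sites`` carries one row per phased child-het site with
    columns chrom, pos, hap_a (0/1 allele on haplotype A). At an
    informative site where the alt allele is paternal, hapA votes
    paternal iff it carries the alt allele. Assignment needs
    >= ``min_sites`` votes and a majority fraction >= ``min_consistency``;
    an exact 50% tie is unassigned.
    """
    merged = block_sites.merge(informative, on=["chrom", "pos"], how="inner")
    n = len(merged)
    if n == 0:
        return PhaseAssignment(block_id, UNASSIGNED, 0, 0.0)
    carries_alt = merged["hap_a"].astype(int) == 1
    vote_paternal = np.where(
        carries_alt, merged["alt_origin"] == PATERNAL, merged["alt_origin"] == MATERNAL
    )
    k_pat = int(vote_paternal.sum())
    majority = max(k_pat, n - k_pat)
    consistency = majority / n
    if n >= min_sites and consistency >= min_consistency and majority != n - majority:
        origin = PATERNAL if k_pat > n - k_pat else MATERNAL
        return PhaseAssignment(block_id, origin, n, consistency)
    return PhaseAssignment(block_id, UNASSIGNED, n, consistency)


def assign_all_blocks(
    block_sites: pd.DataFrame,
    informative: pd.DataFrame,
    min_sites: int = MIN_INFORMATIVE_SITES,
    min_consistency: float = MIN_CONSISTENCY,
) -> dict[int, PhaseAssignment]:
    """Run :func:`assign_block_origin` for every ``block_id`` group."""
    return {
        int(bid): assign_block_origin(grp, informative, int(bid), min_sites, min_consistency)
        for bid, grp in block_sites.groupby("block_id")
    }


def phase_dnm(
    block_id: int,
    hap: Optional[str],
    assignments: dict[int, PhaseAssignment],
) -> str:
    """Origin of a de novo mutation carried on haplotype ``hap`` of block
    ``block_id``; unphased if outside any assigned block."""
    if block_id is None or block_id < 0 or not hap:
        return UNPHASED
    if hap not in ("A", "B"):
        raise ValueError(f"carrier haplotype must be 'A' or 'B', got {hap!r}")
    assignment = assignments.get(block_id)
    if assignment is None:
        return UNPHASED
    return assignment.origin_of(hap)


def phase_dnm_table(
    dnms: pd.DataFrame, assignments: dict[int, PhaseAssignment]
) -> pd.Series:
    """Vectorised :func:`phase_dnm` over a DNM table with ``block_id`` and
    ``hap`` columns."""
    return pd.Series(
        [
            phase_dnm(int(row.block_id), row.hap or None, assignments)
            for row in dnms.itertuples(index=False)
        ],
        index=dnms.index,
    )


def phase_dncnv(
    cnv: CnvEvent,
    het_sites: pd.DataFrame,
    alpha: float = 0.05,
) -> str:
    """Parent-of-origin of a de novo tandem duplication from allele
    ratios at child-het sites inside it.

    ``het_sites`` has columns pos, ref_depth, alt_depth, alt_origin
    (parental origin of the alt allele from pedigree-informative
    configurations). Inside a duplication, the allele on the duplicated
    haplotype is present in 2 of 3 copies, so its read fraction is
    expected at 2/3. Each site is tested one-sided (exact binomial,
    fraction > 0.5) for either allele; significant sites vote for the
    origin of the over-represented allele, and the majority wins.
    Balanced or conflicting evidence returns ``unassigned``.
    """
    if cnv.cnv_type != "DUP":
        raise ValueError(f"only tandem duplications are supported, got {cnv.cnv_type}")
    inside = het_sites[(het_sites["pos"] > cnv.start) & (het_sites["pos"] <= cnv.end)]
    votes: list[str] = []
    for row in inside.itertuples(index=False):
        total = int(row.ref_depth + row.alt_depth)
        if total == 0:
            continue
        alt_high = stats.binomtest(int(row.alt_depth), total, 0.5, alternative="greater")
        ref_high = stats.binomtest(int(row.ref_depth), total, 0.5, alternative="greater")
        if alt_high.pvalue < alpha:
            dup_allele_origin = row.alt_origin
        elif ref_high.pvalue < alpha:
            dup_allele_origin = (
                MATERNAL if row.alt_origin == PATERNAL else PATERNAL
            )
        else:
            continue
        votes.append(dup_allele_origin)
    if not votes:
        return UNASSIGNED
    k_pat = votes.count(PATERNAL)
    if k_pat * 2 == len(votes):
        return UNASSIGNED
    return PATERNAL if k_pat * 2 > len(votes) else MATERNAL
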