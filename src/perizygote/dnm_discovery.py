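"""Trio de novo mutation discovery, filtering and cohort statistics.

Candidate de novo variants are sites where the proband carries an alt
allele seen in neither parental genotype and all three samples have
GQ >= 20. Candidates then pass a filter battery: >= 5 alt-supporting
reads, support on both strands, not adjacent to an indel, not in a
repeat-masked region, and removal of every member of any group of
candidates lying pairwise within 20 bp on one chromosome (clustered
calls are alignment-error prone). Surviving calls are classified
germline versus post-zygotic from the proband variant-read fraction
(VR/TR): a call is post-zygotic iff VR/TR < 0.35 or > 0.65 *and* no
alt read is seen in either parent; the boundaries are strict, so a VAF
of exactly 0.35 stays germline.

Per-record filters are order-independent; the cluster rule runs after
them and its outcome does not depend on input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import GERMLINE, MUTATION_CATEGORIES, POST_ZYGOTIC
from .sequtil import get_seq, revcomp

MIN_GQ = 20
MIN_ALT_READS = 5
CLUSTER_DISTANCE = 20
VAF_LOWER = 0.35
VAF_UPPER = 0.65

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_PYRIMIDINES = {"C", "T"}

REQUIRED_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "child_gt",
    "father_gt",
    "mother_gt",
    "child_ref",
    "child_alt",
    "father_ref",
    "father_alt",
    "mother_ref",
    "mother_alt",
    "child_gq",
    "father_gq",
    "mother_gq",
]


def _check_schema(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"trio table is missing columns: {missing}")


def _gt_alleles(gt: pd.Series) -> pd.DataFrame:
    parts = gt.str.replace("|", "/", regex=False).str.split("/", expand=True)
    return parts.astype(int)


def extract_candidates(table: pd.DataFrame, min_gq: int = MIN_GQ) -> pd.DataFrame:
    """Return sites where the proband carries an alt allele absent from
    both parental genotypes, with GQ >= ``min_gq`` in all three samples."""
    _check_schema(table)
    child = _gt_alleles(table["child_gt"])
    father = _gt_alleles(table["father_gt"])
    mother = _gt_alleles(table["mother_gt"])
    child_has_alt = (child == 1).any(axis=1)
    parent_has_alt = (father == 1).any(axis=1) | (mother == 1).any(axis=1)
    gq_ok = (
        (table["child_gq"] >= min_gq)
        & (table["father_gq"] >= min_gq)
        & (table["mother_gq"] >= min_gq)
    )
    keep = child_has_alt & ~parent_has_alt & gq_ok
    return table.loc[keep].reset_index(drop=True)


def apply_filters(
    candidates: pd.DataFrame,
    cluster_distance: int = CLUSTER_DISTANCE,
    min_alt_reads: int = MIN_ALT_READS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the per-record filter battery, then the clustered-call rule.

    Returns ``(kept, rejection_log)`` where the log records one row per
    rejected candidate with the first failing rule. Candidates must be
    sorted by (chrom, pos).
    """
    _check_schema(candidates)
    pos = candidates[["chrom", "pos"]]
    if not pos.equals(pos.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)):
        raise ValueError("candidates must be sorted by (chrom, pos)")

    reasons = pd.Series("", index=candidates.index, dtype=object)
    low_support = candidates["child_alt"] < min_alt_reads
    reasons[low_support] = "alt_support"
    one_strand = (candidates["child_adf"] == 0) | (candidates["child_adr"] == 0)
    reasons[(reasons == "") & one_strand] = "strand"
    reasons[(reasons == "") & candidates["near_indel"]] = "near_indel"
    reasons[(reasons == "") & candidates["repeat_masked"]] = "repeat_mask"

    survivors = candidates[reasons == ""]
    # chain grouping: transitive closure of pairwise <= cluster_distance
    clustered_idx: list = []
    for _, grp in survivors.groupby("chrom", sort=False):
        p = grp["pos"].to_numpy()
        if len(p) < 2:
            continue
        close = np.diff(p) <= cluster_distance
        in_cluster = np.zeros(len(p), dtype=bool)
        in_cluster[:-1] |= close
        in_cluster[1:] |= close
        clustered_idx.extend(grp.index[in_cluster])
    reasons[clustered_idx] = "clustered"

    kept = candidates[reasons == ""].reset_index(drop=True)
    log = candidates.loc[reasons != "", ["chrom", "pos", "ref", "alt"]].copy()
    log["reason"] = reasons[reasons != ""]
    return kept, log.reset_index(drop=True)


def classify_zygosity(
    child_ref: int,
    child_alt: int,
    father_alt: int,
    mother_alt: int,
    vaf_lower: float = VAF_LOWER,
    vaf_upper: float = VAF_UPPER,
) -> str:
    """Two-class VAF rule: post-zygotic iff VR/TR < 0.35 or > 0.65 and no
    alt read in either parent; otherwise germline."""
    total = child_ref + child_alt
    if total <= 0:
        raise ZeroDivisionError("VAF undefined: zero proband depth")
    vaf = child_alt / total
    shifted = vaf < vaf_lower or vaf > vaf_upper
    if shifted and father_alt == 0 and mother_alt == 0:
        return POST_ZYGOTIC
    return GERMLINE


def classify_zygosity_table(calls: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_zygosity` over a call table."""
    total = calls["child_ref"] + calls["child_alt"]
    if (total <= 0).any():
        bad = calls.loc[total <= 0, ["chrom", "pos"]].iloc[0]
        raise ZeroDivisionError(f"VAF undefined at {bad['chrom']}:{bad['pos']}")
    vaf = calls["child_alt"] / total
    shifted = (vaf < VAF_LOWER) | (vaf > VAF_UPPER)
    parents_clean = (calls["father_alt"] == 0) & (calls["mother_alt"] == 0)
    return pd.Series(
        np.where(shifted & parents_clean, POST_ZYGOTIC, GERMLINE), index=calls.index
    )


def is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 == len(alt)


def titv_ratio(substitutions: Sequence[tuple[str, str]]) -> float:
    """Transition (A<->G, C<->T) to transversion ratio of SNVs."""
    ti = sum(1 for r, a in substitutions if (r, a) in _TRANSITIONS)
    tv = len(substitutions) - ti
    if tv == 0:
        raise ZeroDivisionError("Ti:Tv undefined: no transversions")
    return ti / tv


def mutation_category(ref: str, alt: str, next_base: str) -> str:
    """Collapse one substitution to the pyrimidine strand and bin it into
    the 7 categories; ``next_base`` is the reference base 3' of the site
    on the strand where the reference allele is a pyrimidine."""
    if ref in _PYRIMIDINES:
        pyr_ref, pyr_alt = ref, alt
    else:
        pyr_ref, pyr_alt = revcomp(ref), revcomp(alt)
    sub = f"{pyr_ref}>{pyr_alt}"
    if sub == "C>T":
        return "C>T at CpG" if next_base.upper() == "G" else "C>T at non-CpG"
    return sub


def mutation_categories(calls: pd.DataFrame, reference) -> pd.Series:
    """7-bin substitution counts for SNV calls; bins sum to the SNV count.

    The CpG split needs the base 3' of each C on the pyrimidine strand:
    for a C reference that is the next reference base, for a G reference
    (reverse strand) the complement of the previous one.
    """
    counts = dict.fromkeys(MUTATION_CATEGORIES, 0)
    for row in calls.itertuples(index=False):
        if not is_snv(row.ref, row.alt):
            continue
        pos0 = row.pos - 1
        if row.ref in _PYRIMIDINES:
            next_base = get_seq(reference, row.chrom, pos0 + 1, pos0 + 2)
        else:
            next_base = revcomp(get_seq(reference, row.chrom, pos0 - 1, pos0))
        if len(next_base) != 1:
            raise IndexError(f"no flanking base at {row.chrom}:{row.pos}")
        counts[mutation_category(row.ref, row.alt, next_base)] += 1
    return pd.Series(counts, name="count")


def postzygotic_proportion_test(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float]:
    """Pooled two-proportion z-test (no continuity correction); returns
    (z, two-sided normal p). Applied to post-zygotic fractions of two
    cohorts, e.g. 36/470 vs 11/361 gives p = 0.004."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n with n > 0")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    slope_se: float
    n: int


def germline_age_regression(
    paternal_age: Sequence[float],
    germline_count: Sequence[float],
    ci_level: float = 0.95,
) -> RegressionResult:
    """OLS of germline DNM count on paternal age; the slope is the
    paternal age effect (extra mutations per year), with a t-based CI."""
    x = np.asarray(paternal_age, dtype=float)
    y = np.asarray(germline_count, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 families")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant predictor: paternal age does not vary")
    res = stats.linregress(x, y)
    dof = len(x) - 2
    tcrit = stats.t.ppf(0.5 + ci_level / 2, dof)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=(float(ci[0]), float(ci[1])),
        slope_se=float(res.stderr),
        n=len(x),
    )


def dnm_rate(
    n_dnm: int,
    mappable_haploid_size: float,
    phased_paternal: int = 0,
    phased_maternal: int = 0,
) -> dict[str, float]:
    """Per-bp de novo mutation rates.

    The unphased rate divides the DNM count by the mappable *diploid*
    genome (2x haploid). Per-parent rates extrapolate the total count by
    the fraction of successfully phased DNMs assigned to that parent and
    divide by the haploid size.
    """
    if mappable_haploid_size <= 0:
        raise ValueError("mappable size must be positive")
    out = {"unphased_per_bp": n_dnm / (2.0 * mappable_haploid_size)}
    phased_total = phased_paternal + phased_maternal
    if phased_total:
        for label, k in (("paternal", phased_paternal), ("maternal", phased_maternal)):
            extrapolated = n_dnm * k / phased_total
            out[f"{label}_extrapolated_count"] = extrapolated
            out[f"{label}_per_bp"] = extrapolated / mappable_haploid_size
    return out


def allele_frequency(allele_count: int, allele_number: int) -> float:
    """Population allele frequency AC/AN (e.g. 2990/21518 = 0.139)."""
    if allele_number <= 0:
        raise ValueError("allele number must be positive")
    if not 0 <= allele_count <= allele_number:
        raise ValueError("allele count must lie in [0, allele_number]")
    return allele_count / allele_number


def cohort_summary(per_family: pd.DataFrame) -> dict[str, float]:
    """Summarise a per-family cohort table with columns
    ``germline``, ``post_zygotic`` (counts) and optional ages.

    The per-family identity total = germline + post_zygotic is enforced.
    """
    germ = per_family["germline"].to_numpy()
    post = per_family["post_zygotic"].to_numpy()
    total = germ + post
    if "total" in per_family.columns and not np.array_equal(
        total, per_family["total"].to_numpy()
    ):
        raise ValueError("total != germline + post_zygotic in cohort table")
    return {
        "n_families": int(len(per_family)),
        "germline_total": int(germ.sum()),
        "post_zygotic_total": int(post.sum()),
        "total": int(total.sum()),
        "post_zygotic_fraction": float(post.sum() / total.sum()),
    }
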