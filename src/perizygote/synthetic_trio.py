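"""Synthetic trio genomes with planted peri-zygotic mutational events.

The generator emulates the study design behind the multiple de novo CNV
(MdnCNV) phenomenon: a diploid parent-offspring trio in which the proband
carries

* ``k_cnv`` de novo tandem duplications of roughly 1 Mb, each with a
  planted microhomology of 0-5 bp at the breakpoint junction;
* germline de novo SNVs (expected VAF 0.5) with a paternal bias
  (default 80% paternal, matching the phased fraction seen in trio
  sequencing studies of de novo mutation);
* post-zygotic de novo SNVs with shifted VAF (default uniform 0.10-0.35,
  the range expected for mutations arising around the first cell
  divisions) and, by construction, zero supporting reads in either
  parent;
* a configurable enrichment of de novo mutations within distance ``d``
  of any duplication breakpoint (relative placement density ``rho``
  inside versus 1 outside), emulating the local hypermutation that
  accompanies replicative CNV formation.

Read evidence (allelic depths, strand counts, GQ) is sampled per
genotype from binomial models; read-level simulation (FASTQ/BAM) is out
of scope. A :class:`TruthSet` records every planted event for
round-trip evaluation of the downstream discovery, phasing, clustering
and junction stages.

The default genome is a deliberately scaled-down stand-in (eight 6-Mb
chromosomes) so that a full simulation runs in seconds; duplication
sizes stay at the realistic ~1 Mb scale while the breakpoint-enrichment
distance is scaled to 1 Mb to keep the enriched windows a minority of
the genome. Position-only simulation at human chromosome scale is
available through :func:`sample_dnm_positions`, which needs no sequence.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    GERMLINE,
    MATERNAL,
    PATERNAL,
    POST_ZYGOTIC,
    CnvEvent,
)
from .sequtil import BASES, seq_to_array

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Canonical column order of the trio variant table.
TRIO_COLUMNS = [
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
    "child_adf",
    "child_adr",
    "repeat_masked",
    "near_indel",
]


def _default_chroms() -> dict[str, int]:
    return {f"chr{i}": 6_000_000 for i in range(1, 9)}


@dataclass
class SimConfig:
    """Study conditions for one synthetic trio.

    Defaults follow the MdnCNV study design: eight ~1 Mb tandem
    duplications, 0-5 bp junction microhomology, ~90 germline de novo
    SNVs with 80% paternal origin, a handful of post-zygotic variants
    with VAF in 0.10-0.35, mean sequencing depth 35x.
    """

    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    snp_density: float = 1 / 1500
    k_cnv: int = 8
    cnv_size_mean: float = 1.0e6
    cnv_size_sd: float = 4.0e4
    mh_max: int = 5
    n_germline_dnm: int = 84
    paternal_fraction: float = 0.8
    n_postzygotic_dnm: int = 7
    postzygotic_vaf_range: tuple[float, float] = (0.10, 0.35)
    enrichment_factor: float = 6.0
    enrichment_distance: int = 1_000_000
    mean_depth: float = 35.0
    gc_content: float = 0.41
    block_break_prob: float = 1 / 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths or min(self.chrom_lengths.values()) <= 0:
            raise ValueError("all chromosome lengths must be positive")
        if not 0.0 <= self.paternal_fraction <= 1.0:
            raise ValueError("paternal_fraction must lie in [0, 1]")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        lo, hi = self.postzygotic_vaf_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("postzygotic_vaf_range must be within [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.mh_max < 0:
            raise ValueError("mh_max must be non-negative")


@dataclass
class TruthSet:
    """Planted events: CNVs with parent-of-origin and junction
    microhomology, DNMs with true class/parent/VAF, and the haplotype
    block truth used to score phasing."""

    cnvs: list[CnvEvent]
    dnms: pd.DataFrame  # chrom,pos,ref,alt,zygosity,parent,true_vaf,block_id,hap
    block_sites: pd.DataFrame  # chrom,pos,block_id,hap_a,hap_b,pat_allele,mat_allele
    block_origins: pd.DataFrame  # block_id,chrom,start,end,n_sites,hap_a_origin


@dataclass
class TrioSimulation:
    config: SimConfig
    reference: dict[str, np.ndarray]
    variants: pd.DataFrame
    truth: TruthSet

    def reference_str(self, chrom: str) -> str:
        return self.reference[chrom].tobytes().decode("ascii")

    def write_fasta(self, path) -> None:
        write_fasta(self.reference, path)

    def write_vcf(self, path) -> None:
        write_trio_vcf(self.variants, self.config.chrom_lengths, path)

    def write_cnv_bed(self, path) -> None:
        write_cnv_bed(self.truth.cnvs, path)

    def write_dnm_truth(self, path) -> None:
        self.truth.dnms.to_csv(path, sep="\t", index=False)


@dataclass
class PlantedDuplication:
    """Result of planting one tandem duplication: the microhomology-
    engineered reference (original length), the mutated haplotype with
    the duplicated segment inserted in tandem, and the event record."""

    reference: str
    mutated: str
    event: CnvEvent


def plant_tandem_duplication(
    seq: str, start: int, size: int, mh_len: int, chrom: str = "chrN"
) -> PlantedDuplication:
    """Plant a tandem duplication of ``[start, start+size)`` with an
    engineered exact microhomology of ``mh_len`` bp at the junction.

    The ``mh_len`` bases ending at the proximal breakpoint are made
    identical to those ending at the distal breakpoint, and the base
    immediately 5' of each homology tract is forced to differ so the
    planted length is recovered *exactly* by junction analysis.
    """
    end = start + size
    if start < 0 or end > len(seq):
        raise ValueError(
            f"duplication {chrom}:{start}-{end} outside sequence of length {len(seq)}"
        )
    if mh_len > size:
        raise ValueError("microhomology cannot exceed the duplication size")
    if start - mh_len - 1 < 0:
        raise ValueError("not enough sequence 5' of the proximal breakpoint")
    arr = seq_to_array(seq)
    _engineer_microhomology(arr, start, end, mh_len)
    engineered = arr.tobytes().decode("ascii")
    mutated = engineered[:end] + engineered[start:end] + engineered[end:]
    event = CnvEvent(
        chrom=chrom,
        start=start,
        end=end,
        cnv_type="DUP",
        mh_len=mh_len,
        mh_seq=engineered[start - mh_len : start],
    )
    return PlantedDuplication(reference=engineered, mutated=mutated, event=event)


def _engineer_microhomology(arr: np.ndarray, start: int, end: int, mh: int) -> None:
    """In-place: copy the ``mh`` bases ending at ``end`` over those ending
    at ``start`` and terminate the homology with a mismatching base."""
    if mh > 0:
        arr[start - mh : start] = arr[end - mh : end]
    left = arr[start - mh - 1]
    right = arr[end - mh - 1]
    if left == right:
        base = left.decode("ascii") if isinstance(left, bytes) else chr(left)
        nxt = BASES[(BASES.index(base) + 1) % 4]
        arr[start - mh - 1] = nxt.encode("ascii")


def sample_read_evidence(
    genotype: str,
    true_vaf: Optional[float],
    depth: int,
    rng: np.random.Generator | int,
) -> tuple[int, int, int, int, int]:
    """Sample (ref_depth, alt_depth, alt_forward, alt_reverse, GQ) for one
    sample at one site.

    The alt depth is binomial(depth, VAF) with VAF implied by the
    genotype (0, 0.5, 1) unless ``true_vaf`` overrides it (mosaic
    sites); the strand split of alt reads is binomial(alt, 0.5). GQ is
    the stated monotone function of depth, ``min(99, 3 * depth)``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if true_vaf is None:
        alleles = genotype.replace("|", "/").split("/")
        true_vaf = (alleles.count("1")) / 2.0
    if not 0.0 <= true_vaf <= 1.0:
        raise ValueError("true_vaf must lie in [0, 1]")
    alt = int(rng.binomial(depth, true_vaf))
    adf = int(rng.binomial(alt, 0.5)) if alt else 0
    gq = int(min(99, 3 * depth))
    return depth - alt, alt, adf, alt - adf, gq


# ---------------------------------------------------------------------------
# position placement with breakpoint-proximal enrichment


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _enrichment_windows(
    cnvs: Sequence[CnvEvent], distance: int, chrom_lengths: dict[str, int]
) -> dict[str, list[tuple[int, int]]]:
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for cnv in cnvs:
        length = chrom_lengths[cnv.chrom]
        win = (max(0, cnv.start - distance), min(length, cnv.end + distance))
        per_chrom.setdefault(cnv.chrom, []).append(win)
    return {c: _merge_intervals(w) for c, w in per_chrom.items()}


def _in_windows(windows: list[tuple[int, int]], pos: int) -> bool:
    i = bisect.bisect_right(windows, (pos, float("inf"))) - 1
    return i >= 0 and windows[i][0] <= pos < windows[i][1]


def sample_dnm_positions(
    chrom_lengths: dict[str, int],
    cnvs: Sequence[CnvEvent],
    n: int,
    enrichment_factor: float,
    enrichment_distance: int,
    rng: np.random.Generator,
    min_sep: int = 0,
    forbidden: Optional[set[tuple[str, int]]] = None,
) -> list[tuple[str, int]]:
    """Place ``n`` mutation positions with relative density
    ``enrichment_factor`` inside the merged CNV-breakpoint windows
    (CNV +/- ``enrichment_distance``) and 1 elsewhere.

    With ``enrichment_factor == 1`` placement is uniform over the
    genome. Returns 0-based (chrom, pos) pairs. Needs no sequence, so it
    works at human chromosome scale for clustering calibrations.
    """
    windows = _enrichment_windows(cnvs, enrichment_distance, chrom_lengths)
    win_list = [(c, s, e) for c, ws in windows.items() for s, e in ws]
    w_total = sum(e - s for _, s, e in win_list)
    g_total = sum(chrom_lengths.values())
    if w_total > g_total:
        raise ValueError("windows exceed genome size")
    p_in = (
        enrichment_factor * w_total / (enrichment_factor * w_total + g_total - w_total)
        if w_total
        else 0.0
    )
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    win_lengths = np.array([e - s for _, s, e in win_list], dtype=float)
    placed: dict[str, list[int]] = {c: [] for c in chroms}
    out: list[tuple[str, int]] = []
    forbidden = forbidden or set()

    def _ok(chrom: str, pos: int) -> bool:
        if (chrom, pos) in forbidden:
            return False
        if min_sep:
            arr = placed[chrom]
            i = bisect.bisect_left(arr, pos)
            for j in (i - 1, i):
                if 0 <= j < len(arr) and abs(arr[j] - pos) <= min_sep:
                    return False
        return True

    for _ in range(n):
        for _attempt in range(10_000):
            if win_list and rng.random() < p_in:
                k = rng.choice(len(win_list), p=win_lengths / win_lengths.sum())
                chrom, s, e = win_list[k]
                pos = int(rng.integers(s, e))
            else:
                # uniform over the genome outside the windows, by rejection
                while True:
                    ci = rng.choice(len(chroms), p=chrom_p)
                    chrom = chroms[ci]
                    pos = int(rng.integers(0, chrom_lengths[chrom]))
                    if chrom not in windows or not _in_windows(windows[chrom], pos):
                        break
            if _ok(chrom, pos):
                bisect.insort(placed[chrom], pos)
                out.append((chrom, pos))
                break
        else:
            raise RuntimeError("could not place mutation position (genome too full)")
    return out


# ---------------------------------------------------------------------------
# full trio simulation


def simulate_trio(config: SimConfig) -> TrioSimulation:
    """Generate reference, trio variant table and truth set.

    Deterministic for a fixed ``config.seed``: a single seed sequence
    fans out into independent substreams (reference, CNVs, inherited
    SNPs, DNMs, haplotype blocks, read evidence) so stages are
    reproducible independently.
    """
    ss = np.random.SeedSequence(config.seed)
    (r_ref, r_cnv, r_snp, r_dnm, r_blk, r_reads) = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )

    reference = _random_reference(config, r_ref)
    cnvs = _place_cnvs(config, reference, r_cnv)
    snp = _sample_inherited_snps(config, reference, r_snp)
    block_sites, block_origins = _build_blocks(config, snp, r_blk)
    dnms = _place_dnm_truth(config, reference, cnvs, snp, block_sites, block_origins, r_dnm)

    variants = _assemble_variants(config, snp, dnms, cnvs, r_reads)
    truth = TruthSet(
        cnvs=cnvs, dnms=dnms, block_sites=block_sites, block_origins=block_origins
    )
    return TrioSimulation(config=config, reference=reference, variants=variants, truth=truth)


def _random_reference(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cum = np.cumsum(p)
    alphabet = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    return {
        chrom: alphabet[
            np.minimum(np.searchsorted(cum, rng.random(length), side="right"), 3)
        ]
        for chrom, length in config.chrom_lengths.items()
    }


def _place_cnvs(
    config: SimConfig, reference: dict[str, np.ndarray], rng: np.random.Generator
) -> list[CnvEvent]:
    chroms = list(config.chrom_lengths)
    order = [chroms[i] for i in rng.permutation(len(chroms))]
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    events: list[CnvEvent] = []
    for k in range(config.k_cnv):
        chrom = order[k % len(order)]
        length = config.chrom_lengths[chrom]
        size = int(
            np.clip(rng.normal(config.cnv_size_mean, config.cnv_size_sd), 5e4, None)
        )
        mh = int(rng.integers(0, config.mh_max + 1))
        margin = max(mh + 1, 1000)
        if length < size + 2 * margin:
            raise ValueError(
                f"chromosome {chrom} (length {length}) too short for a "
                f"{size}-bp duplication"
            )
        for _attempt in range(1000):
            start = int(rng.integers(margin, length - size - margin))
            end = start + size
            buffered = (start - 10_000, end + 10_000)
            if all(e <= buffered[0] or s >= buffered[1] for s, e in used[chrom]):
                break
        else:
            raise RuntimeError(f"could not place CNV {k} on {chrom} without overlap")
        used[chrom].append((start, end))
        _engineer_microhomology(reference[chrom], start, end, mh)
        mh_seq = (
            reference[chrom][start - mh : start].tobytes().decode("ascii") if mh else ""
        )
        parent = PATERNAL if rng.random() < 0.5 else MATERNAL
        events.append(
            CnvEvent(
                chrom=chrom,
                start=start,
                end=end,
                cnv_type="DUP",
                parent_of_origin=parent,
                mh_len=mh,
                mh_seq=mh_seq,
            )
        )
    return events


def _sample_inherited_snps(
    config: SimConfig, reference: dict[str, np.ndarray], rng: np.random.Generator
) -> pd.DataFrame:
    frames = []
    for chrom, length in config.chrom_lengths.items():
        n = rng.binomial(length, config.snp_density)
        if n == 0:
            continue
        pos = np.sort(rng.choice(length, size=n, replace=False))
        af = rng.uniform(0.05, 0.95, size=n)
        father = rng.random((n, 2)) < af[:, None]
        mother = rng.random((n, 2)) < af[:, None]
        pat_idx = rng.integers(0, 2, size=n)
        mat_idx = rng.integers(0, 2, size=n)
        pat_allele = father[np.arange(n), pat_idx].astype(int)
        mat_allele = mother[np.arange(n), mat_idx].astype(int)
        keep = father.any(axis=1) | mother.any(axis=1)
        if not keep.any():
            continue
        ref_bases = (
            reference[chrom][pos[keep]].astype("U1")
            if isinstance(reference[chrom], np.ndarray)
            else np.array([reference[chrom][p] for p in pos[keep]])
        )
        alt_bases = np.array(
            [
                _TRANSITION[b] if rng.random() < 2 / 3 else _random_transversion(b, rng)
                for b in ref_bases
            ]
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos0": pos[keep],
                    "ref": ref_bases,
                    "alt": alt_bases,
                    "father_a1": father[keep, 0].astype(int),
                    "father_a2": father[keep, 1].astype(int),
                    "mother_a1": mother[keep, 0].astype(int),
                    "mother_a2": mother[keep, 1].astype(int),
                    "pat_allele": pat_allele[keep],
                    "mat_allele": mat_allele[keep],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "chrom",
                "pos0",
                "ref",
                "alt",
                "father_a1",
                "father_a2",
                "mother_a1",
                "mother_a2",
                "pat_allele",
                "mat_allele",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def _random_transversion(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in BASES if b != base and b != _TRANSITION[base]]
    return choices[int(rng.integers(0, 2))]


def _build_blocks(
    config: SimConfig, snp: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    het = snp[snp["pat_allele"] != snp["mat_allele"]]
    site_rows = []
    origin_rows = []
    block_id = 0
    for chrom, grp in het.groupby("chrom", sort=True):
        pos = grp["pos0"].to_numpy()
        pat = grp["pat_allele"].to_numpy()
        mat = grp["mat_allele"].to_numpy()
        n = len(pos)
        if n == 0:
            continue
        breaks = rng.random(n - 1) < config.block_break_prob if n > 1 else np.array([])
        bounds = np.flatnonzero(breaks) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [n]))
        for s, e in zip(starts, ends):
            origin = PATERNAL if rng.random() < 0.5 else MATERNAL
            hap_a = pat[s:e] if origin == PATERNAL else mat[s:e]
            hap_b = mat[s:e] if origin == PATERNAL else pat[s:e]
            origin_rows.append(
                {
                    "block_id": block_id,
                    "chrom": chrom,
                    "start": int(pos[s]),
                    "end": int(pos[e - 1]) + 1,
                    "n_sites": int(e - s),
                    "hap_a_origin": origin,
                }
            )
            site_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos0": pos[s:e],
                        "block_id": block_id,
                        "hap_a": hap_a,
                        "hap_b": hap_b,
                        "pat_allele": pat[s:e],
                        "mat_allele": mat[s:e],
                    }
                )
            )
            block_id += 1
    block_sites = (
        pd.concat(site_rows, ignore_index=True)
        if site_rows
        else pd.DataFrame(
            columns=["chrom", "pos0", "block_id", "hap_a", "hap_b", "pat_allele", "mat_allele"]
        )
    )
    block_origins = pd.DataFrame(
        origin_rows,
        columns=["block_id", "chrom", "start", "end", "n_sites", "hap_a_origin"],
    )
    return block_sites, block_origins


def _place_dnm_truth(
    config: SimConfig,
    reference: dict[str, np.ndarray],
    cnvs: list[CnvEvent],
    snp: pd.DataFrame,
    block_sites: pd.DataFrame,
    block_origins: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_total = config.n_germline_dnm + config.n_postzygotic_dnm
    forbidden = set(zip(snp["chrom"], snp["pos0"]))
    positions = sample_dnm_positions(
        config.chrom_lengths,
        cnvs,
        n_total,
        config.enrichment_factor,
        config.enrichment_distance,
        rng,
        min_sep=21,
        forbidden=forbidden,
    )
    lo, hi = config.postzygotic_vaf_range
    rows = []
    for i, (chrom, pos0) in enumerate(positions):
        ref = reference[chrom][pos0].decode("ascii")
        alt = (
            _TRANSITION[ref]
            if rng.random() < 2 / 3
            else _random_transversion(ref, rng)
        )
        germline = i < config.n_germline_dnm
        if germline:
            parent = PATERNAL if rng.random() < config.paternal_fraction else MATERNAL
            vaf = 0.5
        else:
            parent = PATERNAL if rng.random() < 0.5 else MATERNAL
            vaf = float(rng.uniform(lo, hi))
        rows.append(
            {
                "chrom": chrom,
                "pos0": pos0,
                "ref": ref,
                "alt": alt,
                "zygosity": GERMLINE if germline else POST_ZYGOTIC,
                "parent": parent,
                "true_vaf": vaf,
            }
        )
    dnms = pd.DataFrame(rows).sort_values(["chrom", "pos0"], kind="stable")
    dnms = dnms.reset_index(drop=True)

    # attach the carrying haplotype through the truth blocks
    block_ids = np.full(len(dnms), -1, dtype=int)
    haps = np.array([""] * len(dnms), dtype=object)
    by_chrom = {c: g for c, g in block_origins.groupby("chrom")}
    for i, row in dnms.iterrows():
        grp = by_chrom.get(row["chrom"])
        if grp is None:
            continue
        hit = grp[(grp["start"] <= row["pos0"]) & (row["pos0"] < grp["end"])]
        if hit.empty:
            continue
        blk = hit.iloc[0]
        block_ids[i] = blk["block_id"]
        haps[i] = "A" if blk["hap_a_origin"] == row["parent"] else "B"
    dnms["block_id"] = block_ids
    dnms["hap"] = haps
    dnms["pos"] = dnms["pos0"] + 1
    return dnms[
        ["chrom", "pos", "pos0", "ref", "alt", "zygosity", "parent", "true_vaf", "block_id", "hap"]
    ]


def _gt(a1: int, a2: int) -> str:
    a, b = sorted((a1, a2))
    return f"{a}/{b}"


def _dup_adjusted_child_vaf(
    snp: pd.DataFrame, cnvs: list[CnvEvent]
) -> tuple[np.ndarray, np.ndarray]:
    """Child allele fraction at inherited sites, accounting for planted
    duplications: inside a duplication the allele on the duplicated
    (parent-of-origin) haplotype is present in 2 of 3 copies."""
    pat = snp["pat_allele"].to_numpy()
    mat = snp["mat_allele"].to_numpy()
    vaf = (pat + mat) / 2.0
    depth_scale = np.ones(len(snp))
    for cnv in cnvs:
        inside = (
            (snp["chrom"] == cnv.chrom).to_numpy()
            & (snp["pos0"].to_numpy() >= cnv.start)
            & (snp["pos0"].to_numpy() < cnv.end)
        )
        if not inside.any():
            continue
        dup_allele = pat if cnv.parent_of_origin == PATERNAL else mat
        other = mat if cnv.parent_of_origin == PATERNAL else pat
        vaf[inside] = (2 * dup_allele[inside] + other[inside]) / 3.0
        depth_scale[inside] = 1.5
    return vaf, depth_scale


def _assemble_variants(
    config: SimConfig,
    snp: pd.DataFrame,
    dnms: pd.DataFrame,
    cnvs: list[CnvEvent],
    rng: np.random.Generator,
) -> pd.DataFrame:
    parts = []
    if len(snp):
        snp_vaf, snp_depth_scale = _dup_adjusted_child_vaf(snp, cnvs)
        parts.append(
            pd.DataFrame(
                {
                    "chrom": snp["chrom"],
                    "pos": snp["pos0"] + 1,
                    "ref": snp["ref"],
                    "alt": snp["alt"],
                    "child_gt": [
                        _gt(p, m) for p, m in zip(snp["pat_allele"], snp["mat_allele"])
                    ],
                    "father_gt": [
                        _gt(a, b) for a, b in zip(snp["father_a1"], snp["father_a2"])
                    ],
                    "mother_gt": [
                        _gt(a, b) for a, b in zip(snp["mother_a1"], snp["mother_a2"])
                    ],
                    "true_child_vaf": snp_vaf,
                    "child_depth_scale": snp_depth_scale,
                }
            )
        )
    if len(dnms):
        parts.append(
            pd.DataFrame(
                {
                    "chrom": dnms["chrom"],
                    "pos": dnms["pos"],
                    "ref": dnms["ref"],
                    "alt": dnms["alt"],
                    "child_gt": "0/1",
                    "father_gt": "0/0",
                    "mother_gt": "0/0",
                    "true_child_vaf": dnms["true_vaf"],
                    "child_depth_scale": 1.0,
                }
            )
        )
    if not parts:
        raise ValueError("simulation produced no variant sites")
    table = pd.concat(parts, ignore_index=True)
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    n = len(table)
    gt_vaf = {"0/0": 0.0, "0/1": 0.5, "1/1": 1.0}
    for sample, gt_col in (
        ("child", "child_gt"),
        ("father", "father_gt"),
        ("mother", "mother_gt"),
    ):
        mean = config.mean_depth
        if sample == "child":
            mean = config.mean_depth * table["child_depth_scale"].to_numpy(dtype=float)
        depth = np.maximum(rng.poisson(mean, size=n), 1)
        vaf = table[gt_col].map(gt_vaf).to_numpy(dtype=float)
        if sample == "child":
            vaf = table["true_child_vaf"].to_numpy(dtype=float)
        alt = rng.binomial(depth, vaf)
        table[f"{sample}_ref"] = depth - alt
        table[f"{sample}_alt"] = alt
        table[f"{sample}_gq"] = np.minimum(99, 3 * depth)
    table["child_adf"] = rng.binomial(table["child_alt"].to_numpy(), 0.5)
    table["child_adr"] = table["child_alt"] - table["child_adf"]
    table["repeat_masked"] = False
    table["near_indel"] = False
    return table[TRIO_COLUMNS]


# ---------------------------------------------------------------------------
# binned depth simulation for the copy-number stage


def simulate_depth_bins(
    chrom_lengths: dict[str, int],
    cnvs: Sequence[CnvEvent],
    mean_depth: float = 35.0,
    bin_size: int = 1000,
    read_length: int = 150,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Binned read-depth evidence in mosdepth style.

    The mean depth of a 1000-bp bin aggregates many reads, so its noise
    is governed by the *fragment* count: reads per bin are Poisson with
    mean ``mean_depth * bin_size / read_length`` scaled by the local
    copy ratio (1.5 over a heterozygous duplication, 0.5/0.0 over
    het/hom deletions, 2.0 over a triplication), and the bin depth is
    reads * read_length / bin_size.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ratios = {"DUP": 1.5, "DEL": 0.5, "HOMDEL": 0.0, "TRP": 2.0}
    frag_per_bin = mean_depth * bin_size / read_length
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        ratio = np.ones(len(starts))
        for cnv in cnvs:
            if cnv.chrom != chrom:
                continue
            lo = cnv.start // bin_size
            hi = (cnv.end + bin_size - 1) // bin_size
            ratio[lo:hi] = ratios.get(cnv.cnv_type, 1.5)
        reads = rng.poisson(frag_per_bin * ratio)
        depth = reads * read_length / bin_size
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "depth": depth}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# writers / readers


def write_fasta(reference: dict[str, np.ndarray], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq.tobytes().decode("ascii")), id=chrom, description="")
        for chrom, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_cnv_bed(cnvs: Sequence[CnvEvent], path) -> None:
    with open(path, "w") as fh:
        for cnv in cnvs:
            name = cnv.cnv_type
            if cnv.parent_of_origin:
                name += f";{cnv.parent_of_origin}"
            if cnv.mh_len is not None:
                name += f";mh={cnv.mh_len}"
            fh.write(f"{cnv.chrom}\t{cnv.start}\t{cnv.end}\t{name}\n")


def write_trio_vcf(variants: pd.DataFrame, chrom_lengths: dict[str, int], path) -> None:
    """Emit the trio table as an uncompressed VCF v4.2 with GT/AD/GQ and
    the custom ADF/ADR strand-count fields on the proband."""
    import pysam

    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.add_line(
        '##INFO=<ID=RM,Number=0,Type=Flag,Description="Overlaps repeat mask">'
    )
    header.add_line(
        '##INFO=<ID=NI,Number=0,Type=Flag,Description="Within 5 bp of an indel call">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_line(
        '##FORMAT=<ID=ADF,Number=1,Type=Integer,Description="Forward-strand alt reads">'
    )
    header.add_line(
        '##FORMAT=<ID=ADR,Number=1,Type=Integer,Description="Reverse-strand alt reads">'
    )
    for sample in ("proband", "father", "mother"):
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in variants.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
            )
            if row.repeat_masked:
                rec.info["RM"] = True
            if row.near_indel:
                rec.info["NI"] = True
            gts = {
                "proband": row.child_gt,
                "father": row.father_gt,
                "mother": row.mother_gt,
            }
            ads = {
                "proband": (int(row.child_ref), int(row.child_alt)),
                "father": (int(row.father_ref), int(row.father_alt)),
                "mother": (int(row.mother_ref), int(row.mother_alt)),
            }
            gqs = {
                "proband": int(row.child_gq),
                "father": int(row.father_gq),
                "mother": int(row.mother_gq),
            }
            for sample in ("proband", "father", "mother"):
                a, b = gts[sample].split("/")
                rec.samples[sample]["GT"] = (int(a), int(b))
                rec.samples[sample].phased = False
                rec.samples[sample]["AD"] = ads[sample]
                rec.samples[sample]["GQ"] = gqs[sample]
            rec.samples["proband"]["ADF"] = int(row.child_adf)
            rec.samples["proband"]["ADR"] = int(row.child_adr)
            vcf.write(rec)


def read_trio_vcf(path) -> pd.DataFrame:
    """Parse a trio VCF (proband/father/mother samples) back into the
    canonical trio table; inverse of :func:`write_trio_vcf`."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        missing = {"proband", "father", "mother"} - set(samples)
        if missing:
            raise ValueError(f"trio VCF lacks samples: {sorted(missing)}")
        for rec in vcf:
            fmt = {}
            for sample, label in (
                ("proband", "child"),
                ("father", "father"),
                ("mother", "mother"),
            ):
                call = rec.samples[sample]
                gt = call["GT"]
                fmt[f"{label}_gt"] = "/".join(str(a) for a in gt)
                ad = call["AD"]
                fmt[f"{label}_ref"], fmt[f"{label}_alt"] = int(ad[0]), int(ad[1])
                fmt[f"{label}_gq"] = int(call["GQ"])
            adf = rec.samples["proband"].get("ADF")
            adr = rec.samples["proband"].get("ADR")
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    **fmt,
                    "child_adf": int(adf) if adf is not None else 0,
                    "child_adr": int(adr) if adr is not None else 0,
                    "repeat_masked": "RM" in rec.info,
                    "near_indel": "NI" in rec.info,
                }
            )
    return pd.DataFrame(rows, columns=TRIO_COLUMNS)
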