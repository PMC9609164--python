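"""Poisson test for de novo mutation clustering near dnCNV breakpoints.

The regional interval for each CNV is the event plus a flanking window
on either side (default 4 Mb, so a ~1 Mb duplication yields a ~9 Mb
interval). Windows are clipped to chromosome ends and overlapping
windows are merged so no mutation is double-counted. Under the null,
mutations fall uniformly over the mappable genome, so the expected
count in the merged windows is

    lambda = total_dnm * window_length / genome_size

with genome_size the mappable *diploid* size for unphased counts, or
the haploid size with per-parent extrapolated counts for the phased
variant. The reported p is the upper tail P(Poisson(lambda) >= observed),
i.e. the probability of the same or more mutations.

The human-scale preset uses a mappable haploid size of 2.91e9 bp
(faCount non-N bases of GRCh38), diploid 5.82e9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import CnvEvent
from .synthetic_trio import _merge_intervals  # shared interval arithmetic

#: non-N GRCh38 bases per haploid genome (faCount)
MAPPABLE_HAPLOID_GRCH38 = 2.91e9
DEFAULT_FLANK = 4_000_000

PLOIDY_MODES = ("diploid", "haploid-paternal", "haploid-maternal")


@dataclass
class WindowSet:
    """Merged per-chromosome intervals (0-based half-open) around CNVs."""

    intervals: dict[str, list[tuple[int, int]]]
    flank: int

    @property
    def total_length(self) -> int:
        return sum(e - s for ws in self.intervals.values() for s, e in ws)

    def contains(self, chrom: str, pos: int) -> bool:
        for s, e in self.intervals.get(chrom, ()):
            if s <= pos < e:
                return True
        return False


@dataclass
class ClusterTestResult:
    observed: int
    expected: float
    p_value: float
    flank: int
    genome_size: float
    ploidy_mode: str
    degenerate: bool = False


def mappable_size(fasta) -> int:
    """Count A/C/G/T bases (case-insensitive) in a FASTA file or a
    mapping of name -> sequence; N and other ambiguity codes are
    excluded, mirroring faCount's non-N total."""
    if isinstance(fasta, (str,)) or hasattr(fasta, "__fspath__"):
        from pyfaidx import Fasta

        fa = Fasta(str(fasta), one_based_attributes=False)
        if len(fa.keys()) == 0:
            raise ValueError(f"no sequences in {fasta}")
        total = 0
        for name in fa.keys():
            seq = str(fa[name][:]).upper()
            total += sum(seq.count(b) for b in "ACGT")
        return total
    total = 0
    for name, seq in fasta.items():
        if isinstance(seq, np.ndarray):
            seq = seq.tobytes().decode("ascii")
        seq = str(seq).upper()
        total += sum(seq.count(b) for b in "ACGT")
    return total


def build_windows(
    cnvs: Sequence[CnvEvent],
    flank: int,
    chrom_lengths: dict[str, int],
) -> WindowSet:
    """Per-event window [start - flank, end + flank], clipped to the
    chromosome and merged per chromosome."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for cnv in cnvs:
        if cnv.chrom not in chrom_lengths:
            raise KeyError(f"unknown chromosome {cnv.chrom}")
        length = chrom_lengths[cnv.chrom]
        if cnv.end > length:
            raise ValueError(
                f"CNV {cnv.chrom}:{cnv.start}-{cnv.end} beyond chromosome end {length}"
            )
        per_chrom.setdefault(cnv.chrom, []).append(
            (max(0, cnv.start - flank), min(length, cnv.end + flank))
        )
    return WindowSet(
        intervals={c: _merge_intervals(w) for c, w in per_chrom.items()}, flank=flank
    )


def poisson_tail(observed: int, lam: float) -> float:
    """P(Poisson(lam) >= observed), the same-or-more tail."""
    if observed <= 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))


def count_in_windows(
    dnm_positions: pd.DataFrame, windows: WindowSet
) -> int:
    """Number of mutations (columns chrom, pos; 1-based) inside the
    merged windows."""
    count = 0
    for row in dnm_positions.itertuples(index=False):
        if windows.contains(row.chrom, int(row.pos) - 1):
            count += 1
    return count


def poisson_cluster_test(
    dnm_positions: pd.DataFrame,
    windows: WindowSet,
    total_dnm: int,
    genome_size: float,
    ploidy_mode: str = "diploid",
    observed: Optional[int] = None,
) -> ClusterTestResult:
    """Poisson tail test of regional DNM excess.

    ``total_dnm`` is the genome-wide count matching ``ploidy_mode``:
    all DNMs with the diploid genome size, or the per-parent
    extrapolated count with the haploid size. ``observed`` overrides
    the window count (used when positions are not available but the
    in-window count is known).
    """
    if ploidy_mode not in PLOIDY_MODES:
        raise ValueError(f"ploidy_mode must be one of {PLOIDY_MODES}")
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    length = windows.total_length
    if length > genome_size:
        raise ValueError("window length exceeds genome size")
    lam = total_dnm * length / genome_size
    if observed is None:
        observed = count_in_windows(dnm_positions, windows)
    degenerate = lam == 0 and observed > 0
    p = 0.0 if degenerate else poisson_tail(observed, lam)
    return ClusterTestResult(
        observed=int(observed),
        expected=float(lam),
        p_value=p,
        flank=windows.flank,
        genome_size=float(genome_size),
        ploidy_mode=ploidy_mode,
        degenerate=degenerate,
    )


def density_scan(
    dnm_positions: pd.DataFrame,
    cnvs: Sequence[CnvEvent],
    chrom_lengths: dict[str, int],
    flanks: Sequence[int] = tuple(int(f) for f in np.arange(1, 11) * 1_000_000),
) -> pd.DataFrame:
    """Observed DNM density (count / merged window length) for a range
    of flanking window sizes (default 1..10 Mb)."""
    rows = []
    for flank in flanks:
        windows = build_windows(cnvs, int(flank), chrom_lengths)
        observed = count_in_windows(dnm_positions, windows)
        length = windows.total_length
        rows.append(
            {
                "flank": int(flank),
                "observed": observed,
                "window_length": length,
                "density": observed / length if length else np.nan,
            }
        )
    return pd.DataFrame(rows)


def distance_to_nearest_breakpoint(
    chrom: str, pos: int, cnvs: Sequence[CnvEvent]
) -> float:
    """Distance (bp) from a 1-based mutation position to the nearest CNV
    breakpoint on the same chromosome; +inf when that chromosome carries
    no CNV. A mutation inside a CNV gets the distance to the nearer
    endpoint."""
    if not cnvs:
        raise ValueError("need at least one CNV")
    pos0 = pos - 1
    best = float("inf")
    for cnv in cnvs:
        if cnv.chrom != chrom:
            continue
        for bp in cnv.breakpoints:
            best = min(best, abs(pos0 - bp))
    return best


def distances_table(dnms: pd.DataFrame, cnvs: Sequence[CnvEvent]) -> pd.Series:
    return pd.Series(
        [
            distance_to_nearest_breakpoint(row.chrom, int(row.pos), cnvs)
            for row in dnms.itertuples(index=False)
        ],
        index=dnms.index,
        name="breakpoint_distance",
    )
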