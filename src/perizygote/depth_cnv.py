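"""Read-depth copy-number analysis: log2 ratios, CBS segmentation,
threshold calls, B-allele frequency and AOH runs.

Coverage arrives as mean depth per 1000-bp bin (mosdepth-style regions).
Each chromosome is normalised by its own median bin depth and converted
to log2 ratios, so 0 is the diploid baseline; a heterozygous duplication
sits near log2(1.5) ~ 0.585. Profiles are segmented with a circular
binary segmentation (CBS) scheme: the best arc of each segment is found
by maximising a circular t-like statistic and accepted when a
permutation test rejects homogeneity, recursing into the parts.
Segment means are called against the fixed thresholds: gain when
mean log2 > 0.58, loss when mean < -1, else neutral.

B-allele frequency (BAF) profiles are alt/(ref+alt) at heterozygous
sites; runs of absence of heterozygosity (AOH) are maximal stretches of
at least ``min_span`` bp in which fewer than ``het_fraction`` of sites
show a heterozygous BAF (within [0.2, 0.8]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GAIN_THRESHOLD = 0.58
LOSS_THRESHOLD = -1.0
ZERO_DEPTH_FLOOR = -5.0
BIN_SIZE = 1000

CBS_ALPHA = 0.01
CBS_PERMUTATIONS = 1000
CBS_MIN_WIDTH = 3


@dataclass
class DepthProfile:
    """Per-chromosome binned depth with median-normalised log2 ratios."""

    chrom: str
    start: np.ndarray  # bin starts, 0-based
    end: np.ndarray
    depth: np.ndarray
    log2: np.ndarray
    floored: np.ndarray  # bins with zero depth, set to the floor

    def __len__(self) -> int:
        return len(self.start)


@dataclass
class Segment:
    chrom: str
    start_bin: int
    end_bin: int  # half-open in bin index space
    start: int
    end: int  # genomic, 0-based half-open
    mean_log2: float
    call: str = "neutral"

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


def normalize_log2(
    bins: pd.DataFrame, floor: float = ZERO_DEPTH_FLOOR
) -> list[DepthProfile]:
    """Median-normalise binned depth per chromosome and take log2.

    ``bins`` has columns chrom, start, end, depth. Zero-depth bins are
    set to ``floor`` and flagged rather than producing -inf. A
    chromosome whose median depth is zero cannot be normalised.
    """
    profiles = []
    for chrom, grp in bins.groupby("chrom", sort=True):
        depth = grp["depth"].to_numpy(dtype=float)
        med = float(np.median(depth))
        if med <= 0:
            raise ValueError(f"median depth of {chrom} is zero; cannot normalise")
        with np.errstate(divide="ignore"):
            log2 = np.log2(depth / med)
        floored = depth == 0
        log2[floored] = floor
        profiles.append(
            DepthProfile(
                chrom=chrom,
                start=grp["start"].to_numpy(),
                end=grp["end"].to_numpy(),
                depth=depth,
                log2=log2,
                floored=floored,
            )
        )
    return profiles


try:  # the O(n^2) arc search dominates runtime; JIT it when possible
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    njit = None


def _arc_search_py(cs: np.ndarray, s: float, n: int, min_width: int):
    best, bi, bj = 0.0, 0, n
    total = cs[n]
    for k in range(min_width, n // 2 + 1):
        inv = 1.0 / k + 1.0 / (n - k)
        denom = s * np.sqrt(inv)
        arc = cs[k : n + 1] - cs[: n - k + 1]
        t = np.abs(arc / k - (total - arc) / (n - k)) / denom
        j = int(np.argmax(t))
        if t[j] > best:
            best, bi, bj = float(t[j]), j, j + k
    return best, bi, bj


if njit is not None:

    @njit(cache=True)
    def _arc_search_jit(cs, s, n, min_width):  # pragma: no cover - jitted
        best = 0.0
        bi = 0
        bj = n
        total = cs[n]
        for k in range(min_width, n // 2 + 1):
            denom = s * np.sqrt(1.0 / k + 1.0 / (n - k))
            for i in range(n - k + 1):
                arc = cs[i + k] - cs[i]
                t = abs(arc / k - (total - arc) / (n - k)) / denom
                if t > best:
                    best = t
                    bi = i
                    bj = i + k
        return best, bi, bj

else:  # pragma: no cover
    _arc_search_jit = None


def _max_arc_stat(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Best circular arc (i, j] of ``x`` by the t-like statistic
    |mean(arc) - mean(rest)| / (s * sqrt(1/k + 1/(n-k))).

    Returns (statistic, i, j) with 0 <= i < j <= n describing the linear
    arc x[i:j]. An arc and its circular complement share split points
    and statistic value, so arcs up to length n/2 suffice.
    """
    n = len(x)
    s = float(np.std(x))
    if s == 0 or n < 2 * min_width:
        return 0.0, 0, n
    cs = np.concatenate(([0.0], np.cumsum(x)))
    if _arc_search_jit is not None:
        best, bi, bj = _arc_search_jit(cs, s, n, min_width)
        return float(best), int(bi), int(bj)
    return _arc_search_py(cs, s, n, min_width)


def _permutation_p(
    x: np.ndarray,
    observed: float,
    min_width: int,
    n_permutations: int,
    alpha: float,
    rng: np.random.Generator,
) -> float:
    """Sequential permutation p-value for the max arc statistic.

    Stops early once the split is clearly non-significant (the exceed
    count alone already pushes p past alpha) or clearly significant
    (no exceedances in the first 200 permutations).
    """
    exceed = 0
    done = 0
    batch = 25
    while done < n_permutations:
        m = min(batch, n_permutations - done)
        for _ in range(m):
            perm = rng.permutation(x)
            stat, _, _ = _max_arc_stat(perm, min_width)
            if stat >= observed:
                exceed += 1
        done += m
        if (exceed / n_permutations) > alpha:
            # even if no further permutation exceeded, p stays > alpha
            return exceed / done
        if exceed == 0 and done >= min(200, n_permutations):
            return 0.0
    return exceed / n_permutations


def segment_cbs(
    log2: np.ndarray,
    alpha: float = CBS_ALPHA,
    n_permutations: int = CBS_PERMUTATIONS,
    min_width: int = CBS_MIN_WIDTH,
    seed: int = 0,
    chrom: str = "chrN",
    bin_starts: Optional[np.ndarray] = None,
    bin_ends: Optional[np.ndarray] = None,
) -> list[Segment]:
    """Recursive circular binary segmentation of one log2 profile.

    Deterministic for a fixed seed. Degenerate inputs (constant or
    shorter than twice ``min_width``) return a single segment.
    """
    x = np.asarray(log2, dtype=float)
    n = len(x)
    if n == 0:
        return []
    if bin_starts is None:
        bin_starts = np.arange(n) * BIN_SIZE
    if bin_ends is None:
        bin_ends = bin_starts + BIN_SIZE
    rng = np.random.default_rng(seed)
    boundaries: list[int] = [0, n]

    def _recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if len(seg) < 2 * min_width:
            return
        stat, i, j = _max_arc_stat(seg, min_width)
        if stat == 0.0:
            return
        # Bonferroni bound over all arcs: when even this conservative
        # parametric bound is far below alpha the permutation test cannot
        # disagree, so the (expensive) permutations are skipped
        from scipy.stats import norm

        m = len(seg)
        p_bound = m * (m // 2) * 2.0 * float(norm.sf(stat))
        if p_bound < alpha / 10:
            p = p_bound
        else:
            p = _permutation_p(seg, stat, min_width, n_permutations, alpha, rng)
        if p >= alpha:
            return
        cuts = sorted({lo + i, lo + j})
        for c in cuts:
            if c not in boundaries and lo < c < hi:
                boundaries.append(c)
        pieces = sorted({lo, *[c for c in cuts if lo < c < hi], hi})
        for a, b in zip(pieces[:-1], pieces[1:]):
            _recurse(a, b)

    _recurse(0, n)
    boundaries = sorted(set(boundaries))
    segments = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        segments.append(
            Segment(
                chrom=chrom,
                start_bin=a,
                end_bin=b,
                start=int(bin_starts[a]),
                end=int(bin_ends[b - 1]),
                mean_log2=float(x[a:b].mean()),
            )
        )
    return segments


def segment_profile(profile: DepthProfile, **kwargs) -> list[Segment]:
    return segment_cbs(
        profile.log2,
        chrom=profile.chrom,
        bin_starts=profile.start,
        bin_ends=profile.end,
        **kwargs,
    )


def recenter_segments(segments: Sequence[Segment]) -> list[Segment]:
    """Re-baseline segment means to the longest (modal, copy-neutral)
    segment.

    Median normalisation leaves a small offset when a sizeable fraction
    of a chromosome is copy-altered (the median of the mixture is not
    the neutral mean), and the arithmetic mean of log2 values carries a
    concave-transform bias; both are shared by the neutral baseline, so
    subtracting the longest segment's mean cancels them. No-op for a
    single segment.
    """
    segs = list(segments)
    if len(segs) < 2:
        return segs
    baseline = max(segs, key=lambda s: s.n_bins).mean_log2
    for seg in segs:
        seg.mean_log2 -= baseline
    return segs


def call_cnv(
    segments: Sequence[Segment],
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> pd.DataFrame:
    """Call gain/neutral/loss per segment (strict thresholds: a mean of
    exactly 0.58 is neutral) and merge adjacent same-call segments into
    events with genomic coordinates."""
    called = []
    for seg in segments:
        if seg.mean_log2 > gain_threshold:
            call = "gain"
        elif seg.mean_log2 < loss_threshold:
            call = "loss"
        else:
            call = "neutral"
        seg.call = call
        called.append(seg)
    events = []
    for seg in called:
        prev = events[-1] if events else None
        if (
            prev is not None
            and prev["chrom"] == seg.chrom
            and prev["call"] == seg.call
            and prev["end"] == seg.start
        ):
            total = prev["n_bins"] + seg.n_bins
            prev["mean_log2"] = (
                prev["mean_log2"] * prev["n_bins"] + seg.mean_log2 * seg.n_bins
            ) / total
            prev["end"] = seg.end
            prev["n_bins"] = total
        else:
            events.append(
                {
                    "chrom": seg.chrom,
                    "start": seg.start,
                    "end": seg.end,
                    "call": seg.call,
                    "mean_log2": seg.mean_log2,
                    "n_bins": seg.n_bins,
                }
            )
    return pd.DataFrame(events, columns=["chrom", "start", "end", "call", "mean_log2", "n_bins"])


@dataclass
class AohRun:
    chrom: str
    start: int
    end: int
    n_sites: int
    het_fraction: float

    @property
    def span(self) -> int:
        return self.end - self.start


def baf_profile(sites: pd.DataFrame) -> pd.Series:
    """BAF = alt/(ref+alt) per site (columns ref_depth, alt_depth)."""
    total = sites["ref_depth"] + sites["alt_depth"]
    if (total <= 0).any():
        raise ValueError("BAF undefined at zero-depth sites")
    return (sites["alt_depth"] / total).rename("baf")


def aoh_runs(
    sites: pd.DataFrame,
    min_span: int = 2_000_000,
    max_het_fraction: float = 0.05,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> list[AohRun]:
    """Maximal AOH stretches per chromosome.

    ``sites`` has columns chrom, pos (1-based), ref_depth, alt_depth.
    A run is a maximal window spanning >= ``min_span`` bp in which the
    fraction of sites with BAF inside ``het_band`` stays below
    ``max_het_fraction``.
    """
    runs: list[AohRun] = []
    for chrom, grp in sites.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        baf = baf_profile(grp).to_numpy()
        het = (baf >= het_band[0]) & (baf <= het_band[1])
        n = len(pos)
        i = 0
        while i < n:
            if het[i]:
                i += 1
                continue
            # grow the window greedily while the het fraction stays low
            j = i
            het_count = 0
            best_j = i
            while j + 1 < n:
                nxt = het_count + int(het[j + 1])
                if nxt / (j + 2 - i) < max_het_fraction or not het[j + 1]:
                    j += 1
                    het_count = nxt
                    if not het[j]:
                        best_j = j
                else:
                    break
            span = int(pos[best_j] - pos[i])
            if span >= min_span:
                n_sites = best_j - i + 1
                frac = float(het[i : best_j + 1].sum() / n_sites)
                runs.append(
                    AohRun(
                        chrom=chrom,
                        start=int(pos[i]) - 1,
                        end=int(pos[best_j]),
                        n_sites=n_sites,
                        het_fraction=frac,
                    )
                )
            i = best_j + 1
    return runs


def read_depth_bins(path) -> pd.DataFrame:
    """Read a mosdepth-style regions table (chrom, start, end, depth)."""
    bins = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"]
    )
    return bins
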