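"""96-channel substitution spectra and strict signature refitting.

A spectrum counts single-base substitutions over the 96 channels formed
by the 6 pyrimidine-strand substitution types (C>A, C>G, C>T, T>A, T>C,
T>G) and the 16 one-base flanking contexts; substitutions with a purine
reference base are reverse-complemented onto the pyrimidine strand.
Channels follow the lexicographic ordering of the standard
``X[R>A]Y`` labels used by the COSMIC catalog files, so spectra are
comparable across runs and directly alignable with a catalog TSV in the
COSMIC column layout (channel rows x signature columns, each column a
probability vector).

Refitting solves the non-negative least squares problem
``min ||m - S x||_2, x >= 0``. The *strict* procedure guards against
overfitting: signatures are removed iteratively (always the one with
the least contribution, refitting after each removal) while the cosine
similarity between the spectrum and its reconstruction drops by less
than ``max_delta`` per removal; alternatively the *best-subset* mode
exhaustively scores the best subset of each size and stops growing the
subset when an extra signature improves the cosine by less than
``max_delta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .records import CnvEvent
from .sequtil import get_seq, revcomp

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the 96 channel labels in lexicographic (COSMIC file) order
CHANNELS: tuple[str, ...] = tuple(
    sorted(
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTIONS
        for five in "ACGT"
        for three in "ACGT"
    )
)

DEFAULT_MAX_DELTA = 0.004


def channel_for(ref: str, alt: str, triplet: str) -> str:
    """Map one substitution with its reference triplet (5'-X ref Y-3')
    to its pyrimidine-strand channel label."""
    triplet = triplet.upper()
    if len(triplet) != 3 or triplet[1] != ref.upper():
        raise ValueError(f"triplet {triplet!r} does not match ref {ref!r}")
    if ref in "AG":
        triplet = revcomp(triplet)
        ref, alt = revcomp(ref), revcomp(alt)
    return f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"


def build_spectrum(calls: pd.DataFrame, reference) -> pd.Series:
    """96-channel spectrum of SNV calls (columns chrom, pos, ref, alt;
    pos 1-based). The channel sum equals the number of SNVs."""
    counts = pd.Series(0, index=list(CHANNELS), dtype=int)
    for row in calls.itertuples(index=False):
        if len(row.ref) != 1 or len(row.alt) != 1:
            continue
        pos0 = int(row.pos) - 1
        triplet = get_seq(reference, row.chrom, pos0 - 1, pos0 + 2)
        if len(triplet) != 3:
            raise IndexError(f"no +/-1 bp context at {row.chrom}:{row.pos}")
        counts[channel_for(row.ref, row.alt, triplet)] += 1
    return counts


def exclude_near_cnv(
    calls: pd.DataFrame, cnvs: Sequence[CnvEvent], flank: int = 1_000_000
) -> pd.DataFrame:
    """Drop calls lying within any CNV or within ``flank`` bp of its
    breakpoints (context-bias control for signature reassessment)."""
    keep = np.ones(len(calls), dtype=bool)
    pos0 = calls["pos"].to_numpy() - 1
    for cnv in cnvs:
        inside = (
            (calls["chrom"] == cnv.chrom).to_numpy()
            & (pos0 >= cnv.start - flank)
            & (pos0 < cnv.end + flank)
        )
        keep &= ~inside
    return calls.loc[keep].reset_index(drop=True)


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def load_catalog(path) -> pd.DataFrame:
    """Read a signature catalog TSV in the COSMIC column layout (first
    column the channel label, one column per signature) and align it to
    the canonical channel order."""
    cat = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS) - set(cat.index)
    if missing:
        raise ValueError(f"catalog lacks {len(missing)} channels, e.g. {sorted(missing)[:3]}")
    cat = cat.loc[list(CHANNELS)]
    _validate_catalog(cat)
    return cat


def _validate_catalog(catalog: pd.DataFrame) -> None:
    if catalog.shape[0] != 96:
        raise ValueError("catalog must have 96 channel rows")
    if (catalog.to_numpy() < 0).any():
        raise ValueError("catalog entries must be non-negative")
    sums = catalog.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = sums[~np.isclose(sums, 1.0, atol=1e-6)].index.tolist()
        raise ValueError(f"catalog columns must sum to 1: {bad}")


def refit_nnls(spectrum, catalog: pd.DataFrame) -> pd.Series:
    """Non-negative least squares exposures ``argmin ||m - S x||, x>=0``
    over all catalog signatures."""
    if catalog.shape[1] == 0:
        raise ValueError("empty signature catalog")
    m = np.asarray(spectrum, dtype=float)
    x, _ = nnls(catalog.to_numpy(dtype=float), m)
    return pd.Series(x, index=catalog.columns, name="exposure")


@dataclass
class RefitResult:
    signatures: list[str]
    exposures: pd.Series
    reconstruction: np.ndarray
    cosine: float
    removal_trace: list[dict] = field(default_factory=list)
    method: str = "strict"


def _fit_subset(m: np.ndarray, catalog: pd.DataFrame, subset: Sequence[str]):
    sub = catalog[list(subset)]
    x, _ = nnls(sub.to_numpy(dtype=float), m)
    recon = sub.to_numpy(dtype=float) @ x
    cos = cosine_similarity(m, recon) if recon.any() and m.any() else 0.0
    return pd.Series(x, index=sub.columns), recon, cos


def strict_refit(
    spectrum,
    catalog: pd.DataFrame,
    max_delta: float = DEFAULT_MAX_DELTA,
) -> RefitResult:
    """Backward-elimination strict refit.

    Starting from all signatures, repeatedly drop the lowest-exposure
    signature and refit; a removal is kept while the reconstruction
    cosine decreases by less than ``max_delta``, and the last signature
    is never removed.
    """
    if catalog.shape[1] == 0:
        raise ValueError("empty signature catalog")
    m = np.asarray(spectrum, dtype=float)
    if not m.any():
        zeros = pd.Series(0.0, index=catalog.columns)
        return RefitResult(list(catalog.columns), zeros, np.zeros(len(m)), 0.0, [], "strict")
    current = list(catalog.columns)
    exposures, recon, cos = _fit_subset(m, catalog, current)
    trace: list[dict] = []
    while len(current) > 1:
        candidate = exposures.idxmin()
        reduced = [s for s in current if s != candidate]
        exp_r, recon_r, cos_r = _fit_subset(m, catalog, reduced)
        if cos - cos_r < max_delta:
            trace.append({"removed": candidate, "cosine_before": cos, "cosine_after": cos_r})
            current, exposures, recon, cos = reduced, exp_r, recon_r, cos_r
        else:
            break
    kept = [s for s in current if exposures[s] > 0] or current
    if kept != current:
        exposures, recon, cos = _fit_subset(m, catalog, kept)
        current = kept
    return RefitResult(current, exposures, recon, cos, trace, "strict")


def best_subset_refit(
    spectrum,
    catalog: pd.DataFrame,
    max_delta: float = DEFAULT_MAX_DELTA,
    max_combinations: int = 20_000,
) -> RefitResult:
    """Exhaustive best-subset strict refit.

    For each subset size the best-cosine subset is found by exhaustive
    NNLS; the subset stops growing when one more signature improves the
    cosine by less than ``max_delta``. Falls back to backward
    elimination when the combinatorial budget is exceeded.
    """
    if catalog.shape[1] == 0:
        raise ValueError("empty signature catalog")
    n = catalog.shape[1]
    total = sum(comb(n, k) for k in range(1, n + 1))
    if total > max_combinations:
        return strict_refit(spectrum, catalog, max_delta)
    m = np.asarray(spectrum, dtype=float)
    if not m.any():
        zeros = pd.Series(0.0, index=catalog.columns)
        return RefitResult(list(catalog.columns), zeros, np.zeros(len(m)), 0.0, [], "best_subset")
    best_by_size: list[tuple[float, tuple[str, ...]]] = []
    for k in range(1, n + 1):
        best = max(
            (
                ( _fit_subset(m, catalog, subset)[2], subset)
                for subset in combinations(catalog.columns, k)
            ),
            key=lambda t: t[0],
        )
        best_by_size.append(best)
        if k > 1 and best_by_size[-1][0] - best_by_size[-2][0] < max_delta:
            chosen = best_by_size[-2][1]
            break
    else:
        chosen = best_by_size[-1][1]
    exposures, recon, cos = _fit_subset(m, catalog, chosen)
    trace = [
        {"size": k + 1, "best_cosine": c, "subset": list(s)}
        for k, (c, s) in enumerate(best_by_size)
    ]
    return RefitResult(list(chosen), exposures, recon, cos, trace, "best_subset")


def synthetic_catalog(n_signatures: int = 5, seed: int = 0, concentration: float = 0.5) -> pd.DataFrame:
    """A synthetic signature catalog (Dirichlet-random probability
    columns over the 96 channels) for demonstrations and tests; not a
    published catalog."""
    rng = np.random.default_rng(seed)
    cols = {
        f"SYN{i + 1}": rng.dirichlet(np.full(96, concentration))
        for i in range(n_signatures)
    }
    cat = pd.DataFrame(cols, index=list(CHANNELS))
    _validate_catalog(cat)
    return cat


def sample_spectrum(
    exposures: Mapping[str, float] | pd.Series,
    catalog: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> pd.Series:
    """Draw a Poisson-noised spectrum from given signature exposures
    (expected counts per signature)."""
    expected = np.zeros(96)
    for name, w in dict(exposures).items():
        expected += w * catalog[name].to_numpy()
    if rng is None:
        return pd.Series(expected, index=list(CHANNELS))
    return pd.Series(rng.poisson(expected), index=list(CHANNELS))


def strict_refit_best_subset(
    spectrum,
    catalog: pd.DataFrame,
    max_delta: float = DEFAULT_MAX_DELTA,
    method: str = "strict",
) -> RefitResult:
    """Dispatch between the two strict-refit modes (``strict`` backward
    elimination, ``best_subset`` exhaustive)."""
    if method == "strict":
        return strict_refit(spectrum, catalog, max_delta)
    if method == "best_subset":
        return best_subset_refit(spectrum, catalog, max_delta)
    raise ValueError(f"unknown refit method {method!r}")
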