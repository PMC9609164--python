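"""Breakpoint-junction characterisation for tandem duplications.

A tandem-duplication junction joins the distal breakpoint back to the
proximal one, so replicative repair leaves its fingerprint as sequence
identity between the two flanks: the *microhomology* is the longest k
such that the k reference bases ending at the distal breakpoint equal
the k bases ending at the proximal breakpoint. *Microhomeology* relaxes
the match to a minimum identity fraction (near-exact homology), and is
reported only when the exact homology is shorter than ``min_len``.
When an observed junction read is supplied, bases at the join matching
neither flank are reported as a templated-nowhere insertion (with
homology 0, the two descriptions being mutually exclusive).

Non-B DNA motif detectors scan +/- ``window`` bp around each breakpoint
on both strands for six motif classes (Z-DNA, G-quadruplex, A-phased
repeats, inverted repeats, mirror repeats, direct repeats). The
detection rules are fixed, documented constants of this module; they
are deliberately simple pattern rules, not a rescoring of any
published web service.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .records import CnvEvent
from .sequtil import get_seq, revcomp

SEARCH_WINDOW = 30
MOTIF_WINDOW = 50

# motif rule constants
G4_PATTERN = re.compile(r"G{3,}(?:[ACGT]{1,7}G{3,}){3}")
ZDNA_MIN_LEN = 10
APR_TRACT = re.compile(r"A{4,9}")
APR_MIN_TRACTS = 3
APR_SPACING = (9, 11)  # centre-to-centre distance of successive A-tracts
DIRECT_MIN_UNIT = 10
DIRECT_MAX_SPACER = 10
INVERTED_MIN_ARM = 6
INVERTED_MAX_LOOP = 100
MIRROR_MIN_ARM = 10
MIRROR_MAX_LOOP = 100

MOTIF_CLASSES = (
    "Z-DNA",
    "G-quadruplex",
    "A-phased repeat",
    "inverted repeat",
    "mirror repeat",
    "direct repeat",
)


@dataclass
class JunctionCall:
    """A tandem-duplication junction described in reference coordinates
    (0-based half-open; proximal < distal on one chromosome)."""

    chrom: str
    proximal: int
    distal: int
    cnv_type: str = "DUP"
    junction_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.proximal >= self.distal:
            raise ValueError("proximal breakpoint must precede the distal one")

    @classmethod
    def from_cnv(cls, cnv: CnvEvent, junction_seq: Optional[str] = None) -> "JunctionCall":
        return cls(cnv.chrom, cnv.start, cnv.end, cnv.cnv_type, junction_seq)


@dataclass
class MicrohomologyResult:
    length: int
    sequence: str
    insertion: str = ""
    identity: float = 1.0
    kind: str = "microhomology"  # or "microhomeology" / "insertion"


@dataclass
class MotifHit:
    motif_class: str
    start: int  # reference coordinates, 0-based half-open
    end: int
    strand: str
    sequence: str


def microhomology(
    reference,
    junction: JunctionCall,
    max_len: int = SEARCH_WINDOW,
) -> MicrohomologyResult:
    """Exact junctional microhomology of a tandem duplication.

    Compares the ``max_len`` bases ending at each breakpoint and returns
    the longest shared suffix. With an observed junction sequence,
    unmatched bases at the join are returned as an insertion instead.
    """
    prox, dist = junction.proximal, junction.distal
    left_start = max(0, prox - max_len)
    flank_prox = get_seq(reference, junction.chrom, left_start, prox)
    flank_dist = get_seq(reference, junction.chrom, dist - (prox - left_start), dist)
    k = 0
    while (
        k < len(flank_prox)
        and k < len(flank_dist)
        and flank_prox[-1 - k] == flank_dist[-1 - k]
    ):
        k += 1
    if junction.junction_seq:
        insertion = _junction_insertion(reference, junction)
        if insertion:
            return MicrohomologyResult(0, "", insertion=insertion, kind="insertion")
    seq = flank_prox[len(flank_prox) - k :] if k else ""
    return MicrohomologyResult(k, seq)


def _junction_insertion(reference, junction: JunctionCall) -> str:
    """Bases in the observed junction read templated by neither flank.

    The read is expected to run ref[distal-L:distal] + insertion +
    ref[proximal:proximal+R] with L and R unknown, so the left flank is
    the longest read prefix that *ends* at the distal breakpoint and the
    right flank the longest read suffix that *starts* at the proximal
    one; whatever sits between is the insertion.
    """
    obs = junction.junction_seq.upper()
    n = len(obs)
    left = 0
    for length in range(n, 0, -1):
        if junction.distal - length < 0:
            continue
        if obs[:length] == get_seq(
            reference, junction.chrom, junction.distal - length, junction.distal
        ):
            left = length
            break
    right = 0
    for length in range(n - left, 0, -1):
        if obs[n - length :] == get_seq(
            reference, junction.chrom, junction.proximal, junction.proximal + length
        ):
            right = length
            break
    return obs[left : n - right]


def microhomeology(
    reference,
    junction: JunctionCall,
    min_identity: float = 0.8,
    min_len: int = 5,
    max_len: int = SEARCH_WINDOW,
) -> MicrohomologyResult:
    """Mismatch-tolerant junctional homology.

    When the exact microhomology reaches ``min_len`` it is returned
    unchanged; otherwise the longest flank-suffix alignment with
    identity >= ``min_identity`` is reported as microhomeology, and a
    zero-length result means no call above threshold.
    """
    exact = microhomology(reference, junction, max_len=max_len)
    if exact.length >= min_len or exact.kind == "insertion":
        return exact
    prox, dist = junction.proximal, junction.distal
    limit = min(max_len, prox, dist - prox)
    for length in range(limit, min_len - 1, -1):
        a = get_seq(reference, junction.chrom, prox - length, prox)
        b = get_seq(reference, junction.chrom, dist - length, dist)
        if a[0] != b[0]:
            # the homeology tract must begin on a matched base, else the
            # same alignment minus its mismatched edge scores higher
            continue
        matches = sum(x == y for x, y in zip(a, b))
        identity = matches / length
        if identity >= min_identity:
            return MicrohomologyResult(
                length, a, identity=identity, kind="microhomeology"
            )
    return exact


# ---------------------------------------------------------------------------
# non-B DNA motif detectors


def _is_purine(b: str) -> bool:
    return b in "AG"


def _find_zdna(seq: str) -> list[tuple[int, int]]:
    """Maximal runs >= ZDNA_MIN_LEN of alternating purine/pyrimidine
    with no A-T steps (dinucleotide steps restricted to GC/GT/AC)."""
    hits = []
    n = len(seq)
    i = 0
    while i < n - 1:
        j = i
        while (
            j + 1 < n
            and _is_purine(seq[j]) != _is_purine(seq[j + 1])
            and {seq[j], seq[j + 1]} != {"A", "T"}
        ):
            j += 1
        if j - i + 1 >= ZDNA_MIN_LEN:
            hits.append((i, j + 1))
        i = max(j, i + 1)
    return hits


def _find_g4(seq: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in G4_PATTERN.finditer(seq)]


def _find_a_phased(seq: str) -> list[tuple[int, int]]:
    """>= 3 A-tracts of 4-9 bp whose centres are ~10 bp (one helical
    turn) apart."""
    tracts = [(m.start(), m.end()) for m in APR_TRACT.finditer(seq)]
    hits = []
    i = 0
    while i < len(tracts):
        run = [tracts[i]]
        j = i
        while j + 1 < len(tracts):
            c1 = (tracts[j][0] + tracts[j][1] - 1) / 2
            c2 = (tracts[j + 1][0] + tracts[j + 1][1] - 1) / 2
            if APR_SPACING[0] <= c2 - c1 <= APR_SPACING[1]:
                run.append(tracts[j + 1])
                j += 1
            else:
                break
        if len(run) >= APR_MIN_TRACTS:
            hits.append((run[0][0], run[-1][1]))
        i = j + 1
    return hits


def _find_direct(seq: str) -> list[tuple[int, int]]:
    """Units >= DIRECT_MIN_UNIT repeated 2+ times with spacer <=
    DIRECT_MAX_SPACER; maximal hits reported."""
    n = len(seq)
    hits = []
    for i in range(n - 2 * DIRECT_MIN_UNIT + 1):
        best = None
        for unit in range(min((n - i) // 2, n), DIRECT_MIN_UNIT - 1, -1):
            for spacer in range(0, DIRECT_MAX_SPACER + 1):
                j = i + unit + spacer
                if j + unit > n:
                    continue
                if seq[i : i + unit] == seq[j : j + unit]:
                    best = (i, j + unit)
                    break
            if best:
                break
        if best:
            hits.append(best)
    return _maximal(hits)


def _find_inverted(seq: str) -> list[tuple[int, int]]:
    n = len(seq)
    hits = []
    for arm in range(min(n // 2, 30), INVERTED_MIN_ARM - 1, -1):
        for i in range(n - 2 * arm + 1):
            left = seq[i : i + arm]
            for loop in range(0, min(INVERTED_MAX_LOOP, n - i - 2 * arm) + 1):
                j = i + arm + loop
                if seq[j : j + arm] == revcomp(left):
                    hits.append((i, j + arm))
                    break
    return _maximal(hits)


def _find_mirror(seq: str) -> list[tuple[int, int]]:
    n = len(seq)
    hits = []
    for arm in range(min(n // 2, 30), MIRROR_MIN_ARM - 1, -1):
        for i in range(n - 2 * arm + 1):
            left = seq[i : i + arm]
            for loop in range(0, min(MIRROR_MAX_LOOP, n - i - 2 * arm) + 1):
                j = i + arm + loop
                if seq[j : j + arm] == left[::-1]:
                    hits.append((i, j + arm))
                    break
    return _maximal(hits)


def _maximal(hits: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Keep non-overlapping maximal spans, longest first."""
    kept: list[tuple[int, int]] = []
    for s, e in sorted(hits, key=lambda h: (-(h[1] - h[0]), h[0])):
        if all(e <= ks or s >= ke for ks, ke in kept):
            kept.append((s, e))
    return sorted(kept)


_DETECTORS = {
    "Z-DNA": _find_zdna,
    "G-quadruplex": _find_g4,
    "A-phased repeat": _find_a_phased,
    "inverted repeat": _find_inverted,
    "mirror repeat": _find_mirror,
    "direct repeat": _find_direct,
}

#: classes whose definition is reverse-complement symmetric, so the
#: minus strand adds nothing new
_STRAND_SYMMETRIC = {"Z-DNA", "inverted repeat", "direct repeat"}


def scan_non_b_motifs(
    reference,
    junction: JunctionCall,
    window: int = MOTIF_WINDOW,
    classes: Sequence[str] = MOTIF_CLASSES,
) -> list[MotifHit]:
    """Scan +/- ``window`` bp around both breakpoints of a junction, on
    both strands, for the six non-B motif classes; returns maximal
    non-overlapping hits per class and strand in reference coordinates."""
    hits: list[MotifHit] = []
    seen: set[tuple[str, int, int, str]] = set()
    for bp in (junction.proximal, junction.distal):
        start = max(0, bp - window)
        seq = get_seq(reference, junction.chrom, start, bp + window)
        for cls in classes:
            detector = _DETECTORS[cls]
            for s, e in detector(seq):
                key = (cls, start + s, start + e, "+")
                if key not in seen:
                    seen.add(key)
                    hits.append(MotifHit(cls, start + s, start + e, "+", seq[s:e]))
            if cls in _STRAND_SYMMETRIC:
                continue
            rc = revcomp(seq)
            for s, e in detector(rc):
                rs, re_ = len(seq) - e, len(seq) - s
                key = (cls, start + rs, start + re_, "-")
                if key not in seen:
                    seen.add(key)
                    hits.append(MotifHit(cls, start + rs, start + re_, "-", rc[s:e]))
    return sorted(hits, key=lambda h: (h.start, h.motif_class))
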