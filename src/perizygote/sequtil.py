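"""Small helpers for reference-sequence access.

A "reference" throughout the package is either a mapping of chromosome
name to sequence (``str`` or a ``numpy`` byte array as produced by the
trio simulator) or any object supporting ``ref[chrom][start:end]``
slicing, e.g. ``pyfaidx.Fasta``.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

BASES = "ACGT"


def get_seq(reference, chrom: str, start: int, end: int) -> str:
    """Return the uppercase reference sequence for 0-based [start, end)."""
    if start < 0:
        raise IndexError(f"negative start {start} on {chrom}")
    seq = reference[chrom]
    if isinstance(seq, np.ndarray):
        chunk = seq[start:end]
        if len(chunk) != end - start:
            raise IndexError(f"{chrom}:{start}-{end} outside reference")
        return chunk.tobytes().decode("ascii").upper()
    chunk = str(seq[start:end])
    if len(chunk) != end - start:
        raise IndexError(f"{chrom}:{start}-{end} outside reference")
    return chunk.upper()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype="S1").copy()
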