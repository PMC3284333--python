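"""Byte-level nucleotide helpers shared across the package.

Sequences are handled in two forms: Python ``str`` at API boundaries and
``numpy.uint8`` arrays of ASCII codes internally (fast vectorised compare,
slice and gather operations on read matrices).
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = (ord(b) for b in "ACGTN")
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTNacgtn", b"TGCANTGCAN"):
    _COMPLEMENT[_x] = _y

_RC_TABLE = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def encode(seq: str) -> np.ndarray:
    """ASCII-encode a nucleotide string as a uint8 array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[..., ::-1]]


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit pack every k-mer of ``arr`` into a uint64 code.

    Positions whose window contains a non-ACGT byte get code 2**63 (never
    indexed).  Requires k <= 31.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 64-bit packing")
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    code2 = np.full(arr.size, 255, dtype=np.uint8)
    code2[arr == A] = 0
    code2[arr == C] = 1
    code2[arr == G] = 2
    code2[arr == T] = 3
    bad = code2 == 255
    vals = code2.astype(np.uint64)
    vals[bad] = 0
    out = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        out <<= np.uint64(2)
        out |= vals[i : i + n]
    if bad.any():
        badwin = np.convolve(bad.astype(np.int32), np.ones(k, dtype=np.int32), "valid") > 0
        out[badwin] = np.uint64(1) << np.uint64(63)
    return out


def homopolymer_run(seq: str, pos: int) -> tuple[int, int]:
    """Return [start, end) of the single-base run containing ``pos``."""
    if not 0 <= pos < len(seq):
        raise IndexError(pos)
    b = seq[pos]
    s = pos
    while s > 0 and seq[s - 1] == b:
        s -= 1
    e = pos + 1
    while e < len(seq) and seq[e] == b:
        e += 1
    return s, e
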