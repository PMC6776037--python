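"""Internal helpers: 2-bit nucleotide encoding and reverse complement."""

from __future__ import annotations

import numpy as np

# A=0, C=1, G=2, T=3; anything else (N, ambiguity codes) is invalid (255).
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)

BASES = "ACGT"


def encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, valid): uint8 base codes and a validity mask.

    Non-ACGT positions get code 0 with valid=False so downstream windowed
    comparisons can mask them out without branching.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    valid = codes != 255
    codes = np.where(valid, codes, 0).astype(np.uint8)
    return codes, valid


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for all-valid code arrays."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def window_valid(valid: np.ndarray, w: int) -> np.ndarray:
    """Boolean mask over the len-w sliding windows that contain only valid bases."""
    n = valid.size
    if n < w:
        return np.zeros(0, dtype=bool)
    csum = np.concatenate(([0], np.cumsum(valid.astype(np.int64))))
    return (csum[w:] - csum[:-w]) == w


def window_mismatches(codes: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Hamming distance of every sliding window of ``codes`` to ``pattern``."""
    w = pattern.size
    n = codes.size
    if n < w:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(n - w + 1, dtype=np.int64)
    for j in range(w):
        out += codes[j : n - w + 1 + j] != pattern[j]
    return out
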