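"""Vectorized DNA primitives: 2-bit encoding, reverse complements and
canonical k-mer extraction.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, IUPAC ambiguity,
lower-case handled by upcasing first) becomes the sentinel 4 and
invalidates every k-mer window it touches.  A k-mer is packed into an
int64 as big-endian base-4 digits, which caps k at 31; the canonical
form is the numeric minimum of the forward and reverse-complement
packings, matching the usual lexicographic-min convention on ACGT.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; sentinel 4 renders as N."""
    return _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N fixed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    valid = out < 4
    out[valid] = 3 - out[valid]
    return out


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical packed k-mer codes for every valid window of a code array.

    Windows containing a sentinel (non-ACGT) are dropped.  Returns an
    int64 array of length <= len(codes) - k + 1.
    """
    if not 2 <= k <= MAX_K:
        raise ValueError(f"k must be in [2, {MAX_K}], got {k}")
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    c = np.minimum(codes, 3).astype(np.int64)
    fwd = np.zeros(m, dtype=np.int64)
    rev = np.zeros(m, dtype=np.int64)
    for i in range(k):
        fwd = (fwd << 2) | c[i : m + i]
        rev |= (3 - c[i : m + i]) << (2 * i)
    canon = np.minimum(fwd, rev)
    bad = (codes > 3).astype(np.int64)
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        valid = (cs[k:] - cs[:-k]) == 0
        canon = canon[valid]
    return canon


def kmer_to_str(code: int, k: int) -> str:
    """Unpack an int64 k-mer code back into its ACGT string."""
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = b"ACGT"[code & 3]
        code >>= 2
    return out.decode("ascii")


def str_to_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        v = _ENCODE[ord(ch)]
        if v > 3:
            raise ValueError(f"non-ACGT symbol in k-mer: {kmer!r}")
        code = (code << 2) | int(v)
    return code


def canonical_str(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def gc_fraction(codes: np.ndarray) -> float:
    """GC fraction over ACGT positions only (ambiguous bases excluded)."""
    valid = codes < 4
    nv = int(valid.sum())
    if nv == 0:
        return 0.0
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / nv
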