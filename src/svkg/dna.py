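"""Two-bit DNA encoding and vectorised canonical k-mer extraction.

Sequences are held as ``uint8`` code arrays (A=0, C=1, G=2, T=3; anything
else, including N, is 255 and invalidates every k-mer window covering it).
A k-mer with k <= 31 packs into a single ``uint64``; the canonical form is
the numeric minimum of the forward and reverse-complement packings, which
coincides with the lexicographic minimum under the A<C<G<T alphabet order.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a code array (all codes must be < 4) back to a string."""
    if codes.size and codes.max() > 3:
        raise ValueError("cannot decode array containing non-ACGT codes")
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtN", "TGCAtgcaN"))[::-1]


def kmer_to_string(value: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = b"ACGT"[value & 3]
        value >>= 2
    return out.decode("ascii")


def string_to_kmer(kmer: str) -> int:
    codes = encode(kmer)
    if (codes > 3).any():
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def canonical_value(kmer: str) -> int:
    """Canonical packed value of one k-mer string (oracle-friendly scalar path)."""
    return min(string_to_kmer(kmer), string_to_kmer(revcomp(kmer)))


_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def revcomp_values(values: np.ndarray, k: int) -> np.ndarray:
    """Packed values of the reverse complements, elementwise.

    Complements (XOR), then reverses the 2-bit groups of the 64-bit word
    (pair swap, nibble swap, byte swap) and shifts the k groups back down.
    """
    x = ~values
    x = ((x >> np.uint64(2)) & _M2) | ((x & _M2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & _M4) | ((x & _M4) << np.uint64(4))
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """All canonical k-mer values of a code array, in positional order.

    Returns ``(values, n_skipped)`` where ``n_skipped`` counts windows that
    contained a non-ACGT code and were dropped.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    m = codes.size - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), 0

    canon = np.empty(m, dtype=np.uint64)
    chunk = 1 << 16  # keep working set cache-resident
    for s in range(0, m, chunk):
        e = min(s + chunk, m)
        mc = e - s
        c = (codes[s : e + k - 1] & np.uint8(3)).astype(np.uint64)
        fwd = np.zeros(mc, dtype=np.uint64)
        buf = np.empty(mc, dtype=np.uint64)
        for j in range(k):
            np.left_shift(c[j : j + mc], np.uint64(2 * (k - 1 - j)), out=buf)
            np.bitwise_or(fwd, buf, out=fwd)
        np.minimum(fwd, revcomp_values(fwd, k), out=canon[s:e])

    bad = np.cumsum(codes > 3)
    window_bad = bad[k - 1 :].copy()
    window_bad[1:] -= bad[: m - 1]
    valid = window_bad == 0
    n_skipped = int(m - valid.sum())
    if n_skipped:
        canon = canon[valid]
    return canon, n_skipped


def concat_with_separators(chunks: list[np.ndarray]) -> np.ndarray:
    """Concatenate code arrays with a 255 separator so windows never span reads."""
    if not chunks:
        return np.empty(0, dtype=np.uint8)
    sep = np.array([255], dtype=np.uint8)
    parts: list[np.ndarray] = []
    for ch in chunks:
        parts.append(ch)
        parts.append(sep)
    return np.concatenate(parts)
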