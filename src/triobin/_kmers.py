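"""Vectorised 2-bit k-mer encoding, canonicalisation and counting primitives.

Every k-mer with k <= 31 is packed into one ``uint64`` (2 bits per base,
A=0, C=1, G=2, T=3, most-significant pair = first base).  The canonical
form of a k-mer is the lexicographic minimum of itself and its reverse
complement over A<C<G<T, which for this encoding equals the numeric
minimum of the two packed codes.  Any non-ACGT base invalidates every
window that contains it.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

# byte -> 2-bit code; 255 marks an invalid (non-ACGT) base
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase
_DEC = b"ACGT"

_COMP = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC bases beyond ACGTN pass through N-like)."""
    return seq.translate(_COMP)[::-1]


def check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError(f"k must be odd (palindromic k-mers are ambiguous): got {k}")
    if not (3 <= k <= MAX_K):
        raise ValueError(f"k must be in [3, {MAX_K}]: got {k}")


def encode(seq: str | bytes) -> np.ndarray:
    """Map a sequence to a uint8 array of 2-bit codes; non-ACGT bases become 255."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENC[np.frombuffer(seq, dtype=np.uint8)]


def kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed forward k-mer codes of all windows plus a validity mask.

    Returns ``(codes, valid)`` with ``len == len(enc) - k + 1`` (empty for
    short input).  Windows containing an invalid base are masked out.
    """
    n = len(enc)
    m = n - k + 1
    if m <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    valid = np.ones(m, dtype=bool)
    for i in np.flatnonzero(enc > 3):  # invalid bases are sparse
        valid[max(0, i - k + 1) : i + 1] = False
    clean = (enc & np.uint8(3)).astype(np.uint64)
    codes = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        codes <<= np.uint64(2)
        codes |= clean[j : j + m]
    return codes, valid


# 2-bit-group reversal within one byte, e.g. 0bAABBCCDD -> 0bDDCCBBAA
_REV2 = np.array(
    [((b & 3) << 6) | ((b >> 2 & 3) << 4) | ((b >> 4 & 3) << 2) | (b >> 6 & 3)
     for b in range(256)],
    dtype=np.uint8,
)


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed codes of the reverse complements.

    Complement is a bitwise NOT of the low 2k bits (3-b per base); the
    base order is reversed by swapping bytes and reversing 2-bit groups
    within each byte via a lookup table, then right-aligning.
    """
    mask = np.uint64((1 << (2 * k)) - 1)
    comp = (codes & mask) ^ mask
    rev_bytes = _REV2[comp.byteswap().view(np.uint8)]
    return rev_bytes.view(np.uint64) >> np.uint64(64 - 2 * k)


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _njit = None


def _canon_scan_py(enc, k, mask, shift):
    n = enc.shape[0]
    m = n - k + 1
    out = np.empty(m, dtype=np.uint64)
    flags = np.zeros(m, dtype=np.bool_)
    code = np.uint64(0)
    rc = np.uint64(0)
    run = 0
    u2 = np.uint64(2)
    for i in range(n):
        b = enc[i]
        if b > 3:
            run = 0
        else:
            code = ((code << u2) | np.uint64(b)) & mask
            rc = (rc >> u2) | (np.uint64(3 - b) << shift)
            run += 1
        j = i - k + 1
        if j >= 0 and run >= k:
            out[j] = code if code < rc else rc
            flags[j] = True
    return out, flags


if _njit is not None:
    _canon_scan = _njit(cache=False, nogil=True)(_canon_scan_py)
else:
    _canon_scan = _canon_scan_py


if _njit is not None:
    from numba import types as _nbtypes
    from numba.typed import Dict as _NbDict

    @_njit(cache=False, nogil=True)
    def _count_into(d, codes):  # pragma: no cover - exercised via count_kmers
        for i in range(codes.shape[0]):
            c = codes[i]
            if c in d:
                d[c] += 1
            else:
                d[c] = 1

    @_njit(cache=False, nogil=True)
    def _dump_counter(d):  # pragma: no cover
        n = len(d)
        codes = np.empty(n, dtype=np.uint64)
        counts = np.empty(n, dtype=np.int64)
        i = 0
        for c, v in d.items():
            codes[i] = c
            counts[i] = v
            i += 1
        return codes, counts

    @_njit(cache=False, nogil=True)
    def _hits_sorted(query, sorted_codes):  # pragma: no cover
        n = sorted_codes.shape[0]
        total = 0
        for i in range(query.shape[0]):
            v = query[i]
            lo = 0
            hi = n
            while lo < hi:
                mid = (lo + hi) >> 1
                if sorted_codes[mid] < v:
                    lo = mid + 1
                else:
                    hi = mid
            if lo < n and sorted_codes[lo] == v:
                total += 1
        return total

    def new_counter():
        return _NbDict.empty(key_type=_nbtypes.uint64, value_type=_nbtypes.int64)

else:  # pragma: no cover
    new_counter = None


def count_hits(sorted_codes: np.ndarray, query: np.ndarray) -> int:
    """Number of query codes present in a sorted code array (with multiplicity)."""
    if len(sorted_codes) == 0 or len(query) == 0:
        return 0
    if _njit is not None:
        return int(_hits_sorted(query, sorted_codes))
    return int(lookup(sorted_codes, query).sum())


def canonical_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Canonical codes of every valid k-mer window, in sequence order.

    Single rolling pass: the forward code is extended at the 3' end and
    the reverse-complement code at the 5' end, so each base is touched
    once regardless of k.
    """
    if len(enc) < k:
        return np.empty(0, dtype=np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    shift = np.uint64(2 * (k - 1))
    out, flags = _canon_scan(enc, k, mask, shift)
    return out[flags]


def decode(code: int, k: int) -> str:
    out = bytearray(k)
    c = int(code)
    for j in range(k - 1, -1, -1):
        out[j] = _DEC[c & 3]
        c >>= 2
    return out.decode("ascii")


def encode_kmer(kmer: str) -> int:
    """Pack one ACGT string into its code (raises on ambiguous bases)."""
    enc = encode(kmer)
    if (enc > 3).any():
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
    code = 0
    for b in enc:
        code = (code << 2) | int(b)
    return code


def canonical_kmer(kmer: str) -> str:
    """Canonical (lexicographically minimal of self / reverse complement) form."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def count_sorted(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique sorted codes with occurrence counts."""
    if len(codes) == 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    uniq, counts = np.unique(codes, return_counts=True)
    return uniq, counts


def merge_counts(
    codes_a: np.ndarray, counts_a: np.ndarray, codes_b: np.ndarray, counts_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Merge two sorted (codes, counts) aggregates into one."""
    if len(codes_a) == 0:
        return codes_b, counts_b
    if len(codes_b) == 0:
        return codes_a, counts_a
    allc = np.concatenate([codes_a, codes_b])
    alln = np.concatenate([counts_a, counts_b])
    uniq, inverse = np.unique(allc, return_inverse=True)
    sums = np.bincount(inverse, weights=alln.astype(np.float64), minlength=len(uniq))
    return uniq, sums.astype(np.int64)


def lookup(sorted_codes: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Boolean membership of each query code in a sorted code array."""
    if len(sorted_codes) == 0 or len(query) == 0:
        return np.zeros(len(query), dtype=bool)
    idx = np.searchsorted(sorted_codes, query)
    idx_clip = np.minimum(idx, len(sorted_codes) - 1)
    return sorted_codes[idx_clip] == query


def lookup_counts(sorted_codes: np.ndarray, counts: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Count of each query code in a sorted (codes, counts) aggregate (0 if absent)."""
    out = np.zeros(len(query), dtype=np.int64)
    if len(sorted_codes) == 0 or len(query) == 0:
        return out
    idx = np.searchsorted(sorted_codes, query)
    idx_clip = np.minimum(idx, len(sorted_codes) - 1)
    hit = sorted_codes[idx_clip] == query
    out[hit] = counts[idx_clip[hit]]
    return out
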