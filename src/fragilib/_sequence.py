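"""Low-level DNA alphabet utilities shared across the package.

Sequences are plain Python strings over {A, C, G, T, N}. For vectorised
work they are encoded as ``int8`` arrays with A=0, C=1, G=2, T=3 and any
other letter = 4 ("N"). A k-mer is identified by its base-4 integer code;
strand symmetry is handled by mapping every code to the canonical code
``min(code, revcomp_code)`` which corresponds to the lexicographic
minimum of the k-mer and its reverse complement.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

BASES = "ACGT"
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[np.asarray(arr, dtype=np.int8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(s: str) -> str:
    """Canonical (strand-symmetric) form: lexicographic min of s and its
    reverse complement.

    Raises ValueError for letters outside {A, C, G, T}.
    """
    su = s.upper()
    if not su or any(c not in BASES for c in su):
        raise ValueError(f"k-mer must be non-empty over A/C/G/T: {s!r}")
    rc = revcomp(su)
    return su if su <= rc else rc


def n_canonical_kmers(k: int) -> int:
    """Number of strand-symmetric k-mer classes.

    Even k admits 4^(k/2) palindromic k-mers (self reverse complements);
    odd k admits none (the centre base would need to complement itself).
    """
    if k % 2 == 0:
        return (4**k + 4 ** (k // 2)) // 2
    return 4**k // 2


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Base-4 code of the k-mer starting at each position; -1 where the
    window contains a non-ACGT letter. Output length is len(arr)-k+1."""
    n = arr.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    a = arr.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = a[j : j + n]
        codes = codes * 4 + np.where(window > 3, 0, window)
        bad |= window > 3
    codes[bad] = -1
    return codes


@lru_cache(maxsize=None)
def _revcomp_code_table(k: int) -> np.ndarray:
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (c % 4))
        c //= 4
    return rc


@lru_cache(maxsize=None)
def canonical_code_tables(k: int) -> tuple[np.ndarray, np.ndarray]:
    """(canon_index, canon_codes): canon_index maps a raw k-mer code to a
    dense index into the sorted canonical code vocabulary; canon_codes
    lists the canonical codes in ascending (= lexicographic) order."""
    codes = np.arange(4**k, dtype=np.int64)
    canon = np.minimum(codes, _revcomp_code_table(k))
    canon_codes = np.unique(canon)
    index = np.searchsorted(canon_codes, canon)
    return index.astype(np.int64), canon_codes


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


@lru_cache(maxsize=None)
def all_canonical_kmers(k: int) -> tuple[str, ...]:
    """All canonical k-mers in lexicographic order."""
    _, canon_codes = canonical_code_tables(k)
    return tuple(code_to_kmer(int(c), k) for c in canon_codes)


def canonical_index_of(kmers, k: int) -> np.ndarray:
    """Dense canonical-vocabulary index of each k-mer string."""
    index, canon_codes = canonical_code_tables(k)
    enc = [encode(s) for s in kmers]
    out = np.empty(len(enc), dtype=np.int64)
    for i, a in enumerate(enc):
        code = 0
        for b in a:
            if b > 3:
                raise ValueError("k-mer contains non-ACGT letter")
            code = code * 4 + int(b)
        out[i] = index[code]
    return out
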