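"""Vectorised 2-bit k-mer encoding shared by the overlapper and evaluation."""

from __future__ import annotations

import numpy as np

_BASE_VAL = np.full(256, 4, dtype=np.uint8)
for _b, _v in zip(b"ACGT", range(4)):
    _BASE_VAL[_b] = _v


def seq_to_vals(seq: str) -> np.ndarray:
    """Map a nucleotide string to 0..3 values; anything else becomes 4."""
    return _BASE_VAL[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All k-mer codes of ``seq``.

    Returns ``(canonical, is_rc, valid)`` where ``canonical`` is the smaller
    of the forward and reverse-complement 2-bit codes, ``is_rc`` marks
    positions whose canonical form is the reverse complement, and ``valid``
    is False wherever the window contains a non-ACGT character.  Requires
    ``k <= 31``.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    vals = seq_to_vals(seq)
    n = len(vals) - k + 1
    if n <= 0:
        z = np.empty(0, dtype=np.uint64)
        return z, np.empty(0, bool), np.empty(0, bool)
    v = (vals & 3).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd |= v[j : j + n] << np.uint64(2 * (k - 1 - j))
        rc |= (np.uint64(3) - v[j : j + n]) << np.uint64(2 * j)
    bad = (vals == 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    canonical = np.minimum(fwd, rc)
    return canonical, rc < fwd, valid


def mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64-style finaliser used for seed subsampling."""
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xFF51AFD7ED558CCD)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xC4CEB9FE1A85EC53)
    x ^= x >> np.uint64(33)
    return x


def canonical_kmer_set(seq: str, k: int) -> set[int]:
    """The set of distinct canonical k-mer codes of ``seq``."""
    canon, _, valid = kmer_codes(seq, k)
    return set(canon[valid].tolist())
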