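"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import hifikit as hk
from hifikit.params import Params


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_seq(rng, n: int) -> str:
    return "".join(np.frombuffer(b"ACGT", np.uint8)[rng.integers(0, 4, n)]
                   .tobytes().decode("ascii"))


@pytest.fixture
def small_params():
    """Parameters scaled for kbp-sized fixtures."""
    return Params(min_overlap_length=200, min_report_contig=5000)


# ---------------------------------------------------------------------------
# brute-force all-pairs overlap oracle (full DP, no seeding)
# ---------------------------------------------------------------------------

def _overlap_dp(a: str, b: str):
    """Edit-distance DP with free start on either sequence's prefix and a
    proper end; returns (D, start) matrices.  start encodes where the
    alignment began: +j for a start at (0, j), -i for a start at (i, 0).

    The horizontal-gap dependency is vectorised with the running-minimum
    identity D[i,j] = min_k (cand[i,k] + (j-k)) for k <= j.
    """
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), np.uint8)
    bv = np.frombuffer(b.encode(), np.uint8)
    D = np.zeros((n + 1, m + 1), dtype=np.int64)
    S = np.zeros((n + 1, m + 1), dtype=np.int64)
    S[0, :] = np.arange(m + 1)
    S[:, 0] = -np.arange(n + 1)
    cols = np.arange(m + 1)
    pack = np.int64(4 * (m + 2))  # value-major packing for argmin ties
    for i in range(1, n + 1):
        cand = np.empty(m + 1, dtype=np.int64)
        srcS = np.empty(m + 1, dtype=np.int64)
        cand[0] = D[i, 0]
        srcS[0] = S[i, 0]
        sub = D[i - 1, :-1] + (bv != av[i - 1])
        up = D[i - 1, 1:] + 1
        cand[1:] = np.minimum(sub, up)
        srcS[1:] = np.where(sub <= up, S[i - 1, :-1], S[i - 1, 1:])
        combo = (cand - cols) * pack + cols
        acc = np.minimum.accumulate(combo)
        k = acc % pack
        D[i] = acc // pack + cols
        S[i] = srcS[k]
    return D, S


def _traceback(a, b, D, i, j):
    """Walk back from (i, j) to the free start, returning (cols, diffs)."""
    diffs = []
    cols = 0
    while i > 0 and j > 0:
        if D[i, j] == D[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            if a[i - 1] != b[j - 1]:
                diffs.append((i - 1, j - 1, "sub"))
            i, j = i - 1, j - 1
        elif D[i, j] == D[i - 1, j] + 1:
            diffs.append((i - 1, j, "del"))
            i -= 1
        else:
            diffs.append((i, j - 1, "ins"))
            j -= 1
        cols += 1
    return cols, diffs[::-1], (i, j)


def brute_force_overlap(a: str, b: str, min_len: int, min_identity: float):
    """Best proper overlap alignment of two oriented sequences, or None.

    Exhaustive DP over all start offsets; endpoints on the final row/column
    are scored by matching bases after an exact traceback.
    """
    n, m = len(a), len(b)
    D, S = _overlap_dp(a, b)
    cand = [(n, j) for j in range(1, m + 1)] + [(i, m) for i in range(1, n)]
    best = None
    for i, j in cand:
        s = S[i, j]
        a0, b0 = (0, s) if s >= 0 else (-s, 0)
        la, lb = i - a0, j - b0
        if min(la, lb) < min_len - 50:
            continue
        if D[i, j] > (1 - min_identity) * max(la, lb) + 2:
            continue
        rank = (max(la, lb) - int(D[i, j]), -int(D[i, j]))
        if best is None or rank > best[0]:
            best = (rank, i, j)
    if best is None:
        return None
    _, i, j = best
    cols, diffs, (a0, b0) = _traceback(a, b, D, i, j)
    nd = len(diffs)
    identity = 1 - nd / cols if cols else 0.0
    if cols < min_len or identity < min_identity:
        return None
    return {"a_span": (a0, i), "b_span": (b0, j), "cols": cols,
            "identity": identity, "score": cols - nd, "diffs": diffs}


def oracle_overlap_set(seqs: dict[str, str], min_len: int,
                       min_identity: float) -> dict:
    """All-pairs brute-force overlaps keyed by (a_id, b_id, strand)."""
    out = {}
    ids = sorted(seqs)
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            a, b = seqs[ids[x]], seqs[ids[y]]
            for strand in "+-":
                b_or = b if strand == "+" else hk.revcomp(b)
                res = brute_force_overlap(a, b_or, min_len, min_identity)
                if res is None:
                    continue
                bs, be = res["b_span"]
                if strand == "-":
                    bs, be = len(b) - be, len(b) - bs
                out[(ids[x], ids[y], strand)] = {
                    "a_span": res["a_span"], "b_span": (bs, be),
                    "identity": res["identity"], "score": res["score"],
                    "cols": res["cols"]}
    return out
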