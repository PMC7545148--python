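"""Candidate overlap detection and alignment between compressed reads.

Reads are compared in homopolymer-compressed space.  Shared subsampled
k-mer seeds nominate read pairs and an approximate diagonal; each candidate
is then aligned exactly by banded edit-distance extension from a seed anchor
(edlib), producing a proper overlap record: spans in both reads, orientation,
an explicit list of alignment differences, an identity stored at ppm
resolution and a score equal to the number of matching bases.  Overlaps below
the candidate identity floor (99% by default) or shorter than the minimum
overlap length are discarded.  The returned list is symmetric: every overlap
appears once with each read as the subject.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
import re

import edlib
import numpy as np

from ._kmers import kmer_codes, mix64
from .hpc import Read, revcomp
from .params import PPM, Params

#: One alignment difference.  ``a_pos``/``b_pos`` are 0-based positions in
#: each read's own forward coordinates.  ``kind`` is "sub" (mismatch),
#: "del" (extra base in a; ``b_pos`` is the half-open junction in b before
#: which it would sit) or "ins" (extra base in b; ``a_pos`` is the junction
#: in a).  ``a_sym``/``o_sym`` are the subject and partner symbols expressed
#: in the subject read's orientation ("-" for a gap).
Diff = namedtuple("Diff", "a_pos b_pos kind a_sym o_sym")

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _parse_cigar(cigar: str):
    return [(int(m.group(1)), m.group(2)) for m in _CIGAR_RE.finditer(cigar)]


@dataclass(frozen=True)
class Overlap:
    """A pairwise alignment record between two (compressed) reads.

    Spans are half-open and given in each read's forward coordinates even for
    reverse-strand overlaps.  ``aln_len`` counts alignment columns; identity
    is ``1 - len(diffs)/aln_len`` and ``score`` the number of matching bases.
    """

    a_id: str
    b_id: str
    strand: str  # "+" or "-"
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    a_len: int
    b_len: int
    aln_len: int
    identity_ppm: int
    score: int
    diffs: tuple

    @property
    def identity(self) -> float:
        return self.identity_ppm / PPM

    @property
    def a_contained(self) -> bool:
        return self.a_start == 0 and self.a_end == self.a_len

    @property
    def b_contained(self) -> bool:
        return self.b_start == 0 and self.b_end == self.b_len

    def hangs_off(self, end: str) -> bool:
        """True if the partner extends past the given end ("5"/"3") of a."""
        if end == "5":
            if self.a_start != 0:
                return False
            return self.b_start > 0 if self.strand == "+" else self.b_end < self.b_len
        if self.a_end != self.a_len:
            return False
        return self.b_end < self.b_len if self.strand == "+" else self.b_start > 0

    @property
    def is_proper(self) -> bool:
        """Reaches an end of each read on the facing sides."""
        if self.strand == "+":
            left = self.a_start == 0 or self.b_start == 0
            right = self.a_end == self.a_len or self.b_end == self.b_len
        else:
            left = self.a_start == 0 or self.b_end == self.b_len
            right = self.a_end == self.a_len or self.b_start == 0
        return left and right

    def partner_end(self, end: str) -> str:
        """Which end of b faces a's ``end`` under this overlap's strand."""
        if self.strand == "+":
            return "5" if end == "3" else "3"
        return end

    def mirror(self) -> "Overlap":
        """The same overlap with the roles of a and b swapped."""
        flip = self.strand == "-"

        def sym(s: str) -> str:
            return revcomp(s) if flip and s != "-" else s

        diffs = []
        for d in self.diffs:
            if d.kind == "sub":
                diffs.append(Diff(d.b_pos, d.a_pos, "sub", sym(d.o_sym), sym(d.a_sym)))
            elif d.kind == "del":  # extra base in a -> extra base in new b
                diffs.append(Diff(d.b_pos, d.a_pos, "ins", "-", sym(d.a_sym)))
            else:  # "ins": extra base in b -> extra base in new a
                diffs.append(Diff(d.b_pos, d.a_pos, "del", sym(d.o_sym), "-"))
        diffs.sort(key=lambda d: (d.a_pos, d.b_pos, d.kind))
        return Overlap(
            self.b_id, self.a_id, self.strand,
            self.b_start, self.b_end, self.a_start, self.a_end,
            self.b_len, self.a_len,
            self.aln_len, self.identity_ppm, self.score, tuple(diffs),
        )


# ---------------------------------------------------------------------------
# seed anchoring
# ---------------------------------------------------------------------------

def _sampled_seeds(seq: str, params: Params):
    """Subsampled canonical k-mer seeds of one read: (codes, positions, is_rc)."""
    canon, is_rc, valid = kmer_codes(seq, params.seed_k)
    if len(canon) == 0:
        return canon, np.empty(0, np.int64), is_rc
    thresh = np.uint64(int(params.seed_density * 2**64))
    keep = valid & (mix64(canon) < thresh)
    pos = np.flatnonzero(keep)
    return canon[pos], pos, is_rc[pos]


def _candidate_anchors(seqs: list[str], params: Params):
    """Seed-matching: yield (i, j, strand, pa, pb_fwd) anchor per read pair.

    Pairs must share at least ``min_seed_count`` subsampled seeds after the
    repetitive-seed filter; the anchor is the shared seed with the median
    diagonal, which the aligner extends in both directions.
    """
    k = params.seed_k
    n = len(seqs)
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    codes, rids, poss, rcs = [], [], [], []
    for i, s in enumerate(seqs):
        c, p, r = _sampled_seeds(s, params)
        codes.append(c)
        rids.append(np.full(len(p), i, dtype=np.int64))
        poss.append(p)
        rcs.append(r)
    if not codes:
        return []
    code = np.concatenate(codes)
    rid = np.concatenate(rids)
    pos = np.concatenate(poss)
    isrc = np.concatenate(rcs)
    if len(code) == 0:
        return []
    order = np.argsort(code, kind="stable")
    code, rid, pos, isrc = code[order], rid[order], pos[order], isrc[order]
    bnd = np.flatnonzero(np.diff(code)) + 1
    starts = np.concatenate([[0], bnd])
    ends = np.concatenate([bnd, [len(code)]])

    key_l, pa_l, pb_l = [], [], []
    for s, e in zip(starts, ends):
        g = e - s
        if g < 2 or g > params.max_seed_occ:
            continue
        r = rid[s:e]
        p = pos[s:e]
        rc = isrc[s:e]
        ii, jj = np.triu_indices(g, 1)
        diff_read = r[ii] != r[jj]
        if not diff_read.any():
            continue
        ii, jj = ii[diff_read], jj[diff_read]
        swap = r[ii] > r[jj]
        x = np.where(swap, jj, ii)
        y = np.where(swap, ii, jj)
        strandrel = (rc[x] ^ rc[y]).astype(np.int64)
        key_l.append((r[x] * n + r[y]) * 2 + strandrel)
        pa_l.append(p[x])
        pb_l.append(p[y])
    if not key_l:
        return []
    key = np.concatenate(key_l)
    pa = np.concatenate(pa_l)
    pb = np.concatenate(pb_l)
    # oriented diagonal per incidence
    r2 = (key // 2) % n
    strandrel = key % 2
    pb_or = np.where(strandrel == 1, lens[r2] - k - pb, pb)
    diag = pa - pb_or

    order = np.lexsort((diag, key))
    key, pa, pb, diag = key[order], pa[order], pb[order], diag[order]
    bnd = np.flatnonzero(np.diff(key)) + 1
    starts = np.concatenate([[0], bnd])
    ends = np.concatenate([bnd, [len(key)]])
    anchors = []
    for s, e in zip(starts, ends):
        if e - s < params.min_seed_count:
            continue
        m = s + (e - s - 1) // 2  # the incidence at the median diagonal
        kk = int(key[m])
        strand = "-" if kk % 2 else "+"
        pair = kk // 2
        anchors.append((pair // n, pair % n, strand, int(pa[m]), int(pb[m])))
    return anchors


# ---------------------------------------------------------------------------
# anchored banded alignment
# ---------------------------------------------------------------------------

def _edit_budget(length: int, params: Params) -> int:
    return max(32, int(params.max_align_error * length) + 16)


def _align_prefix(query: str, target: str, params: Params):
    """SHW-align ``query`` (or its longest alignable prefix) to ``target``.

    If the full query exceeds its edit budget — as happens when a chimeric
    junction or an adapter ends the homology mid-read — binary-search the
    longest prefix that stays within budget, so the overlap can stop where
    the agreement stops.  Returns the edlib result (with the consumed query
    length attached) or None.
    """
    res = edlib.align(query, target, mode="SHW", task="path",
                      k=_edit_budget(len(query), params))
    if res["editDistance"] >= 0:
        res["query_len"] = len(query)
        return res
    lo, hi, best = 0, len(query) - 1, None
    while lo <= hi:
        mid = (lo + hi) // 2
        r = edlib.align(query[:mid], target, mode="SHW", task="path",
                        k=_edit_budget(mid, params))
        if r["editDistance"] >= 0:
            r["query_len"] = mid
            best = r
            lo = mid + 1
        else:
            hi = mid - 1
    if best is not None:
        _truncate_to_best_prefix(best)
    return best


def _truncate_to_best_prefix(res, match: int = 1, penalty: int = 4) -> None:
    """Cut a prefix alignment back to its maximum-scoring column.

    The budgeted prefix search overshoots into non-homologous sequence by up
    to its edit allowance; scoring columns (+1 match, -4 difference) and
    truncating at the running maximum removes that garbage overhang.
    Modifies ``res['cigar']``/``res['query_len']`` in place.
    """
    ops = _parse_cigar(res["cigar"])
    score = best_score = 0
    q = best_q = cols = best_cols = 0
    for cnt, op in ops:
        if op == "=":
            score += match * cnt
            q += cnt
        else:
            score -= penalty * cnt
            if op != "D":
                q += cnt
        cols += cnt
        if score > best_score:
            best_score, best_q, best_cols = score, q, cols
    if best_cols == cols:
        return
    out, used = [], 0
    for cnt, op in ops:
        take = min(cnt, best_cols - used)
        if take > 0:
            out.append(f"{take}{op}")
            used += take
        if used == best_cols:
            break
    res["cigar"] = "".join(out)
    res["query_len"] = best_q


def _extend_right(a: str, b: str, a0: int, b0: int, params: Params):
    """Align a[a0:] with b[b0:] until one sequence ends (or the alignment
    stops being an alignment — see :func:`_align_prefix`).

    Returns (a_end, b_end, cols, diffs) with diffs in (a_pos, b_or_pos,
    kind, a_sym, o_sym) form, or None if nothing aligns.
    """
    qa, qb = a[a0:], b[b0:]
    if not qa or not qb:
        return a0, b0, 0, []
    a_is_query = len(qa) <= len(qb)
    query, target = (qa, qb) if a_is_query else (qb, qa)
    res = _align_prefix(query, target, params)
    if res is None:
        return None
    diffs, cols = [], 0
    ia, ib = a0, b0
    for cnt, op in _parse_cigar(res["cigar"]):
        if op == "=":
            ia += cnt
            ib += cnt
        elif op == "X":
            for _ in range(cnt):
                diffs.append((ia, ib, "sub", a[ia], b[ib]))
                ia += 1
                ib += 1
        elif (op == "I") == a_is_query:  # extra base(s) in a
            for _ in range(cnt):
                diffs.append((ia, ib, "del", a[ia], "-"))
                ia += 1
        else:  # extra base(s) in b
            for _ in range(cnt):
                diffs.append((ia, ib, "ins", "-", b[ib]))
                ib += 1
        cols += cnt
    return ia, ib, cols, diffs


def _extend_left(a: str, b: str, a0: int, b0: int, params: Params):
    """Align a[:a0] with b[:b0] leftwards from the anchor (reversed SHW)."""
    qa, qb = a[:a0][::-1], b[:b0][::-1]
    if not qa or not qb:
        return a0, b0, 0, []
    a_is_query = len(qa) <= len(qb)
    query, target = (qa, qb) if a_is_query else (qb, qa)
    res = _align_prefix(query, target, params)
    if res is None:
        return None
    diffs, cols = [], 0
    # ra/rb index into the reversed prefixes; real pos = a0-1-ra etc.
    ra, rb = 0, 0
    for cnt, op in _parse_cigar(res["cigar"]):
        if op == "=":
            ra += cnt
            rb += cnt
        elif op == "X":
            for _ in range(cnt):
                ap, bp = a0 - 1 - ra, b0 - 1 - rb
                diffs.append((ap, bp, "sub", a[ap], b[bp]))
                ra += 1
                rb += 1
        elif (op == "I") == a_is_query:  # extra base(s) in a
            for _ in range(cnt):
                ap = a0 - 1 - ra
                diffs.append((ap, b0 - rb, "del", a[ap], "-"))
                ra += 1
        else:  # extra base(s) in b
            for _ in range(cnt):
                bp = b0 - 1 - rb
                diffs.append((a0 - ra, bp, "ins", "-", b[bp]))
                rb += 1
        cols += cnt
    return a0 - ra, b0 - rb, cols, diffs


def align_anchored(a: str, b_or: str, pa: int, pb: int, k: int, params: Params):
    """Overlap alignment of a with oriented b through the exact seed match at
    (pa, pb).  Returns (a_span, b_or_span, cols, diffs) or None."""
    left = _extend_left(a, b_or, pa, pb, params)
    if left is None:
        return None
    right = _extend_right(a, b_or, pa + k, pb + k, params)
    if right is None:
        return None
    a_start, b_start, lcols, ldiffs = left
    a_end, b_end, rcols, rdiffs = right
    cols = lcols + k + rcols
    diffs = sorted(ldiffs) + rdiffs
    return (a_start, a_end), (b_start, b_end), cols, diffs


def _oriented_to_overlap(a_id, b_id, strand, a_span, b_or_span, cols, diffs,
                         a_len, b_len) -> Overlap:
    """Convert an oriented alignment into a forward-coordinate Overlap."""
    a_start, a_end = a_span
    bs_or, be_or = b_or_span
    if strand == "+":
        b_start, b_end = bs_or, be_or
        conv_base = conv_junc = lambda p: p
    else:
        b_start, b_end = b_len - be_or, b_len - bs_or
        conv_base = lambda p: b_len - 1 - p
        conv_junc = lambda p: b_len - p
    out = []
    for ap, bp, kind, a_sym, o_sym in diffs:
        bf = conv_junc(bp) if kind == "del" else conv_base(bp)
        out.append(Diff(ap, bf, kind, a_sym, o_sym))
    out.sort(key=lambda d: (d.a_pos, d.b_pos, d.kind))
    nd = len(out)
    identity_ppm = round((1 - nd / cols) * PPM) if cols else 0
    return Overlap(a_id, b_id, strand, a_start, a_end, b_start, b_end,
                   a_len, b_len, cols, identity_ppm, cols - nd, tuple(out))


def _overlap_sort_key(o: Overlap):
    return (o.a_id, o.b_id, o.strand, o.a_start, o.b_start)


def find_overlaps(seqs: dict[str, str], params: Params | None = None,
                  require_proper: bool = True) -> list[Overlap]:
    """All proper pairwise overlaps among ``seqs`` (id -> compressed sequence).

    Both strands are considered.  Every retained overlap has identity at
    least ``min_candidate_identity`` and alignment length at least
    ``min_overlap_length``; the result contains each overlap in both
    directions and is deterministically ordered.  With
    ``require_proper=False``, overlaps that stop mid-read (chimeric
    junctions, adapters) are kept too — the trimming stage needs them.
    """
    params = params or Params()
    ids = sorted(seqs)
    seq_list = [seqs[i] for i in ids]
    rc_cache: dict[int, str] = {}
    min_ppm = params.min_candidate_identity_ppm
    out: list[Overlap] = []
    for i, j, strand, pa, pbf in _candidate_anchors(seq_list, params):
        a, b = seq_list[i], seq_list[j]
        if strand == "+":
            b_or, pb = b, pbf
        else:
            b_or = rc_cache.setdefault(j, revcomp(b))
            pb = len(b) - params.seed_k - pbf
        if a[pa : pa + params.seed_k] != b_or[pb : pb + params.seed_k]:
            continue  # hash collision; the seed was not an exact match
        res = align_anchored(a, b_or, pa, pb, params.seed_k, params)
        if res is None:
            continue
        a_span, b_or_span, cols, diffs = res
        if cols < params.min_overlap_length:
            continue
        if require_proper:
            if not ((a_span[0] == 0 or b_or_span[0] == 0)
                    and (a_span[1] == len(a) or b_or_span[1] == len(b_or))):
                continue
        ovl = _oriented_to_overlap(ids[i], ids[j], strand, a_span, b_or_span,
                                   cols, diffs, len(a), len(b))
        if ovl.identity_ppm < min_ppm:
            continue
        out.append(ovl)
        out.append(ovl.mirror())
    out.sort(key=_overlap_sort_key)
    return out


# ---------------------------------------------------------------------------
# overlap-based trimming
# ---------------------------------------------------------------------------

def trim_reads(reads: dict[str, Read], overlaps: list[Overlap],
               min_cov: int = 2) -> None:
    """Set each read's trim interval to its longest well-covered stretch.

    The trim interval is the longest interval covered by at least ``min_cov``
    overlapping reads, which removes chimeric junctions and adapter remnants
    (those attract overlaps on only one side of the artifact).  Reads with no
    overlaps keep their full interval and are flagged ``no_overlaps``; reads
    that never reach ``min_cov`` fall back to coverage >= 1 and are flagged
    ``low_coverage``.  Operates in place on compressed coordinates.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for o in overlaps:
        spans.setdefault(o.a_id, []).append((o.a_start, o.a_end))
    for rid, read in reads.items():
        n = len(read.hpc_seq)
        iv = spans.get(rid)
        if not iv:
            read.trim = (0, n)
            read.flags.add("no_overlaps")
            continue
        cov = np.zeros(n + 1, dtype=np.int32)
        for s, e in iv:
            cov[s] += 1
            cov[e] -= 1
        cov = np.cumsum(cov[:-1])
        trim = _longest_run(cov >= min_cov)
        if trim is None:
            trim = _longest_run(cov >= 1)
            read.flags.add("low_coverage")
        read.trim = trim if trim is not None else (0, n)


def _longest_run(mask: np.ndarray) -> tuple[int, int] | None:
    """Longest (leftmost on ties) True run as a half-open interval."""
    if not mask.any():
        return None
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    best = np.argmax(ends - starts)
    return int(starts[best]), int(ends[best])
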