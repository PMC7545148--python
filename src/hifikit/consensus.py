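"""Contig consensus over the original, uncompressed reads.

Layouts are built in homopolymer-compressed space, but the reported contig
must be an uncompressed sequence.  Each placed read's coordinate map gives
the correspondence between its compressed positions and original positions,
which lets us (1) expand the layout to uncompressed coordinates and (2) call
a consensus in two parts: the compressed backbone is polished by per-column
majority vote over all reads realigned to it, and every surviving column's
homopolymer run length is decided by plain majority over the uncompressed
run-length observations of the reads aligned to that column.  Reads that
fail to align to their layout window at the minimum identity are excluded
from the consensus (they may later surface as short low-coverage contigs,
which the reporting filter hides by default).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._kmers import seq_to_vals
from .hpc import Read
from .layout import ContigLayout, Placement
from .overlapper import _parse_cigar
from .params import Params

logger = logging.getLogger(__name__)

_SYMS = "ACGT-"


@dataclass
class Contig:
    contig_id: str
    seq: str
    cls: str = "draft"
    #: (read_id, orient, (u_start, u_end)) in uncompressed contig coordinates
    placements: list = field(default_factory=list)
    excluded_reads: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# layout expansion
# ---------------------------------------------------------------------------

def expand_layout(layout: ContigLayout, reads: dict[str, Read]):
    """Convert compressed placements to uncompressed contig coordinates.

    The uncompressed offset of each read is obtained by expanding, through
    the coordinate map of the preceding overlapping read, the compressed
    distance between their offsets.  Relative order is preserved.  Raises
    ``KeyError`` if a placed read (and hence its coordinate map) is missing.
    """
    out = []
    prev: list[tuple[Placement, int, np.ndarray]] = []  # (placement, u_off, cumsum)
    for p in sorted(layout.placements, key=lambda p: (p.offset, p.read_id)):
        read = reads[p.read_id]
        cum = np.concatenate([[0], np.cumsum(read.trimmed_run_lengths(p.orient))])
        if not prev:
            u_off = 0
        else:
            anchor = None
            for q, u_q, cum_q in reversed(prev):
                if q.end > p.offset:
                    anchor = (q, u_q, cum_q)
                    break
            if anchor is None:
                q, u_q, cum_q = prev[-1]
                u_off = u_q + int(cum_q[-1]) + (p.offset - q.end)
            else:
                q, u_q, cum_q = anchor
                delta = p.offset - q.offset
                u_off = u_q + int(cum_q[min(delta, len(cum_q) - 1)])
        prev.append((p, u_off, cum))
        out.append((p.read_id, p.orient, (u_off, u_off + int(cum[-1]))))
    return out


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _build_backbone(layout: ContigLayout, reads: dict[str, Read]):
    """Tiling-path backbone in compressed space, with per-column run lengths
    taken from the contributing read (used only as a fallback)."""
    chunks: list[str] = []
    rl_chunks: list[np.ndarray] = []
    cur_end = 0
    for p in sorted(layout.placements, key=lambda p: (p.offset, p.read_id)):
        seq = reads[p.read_id].trimmed_hpc(p.orient)
        rl = reads[p.read_id].trimmed_run_lengths(p.orient)
        if not chunks:
            chunks.append(seq)
            rl_chunks.append(rl)
            cur_end = p.offset + len(seq)
            continue
        if p.offset + len(seq) <= cur_end:
            continue
        splice = cur_end - p.offset
        if splice < 0:
            # coverage gap in the layout; should not happen for layouts built
            # from connected overlap paths, but keep the backbone well formed
            chunks.append("N" * (-splice))
            rl_chunks.append(np.ones(-splice, dtype=np.int64))
            splice = 0
        chunks.append(seq[splice:])
        rl_chunks.append(rl[splice:])
        cur_end = p.offset + len(seq)
    return "".join(chunks), np.concatenate(rl_chunks) if rl_chunks else np.empty(0, np.int64)


def _left_shift_indels(ops, seq: str, backbone: str, bstart: int):
    """Left-normalise indel runs of a read-to-backbone alignment.

    A gap adjacent to equal bases has several co-optimal placements and
    different reads' aligners may choose different ones, splitting the
    per-column vote (microsatellite arrays are the worst case).  Shifting
    every indel run as far left as the immediately preceding match run
    allows makes equivalent observations agree on the same columns.
    """
    res: list[list] = []
    ib, ir = bstart, 0
    for cnt, op in ops:
        if op in ("I", "D") and res and res[-1][1] == "=":
            prev = res[-1]
            s = 0
            if op == "D":
                while (s < prev[0]
                       and backbone[ib - 1 - s] == backbone[ib + cnt - 1 - s]):
                    s += 1
            else:
                while (s < prev[0]
                       and backbone[ib - 1 - s] == seq[ir + cnt - 1 - s]):
                    s += 1
            if s:
                prev[0] -= s
                if prev[0] == 0:
                    res.pop()
                if res and res[-1][1] == op:
                    res[-1][0] += cnt
                else:
                    res.append([cnt, op])
                res.append([s, "="])
                if op == "D":
                    ib += cnt
                else:
                    ir += cnt
                continue
        if res and res[-1][1] == op:
            res[-1][0] += cnt
        else:
            res.append([cnt, op])
        if op in ("=", "X"):
            ib += cnt
            ir += cnt
        elif op == "D":
            ib += cnt
        else:
            ir += cnt
    return [(c, o) for c, o in res]


def compute_consensus(layout: ContigLayout, reads: dict[str, Read],
                      params: Params | None = None, passes: int = 2) -> Contig:
    """Consensus sequence of one layout from the uncompressed reads.

    Every placed read is realigned (banded edit distance) to its window of
    the compressed backbone; per-column votes decide each base, per-junction
    indel observations (hierarchical plurality, see :func:`_call_junction`)
    decide insertions and deletions, and each surviving column's homopolymer
    run length is the majority (ties toward shorter) of the uncompressed run
    lengths observed by the reads aligned to it.

    The vote is iterated (two passes by default): the first pass polishes
    the raw tiling-path backbone, the second realigns every read to that
    polished sequence.  Residual backbone errors — in particular mismatches
    inside repeat arrays that block the left-shift normalisation and split
    indel votes across junctions — disappear after the first pass, so the
    second pass sees cleanly mergeable evidence.  Deterministic given the
    layout and reads.
    """
    params = params or Params()
    if not layout.placements:
        return Contig(layout.id, "", layout.cls)
    backbone, bb_rl = _build_backbone(layout, reads)
    chars: list[str] = []
    runs: list[int] = []
    cov = np.empty(0)
    excluded: list[str] = []
    for _ in range(max(1, passes)):
        result = _consensus_pass(backbone, bb_rl, layout, reads, params)
        if result is None:
            return Contig(layout.id, "", layout.cls, excluded_reads=excluded)
        chars, runs, cov, excluded = result
        backbone = "".join(chars)
        bb_rl = np.asarray(runs, dtype=np.int64)

    # contig tips covered by a single read would pass that read's private
    # errors straight through; emit only the range covered by >= 2 reads
    # (single-read layouts keep their full extent)
    well = np.flatnonzero(cov >= 2)
    lo, hi = (int(well[0]), int(well[-1])) if len(well) else (0, len(chars) - 1)
    prefix_clip = int(sum(runs[:lo]))
    seq = "".join(ch * r for ch, r in zip(chars[lo : hi + 1], runs[lo : hi + 1]))

    contig = Contig(layout.id, seq, layout.cls, excluded_reads=excluded)
    contig.placements = [
        (rid, orient, (s - prefix_clip, e - prefix_clip))
        for rid, orient, (s, e) in expand_layout(layout, reads)]
    return contig


def _consensus_pass(backbone: str, bb_rl: np.ndarray, layout: ContigLayout,
                    reads: dict[str, Read], params: Params):
    """One realign-and-vote round against ``backbone``.

    Returns ``(chars, runs, coverage, excluded)`` — one output column per
    consensus base with its majority run length and supporting read count —
    or None if nothing aligned.
    """
    n = len(backbone)
    bb_vals = seq_to_vals(backbone)
    pad = params.consensus_window_pad

    sym_cols: list[np.ndarray] = []
    sym_vals: list[np.ndarray] = []
    rl_cols: list[np.ndarray] = []
    rl_vals: list[np.ndarray] = []
    jcov = np.zeros(n + 1, dtype=np.int32)
    # per-junction indel observations (canonically left-shifted, so
    # equivalent events from different reads land on the same junction)
    ins_props: dict[int, list] = {}   # junction -> [(string, run lengths)]
    del_props: dict[int, list] = {}   # junction -> [run length]
    excluded = []

    for p in sorted(layout.placements, key=lambda p: (p.offset, p.read_id)):
        read = reads[p.read_id]
        seq = read.trimmed_hpc(p.orient)
        rl = np.asarray(read.trimmed_run_lengths(p.orient))
        w0 = max(0, p.offset - pad)
        w1 = min(n, p.offset + len(seq) + pad)
        window = backbone[w0:w1]
        res = edlib.align(seq, window, mode="HW", task="path",
                          k=max(64, int(0.1 * len(seq))))
        if res["editDistance"] < 0 or (
                len(seq) and res["editDistance"] / len(seq) >
                1 - params.consensus_min_identity):
            excluded.append(p.read_id)
            logger.warning("read %s failed to align to contig %s window; "
                           "excluded from consensus", p.read_id, layout.id)
            continue
        start = w0 + res["locations"][0][0]
        ib, ir = start, 0
        vals = seq_to_vals(seq)
        ops = _left_shift_indels(_parse_cigar(res["cigar"]), seq, backbone, start)
        for cnt, op in ops:
            if op in ("=", "X"):
                cols = np.arange(ib, ib + cnt)
                sym_cols.append(cols)
                sym_vals.append(vals[ir : ir + cnt].astype(np.int64))
                rl_cols.append(cols)
                rl_vals.append(rl[ir : ir + cnt])
                ib += cnt
                ir += cnt
            elif op == "D":  # read lacks these backbone columns
                del_props.setdefault(ib, []).append(cnt)
                ib += cnt
            else:  # "I": read has extra bases before column ib
                s = seq[ir : ir + cnt]
                ins_props.setdefault(ib, []).append((s, rl[ir : ir + cnt]))
                ir += cnt
        jcov[start + 1 : ib] += 1

    if not sym_cols:
        return None

    cols = np.concatenate(sym_cols)
    vals = np.concatenate(sym_vals)
    counts = np.zeros((n, 5), dtype=np.int32)  # A C G T N/other
    np.add.at(counts, (cols, vals), 1)
    base_counts = counts[:, :4]
    coverage = base_counts.sum(axis=1)

    # majority symbol per column; the backbone symbol wins ties
    top = base_counts.max(axis=1)
    win = base_counts.argmax(axis=1)
    bb_is_top = (bb_vals < 4) & (counts[np.arange(n), bb_vals] == top)
    win = np.where(bb_is_top, bb_vals, win)
    keep = coverage > 0

    # junction indel calls: accepted insertions and column deletions
    insertions: dict[int, tuple] = {}
    for j in sorted(set(ins_props) | set(del_props)):
        ins_cols, n_del, n_sup = _call_junction(
            ins_props.get(j, []), del_props.get(j, []), int(jcov[j]))
        if ins_cols:
            insertions[j] = (ins_cols, n_sup)
        elif n_del:
            keep[j : j + n_del] = False

    # majority run length per kept column
    rcols = np.concatenate(rl_cols)
    rvals = np.concatenate(rl_vals).astype(np.int64)
    run_len = _majority_run_lengths(n, rcols, rvals, bb_rl)

    out_chars: list[str] = []
    out_runs: list[int] = []
    out_cov: list[int] = []
    for i in range(n):
        if i > 0 and i in insertions:
            ins_cols, n_sup = insertions[i]
            for ch, r in ins_cols:
                out_chars.append(ch)
                out_runs.append(r)
                out_cov.append(n_sup)
        if keep[i]:
            out_chars.append(_SYMS[win[i]])
            out_runs.append(int(run_len[i]))
            out_cov.append(int(coverage[i]))
    return out_chars, out_runs, np.asarray(out_cov), excluded


def _call_junction(ins_list: list, del_lens: list, junction_cov: int
                   ) -> tuple[list, int, int]:
    """Net indel call at one backbone junction by hierarchical plurality.

    Each read spanning the junction contributes one observation: an
    insertion of some string, a deletion of some number of backbone
    columns, or agreement with the backbone.  A repeat-unit miscount
    rarely commands an absolute majority (the remaining reads split
    between agreement and opposite shifts), so the decision is the
    plurality over exact observations, extended hierarchically: a read
    proposing two extra units also supports the first one, and the call
    grows while its cumulative support beats every alternative
    observation group.  Returns (inserted sequence, deleted columns),
    at most one of which is non-trivial.
    """
    n_ins, n_del = len(ins_list), len(del_lens)
    if n_ins == 0 and n_del == 0:
        return [], 0, 0
    denom = max(junction_cov, n_ins + n_del)
    zeros = max(0, denom - n_ins - n_del)
    ins_lens = [len(s) for s, _ in ins_list]

    def f(t):  # reads observing an insertion of at least t bases
        return sum(1 for L in ins_lens if L >= t)

    def g(t):  # reads observing a deletion of at least t columns
        return sum(1 for L in del_lens if L >= t)

    m = max(zeros, f(1), g(1))
    if m == zeros:
        return [], 0, 0
    if g(1) == m and g(1) >= f(1):  # ties between directions go to deletion
        exact = Counter(del_lens)
        t = 1
        while True:
            opp = max([zeros, f(1)] + [c for u, c in exact.items() if u <= t])
            if g(t + 1) > opp:
                t += 1
            else:
                return [], t, 0
    exact = Counter(ins_lens)
    t = 1
    while True:
        opp = max([zeros, g(1)] + [c for u, c in exact.items() if u <= t])
        if f(t + 1) > opp:
            t += 1
        else:
            break
    # per-position majority of bases and run lengths over the supporters
    out = []
    for k in range(t):
        ch_votes, rl_votes = Counter(), Counter()
        for s, rl in ins_list:
            if len(s) >= t:
                ch_votes[s[k]] += 1
                rl_votes[int(rl[k])] += 1
        top_c = max(ch_votes.values())
        ch = min(c for c, v in ch_votes.items() if v == top_c)
        top_r = max(rl_votes.values())
        r = min(v for v, c in rl_votes.items() if c == top_r)
        out.append((ch, r))
    return out, 0, f(t)


def _majority_of(values: np.ndarray) -> int:
    vals, cnt = np.unique(values, return_counts=True)
    best = cnt.max()
    return int(vals[cnt == best].min())


def _majority_run_lengths(n: int, cols: np.ndarray, vals: np.ndarray,
                          fallback: np.ndarray) -> np.ndarray:
    """Per-column majority of run-length observations (ties toward shorter)."""
    out = fallback.copy() if len(fallback) == n else np.ones(n, dtype=np.int64)
    if len(cols) == 0:
        return out
    order = np.lexsort((vals, cols))
    c, v = cols[order], vals[order]
    # count identical (col, val) pairs
    new = np.empty(len(c), dtype=bool)
    new[0] = True
    new[1:] = (c[1:] != c[:-1]) | (v[1:] != v[:-1])
    starts = np.flatnonzero(new)
    counts = np.diff(np.append(starts, len(c)))
    gc, gv = c[starts], v[starts]
    # per column: maximal count, smallest value among ties; within one column
    # groups are ordered by value, so a strict '>' keeps the smallest tie
    best_count = np.zeros(n, dtype=np.int64)
    for i in range(len(gc)):
        col = gc[i]
        if counts[i] > best_count[col]:
            best_count[col] = counts[i]
            out[col] = gv[i]
    return out
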