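"""Overlap error adjustment: pileup voting, microsatellite masking and
identity recomputation.

Residual errors in compressed reads are identified by jointly considering all
of a read's overlapping reads: every partner votes, at each position it
covers, either for the read's original symbol (where the alignment matches)
or for a change (the partner's base, a deletion, or an insertion before the
position).  A position is corrected when no partner supports the original
symbol and the majority of votes agree on one change — or, when some partner
does support the original, only if the winning change additionally gathers at
least ``vote_min_count`` votes (seven by default).

Indel differences have co-optimal placements (a gap adjacent to equal bases
can sit at several equivalent positions, and alignments computed in opposite
orientations shift gaps in opposite directions), so every indel event is
normalised to its left-most equivalent representation in the subject read's
frame before votes are tallied or corrections are matched; otherwise
equivalent observations would split the vote.

A second, systematic error mode concentrates in microsatellite arrays, where
the repeat unit count is miscounted consistently across reads and therefore
survives voting.  Such differences are not corrected but *masked* when
overlap identities are recomputed: a difference is ignored if, in either
read, at least 5 of the 6 consecutive non-overlapping flanking k-mers on one
side are identical to each other, for any k in [2, 6] and any start offset
in [0, k-1] from the difference.

Corrections are virtual throughout: stored read sequences are never modified
(doing so would invalidate every previously computed overlap coordinate);
instead each overlap's difference list is re-walked and differences resolved
by a correction in either read, or masked as microsatellite-flanked, are
dropped before the identity is recomputed.  Identities can therefore only
increase.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .hpc import revcomp
from .overlapper import Overlap
from .params import PPM, Params


@dataclass
class PileupVotes:
    """Per-position vote table over one read, in compressed coordinates.

    ``coverage[p]`` counts overlaps covering position ``p``; every covering
    overlap votes there exactly once, either for the original symbol or (via
    ``changes``) for a substitution/deletion.  Insertion votes live between
    positions: ``ins_changes[j]`` counts insertion strings proposed before
    position ``j`` and ``junction_coverage[j]`` the overlaps spanning that
    junction.
    """

    read_id: str
    length: int
    coverage: np.ndarray
    junction_coverage: np.ndarray
    changes: dict = field(default_factory=dict)        # pos -> Counter(sym)
    change_count: dict = field(default_factory=dict)   # pos -> #overlaps with a diff
    ins_changes: dict = field(default_factory=dict)    # junction -> Counter(str)

    def support(self, pos: int) -> int:
        """Overlaps that cover ``pos`` and agree with the original symbol."""
        return int(self.coverage[pos]) - self.change_count.get(pos, 0)

    def ins_support(self, junction: int) -> int:
        total = sum(self.ins_changes.get(junction, Counter()).values())
        return int(self.junction_coverage[junction]) - total

    def covered_positions(self) -> np.ndarray:
        return np.flatnonzero(self.coverage > 0)


@dataclass(frozen=True)
class Correction:
    """A virtual edit to one read: never applied to the stored sequence."""

    read_id: str
    pos: int            # position for sub/del; junction for ins
    kind: str           # "sub" | "del" | "ins"
    original: str
    replacement: str    # new base, "-" for del, inserted string for ins


# ---------------------------------------------------------------------------
# indel events and canonical placement
# ---------------------------------------------------------------------------

def canonical_ins(seq: str, junction: int, s: str) -> tuple[int, str]:
    """Left-most equivalent placement of inserting ``s`` before ``junction``."""
    while junction > 0 and s and seq[junction - 1] == s[-1]:
        s = seq[junction - 1] + s[:-1]
        junction -= 1
    return junction, s


def canonical_del(seq: str, start: int, length: int) -> int:
    """Left-most equivalent start of deleting ``seq[start:start+length]``."""
    while start > 0 and seq[start - 1] == seq[start + length - 1]:
        start -= 1
    return start


def overlap_events(o: Overlap):
    """Group an overlap's differences into events on the subject read.

    Yields ``("sub", [diff])``, ``("del", members)`` (a run of extra subject
    bases grouped by their shared junction in b) or ``("ins", members)``
    (extra partner bases grouped by their junction in a, ordered along the
    alignment).  Multi-column indels are treated as one event so that their
    placement can be normalised consistently.
    """
    dels: dict[int, list] = {}
    inss: dict[int, list] = {}
    for d in o.diffs:
        if d.kind == "sub":
            yield "sub", [d]
        elif d.kind == "del":
            dels.setdefault(d.b_pos, []).append(d)
        else:
            inss.setdefault(d.a_pos, []).append(d)
    for j in sorted(dels):
        yield "del", sorted(dels[j], key=lambda d: d.a_pos)
    rev = o.strand == "-"
    for j in sorted(inss):
        yield "ins", sorted(inss[j], key=lambda d: d.b_pos, reverse=rev)


def collect_votes(read_id: str, seq: str, overlaps: list[Overlap]) -> PileupVotes:
    """Tally the votes cast on ``read_id`` by all overlaps where it is the
    subject (a-side).  The table covers exactly the positions covered by at
    least one overlap; indel events vote at their canonical placement."""
    n = len(seq)
    cov = np.zeros(n, dtype=np.int32)
    jcov = np.zeros(n + 1, dtype=np.int32)
    votes = PileupVotes(read_id, n, cov, jcov)
    for o in overlaps:
        if o.a_id != read_id:
            continue
        cov[o.a_start : o.a_end] += 1
        # junction j sits between positions j-1 and j; the overlap spans it
        # when both flanking positions are covered
        if o.a_end - o.a_start >= 2:
            jcov[o.a_start + 1 : o.a_end] += 1
        for kind, members in overlap_events(o):
            if kind == "sub":
                d = members[0]
                votes.changes.setdefault(d.a_pos, Counter())[d.o_sym] += 1
                votes.change_count[d.a_pos] = votes.change_count.get(d.a_pos, 0) + 1
            elif kind == "del":
                start = canonical_del(seq, members[0].a_pos, len(members))
                for pos in range(start, start + len(members)):
                    votes.changes.setdefault(pos, Counter())["-"] += 1
                    votes.change_count[pos] = votes.change_count.get(pos, 0) + 1
            else:
                s = "".join(d.o_sym for d in members)
                j, s = canonical_ins(seq, members[0].a_pos, s)
                votes.ins_changes.setdefault(j, Counter())[s] += 1
    return votes


def _winning_change(counter: Counter) -> tuple[str, int]:
    """Top-voted change with a deterministic tie-break (lexicographic)."""
    top_count = max(counter.values())
    top = min(s for s, c in counter.items() if c == top_count)
    return top, top_count


def call_corrections(votes: PileupVotes, seq: str, params: Params | None = None
                     ) -> list[Correction]:
    """Apply the voting rule to a pileup and emit corrections.

    A change wins at a position iff it takes more than
    ``vote_majority_fraction`` of all votes there (change votes plus
    original-support votes) and either nothing supports the original symbol
    or the change has at least ``vote_min_count`` votes.
    """
    params = params or Params()
    out = []
    for pos in sorted(votes.changes):
        counter = votes.changes[pos]
        top, n = _winning_change(counter)
        total = int(votes.coverage[pos])
        if total == 0:
            continue
        sup = votes.support(pos)
        if n / total <= params.vote_majority_fraction:
            continue
        if (sup > 0 or params.vote_always_require_min) and n < params.vote_min_count:
            continue
        kind = "del" if top == "-" else "sub"
        out.append(Correction(votes.read_id, pos, kind, seq[pos], top))
    for j in sorted(votes.ins_changes):
        counter = votes.ins_changes[j]
        top, n = _winning_change(counter)
        total = int(votes.junction_coverage[j])
        if total == 0:
            continue
        sup = votes.ins_support(j)
        if n / total <= params.vote_majority_fraction:
            continue
        if (sup > 0 or params.vote_always_require_min) and n < params.vote_min_count:
            continue
        out.append(Correction(votes.read_id, j, "ins", "", top))
    out.sort(key=lambda c: (c.pos, c.kind))
    return out


def collect_all_corrections(seqs: dict[str, str], overlaps: list[Overlap],
                            params: Params | None = None) -> dict[str, list[Correction]]:
    """Run vote collection and correction calling for every read.

    Only overlaps at or above ``vote_identity_floor`` cast votes: a partner
    from a diverged repeat copy or the other haplotype carries genuine
    variants as "differences" and, given the chance, would vote them away
    half the time; same-locus partners stay above the floor even with
    several residual sequencing errors in the overlap.
    """
    params = params or Params()
    floor = round(params.vote_identity_floor * PPM)
    by_read: dict[str, list[Overlap]] = {}
    for o in overlaps:
        if o.identity_ppm >= floor:
            by_read.setdefault(o.a_id, []).append(o)
    out: dict[str, list[Correction]] = {}
    for rid in sorted(seqs):
        votes = collect_votes(rid, seqs[rid], by_read.get(rid, []))
        out[rid] = call_corrections(votes, seqs[rid], params)
    return out


# ---------------------------------------------------------------------------
# microsatellite-flank masking
# ---------------------------------------------------------------------------

def _flank_is_repeat(seq: str, left_end: int, right_start: int,
                     params: Params) -> bool:
    """5-of-6 flanking k-mer test around one difference in one read.

    ``left_end`` is the last position before the difference, ``right_start``
    the first position after it (both in the read's own coordinates).  A side
    qualifies when, for some k in [k_min, k_max] and some offset in [0, k-1],
    the window of 6 consecutive non-overlapping k-mers adjacent to the
    difference contains one k-mer value at least 5 times.  Windows that run
    off the read are skipped.
    """
    w = params.mask_window_kmers
    need = params.mask_kmers_required
    n = len(seq)
    for k in range(params.mask_k_min, params.mask_k_max + 1):
        span = w * k
        for off in range(k):
            start = left_end - off - span + 1
            if start >= 0 and left_end - off + 1 <= n:
                if _has_dominant_kmer(seq[start : start + span], k, w, need):
                    return True
            start = right_start + off
            if start + span <= n:
                if _has_dominant_kmer(seq[start : start + span], k, w, need):
                    return True
    return False


def _has_dominant_kmer(window: str, k: int, w: int, need: int) -> bool:
    counts = Counter(window[i * k : (i + 1) * k] for i in range(w))
    return max(counts.values()) >= need


def is_microsatellite_flanked(seq_a: str, seq_b: str, diff,
                              params: Params | None = None) -> bool:
    """True if the difference is flanked by a microsatellite in either read.

    ``seq_b`` must be the partner read in its forward orientation (the diff
    stores forward b coordinates).  A microsatellite pattern is strand
    symmetric, so the orientation of the comparison never changes the answer.
    """
    params = params or Params()
    if diff.kind == "sub":
        a_left, a_right = diff.a_pos - 1, diff.a_pos + 1
        b_left, b_right = diff.b_pos - 1, diff.b_pos + 1
    elif diff.kind == "del":  # extra base in a; b_pos is a junction
        a_left, a_right = diff.a_pos - 1, diff.a_pos + 1
        b_left, b_right = diff.b_pos - 1, diff.b_pos
    else:  # "ins": extra base in b; a_pos is a junction
        a_left, a_right = diff.a_pos - 1, diff.a_pos
        b_left, b_right = diff.b_pos - 1, diff.b_pos + 1
    return (_flank_is_repeat(seq_a, a_left, a_right, params)
            or _flank_is_repeat(seq_b, b_left, b_right, params))


# ---------------------------------------------------------------------------
# identity recomputation
# ---------------------------------------------------------------------------

def _correction_index(corrections: dict[str, list[Correction]]):
    idx: dict[tuple[str, str, int], str] = {}
    for rid, lst in corrections.items():
        for c in lst:
            idx[(rid, c.kind, c.pos)] = c.replacement
    return idx


def _event_resolved(o: Overlap, kind: str, members: list, idx,
                    seq_a: str, seq_b: str) -> bool:
    """Does a correction in either read cancel this event entirely?"""
    flip = o.strand == "-"

    def b_frame(s: str) -> str:
        return revcomp(s) if flip else s

    if kind == "sub":
        d = members[0]
        if idx.get((o.a_id, "sub", d.a_pos)) == d.o_sym:
            return True
        return idx.get((o.b_id, "sub", d.b_pos)) == b_frame(d.a_sym)

    if kind == "del":  # run of extra bases in a; junction in b
        m = len(members)
        start = canonical_del(seq_a, members[0].a_pos, m)
        if all((o.a_id, "del", p) in idx for p in range(start, start + m)):
            return True
        content_b = b_frame("".join(d.a_sym for d in members))
        j, s = canonical_ins(seq_b, members[0].b_pos, content_b)
        return idx.get((o.b_id, "ins", j)) == s

    # "ins": run of extra bases in b; junction in a
    m = len(members)
    s = "".join(d.o_sym for d in members)
    j, s = canonical_ins(seq_a, members[0].a_pos, s)
    if idx.get((o.a_id, "ins", j)) == s:
        return True
    start = canonical_del(seq_b, min(d.b_pos for d in members), m)
    return all((o.b_id, "del", p) in idx for p in range(start, start + m))


def recompute_identities(overlaps: list[Overlap],
                         corrections: dict[str, list[Correction]],
                         seqs: dict[str, str],
                         params: Params | None = None,
                         masking: bool = True) -> list[Overlap]:
    """Re-walk every overlap's difference list and recompute its identity.

    Effective differences are the original ones minus those resolved by a
    correction in either read minus (optionally) those masked as
    microsatellite-flanked.  Sequences are untouched; scores and identities
    are recomputed from the surviving differences, so identity never
    decreases.  The surviving differences replace the stored list.
    """
    params = params or Params()
    idx = _correction_index(corrections)
    out = []
    for o in overlaps:
        if not o.diffs:
            out.append(o)
            continue
        seq_a, seq_b = seqs[o.a_id], seqs[o.b_id]
        kept = []
        for kind, members in overlap_events(o):
            if _event_resolved(o, kind, members, idx, seq_a, seq_b):
                continue
            for d in members:
                if masking and is_microsatellite_flanked(seq_a, seq_b, d, params):
                    continue
                kept.append(d)
        kept.sort(key=lambda d: (d.a_pos, d.b_pos, d.kind))
        nd = len(kept)
        out.append(Overlap(
            o.a_id, o.b_id, o.strand, o.a_start, o.a_end, o.b_start, o.b_end,
            o.a_len, o.b_len, o.aln_len,
            round((1 - nd / o.aln_len) * PPM), o.aln_len - nd, tuple(kept)))
    return out
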