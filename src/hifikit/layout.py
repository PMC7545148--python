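"""Contig construction from adjusted overlaps: threshold selection, best
overlap graph, greedy contigs, bubble flagging and repeat breaking.

The error-adjusted overlaps are first thinned by a two-step identity
threshold: every overlap below a fixed floor (99.97%, i.e. three differences
in 10,000 bp) is dropped — removing most cross-haplotype overlaps even for
low-heterozygosity genomes — and the final threshold is then set to the 90th
percentile (ascending nearest-rank) of the identities of the best-scoring
surviving overlap off each read end.  On accurate data this sample is
dominated by perfect overlaps and the selected threshold is 100%.

The best overlap graph keeps, for every non-contained read, the best-scoring
surviving overlap off each of its ends (score = number of matching bases).
Mutually-agreeing best edges form non-branching paths, the greedy contigs.
Contigs representing an alternative allele of a region already present in a
larger contig are flagged as bubbles: both their first and last reads must
place in the same larger contig, consistently oriented, at 75%-125% of the
candidate's length, through overlaps whose quality is within 0.1% of the
overlaps already incorporated there.  Bubble reads are then excluded from
repeat detection, which breaks the remaining drafts at suspected repeat
regions — stretches whose reads overlap reads outside the contig — unless a
placed read spans the region and no similar-length alternate overlap exists
at the junction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .overlapper import Overlap
from .params import PPM, Params, ppm

logger = logging.getLogger(__name__)


@dataclass
class Placement:
    read_id: str
    offset: int
    orient: str
    length: int  # trimmed compressed length

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class ContigLayout:
    """Ordered read placements in compressed contig coordinates."""

    id: str
    placements: list
    cls: str = "draft"  # "draft" | "bubble"
    #: (C0, C1, identity_ppm, aln_len) per incorporated best edge
    edges: list = field(default_factory=list)
    #: for bubbles: (host_layout_id, host_start, host_end)
    host: tuple | None = None

    @property
    def span(self) -> int:
        return max((p.end for p in self.placements), default=0)

    def read_ids(self) -> set:
        return {p.read_id for p in self.placements}


@dataclass
class BestOverlapGraph:
    best: dict          # read_id -> {"5": Overlap|None, "3": Overlap|None}
    contained: dict     # read_id -> sorted list of container overlaps (a=read)
    overlaps: list      # the threshold-filtered overlap set


# ---------------------------------------------------------------------------
# two-step identity threshold
# ---------------------------------------------------------------------------

def _contained_ids(overlaps: list[Overlap]) -> set:
    """Reads fully covered by a partner.

    Mutually contained reads (identical extents) are tie-broken so that the
    lexicographically smallest read of the group stays non-contained.
    """
    out = set()
    for o in overlaps:
        if o.a_contained and (not o.b_contained or o.b_id < o.a_id):
            out.add(o.a_id)
    return out


def _best_end_overlaps(overlaps: list[Overlap]):
    """Best-scoring dovetail overlap per (read, end) among non-contained reads."""
    contained = _contained_ids(overlaps)
    best: dict[tuple[str, str], Overlap] = {}
    for o in overlaps:
        if o.a_id in contained or o.b_id in contained:
            continue
        for end in ("5", "3"):
            if not o.hangs_off(end):
                continue
            key = (o.a_id, end)
            cur = best.get(key)
            if cur is None or _edge_rank(o) < _edge_rank(cur):
                best[key] = o
    return best, contained


def _edge_rank(o: Overlap):
    # maximal score; ties resolved toward higher identity, then lower
    # lexicographic partner id, then deterministically
    return (-o.score, -o.identity_ppm, o.b_id, o.strand, o.a_start)


def nearest_rank_percentile(sample: list[float], pct: float) -> float:
    """Ascending nearest-rank percentile of a non-empty sample."""
    s = sorted(sample)
    idx = max(0, math.ceil(pct / 100 * len(s)) - 1)
    return s[idx]


def select_identity_threshold(overlaps: list[Overlap],
                              params: Params | None = None) -> float:
    """Two-step overlap identity threshold.

    Drops overlaps below the fixed floor, samples the identity of the
    best-scoring surviving overlap off each read end, and returns the
    ascending nearest-rank ``percentile`` of that sample (as a fraction).
    Falls back to the floor, with a warning, when the sample is empty.
    """
    params = params or Params()
    floor = params.identity_floor_ppm
    surviving = [o for o in overlaps if o.identity_ppm >= floor]
    best, _ = _best_end_overlaps(surviving)
    sample = [o.identity_ppm for o in best.values()]
    if not sample:
        logger.warning(
            "no overlaps survive the %.4f identity floor; using it as the "
            "threshold", params.identity_floor)
        return params.identity_floor
    return nearest_rank_percentile(sample, params.percentile) / PPM


def filter_overlaps(overlaps: list[Overlap], threshold: float) -> list[Overlap]:
    t = ppm(threshold)
    return [o for o in overlaps if o.identity_ppm >= t]


# ---------------------------------------------------------------------------
# best overlap graph
# ---------------------------------------------------------------------------

def build_best_overlap_graph(overlaps: list[Overlap], threshold: float,
                             params: Params | None = None) -> BestOverlapGraph:
    """Best-scoring overlap off both ends of every non-contained read.

    ``overlaps`` must already be error-adjusted; they are filtered at
    ``threshold`` here.  Contained reads receive no best edges (they are
    placed into their container's contig later).
    """
    filtered = filter_overlaps(overlaps, threshold)
    best_map, contained = _best_end_overlaps(filtered)
    read_ids = sorted({o.a_id for o in filtered})
    best = {rid: {"5": best_map.get((rid, "5")), "3": best_map.get((rid, "3"))}
            for rid in read_ids if rid not in contained}
    containers: dict[str, list[Overlap]] = {}
    for o in filtered:
        if o.a_id in contained and o.a_contained:
            containers.setdefault(o.a_id, []).append(o)
    for lst in containers.values():
        lst.sort(key=_edge_rank)
    return BestOverlapGraph(best, containers, filtered)


def _mutual_link(graph: BestOverlapGraph, rid: str, end: str):
    """The (partner, partner_end, overlap) of a reciprocated best edge."""
    o = graph.best.get(rid, {}).get(end)
    if o is None:
        return None
    pend = o.partner_end(end)
    back = graph.best.get(o.b_id, {}).get(pend)
    if back is None or back.b_id != rid:
        return None
    if (back.strand, back.a_start, back.a_end, back.b_start, back.b_end) != (
            o.strand, o.b_start, o.b_end, o.a_start, o.a_end):
        return None
    return o.b_id, pend, o


def _aligned_contig_interval(pl: Placement, a_start: int, a_end: int,
                             a_len: int) -> tuple[int, int]:
    """Contig coordinates of an aligned region given in read coordinates."""
    if pl.orient == "+":
        return pl.offset + a_start, pl.offset + a_end
    return pl.offset + a_len - a_end, pl.offset + a_len - a_start


def _partner_offset(C0: int, o: Overlap, partner_orient: str) -> int:
    if partner_orient == "+":
        return C0 - o.b_start
    return C0 - (o.b_len - o.b_end)


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def greedy_contigs(graph: BestOverlapGraph) -> list[ContigLayout]:
    """Non-branching paths of mutually-agreeing best edges become layouts.

    Reads whose best edges are not reciprocated start or stop paths; cycles
    (circular tilings) are opened at their smallest read id.  Contained
    reads are placed into their best-scoring container's layout; every read
    ends up in exactly one layout.  The result is independent of read input
    order.
    """
    visited: set[str] = set()
    paths = []
    rids = sorted(graph.best)

    def walk(start: str, out_end: str):
        orient = "+" if out_end == "3" else "-"
        placements = [Placement(start, 0, orient, _read_len(graph, start))]
        edges = []
        visited.add(start)
        cur, coff = start, 0
        while True:
            cr_end = "3" if orient == "+" else "5"
            link = _mutual_link(graph, cur, cr_end)
            if link is None or link[0] in visited:
                break
            nxt, _, o = link
            pl = placements[-1]
            C0, C1 = _aligned_contig_interval(pl, o.a_start, o.a_end, o.a_len)
            norient = pl.orient if o.strand == "+" else _flip(pl.orient)
            noff = _partner_offset(C0, o, norient)
            placements.append(Placement(nxt, noff, norient, o.b_len))
            edges.append((C0, C1, o.identity_ppm, o.aln_len))
            visited.add(nxt)
            cur, orient, coff = nxt, norient, noff
        return placements, edges

    def canonical(placements, edges):
        shift = min(p.offset for p in placements)
        for p in placements:
            p.offset -= shift
        edges = [(c0 - shift, c1 - shift, i, l) for c0, c1, i, l in edges]
        if placements[-1].read_id < placements[0].read_id:
            span = max(p.end for p in placements)
            for p in placements:
                p.offset = span - p.end
                p.orient = _flip(p.orient)
            placements.reverse()
            edges = [(span - c1, span - c0, i, l) for c0, c1, i, l in edges][::-1]
        placements.sort(key=lambda p: (p.offset, p.read_id))
        return placements, edges

    # path terminals first, then any remaining cycles
    for rid in rids:
        if rid in visited:
            continue
        links = {e: _mutual_link(graph, rid, e) for e in ("5", "3")}
        n_links = sum(v is not None for v in links.values())
        if n_links == 2:
            continue
        out_end = "3" if links["3"] is not None else ("5" if links["5"] else "3")
        paths.append(canonical(*walk(rid, out_end)))
    for rid in rids:
        if rid not in visited:
            paths.append(canonical(*walk(rid, "3")))

    paths.sort(key=lambda pe: pe[0][0].read_id)
    layouts = [ContigLayout(f"tig{i:05d}", pls, edges=edges)
               for i, (pls, edges) in enumerate(paths)]

    _place_contained(graph, layouts)
    for lay in layouts:
        lay.placements.sort(key=lambda p: (p.offset, p.read_id))
    return layouts


def _read_len(graph: BestOverlapGraph, rid: str) -> int:
    for end in ("5", "3"):
        o = graph.best[rid][end]
        if o is not None:
            return o.a_len
    for o in graph.overlaps:
        if o.a_id == rid:
            return o.a_len
    return 0


def _place_contained(graph: BestOverlapGraph, layouts: list[ContigLayout]) -> None:
    placement_of: dict[str, tuple[ContigLayout, Placement]] = {}
    for lay in layouts:
        for p in lay.placements:
            placement_of[p.read_id] = (lay, p)
    pending = sorted(graph.contained)
    for _ in range(len(pending) + 1):
        if not pending:
            break
        still = []
        for rid in pending:
            placed = False
            for o in graph.contained[rid]:  # o: a=rid contained in b
                host = placement_of.get(o.b_id)
                if host is None:
                    continue
                lay, ppl = host
                m = o.mirror()  # a = container
                C0, _ = _aligned_contig_interval(ppl, m.a_start, m.a_end, m.a_len)
                orient = ppl.orient if m.strand == "+" else _flip(ppl.orient)
                off = _partner_offset(C0, m, orient)
                pl = Placement(rid, off, orient, o.a_len)
                lay.placements.append(pl)
                placement_of[rid] = (lay, pl)
                placed = True
                break
            if not placed:
                still.append(rid)
        if len(still) == len(pending):
            break
        pending = still
    # anything left over (isolated containment cycles) becomes a singleton
    for i, rid in enumerate(pending):
        lay = ContigLayout(f"tig{len(layouts) + i:05d}",
                           [Placement(rid, 0, "+", _read_len(graph, rid))])
        layouts.append(lay)


# ---------------------------------------------------------------------------
# bubble contigs
# ---------------------------------------------------------------------------

def _mean_edge_identity(layout: ContigLayout, c0: int, c1: int,
                        pad: int) -> int | None:
    vals = [i for (e0, e1, i, _) in layout.edges
            if e1 > c0 - pad and e0 < c1 + pad]
    if not vals:
        vals = [i for (_, _, i, _) in layout.edges]
    if not vals:
        return None
    return int(sum(vals) / len(vals))


def _best_placement_in_larger(read_pl: Placement, own: ContigLayout,
                              layouts_by_read: dict, by_a: dict,
                              params: Params):
    """Best qualifying placement of one read into a larger contig."""
    best = None
    tol = round(params.bubble_quality_tol * PPM)
    for o in by_a.get(read_pl.read_id, []):
        host = layouts_by_read.get(o.b_id)
        if host is None:
            continue
        lay, ppl = host
        if lay is own or lay.span <= own.span:
            continue
        C0, C1 = _aligned_contig_interval(ppl, o.b_start, o.b_end, o.b_len)
        ref = _mean_edge_identity(lay, C0, C1, pad=2 * o.a_len)
        if ref is None or o.identity_ppm < ref - tol:
            continue
        orient = ppl.orient if o.strand == "+" else _flip(ppl.orient)
        rank = (-o.score, -o.identity_ppm, lay.id, o.b_id)
        if best is None or rank < best[0]:
            best = (rank, lay, C0, C1, orient)
    return best


def identify_bubbles(layouts: list[ContigLayout], overlaps: list[Overlap],
                     params: Params | None = None) -> list[ContigLayout]:
    """Flag layouts that are alternative alleles of larger layouts.

    ``overlaps`` should be the full error-adjusted candidate set (not just
    the threshold survivors): placements into the homologous contig are
    judged against the incorporated overlap quality with the 0.1% tolerance,
    which admits overlaps the contig-construction threshold rejected.
    """
    params = params or Params()
    by_a: dict[str, list[Overlap]] = {}
    for o in overlaps:
        by_a.setdefault(o.a_id, []).append(o)
    layouts_by_read = {}
    for lay in layouts:
        for p in lay.placements:
            layouts_by_read[p.read_id] = (lay, p)

    for lay in sorted(layouts, key=lambda l: (l.span, l.id)):
        if not lay.placements:
            continue
        first, last = lay.placements[0], lay.placements[-1]
        pf = _best_placement_in_larger(first, lay, layouts_by_read, by_a, params)
        if pf is None:
            continue
        pl_ = _best_placement_in_larger(last, lay, layouts_by_read, by_a, params)
        if pl_ is None:
            continue
        _, host_f, f0, f1, of = pf
        _, host_l, l0, l1, ol = pl_
        if host_f is not host_l:
            continue
        if (first.orient == last.orient) != (of == ol):
            continue
        placed_span = max(f1, l1) - min(f0, l0)
        ratio = placed_span / lay.span if lay.span else 0.0
        if not (params.bubble_span_low <= ratio <= params.bubble_span_high):
            continue
        lay.cls = "bubble"
        lay.host = (host_f.id, min(f0, l0), max(f1, l1))
    return layouts


# ---------------------------------------------------------------------------
# repeat breaking
# ---------------------------------------------------------------------------

def _merge_intervals(ivs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def break_repeats(layouts: list[ContigLayout], all_overlaps: list[Overlap],
                  params: Params | None = None,
                  merge_gap: int = 2000) -> list[ContigLayout]:
    """Break draft layouts at incorrectly traversed long repeats.

    A region of a draft whose reads overlap reads outside the contig
    (ignoring bubble reads, which represent the other allele rather than a
    repeat copy) is a suspected repeat.  It is broken at its boundaries
    unless some placed read spans it entirely and no alternate overlap of
    similar length (within ``repeat_alt_length_tol``) exists at the
    junction.  ``all_overlaps`` must be the threshold-passing set.

    Breakpoints are only placed deeper than the longest placed read from
    either contig end: separately constructed contigs legitimately tile
    adjacent or allelic genome segments with up to a read length of shared
    sequence (a best-edge chain restart duplicates its seed read's extent),
    so end-proximal external overlaps are adjacency evidence, not evidence
    of a mis-traversed interior repeat.
    """
    params = params or Params()
    bubble_reads = set()
    for lay in layouts:
        if lay.cls == "bubble":
            bubble_reads |= lay.read_ids()
    by_a: dict[str, list[Overlap]] = {}
    for o in all_overlaps:
        by_a.setdefault(o.a_id, []).append(o)

    out = []
    for lay in layouts:
        if lay.cls == "bubble" or len(lay.placements) <= 1:
            out.append(lay)
            continue
        own = lay.read_ids()
        edge_lens = sorted(l for (_, _, _, l) in lay.edges)
        med_edge = (edge_lens[len(edge_lens) // 2] if edge_lens
                    else max(p.length for p in lay.placements))
        min_evidence = params.repeat_evidence_min_frac * med_edge
        ext: list[tuple[int, int, int]] = []  # (C0, C1, aln_len)
        for p in lay.placements:
            if p.read_id in bubble_reads:
                continue
            for o in by_a.get(p.read_id, []):
                if o.b_id in own or o.b_id in bubble_reads:
                    continue
                if o.aln_len < min_evidence:
                    continue
                C0, C1 = _aligned_contig_interval(p, o.a_start, o.a_end, o.a_len)
                ext.append((max(0, C0), min(lay.span, C1), o.aln_len))
        regions = _merge_intervals([(c0, c1) for c0, c1, _ in ext], merge_gap)
        margin = max((p.length for p in lay.placements), default=0) + merge_gap
        breakpoints: list[int] = []
        for r0, r1 in regions:
            spanned = any(p.offset < r0 and p.end > r1 for p in lay.placements)
            if spanned and not _has_similar_alternate(lay, ext, r0, r1, params):
                continue
            breakpoints += [bp for bp in (r0, r1)
                            if margin < bp < lay.span - margin]
        if not breakpoints:
            out.append(lay)
            continue
        out.extend(_split_layout(lay, sorted(set(breakpoints))))
    return out


def _has_similar_alternate(lay: ContigLayout, ext, r0: int, r1: int,
                           params: Params) -> bool:
    """Is there an external overlap at a junction whose length rivals the
    incorporated overlap there?"""
    for bp in (r0, r1):
        junction_edges = [l for (e0, e1, _, l) in lay.edges if e0 <= bp <= e1]
        if not junction_edges:
            continue
        chosen = max(junction_edges)
        for c0, c1, alt_len in ext:
            if c0 <= bp <= c1 and abs(alt_len - chosen) <= params.repeat_alt_length_tol * chosen:
                return True
    return False


def _split_layout(lay: ContigLayout, breakpoints: list[int]) -> list[ContigLayout]:
    import bisect

    bins: dict[int, list[Placement]] = {}
    for p in lay.placements:
        mid = (p.offset + p.end) / 2
        bins.setdefault(bisect.bisect_right(breakpoints, mid), []).append(p)
    parts = []
    for i, key in enumerate(sorted(bins)):
        pls = bins[key]
        shift = min(p.offset for p in pls)
        for p in pls:
            p.offset -= shift
        pls.sort(key=lambda p: (p.offset, p.read_id))
        parts.append(ContigLayout(f"{lay.id}.{i}", pls, cls="draft"))
    return parts
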