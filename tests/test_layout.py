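"""Threshold selection, best overlap graph, greedy contigs, bubbles,
repeat breaking."""

import math

import edlib
import numpy as np
import pytest

import hifikit as hk
from hifikit.layout import (ContigLayout, Placement, break_repeats,
                            build_best_overlap_graph, filter_overlaps,
                            greedy_contigs, identify_bubbles,
                            nearest_rank_percentile,
                            select_identity_threshold)
from hifikit.overlapper import Overlap
from hifikit.params import PPM, Params

from conftest import random_seq


def overlaps_from_positions(positions: dict, identity_ppm: int = PPM,
                            min_len: int = 50) -> list[Overlap]:
    """Fabricate exact same-strand overlap records from read intervals on a
    virtual genome line."""
    out = []
    ids = sorted(positions)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            (a0, a1), (b0, b1) = positions[a], positions[b]
            s, e = max(a0, b0), min(a1, b1)
            if e - s < min_len:
                continue
            cols = e - s
            nd = round((1 - identity_ppm / PPM) * cols)
            o = Overlap(a, b, "+", s - a0, e - a0, s - b0, e - b0,
                        a1 - a0, b1 - b0, cols, identity_ppm, cols - nd,
                        tuple())
            out.append(o)
            out.append(o.mirror())
    return sorted(out, key=lambda o: (o.a_id, o.b_id))


class TestThreshold:
    def test_all_perfect_best_overlaps_select_100_percent(self):
        pos = {f"r{i}": (i * 400, i * 400 + 1000) for i in range(6)}
        ovls = overlaps_from_positions(pos)
        assert select_identity_threshold(ovls, Params()) == 1.0

    def test_overlap_below_floor_is_dropped_before_sampling(self):
        pos = {f"r{i}": (i * 400, i * 400 + 1000) for i in range(4)}
        good = overlaps_from_positions(pos)
        # make one flank overlap clearly the best score but below the floor
        bad = overlaps_from_positions({"r0": pos["r0"], "r1": pos["r1"]},
                                      identity_ppm=999_000)
        boosted = [Overlap(o.a_id, o.b_id, o.strand, o.a_start, o.a_end,
                           o.b_start, o.b_end, o.a_len, o.b_len, o.aln_len,
                           o.identity_ppm, o.score + 10_000, o.diffs)
                   for o in bad]
        thr = select_identity_threshold(good + boosted, Params())
        assert thr == 1.0

    def test_nearest_rank_matches_brute_force_scan(self, rng):
        def scan(sample, pct):
            s = sorted(sample)
            need = math.ceil(pct / 100 * len(s))
            count = 0
            for v in s:
                count += 1
                if count >= need:
                    return v
        mixed = [0.9997] * 2 + [0.9999] * 3 + [1.0] * 15
        assert nearest_rank_percentile(mixed, 90) == scan(mixed, 90) == 1.0
        for _ in range(50):
            sample = rng.random(int(rng.integers(1, 40))).tolist()
            pct = float(rng.integers(1, 100))
            assert nearest_rank_percentile(sample, pct) == scan(sample, pct)

    def test_empty_sample_falls_back_to_floor(self):
        assert select_identity_threshold([], Params()) == Params().identity_floor


class TestBestOverlapGraph:
    def test_three_reads_tiling_form_a_path(self):
        pos = {"a": (0, 1000), "b": (600, 1600), "c": (1200, 2200)}
        graph = build_best_overlap_graph(overlaps_from_positions(pos), 1.0)
        assert graph.best["b"]["5"].b_id == "a"
        assert graph.best["b"]["3"].b_id == "c"
        assert graph.best["a"]["5"] is None

    def test_higher_score_beats_higher_identity(self):
        """Score is matching bases: a longer 99.99% overlap (score 5999)
        beats a shorter perfect one (score 5000)."""
        short = Overlap("x", "y", "+", 5000, 10_000, 0, 5000, 10_000, 10_000,
                        5000, PPM, 5000, ())
        long_ = Overlap("x", "z", "+", 4001, 10_000, 0, 5999, 10_000, 10_000,
                        5999, 999_900, 5999 - 0, ())
        ovls = [short, short.mirror(), long_, long_.mirror()]
        graph = build_best_overlap_graph(ovls, 0.999)
        assert graph.best["x"]["3"].b_id == "z"

    def test_equal_scores_tie_break_to_lower_read_id(self):
        mk = lambda b: Overlap("x", b, "+", 5000, 10_000, 0, 5000,
                               10_000, 10_000, 5000, PPM, 5000, ())
        ovls = []
        for b in ("n2", "n1"):
            ovls += [mk(b), mk(b).mirror()]
        graph = build_best_overlap_graph(ovls, 0.999)
        assert graph.best["x"]["3"].b_id == "n1"


class TestGreedyContigs:
    def test_ten_reads_tiling_give_one_ordered_layout(self):
        pos = {f"r{i:02d}": (i * 500, i * 500 + 1200) for i in range(10)}
        graph = build_best_overlap_graph(overlaps_from_positions(pos), 1.0)
        layouts = greedy_contigs(graph)
        assert len(layouts) == 1
        lay = layouts[0]
        assert [p.read_id for p in lay.placements] == sorted(pos)
        offsets = [p.offset for p in lay.placements]
        assert offsets == sorted(offsets) and offsets[0] == 0

    def test_unreciprocated_best_edge_breaks_the_path(self):
        """c's 3' best edge points to d, but d's facing best edge points to
        the higher-scoring e; the path must break between c and d."""
        pos = {"a": (0, 1000), "b": (600, 1600), "c": (1200, 2200)}
        ovls = overlaps_from_positions(pos)
        d = Overlap("c", "d", "+", 1600 - 1200, 1000, 0, 400, 1000, 1000,
                    400, PPM, 400, ())
        e = Overlap("d", "e", "-", 0, 900, 0, 900, 1000, 1000, 900, PPM, 900, ())
        ovls += [d, d.mirror(), e, e.mirror()]
        graph = build_best_overlap_graph(ovls, 1.0)
        assert graph.best["c"]["3"].b_id == "d"
        assert graph.best["d"]["5"].b_id != "c"
        layouts = greedy_contigs(graph)
        by_read = {p.read_id: lay.id for lay in layouts for p in lay.placements}
        assert by_read["c"] != by_read["d"]

    def test_isolated_read_becomes_singleton_layout(self):
        pos = {"a": (0, 1000), "b": (600, 1600)}
        ovls = overlaps_from_positions(pos)
        lone = Overlap("z", "z2", "+", 0, 0, 0, 0, 800, 800, 0, PPM, 0, ())
        graph = build_best_overlap_graph(ovls, 1.0)
        graph.best["z"] = {"5": None, "3": None}
        layouts = greedy_contigs(graph)
        singles = [l for l in layouts if [p.read_id for p in l.placements] == ["z"]]
        assert len(singles) == 1

    def test_contained_reads_are_placed_in_their_container(self):
        pos = {"a": (0, 1000), "b": (600, 1600), "inner": (100, 700)}
        graph = build_best_overlap_graph(overlaps_from_positions(pos), 1.0)
        assert "inner" in graph.contained
        layouts = greedy_contigs(graph)
        assert len(layouts) == 1
        inner = [p for p in layouts[0].placements if p.read_id == "inner"]
        assert inner and abs(inner[0].offset - 100) <= 2

    def test_every_read_lands_in_exactly_one_layout(self):
        g = hk.simulate_genome(30_000, seed=9, microsat_spec=hk.MicrosatSpec())
        reads = hk.simulate_reads(g, coverage=15, read_length_mean=4000, seed=10)
        cfg = hk.PipelineConfig()
        cfg.params.min_report_contig = 1000
        res = hk.run_assemble({r.id: r.seq for r in reads}, cfg)
        placed = [p.read_id for lay in res.layouts for p in lay.placements]
        assert sorted(placed) == sorted(r.id for r in reads)

    def test_layouts_do_not_depend_on_read_input_order(self):
        g = hk.simulate_genome(20_000, seed=13, microsat_spec=None)
        reads = hk.simulate_reads(g, coverage=12, read_length_mean=4000, seed=14)
        cfg = hk.PipelineConfig()
        fwd = {r.id: r.seq for r in reads}
        rev = dict(reversed(list(fwd.items())))
        out1 = hk.run_assemble(fwd, cfg)
        out2 = hk.run_assemble(rev, cfg)
        assert {c.contig_id: c.seq for c in out1.contigs} == \
               {c.contig_id: c.seq for c in out2.contigs}


def _host_and_candidate(l_offset=700, l_strand="+"):
    """A large host layout plus a 2-read candidate whose end reads place
    into the host; ``l_offset`` positions the candidate's last read (and so
    its span) while the host placements stay fixed at 50..1000."""
    host = ContigLayout("host", [Placement(f"H{i}", i * 250, "+", 300)
                                 for i in range(5)])
    host.edges = [(0, host.span, PPM, 200)]
    cand = ContigLayout("cand", [Placement("F", 0, "+", 300),
                                 Placement("L", l_offset, "+", 300)])
    # F aligns to H0's tail (host 50..300); L aligns onto H3 (host 750..1000)
    of = Overlap("F", "H0", "+", 0, 250, 50, 300, 300, 300, 250, PPM, 250, ())
    ol = Overlap("L", "H3", l_strand, 0, 250, 0, 250, 300, 300,
                 250, PPM, 250, ())
    ovls = [of, of.mirror(), ol, ol.mirror()]
    return host, cand, ovls


class TestBubbles:
    def test_allelic_contig_with_matching_span_is_flagged(self):
        # candidate span 1000, placed span 950: ratio 0.95 within 75%-125%
        host, cand, ovls = _host_and_candidate(l_offset=700)
        identify_bubbles([host, cand], ovls, Params())
        assert cand.cls == "bubble"
        assert cand.host and cand.host[0] == "host"

    def test_span_well_below_75_percent_is_rejected(self):
        # candidate claims span 1900 but places over only 950 (ratio 0.5)
        host, cand, ovls = _host_and_candidate(l_offset=1600)
        identify_bubbles([host, cand], ovls, Params())
        assert cand.cls == "draft"

    def test_inconsistent_end_orientations_are_rejected(self):
        host, cand, ovls = _host_and_candidate(l_offset=700, l_strand="-")
        identify_bubbles([host, cand], ovls, Params())
        assert cand.cls == "draft"

    def test_low_quality_placement_is_rejected(self):
        host, cand, ovls = _host_and_candidate(l_offset=700)
        worse = [Overlap(o.a_id, o.b_id, o.strand, o.a_start, o.a_end,
                         o.b_start, o.b_end, o.a_len, o.b_len, o.aln_len,
                         995_000, o.score, o.diffs) for o in ovls]
        layouts = identify_bubbles([host, cand], worse, Params())
        assert cand.cls == "draft"


def _repeat_genome(rng, flank, rep_len, divergence):
    from hifikit.sim import _mutate
    R = random_seq(rng, rep_len)
    R2 = R if divergence == 0 else _mutate(np.random.default_rng(17), R, divergence)[0]
    return (random_seq(rng, flank) + R + random_seq(rng, flank) + R2 +
            random_seq(rng, flank)), R, R2


class TestRepeatBreaking:
    def _assemble(self, genome, read_len=3000, seed=15):
        g = hk.SimGenome(haplotypes=[genome])
        reads = hk.simulate_reads(g, coverage=25, read_length_mean=read_len,
                                  error_model=hk.ERROR_FREE, seed=seed)
        cfg = hk.PipelineConfig()
        cfg.params.min_overlap_length = 300
        cfg.params.min_report_contig = 1000
        return hk.run_assemble({r.id: r.seq for r in reads}, cfg)

    @staticmethod
    def _residual(contig, genome):
        return min(edlib.align(contig, genome, mode="HW")["editDistance"],
                   edlib.align(hk.revcomp(contig), genome, mode="HW")["editDistance"])

    def test_unspanned_identical_repeat_is_broken_out(self, rng):
        genome, R, _ = _repeat_genome(rng, 6000, 6000, 0.0)
        res = self._assemble(genome)
        big = [c for c in res.contigs if len(c.seq) >= 1000]
        # the repeat cannot be traversed, so the assembly must be in pieces
        assert len(big) >= 4
        # no piece may retain a mis-join: each aligns to the genome with at
        # most boundary-read stubs of divergence (< 1 read), never a whole
        # skipped segment
        for c in big:
            assert self._residual(c.seq, genome) < 3000
        # and at least one broken-out piece is dominated by repeat sequence
        def repeat_content(c):
            ed = min(edlib.align(R, c.seq, mode="HW")["editDistance"],
                     edlib.align(R, hk.revcomp(c.seq), mode="HW")["editDistance"])
            return len(R) - ed
        assert any(repeat_content(c) >= 0.5 * len(c.seq) for c in big)

    def test_divergent_repeat_resolves_without_breaking(self, rng):
        genome, _, _ = _repeat_genome(rng, 6000, 6000, 0.01)
        res = self._assemble(genome)
        big = sorted((c for c in res.contigs if len(c.seq) >= 5000),
                     key=lambda c: -len(c.seq))
        assert len(big) == 1
        assert self._residual(big[0].seq, genome) == 0
        assert len(big[0].seq) > 0.95 * len(genome)

    def test_spanned_short_repeat_is_not_broken(self, rng):
        genome, _, _ = _repeat_genome(rng, 6000, 1500, 0.0)
        res = self._assemble(genome)
        big = [c for c in res.contigs if len(c.seq) >= 5000]
        assert len(big) == 1
        assert self._residual(big[0].seq, genome) == 0
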