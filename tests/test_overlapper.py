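"""Overlap detection, alignment records, trimming, PAF round trip."""

import numpy as np
import pytest

import hifikit as hk
from hifikit.hpc import Read, compress, revcomp
from hifikit.overlapper import find_overlaps, trim_reads
from hifikit.pafio import paf_to_overlap, overlap_to_paf
from hifikit.params import Params

from conftest import oracle_overlap_set, random_seq


def _hpc(seq):
    return compress(seq)[0]


def test_identical_reads_give_containment(small_params, rng):
    s = _hpc(random_seq(rng, 1500))
    ovls = find_overlaps({"x": s, "y": s}, small_params)
    assert {(o.a_id, o.b_id) for o in ovls} == {("x", "y"), ("y", "x")}
    o = ovls[0]
    assert o.strand == "+"
    assert o.a_contained and o.b_contained
    assert o.identity == 1.0
    assert o.score == len(s)
    assert o.diffs == ()


def test_one_substitution_identity_is_retained_at_the_floor(rng):
    """A shared 100-column stretch with one substitution scores 99/100 and
    is kept: the candidate identity threshold is inclusive."""
    p = Params(min_overlap_length=100, min_seed_count=1)
    shared = random_seq(rng, 230)
    shared = _hpc(shared)[:100]
    mut = shared[:50] + ("A" if shared[50] != "A" else "C") + shared[51:]
    a = _hpc(random_seq(rng, 700)) + shared
    b = mut + _hpc(random_seq(rng, 700))
    # guard against accidental compression at the junctions
    a, b = _hpc(a), _hpc(b)
    ovls = [o for o in find_overlaps({"a": a, "b": b}, p) if o.a_id == "a"]
    assert len(ovls) == 1
    o = ovls[0]
    assert len(o.diffs) == 1
    assert o.aln_len >= 100
    assert o.identity >= 0.99


def test_symmetry_and_strand_consistency(small_params, rng):
    """overlap(a,b) implies overlap(b,a) with mirrored spans and equal
    identity/score; reverse-complementing one read flips orientation only."""
    g = random_seq(rng, 6000)
    seqs = {"a": _hpc(g[:3500]), "b": _hpc(g[2500:])}
    ovls = find_overlaps(seqs, small_params)
    fwd = {(o.a_id, o.b_id): o for o in ovls}
    o, m = fwd[("a", "b")], fwd[("b", "a")]
    assert (m.a_start, m.a_end) == (o.b_start, o.b_end)
    assert (m.b_start, m.b_end) == (o.a_start, o.a_end)
    assert m.identity_ppm == o.identity_ppm and m.score == o.score
    assert m.mirror() == o

    flipped = {"a": seqs["a"], "b": revcomp(seqs["b"])}
    ovls2 = find_overlaps(flipped, small_params)
    o2 = {(x.a_id, x.b_id): x for x in ovls2}[("a", "b")]
    assert o2.strand == "-" and o.strand == "+"
    assert o2.identity_ppm == o.identity_ppm and o2.score == o.score
    assert (o2.a_start, o2.a_end) == (o.a_start, o.a_end)


def test_identity_resolution_distinguishes_one_diff_in_10kbp(rng):
    """Identity is stored at ppm resolution: one difference in 10,000
    columns must be distinguishable from a perfect overlap."""
    p = Params(min_overlap_length=500)
    base = _hpc(random_seq(rng, 16000))[:10600]
    mut = base[:5000] + ("A" if base[5000] != "A" else "C") + base[5001:]
    mut = _hpc(mut)
    ovls = {(o.a_id, o.b_id): o for o in find_overlaps(
        {"a": base, "b": mut, "c": base}, p)}
    perfect = ovls[("a", "c")]
    one_diff = ovls[("a", "b")]
    assert perfect.identity_ppm == 1_000_000
    assert one_diff.identity_ppm < perfect.identity_ppm
    assert one_diff.identity_ppm >= 999_800


@pytest.mark.parametrize("error_free", [True, False])
def test_oracle_equivalence_on_simulated_reads(error_free):
    """The seed-and-extend overlapper finds exactly the overlaps a
    brute-force all-pairs DP oracle finds on a small simulated instance."""
    g = hk.simulate_genome(30_000, seed=3, microsat_spec=None)
    em = hk.ERROR_FREE if error_free else hk.ErrorModel(chimera_rate=0.0)
    reads = hk.simulate_reads(g, coverage=1.8, read_length_mean=1500,
                              error_model=em, seed=4)[:36]
    seqs = {r.id: _hpc(r.seq) for r in reads}
    p = Params(min_overlap_length=300, min_seed_count=2)
    found = {(o.a_id, o.b_id, o.strand): o
             for o in find_overlaps(seqs, p) if o.a_id < o.b_id}
    expected = oracle_overlap_set(seqs, 300, p.min_candidate_identity)
    assert set(found) == set(expected)
    for key, exp in expected.items():
        o = found[key]
        assert abs(o.identity - exp["identity"]) <= 2e-5
        assert abs(o.score - exp["score"]) <= 3
        for got_span, exp_span in ((o.a_start, o.a_end), exp["a_span"]), \
                                  ((o.b_start, o.b_end), exp["b_span"]):
            assert abs(got_span[0] - exp_span[0]) <= 3
            assert abs(got_span[1] - exp_span[1]) <= 3


def test_paf_round_trip_is_bit_exact(small_params, rng):
    g = random_seq(rng, 9000)
    reads = {"a": g[:5000], "b": g[4000:]}
    mut = reads["b"]
    mut = mut[:300] + ("T" if mut[300] != "T" else "G") + mut[301:]
    seqs = {"a": _hpc(reads["a"]), "b": _hpc(mut), "c": _hpc(revcomp(g[2000:7000]))}
    ovls = find_overlaps(seqs, small_params)
    assert ovls, "fixture must produce overlaps"
    for o in ovls:
        line = overlap_to_paf(o)
        assert paf_to_overlap(line) == o
        assert overlap_to_paf(paf_to_overlap(line)) == line


class TestTrimming:
    def test_chimeric_read_trimmed_to_supported_prefix(self, rng):
        """A read joining two loci keeps only the part covered by >=2
        overlapping reads."""
        p = Params(min_overlap_length=200, min_seed_count=2)
        locus_a, locus_b = random_seq(rng, 4000), random_seq(rng, 8000)
        chimera = locus_a[500:2500] + locus_b[6000:7000]
        support = {f"s{i}": locus_a[i * 300 : i * 300 + 3000] for i in range(4)}
        reads = {rid: Read.from_raw(rid, s) for rid, s in
                 {"chim": chimera, **support}.items()}
        ovls = find_overlaps({rid: r.hpc_seq for rid, r in reads.items()}, p,
                             require_proper=False)
        trim_reads(reads, ovls, min_cov=2)
        chim = reads["chim"]
        junction = len(compress(locus_a[500:2500])[0])
        assert chim.trim[0] < 100
        assert abs(chim.trim[1] - junction) < 100

    def test_fully_covered_read_keeps_full_interval(self, rng):
        p = Params(min_overlap_length=200, min_seed_count=2)
        g = random_seq(rng, 3000)
        reads = {"m": Read.from_raw("m", g[1000:2000])}
        for i in range(10):
            rid = f"c{i}"
            reads[rid] = Read.from_raw(rid, g[500 + i * 50 : 2500 + i * 10])
        ovls = find_overlaps({rid: r.hpc_seq for rid, r in reads.items()}, p)
        trim_reads(reads, ovls, min_cov=2)
        assert reads["m"].trim == (0, len(reads["m"].hpc_seq))

    def test_read_without_overlaps_is_flagged(self, rng):
        p = Params(min_overlap_length=200)
        reads = {"solo": Read.from_raw("solo", random_seq(rng, 1500))}
        trim_reads(reads, [], min_cov=2)
        assert reads["solo"].trim == (0, len(reads["solo"].hpc_seq))
        assert "no_overlaps" in reads["solo"].flags
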