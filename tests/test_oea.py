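"""Pileup voting, correction calling, microsatellite masking, identity
recomputation."""

from collections import Counter

import numpy as np
import pytest

import hifikit as hk
from hifikit.oea import (PileupVotes, call_corrections, collect_votes,
                         collect_all_corrections, is_microsatellite_flanked,
                         recompute_identities)
from hifikit.overlapper import Diff, find_overlaps
from hifikit.params import PPM, Params

from conftest import random_seq


def _pileup_reads(rng, n_partners=10, errors=()):
    """One subject read plus exact-copy partners; ``errors`` plants
    (pos, kind, base) edits into the subject only."""
    core = random_seq(rng, 3000)
    core = hk.compress(core)[0]
    subject = core
    for pos, kind, base in sorted(errors, reverse=True):
        if kind == "sub":
            subject = subject[:pos] + base + subject[pos + 1:]
        elif kind == "del":
            subject = subject[:pos] + subject[pos + 1:]
        else:
            subject = subject[:pos] + base + subject[pos:]
    seqs = {"subj": subject}
    for i in range(n_partners):
        seqs[f"p{i:02d}"] = core
    return seqs, core


@pytest.fixture
def params():
    return Params(min_overlap_length=200)


class TestVotes:
    def test_identical_partners_support_everything(self, rng, params):
        seqs, _ = _pileup_reads(rng, n_partners=10)
        ovls = find_overlaps(seqs, params)
        votes = collect_votes("subj", seqs["subj"],
                              [o for o in ovls if o.a_id == "subj"])
        covered = votes.covered_positions()
        assert len(covered) == len(seqs["subj"])
        assert all(votes.coverage[p] == 10 for p in covered)
        assert votes.changes == {} and votes.ins_changes == {}

    def test_substitution_error_collects_partner_votes(self, rng, params):
        seqs, core = _pileup_reads(rng, n_partners=10,
                                   errors=[(1500, "sub", "N")])
        # plant a concrete disagreeing base
        true = core[1500]
        alt = next(b for b in "ACGT" if b != true and b not in
                   (core[1499], core[1501]))
        seqs["subj"] = core[:1500] + alt + core[1501:]
        ovls = find_overlaps(seqs, params)
        votes = collect_votes("subj", seqs["subj"],
                              [o for o in ovls if o.a_id == "subj"])
        assert votes.changes[1500] == Counter({true: 10})
        assert votes.support(1500) == 0

    def test_uncovered_positions_absent(self, rng, params):
        # partner shares only a suffix of the subject
        g = random_seq(rng, 6000)
        seqs = {"subj": hk.compress(g[:4000])[0],
                "p00": hk.compress(g[3000:])[0]}
        ovls = find_overlaps(seqs, params)
        votes = collect_votes("subj", seqs["subj"],
                              [o for o in ovls if o.a_id == "subj"])
        covered = votes.covered_positions()
        assert len(covered) < len(seqs["subj"])
        assert covered[0] > 0


class TestCorrectionRule:
    def _votes(self, length=10, coverage=10, changes=None, original="T"):
        cov = np.full(length, coverage, dtype=np.int32)
        jcov = np.full(length + 1, coverage, dtype=np.int32)
        v = PileupVotes("r", length, cov, jcov)
        for pos, counter in (changes or {}).items():
            v.changes[pos] = Counter(counter)
            v.change_count[pos] = sum(counter.values())
        return v

    def test_unanimous_change_with_no_original_support(self):
        v = self._votes(changes={5: {"C": 10}})
        out = call_corrections(v, "T" * 10, Params())
        assert [(c.pos, c.original, c.replacement) for c in out] == [(5, "T", "C")]

    def test_six_votes_with_original_support_is_not_enough(self):
        v = self._votes(coverage=7, changes={5: {"C": 6}})
        assert call_corrections(v, "T" * 10, Params()) == []

    def test_eight_of_ten_with_original_support_corrects(self):
        v = self._votes(coverage=10, changes={5: {"C": 8, "G": 1}})
        out = call_corrections(v, "T" * 10, Params())
        assert [(c.pos, c.replacement) for c in out] == [(5, "C")]

    def test_even_split_is_no_majority(self):
        v = self._votes(coverage=10, changes={5: {"C": 5}})
        assert call_corrections(v, "T" * 10, Params()) == []

    def test_strict_reading_requires_seven_even_without_support(self):
        v = self._votes(coverage=5, changes={5: {"C": 5}})
        assert len(call_corrections(v, "T" * 10, Params())) == 1
        strict = Params(vote_always_require_min=True)
        assert call_corrections(v, "T" * 10, strict) == []


class TestMicrosatelliteMasking:
    @staticmethod
    def _brute_force(seq_a, seq_b, diff, params=Params()):
        """Literal restatement of the flanking k-mer rule."""
        def flanks(seq, p_left, p_right):
            for k in range(params.mask_k_min, params.mask_k_max + 1):
                for off in range(k):
                    left_hi = p_left - off + 1
                    windows = []
                    if left_hi - 6 * k >= 0 and left_hi <= len(seq):
                        w = seq[left_hi - 6 * k : left_hi]
                        windows.append([w[i * k:(i + 1) * k] for i in range(6)])
                    lo = p_right + off
                    if lo + 6 * k <= len(seq):
                        w = seq[lo : lo + 6 * k]
                        windows.append([w[i * k:(i + 1) * k] for i in range(6)])
                    for kmers in windows:
                        if max(Counter(kmers).values()) >= 5:
                            return True
            return False

        if diff.kind == "sub":
            pa = (diff.a_pos - 1, diff.a_pos + 1)
            pb = (diff.b_pos - 1, diff.b_pos + 1)
        elif diff.kind == "del":
            pa = (diff.a_pos - 1, diff.a_pos + 1)
            pb = (diff.b_pos - 1, diff.b_pos)
        else:
            pa = (diff.a_pos - 1, diff.a_pos)
            pb = (diff.b_pos - 1, diff.b_pos + 1)
        return flanks(seq_a, *pa) or flanks(seq_b, *pb)

    def test_indel_inside_microsatellite_array_is_masked(self):
        arr = "AAAGG" * 60
        a = hk.compress(arr)[0]          # (AG) * 60
        pos = len(a) // 2
        b = a[:pos] + a[pos + 2:]        # one unit removed
        d1 = Diff(pos, pos, "del", a[pos], "-")
        assert is_microsatellite_flanked(a, b, d1)
        assert self._brute_force(a, b, d1)

    def test_substitution_in_unique_sequence_is_not_masked(self, rng):
        a = hk.compress(random_seq(rng, 200))[0]
        b = a[:60] + ("A" if a[60] != "A" else "C") + a[61:]
        d = Diff(60, 60, "sub", a[60], b[60])
        assert not is_microsatellite_flanked(a, b, d)
        assert not self._brute_force(a, b, d)

    def test_difference_near_read_end_skips_short_windows(self, rng):
        a = hk.compress(random_seq(rng, 40))[0][:10]
        b = a[:3] + ("A" if a[3] != "A" else "C") + a[4:]
        d = Diff(3, 3, "sub", a[3], b[3])
        assert not is_microsatellite_flanked(a, b, d)

    def test_agrees_with_brute_force_on_random_diffs(self, rng):
        mixed = (random_seq(rng, 150) + "ACACACACACACACAC" +
                 random_seq(rng, 80) + "AGGAGGAGGAGGAGGAGGAGG" +
                 random_seq(rng, 150))
        a = hk.compress(mixed)[0]
        for pos in range(8, len(a) - 8, 7):
            for kind in ("sub", "del", "ins"):
                d = Diff(pos, pos, kind,
                         "-" if kind == "ins" else a[pos],
                         "-" if kind == "del" else "T")
                assert (is_microsatellite_flanked(a, a, d)
                        == self._brute_force(a, a, d)), (pos, kind)


class TestRecompute:
    def test_fully_corrected_overlap_reaches_full_identity(self, rng, params):
        seqs, core = _pileup_reads(rng, n_partners=10)
        true1, true2 = core[800], core[2000]
        alt1 = next(b for b in "ACGT" if b not in (true1, core[799], core[801]))
        alt2 = next(b for b in "ACGT" if b not in (true2, core[1999], core[2001]))
        seqs["subj"] = (core[:800] + alt1 + core[801:2000] + alt2 + core[2001:])
        ovls = find_overlaps(seqs, params)
        corr = collect_all_corrections(seqs, ovls, params)
        assert len(corr["subj"]) == 2
        adj = recompute_identities(ovls, corr, seqs, params)
        subj = [o for o in adj if o.a_id == "subj"]
        assert subj and all(o.identity_ppm == PPM and not o.diffs for o in subj)

    def test_single_unresolved_sub_in_10kbp_gives_9999(self):
        # direct arithmetic on a synthetic overlap record
        from hifikit.overlapper import Overlap
        d = Diff(5000, 5000, "sub", "A", "C")
        o = Overlap("a", "b", "+", 0, 10_000, 0, 10_000, 10_000, 10_000,
                    10_000, 999_900, 9_999, (d,))
        seqs = {"a": "A" * 10_000, "b": "A" * 10_000}  # flank test: all-homopolymer
        adj = recompute_identities([o], {"a": [], "b": []}, seqs,
                                   Params(), masking=False)
        assert adj[0].identity_ppm == round((1 - 1 / 10_000) * PPM)

    def test_no_corrections_or_masks_leaves_identity_unchanged(self, rng, params):
        # two reads carry each allele: every pileup shows 2 change votes
        # against 1 original support, below the 7-vote requirement, so no
        # correction is called and identities stay put
        seqs, core = _pileup_reads(rng, n_partners=3)
        t = core[1200]
        alt = next(b for b in "ACGT" if b not in (t, core[1199], core[1201]))
        variant = core[:1200] + alt + core[1201:]
        seqs["subj"] = variant
        seqs["p02"] = variant
        ovls = find_overlaps(seqs, params)
        corr = collect_all_corrections(seqs, ovls, params)
        assert all(not c for c in corr.values())
        adj = recompute_identities(ovls, corr, seqs, params, masking=False)
        for before, after in zip(ovls, adj):
            assert after.identity_ppm == before.identity_ppm

    def test_recomputed_identity_is_monotone(self, rng):
        """Corrections and masks only remove differences."""
        p = Params(min_overlap_length=300)
        g = hk.simulate_genome(20_000, seed=7, microsat_spec=hk.MicrosatSpec(spacing=5_000))
        reads = hk.simulate_reads(g, coverage=12, read_length_mean=4_000, seed=8)
        seqs = {r.id: hk.compress(r.seq)[0] for r in reads}
        ovls = find_overlaps(seqs, p)
        corr = collect_all_corrections(seqs, ovls, p)
        adj = recompute_identities(ovls, corr, seqs, p)
        assert any(o.diffs for o in ovls)
        for before, after in zip(ovls, adj):
            assert after.identity_ppm >= before.identity_ppm
            assert after.score >= before.score


def test_corrections_match_column_majority_oracle(rng):
    """On a small exact pileup, the called corrections equal a per-column
    counting oracle that applies the same voting rule to the known MSA."""
    params = Params(min_overlap_length=200)
    seqs, core = _pileup_reads(rng, n_partners=15)
    true_sub = core[900]
    alt = next(b for b in "ACGT" if b not in (true_sub, core[899], core[901]))
    subject = core[:900] + alt + core[901:]
    del_pos = 1800
    subject = subject[:del_pos] + subject[del_pos + 1:]
    seqs["subj"] = subject
    ovls = find_overlaps(seqs, params)
    corr = collect_all_corrections(seqs, ovls, params)

    # oracle: positions are known exactly, votes are the 15 partner copies
    expected = []
    n = 15
    if n / n > 0.5:
        expected.append((900, "sub", true_sub))
        # insertion restores the deleted base at its canonical placement
        from hifikit.oea import canonical_ins
        j, s = canonical_ins(subject, del_pos, core[del_pos])
        expected.append((j, "ins", s))
    got = [(c.pos, c.kind, c.replacement) for c in corr["subj"]]
    assert sorted(got) == sorted(expected)
    for rid in seqs:
        if rid != "subj":
            assert corr[rid] == []
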