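"""Assembly evaluation: NG50, k-mer consensus QV, phase blocks, resolved
regions.

The consensus quality value follows the k-mer survey approach: with ``Kt``
total assembly k-mers and ``Ke`` of them absent from a trusted k-mer set,
the per-base error rate is ``E = 1 - (1 - Ke/Kt)**(1/k)`` and
``QV = -10*log10(E)``; a perfect assembly reports a configurable cap.  Here
the trusted set is built from the simulated haplotypes, standing in for the
short-read databases used with real genomes.

Phase blocks are maximal runs of haplotype-specific k-mer markers assigned
to one parent, tolerating isolated discordant markers; the switch rate is
the fraction of discordant markers within blocks.  A truth region counts as
"resolved" when at least 99.5% of its length aligns to a single contig in
one orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._kmers import canonical_kmer_set, kmer_codes
from .params import Params


def ng50(contig_lengths: list[int], genome_size: int) -> int:
    """Length of the contig at which the sorted-descending cumulative sum
    first reaches half the genome size; 0 if it never does."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    acc = 0
    for ln in sorted(contig_lengths, reverse=True):
        acc += ln
        if acc >= genome_size / 2:
            return ln
    return 0


def kmer_qv(assembly: str | list[str], truth_kmers: set[int], k: int = 21,
            cap: float = 60.0) -> float:
    """Phred-scaled consensus accuracy from assembly k-mers absent in truth.

    ``truth_kmers`` must hold canonical k-mer codes (see
    :func:`truth_kmer_set`).  Counts k-mer positions, not distinct k-mers.
    """
    seqs = [assembly] if isinstance(assembly, str) else list(assembly)
    kt = ke = 0
    for seq in seqs:
        if len(seq) < k:
            continue
        canon, _, valid = kmer_codes(seq, k)
        canon = canon[valid]
        kt += len(canon)
        if len(canon):
            uniq, cnt = np.unique(canon, return_counts=True)
            missing = np.array([int(u) not in truth_kmers for u in uniq.tolist()])
            ke += int(cnt[missing].sum()) if missing.any() else 0
    if kt == 0:
        raise ValueError("assembly shorter than k")
    if ke == 0:
        return cap
    err = 1 - (1 - ke / kt) ** (1 / k)
    return min(cap, -10 * math.log10(err))


def truth_kmer_set(haplotypes: list[str], k: int = 21) -> set[int]:
    out: set[int] = set()
    for h in haplotypes:
        out |= canonical_kmer_set(h, k)
    return out


def haplotype_marker_kmers(hap_a: str, hap_b: str, k: int = 21
                           ) -> tuple[set[int], set[int]]:
    """Haplotype-specific canonical k-mers (the symmetric difference)."""
    sa, sb = canonical_kmer_set(hap_a, k), canonical_kmer_set(hap_b, k)
    return sa - sb, sb - sa


@dataclass
class PhaseBlock:
    contig_id: str
    start: int
    end: int
    haplotype: str
    n_markers: int
    n_discordant: int


@dataclass
class PhaseBlockReport:
    blocks: list = field(default_factory=list)
    markers_per_contig: dict = field(default_factory=dict)

    @property
    def total_markers(self) -> int:
        return sum(b.n_markers for b in self.blocks)

    @property
    def discordant_markers(self) -> int:
        return sum(b.n_discordant for b in self.blocks)

    @property
    def switch_rate(self) -> float:
        t = self.total_markers
        return self.discordant_markers / t if t else 0.0

    def block_ng50(self, genome_size: int) -> int:
        return ng50([b.end - b.start for b in self.blocks], genome_size)


def phase_blocks(contigs: dict[str, str],
                 marker_sets: tuple[set[int], set[int]],
                 k: int = 21, tolerance: int = 1) -> PhaseBlockReport:
    """Locate haplotype markers on contigs and segment them into blocks.

    Runs of up to ``tolerance`` markers of the other haplotype flanked on
    both sides by the same haplotype are absorbed into the block and counted
    as discordant; longer (or unflanked) runs start a new block.
    """
    set_a, set_b = marker_sets
    if set_a & set_b:
        raise ValueError("marker sets must be disjoint")
    report = PhaseBlockReport()
    for cid in sorted(contigs):
        seq = contigs[cid]
        canon, _, valid = kmer_codes(seq, k)
        labels, positions = [], []
        for i in range(len(canon)):
            if not valid[i]:
                continue
            c = int(canon[i])
            if c in set_a:
                labels.append("A")
                positions.append(i)
            elif c in set_b:
                labels.append("B")
                positions.append(i)
        report.markers_per_contig[cid] = list(zip(positions, labels))
        report.blocks.extend(_segment_blocks(cid, positions, labels, tolerance))
    return report


def _segment_blocks(cid: str, positions: list[int], labels: list[str],
                    tolerance: int) -> list[PhaseBlock]:
    if not labels:
        return []
    runs = []  # (label, count, first_idx)
    for i, lab in enumerate(labels):
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1, i])
    blocks = []
    i = 0
    while i < len(runs):
        lab = runs[i][0]
        n = runs[i][1]
        first = runs[i][2]
        disc = 0
        j = i + 1
        while j + 1 < len(runs) and runs[j][1] <= tolerance and runs[j + 1][0] == lab:
            disc += runs[j][1]
            n += runs[j][1] + runs[j + 1][1]
            j += 2
        last_idx = first + n - 1
        blocks.append(PhaseBlock(cid, positions[first], positions[last_idx] + 1,
                                 lab, n, disc))
        i = j
    return blocks


# ---------------------------------------------------------------------------
# resolved-region criterion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionAlignment:
    """One alignment of part of a truth region to a contig."""
    region_start: int
    region_end: int
    contig_id: str
    strand: str


def resolved_check(region_length: int, alignments: list[RegionAlignment],
                   params: Params | None = None) -> bool:
    """True iff enough of the region aligns to one contig, one orientation."""
    params = params or Params()
    by_target: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for a in alignments:
        by_target.setdefault((a.contig_id, a.strand), []).append(
            (a.region_start, a.region_end))
    best = 0
    for ivs in by_target.values():
        ivs.sort()
        covered, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        best = max(best, covered)
    return best >= params.resolved_fraction * region_length


def align_region_to_contigs(region_seq: str, contigs: dict[str, str],
                            max_divergence: float = 0.02
                            ) -> list[RegionAlignment]:
    """Locate a truth region in an assembly (infix alignment per contig and
    strand), producing records for :func:`resolved_check`.

    A full-length hit is reported when the whole region aligns within
    ``max_divergence``; otherwise both halves are tried recursively, so a
    region split across contigs yields partial alignments.
    """
    from .hpc import revcomp

    out: list[RegionAlignment] = []

    def locate(seq: str, r0: int, r1: int, depth: int) -> None:
        budget = int(max_divergence * len(seq)) + 8
        best = None
        for cid in sorted(contigs):
            for strand, target in (("+", contigs[cid]), ("-", revcomp(contigs[cid]))):
                if len(target) == 0:
                    continue
                res = edlib.align(seq, target, mode="HW", k=budget)
                if res["editDistance"] < 0:
                    continue
                if best is None or res["editDistance"] < best[0]:
                    best = (res["editDistance"], cid, strand)
        if best is not None:
            out.append(RegionAlignment(r0, r1, best[1], best[2]))
            return
        if depth >= 4 or len(seq) < 2000:
            return
        mid = len(seq) // 2
        locate(seq[:mid], r0, r0 + mid, depth + 1)
        locate(seq[mid:], r0 + mid, r1, depth + 1)

    locate(region_seq, 0, len(region_seq), 0)
    return out
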