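# Methods

`hifikit` assembles high-fidelity (HiFi-class) long reads with an
overlap–layout–consensus pipeline that runs almost entirely in
homopolymer-compressed sequence space, and ships a matched read simulator
and evaluation suite so that every stage can be exercised on synthetic
data with exact ground truth.  This note records the model, the defaults,
the numerical choices, and what the synthetic data does and does not show.

## The error model the pipeline is built around

HiFi-class reads are circular-consensus reads with per-base accuracy above
99.9%.  Their residual errors are not uniform: the dominant mode is
miscounting the length of a homopolymer run, and a second, systematic mode
miscounts the number of repeat units in short microsatellite arrays, with
the same wrong count recurring across reads.  Ordinary substitutions are
rare.  The pipeline neutralises each mode at a different stage:

1. **Homopolymer compression** collapses every maximal single-nucleotide
   run to one base, hiding run-length errors entirely while preserving the
   base-transition structure that distinguishes loci.  Per-run lengths are
   stored in a coordinate map (`CoordMap`), so compression is losslessly
   invertible and intervals map in both directions; the assembler never
   mutates the original reads.
2. **Overlap error adjustment (OEA)** removes the remaining random errors
   virtually.  Every overlap partner votes at each compressed position it
   covers — for the original symbol where the alignment matches, otherwise
   for the partner's base, a deletion, or an insertion before the position.
   A position is corrected when no partner supports the original symbol and
   one change takes more than half of the votes, or, if something does
   support the original, when the winning change additionally has at least
   seven votes.  Only overlaps at or above 99.9% identity may vote: a
   partner from a diverged repeat copy or the other haplotype carries
   genuine variants as "differences" and, admitted at the 99% candidate
   floor, would erase them about half the time; same-locus overlaps stay
   above 99.9% even with several residual errors.  Corrections are stored
   per read and applied only when overlap difference lists are re-walked;
   stored sequences are untouched, so previously computed overlap
   coordinates stay valid and recomputed identities can only increase.
3. **Microsatellite masking** handles the systematic mode, which voting
   cannot fix (the wrong unit count is itself supported by several reads,
   so no change reaches a majority).  When identities are recomputed, a
   difference is ignored if, in either read, at least 5 of the 6
   consecutive non-overlapping flanking k-mers on one side are identical to
   each other, for any k in [2, 6] and any start offset in [0, k-1] from
   the difference; windows that run off the read are skipped.

After these three steps the best overlap of nearly every read is
difference-free, which is what makes the very aggressive overlap filtering
below safe.

### Canonical indel placement

A gap adjacent to equal bases has several co-optimal alignments, and
aligners place it differently depending on sequence context and strand.
Left unhandled, equivalent observations split the pileup vote (microsatellite
arrays are the worst case) and equivalent corrections fail to match their
differences.  Every indel event — in OEA voting, in correction matching,
and in the consensus realignment — is therefore normalised to its left-most
equivalent placement in the subject read's frame before it is counted.

## Contig construction

**Threshold.** Candidate overlaps require 99% identity and 500 compressed
bp (identities are carried as integer parts-per-million so one difference
in 10 kbp is representable).  After OEA, a two-step procedure sets the
working threshold: overlaps below a fixed floor of 99.97% ("three
differences in 10,000 bp") are dropped — this removes most cross-haplotype
overlaps even at human-like heterozygosity — and the final threshold is the
ascending nearest-rank 90th percentile of the identities of the
best-scoring surviving overlap off each read end (score = number of
matching bases).  On clean data this sample is dominated by perfect
overlaps and the selected threshold is 100%.

**Best overlap graph.** Each non-contained read keeps its best-scoring
surviving overlap off each end; score ties resolve toward higher identity,
then the lexicographically smaller partner.  Mutually-agreeing best edges
form non-branching paths (greedy contigs); contained reads are placed into
their best container's layout, so every read lands in exactly one layout,
and the result is independent of input order.

**Bubbles.** A smaller contig is an allelic *bubble* of a larger one when
both its first and last reads place into the same larger contig,
consistently oriented, spanning 75%–125% of the candidate's length, through
overlaps within 0.1% identity of the overlaps already incorporated in that
window.  Placement draws on the full 99%-candidate overlap set, not just
the threshold survivors — the 0.1% tolerance is only meaningful against a
set wider than a 100% threshold.  Bubble reads are excluded from repeat
detection; this is what keeps pseudohaplotype drafts from being shredded at
the boundaries between divergent and homozygous regions.

**Repeat breaking.** A draft region whose reads overlap reads outside the
contig (bubble reads ignored) is a suspected repeat; it is broken at its
boundaries unless a placed read spans it entirely and no alternate overlap
within 10% of the junction overlap's length competes there.  External
overlaps shorter than half the contig's median incorporated overlap are
not evidence — short perfect overlaps arise legitimately between the
identical stretches of diverged repeat copies or alleles.  A second
refinement: breakpoints are only placed deeper than the longest placed read
from either contig end.  Separately constructed contigs legitimately share
up to a read length of sequence at their boundaries — a best-edge chain
restart duplicates its seed read's extent, and allelic drafts share
homozygous anchors — and such end-proximal evidence indicates adjacency,
not a mis-traversed interior repeat.  Without this rule, diploid anchor
sharing re-created exactly the fragmentation that bubble flagging exists to
prevent.  Reads are assigned to break segments by midpoint, so broken
pieces can carry up to half a read of flanking sequence from each repeat
copy.

## Consensus

Layouts live in compressed space; contigs are reported uncompressed.  The
consensus is computed in two parts.  A compressed backbone (the splice of
the tiling path) is polished by realigning every placed read to its window
(banded edit distance, window pad 100 columns): per-column majority votes
decide each base (the backbone symbol wins ties), and indels are decided
per junction by hierarchical plurality — every junction-spanning read
contributes one net observation (insert a string, delete a run of columns,
or agree with the backbone), a read proposing two extra repeat units also
supports the first one, and the call extends while its cumulative support
beats every alternative observation group.  A plain majority rule fails
exactly where it matters: a miscounted repeat unit rarely commands more
than half the pileup, while the true count still holds a plurality.  The
vote is run twice, the second pass realigning all reads to the first-pass
consensus: a residual backbone mismatch inside a repeat array blocks the
left-shift normalisation and splits indel votes across junctions, and the
first pass removes it.  Each surviving column's homopolymer run length is
then the plain majority (ties toward shorter) of the uncompressed
run-length observations of the reads aligned to it, and the contig is the
expansion of the polished backbone under those lengths.
Reads that fail to align to their window at 99% identity are excluded with
a warning and may surface as short, low-coverage contigs, which the
reporting filter hides.  Contig tips covered by a single read are trimmed:
a 1× tip reproduces that read's private errors verbatim, and at
sub-megabase scale those few hundred bases would dominate the error budget.
Consensus is deterministic given the layout and reads.

Contigs shorter than 50 kbp are excluded from the primary output FASTA (a
secondary file keeps them); test profiles scale this filter down with
genome size.

## The simulator

`simulate_genome` builds haploid or diploid genomes with annotated
microsatellite arrays (one per 10 kbp by default, 30–60 units of motifs
such as AAAGG or AGAT), optional repeat families, and, for diploid
genomes, SNV heterozygosity.  Repeat copies diverge by an exact
substitution count matching the requested rate, placed stratified (one per
equal-width stratum, jittered) so the local divergence of every
read-length window stays near the request — repeat separation rests on
each overlap against the wrong copy containing several differences, a
property a uniform draw can violate by clumping.  Heterozygous sites are clustered by default: divergent
islands (about 30 kbp) separated by homozygous anchors (about 30 kbp,
longer than a read), covering half the genome, with the island-internal SNV
rate scaled so the requested genome-wide heterozygosity is preserved.  Real
diploid genomes show this structure, and it is the regime in which allelic
bubbles actually arise — with uniformly spread heterozygosity every read is
haplotype-informative and the assembly is simply two parallel haplotypes.
A uniform placement mode is available (`HetModel(clustered=False)`).

`simulate_reads` draws reads (default 15 kbp mean, 10% sd) to a requested
combined depth and injects, in order:

* **microsatellite unit-count errors** — with probability 0.4 per covering
  read, the unit count shifts, drawn around the array's own recurrent
  direction (62.5% one unit that way, 18.75% one unit opposite, 18.75% two
  units that way).  The dominant wrong count is therefore supported by
  multiple reads and no restoring change reaches a vote majority, while the
  true count keeps a per-pileup plurality so the consensus stays correct;
* **homopolymer run-length errors** — a run of length n gains or loses one
  base with probability `0.01 * min(n, 10) / 10`; length-1 runs only gain,
  so the injected error is always a run-length miscount and vanishes under
  compression;
* **substitutions** at 5e-5 per base;
* optional **chimeras** (off by default) joining two random loci.

Every read carries an exact error ledger; replaying it in reverse recovers
the true substring, which the tests verify.  All randomness derives from
the caller's seed.

What passing on this data does *not* show: instrument pass-number and
quality-value structure, coverage biases (the low-complexity dropout mode
is off by default), adapter contamination, and genome-scale repeat
landscapes are not modelled, so results here demonstrate the mechanics of
the method at desk scale, not performance on real genomes.

## Evaluation

* **NG50**: length of the contig at which the descending cumulative sum
  first reaches half the (haploid) genome size.
* **k-mer QV**: with `Kt` assembly k-mer positions and `Ke` of them absent
  from the trusted set (here: k-mers of the simulated haplotypes, k = 21),
  the error rate is `E = 1 − (1 − Ke/Kt)^(1/k)` and `QV = −10·log10(E)`,
  capped at 60 when `Ke = 0`.
* **Phase blocks**: haplotype-specific k-mers of the two truth haplotypes
  are located on contigs; blocks are maximal same-haplotype marker runs,
  absorbing isolated discordant runs up to length 1 (counted into the
  switch rate: discordant markers within blocks over all markers in
  blocks).
* **Resolved regions**: a truth region is resolved when at least 99.5% of
  its length aligns to a single contig in one orientation.

## Pipeline, determinism, and problem sizes

Stage order: compress → overlap → trim (largest interval covered by ≥2
overlapping reads, computed from budget-bounded partial overlaps so a
chimeric junction is visible) → re-overlap trimmed reads (records between
untouched reads are reused; trimming only shrinks reads) → OEA → threshold
→ best overlap graph → greedy contigs → bubbles → repeat breaking →
consensus.  Execution is single-process.  Stage outputs are checkpointed as
plain text (PAF with ppm-identity and difference-list tags, TSV, JSON);
every serialisation round-trips bit-exactly, and a run resumed from any
checkpoint reproduces the remaining outputs byte-for-byte.  All tie-breaks
are deterministic and reads are processed in sorted-id order, so results do
not depend on input order.

The test and validation suites run simulations between 20 kbp and 500 kbp
at 15–25× coverage — large enough for every mechanism (error hiding,
threshold selection, repeat separation at 99.9% identity, diploid
draft+bubble structure, QV50-level consensus) to be measurable in minutes
on one core.

## Known limitations

* Bubble placement fails for long alternate alleles whose end reads have
  no high-identity anchor in the larger contig; such alleles remain
  drafts, and primary/alternate partitioning of the output is left to
  downstream tools.
* Pieces produced by repeat breaking carry up to half a read of flanking
  sequence from each copy at their new ends.
* Microsatellite arrays where a wrong unit count reaches a local
  *plurality* of the sampled reads are reproduced wrongly in consensus
  (about 2–3% of arrays at 25× under the default error model); the
  masking stage protects overlap identities, not the consensus itself.
* The overlapper's seed subsampling (1/12 of 21-mers) makes missed true
  overlaps possible in principle; for overlaps at the 500-bp minimum the
  probability is negligible, and the oracle-equivalence tests check the
  result set exactly at small scale.
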