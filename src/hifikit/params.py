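"""Pipeline-wide parameters.

Every tunable constant of the assembler lives in :class:`Params` so that the
overlapper, the overlap-error-adjustment stage, contig construction, consensus
and evaluation all read from a single, serializable record.  The defaults are
the values the method was designed around: a 99% candidate overlap identity
floor, a 99.97% identity drop threshold ("three differences in 10,000 bp"),
a 90th-percentile final threshold, the ">50% and at least seven" voting rule,
5-of-6 flanking k-mer microsatellite masking for k in [2, 6], a 0.1% bubble
quality tolerance with a 75%-125% span window, a 50-kbp contig reporting
filter and a 99.5% resolved-region criterion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

PPM = 1_000_000


def ppm(fraction: float) -> int:
    """Convert an identity fraction to integer parts-per-million.

    Overlap identities are carried as integer ppm throughout the pipeline so
    that two overlaps differing by one difference in 10,000 bp (1e-4) remain
    distinguishable after storage.
    """
    return round(fraction * PPM)


@dataclass
class Params:
    # --- candidate overlap detection (homopolymer-compressed space) ---
    min_candidate_identity: float = 0.99
    #: minimum alignment length of a reported overlap, in compressed bp
    min_overlap_length: int = 500
    #: seed k-mer size in compressed space
    seed_k: int = 21
    #: fraction of k-mer positions retained as seeds (hash mod-sampling)
    seed_density: float = 1 / 12
    #: seeds occurring more often than this across all reads are ignored
    max_seed_occ: int = 100
    #: minimum shared seeds before a read pair is aligned
    min_seed_count: int = 3
    #: per-extension edit budget as a fraction of the extension length
    max_align_error: float = 0.05

    # --- overlap-based trimming ---
    trim_min_cov: int = 2

    # --- overlap error adjustment (pileup voting) ---
    vote_majority_fraction: float = 0.5
    vote_min_count: int = 7
    #: if True, require vote_min_count even when nothing supports the original
    vote_always_require_min: bool = False
    #: only overlaps at or above this identity may vote: partners from a
    #: diverged repeat copy or the other haplotype sit below it, while
    #: same-locus overlaps stay above it even with several residual errors
    vote_identity_floor: float = 0.999

    # --- microsatellite-flank masking ---
    mask_k_min: int = 2
    mask_k_max: int = 6
    mask_window_kmers: int = 6
    mask_kmers_required: int = 5

    # --- contig construction ---
    identity_floor: float = 0.9997
    percentile: float = 90.0
    #: an alternate overlap within this relative length of the junction
    #: overlap makes a spanned repeat suspect anyway
    repeat_alt_length_tol: float = 0.10
    #: an external overlap only counts as repeat evidence when its length
    #: reaches this fraction of the contig's median incorporated overlap --
    #: short perfect overlaps arise legitimately between the identical
    #: stretches of diverged repeat copies or alleles
    repeat_evidence_min_frac: float = 0.5
    bubble_quality_tol: float = 0.001
    bubble_span_low: float = 0.75
    bubble_span_high: float = 1.25

    # --- consensus ---
    consensus_min_identity: float = 0.99
    consensus_window_pad: int = 100

    # --- reporting and evaluation ---
    min_report_contig: int = 50_000
    resolved_fraction: float = 0.995
    qv_cap: float = 60.0
    eval_k: int = 21
    phase_block_tolerance: int = 1

    # --- read intake ---
    max_n_fraction: float = 0.05

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    @property
    def min_candidate_identity_ppm(self) -> int:
        return ppm(self.min_candidate_identity)

    @property
    def identity_floor_ppm(self) -> int:
        return ppm(self.identity_floor)
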