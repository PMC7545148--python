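"""Synthetic genomes and HiFi-like reads with exact ground truth.

The simulator emulates the error structure of circular-consensus long
reads so that every pipeline stage can be exercised without downloads:

* homopolymer run-length miscounts are the dominant error mode — a run of
  length ``n`` is reported as ``n±1`` with probability
  ``p0 * min(n, 10) / 10`` (runs of length 1 only ever gain a base, so the
  error is always invisible after homopolymer compression, as it is for a
  genuine run-length miscount);
* microsatellite arrays suffer *systematic* repeat-unit-count errors: each
  array is assigned one unit-shift direction, and every read covering it
  reproduces that same shift with a configured probability, so the error
  recurs across reads and survives majority voting;
* rare substitutions;
* optional chimeric reads joining two unrelated loci.

Genomes may be haploid or diploid with tunable heterozygosity (SNVs, by
default clustered into divergent islands separated by homozygous anchors
longer than a read, the pattern real diploid genomes show), repeat families
of tunable divergence, and microsatellite arrays.  All randomness derives
from an explicit seed; the injected-error ledger of every read is exact, so
replaying it in reverse recovers the true substring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hpc import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatSpec:
    """One repeat family: ``copies`` copies of length ``length`` whose
    pairwise divergence (substitution rate between copies) is ``divergence``."""
    copies: int = 2
    length: int = 30_000
    divergence: float = 0.001


@dataclass(frozen=True)
class MicrosatSpec:
    """Microsatellite content: one array per ``spacing`` bp on average, each
    ``units`` copies of a motif drawn from ``motifs``."""
    spacing: int = 10_000
    motifs: tuple = ("AAAGG", "AT", "AAC", "AGG", "AGAT", "AAGG")
    min_units: int = 30
    max_units: int = 60


@dataclass(frozen=True)
class HetModel:
    """Placement of heterozygous SNVs for diploid genomes.

    With ``clustered`` True, variants are confined to divergent islands
    covering ``island_fraction`` of the genome, separated by homozygous
    anchors of about ``anchor_length`` bp; the overall SNV density still
    matches the requested heterozygosity.
    """
    clustered: bool = True
    island_fraction: float = 0.5
    island_length: int = 30_000
    anchor_length: int = 30_000


@dataclass
class SimGenome:
    haplotypes: list
    variants: list = field(default_factory=list)      # (pos, ref, alt)
    repeats: list = field(default_factory=list)       # (family, [(s,e)], divergence)
    microsats: list = field(default_factory=list)     # (motif, s, e)
    islands: list = field(default_factory=list)       # (s, e) divergent islands
    run_length_histogram: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.haplotypes[0])

    def heterozygosity(self) -> float:
        return len(self.variants) / self.length if self.length else 0.0


@dataclass(frozen=True)
class ErrorModel:
    """Per-read error process; rates are per run / per array / per base."""
    hp_error_rate: float = 0.01
    hp_max_scale_len: int = 10
    substitution_rate: float = 5e-5
    #: probability that a read covering a microsatellite array miscounts its
    #: repeat units; the shift is drawn around the array's own recurrent
    #: direction (see microsat_direction_bias), so the same wrong count is
    #: supported by multiple reads and survives majority voting, while the
    #: true count keeps a per-pileup plurality
    microsat_error_prob: float = 0.4
    #: of the erroneous reads: this fraction shifts one unit in the array's
    #: systematic direction; half the remainder shifts one unit the other
    #: way and half two units in the systematic direction
    microsat_direction_bias: float = 0.625
    chimera_rate: float = 0.0


ERROR_FREE = ErrorModel(hp_error_rate=0.0, substitution_rate=0.0,
                        microsat_error_prob=0.0, chimera_rate=0.0)


@dataclass
class SimRead:
    id: str
    seq: str
    hap: int
    start: int
    end: int
    orient: str = "+"
    #: applied in order to the true substring; each entry is
    #: (etype, pos_in_sequence_at_application, removed, inserted)
    errors: list = field(default_factory=list)
    chimera: bool = False
    chimera_parts: list = field(default_factory=list)

    def true_substring(self, genome: SimGenome) -> str:
        s = genome.haplotypes[self.hap][self.start : self.end]
        return s if self.orient == "+" else revcomp(s)

    def replay_errors(self) -> str:
        """Invert the injected errors, recovering the true (oriented)
        substring exactly."""
        seq = self.seq
        for _, pos, removed, inserted in reversed(self.errors):
            assert seq[pos : pos + len(inserted)] == inserted
            seq = seq[:pos] + removed + seq[pos + len(inserted) :]
        return seq


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, list]:
    # an exact substitution count keeps the realised divergence within
    # rounding of the request, and stratified placement (one substitution
    # per equal-width stratum, jittered) keeps the local divergence of every
    # read-length window near the request — repeat separation rests on each
    # overlap against the wrong copy containing several differences, which
    # a uniform draw can violate by clumping
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n_mut = round(len(arr) * rate)
    bounds = np.linspace(0, len(arr), n_mut + 1).astype(np.int64)
    pos = np.array([int(rng.integers(bounds[i], max(bounds[i] + 1, bounds[i + 1])))
                    for i in range(n_mut)], dtype=np.int64)
    muts = []
    for p in pos:
        old = chr(arr[p])
        new = rng.choice([b for b in "ACGT" if b != old])
        arr[p] = ord(new)
        muts.append((int(p), old, str(new)))
    return arr.tobytes().decode("ascii"), muts


def simulate_genome(length: int, ploidy: int = 1, heterozygosity: float = 0.0,
                    repeat_spec: list | RepeatSpec | None = None,
                    microsat_spec: MicrosatSpec | None = None,
                    seed: int = 0,
                    het_model: HetModel | None = None) -> SimGenome:
    """Build a random genome with annotated repeats, microsatellite arrays
    and (for diploid genomes) heterozygous SNVs.  Deterministic per seed."""
    if length <= 0 or ploidy not in (1, 2):
        raise ValueError("length must be positive and ploidy 1 or 2")
    rng = np.random.default_rng(seed)
    base = _random_seq(rng, length)
    genome = SimGenome(haplotypes=[base])

    occupied: list[tuple[int, int]] = []

    def reserve(size: int, margin: int = 200) -> int | None:
        for _ in range(200):
            s = int(rng.integers(0, max(1, length - size)))
            if all(s + size + margin <= a or s >= b + margin for a, b in occupied):
                occupied.append((s, s + size))
                return s
        return None

    if microsat_spec is not None:
        n_arrays = max(0, length // microsat_spec.spacing)
        for _ in range(n_arrays):
            motif = str(rng.choice(microsat_spec.motifs))
            units = int(rng.integers(microsat_spec.min_units,
                                     microsat_spec.max_units + 1))
            arr = motif * units
            s = reserve(len(arr))
            if s is None:
                continue
            base = base[:s] + arr + base[s + len(arr):]
            genome.microsats.append((motif, s, s + len(arr)))

    if repeat_spec is not None:
        specs = [repeat_spec] if isinstance(repeat_spec, RepeatSpec) else list(repeat_spec)
        for fam, spec in enumerate(specs):
            if spec.copies * (spec.length + 400) > length:
                raise ValueError("repeat family does not fit in the genome")
            starts = []
            for _ in range(spec.copies):
                s = reserve(spec.length)
                if s is None:
                    raise ValueError("could not place repeat copies; genome too full")
                starts.append(s)
            template = base[starts[0] : starts[0] + spec.length]
            coords = [(starts[0], starts[0] + spec.length)]
            for s in starts[1:]:
                copy, _ = _mutate(rng, template, spec.divergence)
                base = base[:s] + copy + base[s + spec.length:]
                coords.append((s, s + spec.length))
            genome.repeats.append((fam, sorted(coords), spec.divergence))

    genome.haplotypes = [base]

    if ploidy == 2:
        het_model = het_model or HetModel()
        if het_model.clustered:
            islands = _draw_islands(rng, length, het_model)
            island_bp = sum(e - s for s, e in islands)
            local_rate = heterozygosity * length / island_bp if island_bp else 0.0
            genome.islands = islands
        else:
            islands = [(0, length)]
            local_rate = heterozygosity
            genome.islands = islands
        hap2 = np.frombuffer(base.encode("ascii"), dtype=np.uint8).copy()
        variants = []
        for s, e in islands:
            n_v = rng.binomial(e - s, min(1.0, local_rate))
            pos = np.sort(rng.choice(e - s, size=n_v, replace=False)) + s
            for p in pos:
                ref = chr(hap2[p])
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                hap2[p] = ord(alt)
                variants.append((int(p), ref, alt))
        genome.haplotypes.append(hap2.tobytes().decode("ascii"))
        genome.variants = variants

    lens = _run_lengths(genome.haplotypes[0])
    vals, cnt = np.unique(lens, return_counts=True)
    genome.run_length_histogram = dict(zip(vals.tolist(), cnt.tolist()))
    return genome


def _draw_islands(rng: np.random.Generator, length: int,
                  m: HetModel) -> list[tuple[int, int]]:
    islands = []
    pos = int(rng.integers(0, m.anchor_length))
    while pos < length:
        ilen = int(rng.normal(m.island_length, 0.2 * m.island_length))
        ilen = max(m.island_length // 2, ilen)
        end = min(length, pos + ilen)
        if end - pos > 1000:
            islands.append((pos, end))
        alen = int(rng.normal(m.anchor_length, 0.2 * m.anchor_length))
        pos = end + max(m.anchor_length // 2, alen)
    return islands


def _run_lengths(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if len(arr) == 0:
        return np.empty(0, dtype=np.int64)
    starts = np.flatnonzero(np.concatenate([[True], arr[1:] != arr[:-1]]))
    return np.diff(np.append(starts, len(arr)))


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(genome: SimGenome, coverage: float,
                   read_length_mean: int = 15_000,
                   error_model: ErrorModel | None = None,
                   seed: int = 0,
                   read_length_sd: float | None = None) -> list[SimRead]:
    """Sample reads to the requested depth and inject the error modes.

    ``coverage`` is combined depth over the genome locus (haplotypes of a
    diploid genome share it).  Reads are drawn until the sampled bases reach
    ``coverage * length``, keeping realised coverage within a read of the
    target.  Microsatellite unit-count errors are systematic: each array
    gets one shift direction for the whole run, applied per covering read
    with ``microsat_error_prob``.
    """
    em = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    L = genome.length
    sd = read_length_sd if read_length_sd is not None else 0.1 * read_length_mean
    array_shift = {i: int(rng.choice([-1, 1]))
                   for i in range(len(genome.microsats))}
    target = coverage * L
    reads: list[SimRead] = []
    total = 0
    i = 0
    while total < target:
        rid = f"read{i:06d}"
        i += 1
        rlen = int(np.clip(rng.normal(read_length_mean, sd),
                           0.3 * read_length_mean, max(1, L)))
        hap = int(rng.integers(0, len(genome.haplotypes)))
        orient = "+" if rng.random() < 0.5 else "-"
        if em.chimera_rate > 0 and rng.random() < em.chimera_rate:
            read = _make_chimera(rng, genome, rid, rlen)
        else:
            start = int(rng.integers(0, max(1, L - rlen + 1)))
            read = SimRead(rid, "", hap, start, min(L, start + rlen), orient)
            read.seq = read.true_substring(genome)
        _inject_errors(rng, genome, read, em, array_shift)
        total += len(read.seq)
        reads.append(read)
    return reads


def _make_chimera(rng, genome: SimGenome, rid: str, rlen: int) -> SimRead:
    L = genome.length
    l1 = rlen // 2
    parts = []
    seqs = []
    for plen in (l1, rlen - l1):
        hap = int(rng.integers(0, len(genome.haplotypes)))
        start = int(rng.integers(0, max(1, L - plen + 1)))
        orient = "+" if rng.random() < 0.5 else "-"
        s = genome.haplotypes[hap][start : start + plen]
        seqs.append(s if orient == "+" else revcomp(s))
        parts.append((hap, start, start + plen, orient))
    read = SimRead(rid, "".join(seqs), parts[0][0], parts[0][1], parts[0][2],
                   parts[0][3], chimera=True, chimera_parts=parts)
    return read


def _inject_errors(rng, genome: SimGenome, read: SimRead, em: ErrorModel,
                   array_shift: dict) -> None:
    """Apply the error model to ``read.seq`` in place, recording the ledger."""
    seq = read.seq
    errors = []

    # systematic microsatellite unit-count errors (skip chimeras' coordinate
    # bookkeeping by locating the array inside the read directly)
    if em.microsat_error_prob > 0 and not read.chimera:
        for idx, (motif, s, e) in enumerate(genome.microsats):
            if read.orient == "+":
                rs, re_ = s - read.start, e - read.start
            else:
                rs, re_ = read.end - e, read.end - s
            if rs < 0 or re_ > len(seq):
                continue
            if rng.random() >= em.microsat_error_prob:
                continue
            u = rng.random()
            bias = em.microsat_direction_bias
            if u < bias:
                shift = array_shift[idx]
            elif u < bias + (1 - bias) / 2:
                shift = -array_shift[idx]
            else:
                shift = 2 * array_shift[idx]
            m = motif if read.orient == "+" else revcomp(motif)
            unit = len(m)
            if shift > 0:
                pos = rs + unit
                ins = m * shift
                seq = seq[:pos] + ins + seq[pos:]
                errors.append(("microsat", pos, "", ins))
            else:
                ndel = -shift * unit
                if re_ - rs <= 2 * ndel:
                    continue
                pos = rs + unit
                removed = seq[pos : pos + ndel]
                seq = seq[:pos] + seq[pos + ndel :]
                errors.append(("microsat", pos, removed, ""))

    # homopolymer run-length errors
    if em.hp_error_rate > 0:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        starts = np.flatnonzero(np.concatenate([[True], arr[1:] != arr[:-1]]))
        lens = np.diff(np.append(starts, len(arr)))
        p = em.hp_error_rate * np.minimum(lens, em.hp_max_scale_len) / em.hp_max_scale_len
        hit = np.flatnonzero(rng.random(len(lens)) < p)
        offset = 0
        for h in hit:
            s = int(starts[h]) + offset
            n = int(lens[h])
            ch = seq[s]
            if n == 1 or rng.random() < 0.5:
                seq = seq[:s] + ch + seq[s:]
                errors.append(("homopolymer", s, "", ch))
                offset += 1
            else:
                seq = seq[:s] + seq[s + 1 :]
                errors.append(("homopolymer", s, ch, ""))
                offset -= 1

    # substitutions
    if em.substitution_rate > 0:
        n_sub = rng.binomial(len(seq), em.substitution_rate)
        pos = np.sort(rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False))
        for p in pos:
            old = seq[int(p)]
            if old not in "ACGT":
                continue
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            seq = seq[: int(p)] + new + seq[int(p) + 1 :]
            errors.append(("substitution", int(p), old, new))

    read.seq = seq
    read.errors = errors
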