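"""End-to-end assembly and evaluation orchestration.

Pipeline order: compress -> overlap -> trim -> re-overlap -> overlap error
adjustment (vote, correct, mask) -> identity threshold -> best overlap graph
-> greedy contigs -> bubble flagging -> repeat breaking -> uncompressed
consensus.  Stage outputs are checkpointed to the output directory in plain
text (PAF/TSV), and a run can resume from any checkpoint, reproducing the
remaining stages bit-exactly.  Contigs shorter than the reporting filter are
written to a secondary FASTA.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import consensus as cns
from . import evaluate as ev
from . import layout as lo
from . import oea, overlapper, pafio
from .hpc import Read, VALID_BASES
from .params import Params

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    params: Params = field(default_factory=Params)
    trim: bool = True
    mask: bool = True
    bubbles: bool = True
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = {"trim": self.trim, "mask": self.mask, "bubbles": self.bubbles,
             "seed": self.seed, "params": self.params.to_dict()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ValueError(f"malformed config file: {path}")
        params = Params.from_dict(d.pop("params", {}))
        known = {"trim", "mask", "bubbles", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(params=params, **d)


@dataclass
class AssemblyResult:
    reads: dict
    overlaps: list
    threshold: float
    layouts: list
    contigs: list

    def reported_contigs(self, min_len: int) -> list:
        return [c for c in self.contigs if len(c.seq) >= min_len]


def load_reads(source, params: Params) -> dict[str, Read]:
    """Read FASTA/FASTQ (or an id->sequence mapping) into compressed reads.

    Sequences with characters outside {A,C,G,T,N} or more than
    ``max_n_fraction`` N are rejected with a descriptive error.
    """
    seqs = pafio.read_fastx(source) if isinstance(source, (str, Path)) else dict(source)
    reads: dict[str, Read] = {}
    for rid in sorted(seqs):
        seq = seqs[rid].upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"read {rid}: invalid character(s) {sorted(bad)}")
        if seq and seq.count("N") / len(seq) > params.max_n_fraction:
            raise ValueError(f"read {rid}: more than "
                             f"{params.max_n_fraction:.0%} ambiguous bases")
        reads[rid] = Read.from_raw(rid, seq)
    return reads


def run_assemble(source, config: PipelineConfig | None = None,
                 outdir=None, resume: bool = False) -> AssemblyResult:
    """Assemble reads from a file path or an id->sequence mapping."""
    config = config or PipelineConfig()
    p = config.params
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for fname, fval in dataclasses.asdict(p).items():
        logger.info("param %s = %r", fname, fval)
    logger.info("stages: trim=%s mask=%s bubbles=%s", config.trim,
                config.mask, config.bubbles)

    def ckpt(name):
        return out / name if out is not None else None

    def have(name):
        f = ckpt(name)
        return resume and f is not None and f.exists()

    reads = load_reads(source, p)
    pre = None
    if not reads:
        logger.warning("no input reads; writing empty outputs")
        if out is not None:
            _write_outputs(out, [], [], p)
        return AssemblyResult(reads, [], p.identity_floor, [], [])

    # --- trimming (uses overlaps of the untrimmed compressed reads) ---
    if have("trim.tsv"):
        pafio.apply_trim_tsv(ckpt("trim.tsv"), reads)
    elif config.trim:
        full = {rid: r.hpc_seq for rid, r in reads.items()}
        logger.info("overlapping %d untrimmed reads", len(reads))
        pre = overlapper.find_overlaps(full, p, require_proper=False)
        overlapper.trim_reads(reads, pre, p.trim_min_cov)
        if out is not None:
            pafio.write_paf(ckpt("overlaps.untrimmed.paf"), pre)
    if out is not None and not have("trim.tsv"):
        pafio.write_trim_tsv(ckpt("trim.tsv"), reads)

    seqs = {rid: r.trimmed_hpc() for rid, r in reads.items()}

    # --- overlaps on trimmed reads ---
    if have("overlaps.paf"):
        ovls = pafio.read_paf(ckpt("overlaps.paf"))
    else:
        ovls = _trimmed_overlaps(reads, seqs, pre, p)
        if out is not None:
            pafio.write_paf(ckpt("overlaps.paf"), ovls)

    # --- overlap error adjustment ---
    if have("corrections.tsv"):
        corrections = pafio.read_corrections_tsv(ckpt("corrections.tsv"))
        corrections = {rid: corrections.get(rid, []) for rid in seqs}
    else:
        logger.info("voting on read pileups")
        corrections = oea.collect_all_corrections(seqs, ovls, p)
        if out is not None:
            pafio.write_corrections_tsv(ckpt("corrections.tsv"), corrections)
    if have("overlaps.adjusted.paf"):
        adjusted = pafio.read_paf(ckpt("overlaps.adjusted.paf"))
    else:
        adjusted = oea.recompute_identities(ovls, corrections, seqs, p,
                                            masking=config.mask)
        if out is not None:
            pafio.write_paf(ckpt("overlaps.adjusted.paf"), adjusted)

    # --- contig construction ---
    threshold = lo.select_identity_threshold(adjusted, p)
    logger.info("selected overlap identity threshold: %.4f%%", threshold * 100)
    if have("layouts.tsv"):
        layouts = pafio.read_layouts_tsv(ckpt("layouts.tsv"))
    else:
        graph = lo.build_best_overlap_graph(adjusted, threshold, p)
        layouts = lo.greedy_contigs(graph)
        if config.bubbles:
            layouts = lo.identify_bubbles(layouts, adjusted, p)
        layouts = lo.break_repeats(layouts, lo.filter_overlaps(adjusted, threshold), p)
        if out is not None:
            pafio.write_layouts_tsv(ckpt("layouts.tsv"), layouts)

    # --- consensus over uncompressed reads ---
    logger.info("computing consensus for %d layouts", len(layouts))
    contigs = [cns.compute_consensus(lay, reads, p) for lay in layouts]
    if out is not None:
        _write_outputs(out, contigs, layouts, p, threshold)
    return AssemblyResult(reads, adjusted, threshold, layouts, contigs)


def _trimmed_overlaps(reads, seqs, pre, p: Params):
    """Overlaps of the trimmed reads, reusing untrimmed-round records.

    Trimming only shrinks reads, so no new overlaps can appear; records
    between two untouched reads are identical in both rounds and only pairs
    involving a trimmed read need realignment.
    """
    if pre is None:
        logger.info("overlapping %d trimmed reads", len(reads))
        return overlapper.find_overlaps(seqs, p)
    changed = {rid for rid, r in reads.items() if r.trim != (0, len(r.hpc_seq))}
    if not changed:
        return sorted((o for o in pre if o.is_proper),
                      key=overlapper._overlap_sort_key)
    logger.info("re-overlapping %d trimmed reads and their partners",
                len(changed))
    partners = set(changed)
    for o in pre:
        if o.a_id in changed:
            partners.add(o.b_id)
    sub = {rid: seqs[rid] for rid in partners}
    recomputed = [o for o in overlapper.find_overlaps(sub, p)
                  if o.a_id in changed or o.b_id in changed]
    kept = [o for o in pre if o.is_proper
            and o.a_id not in changed and o.b_id not in changed]
    return sorted(kept + recomputed, key=overlapper._overlap_sort_key)


def _write_outputs(out: Path, contigs, layouts, p: Params,
                   threshold: float | None = None) -> None:
    primary = {c.contig_id: c.seq for c in contigs if len(c.seq) >= p.min_report_contig}
    short = {c.contig_id: c.seq for c in contigs if len(c.seq) < p.min_report_contig}
    pafio.write_fasta(out / "contigs.fasta", primary)
    pafio.write_fasta(out / "contigs.short.fasta", short)
    pafio.write_gfa(out / "assembly.gfa", contigs, layouts)
    bed = []
    for c in contigs:
        for rid, orient, (s, e) in c.placements:
            bed.append((c.contig_id, s, e, rid, 0, orient))
    pafio.write_bed(out / "placements.bed", bed)
    stats = {
        "n_contigs": len(contigs),
        "n_reported": len(primary),
        "threshold_pct": None if threshold is None else round(threshold * 100, 4),
        "contigs": {c.contig_id: {"length": len(c.seq), "class": c.cls}
                    for c in contigs},
    }
    (out / "report.json").write_text(json.dumps(stats, indent=2, sort_keys=True))


def run_evaluate(contigs_source, haplotypes_source, outdir=None,
                 params: Params | None = None, regions=None) -> dict:
    """NG50, k-mer QV, phase blocks and resolved-region reports.

    ``regions`` is an optional list of (name, sequence) truth regions to
    test with the resolved criterion.
    """
    p = params or Params()
    contigs = (pafio.read_fastx(contigs_source)
               if isinstance(contigs_source, (str, Path)) else dict(contigs_source))
    haps = (pafio.read_fastx(haplotypes_source)
            if isinstance(haplotypes_source, (str, Path)) else dict(haplotypes_source))
    hap_seqs = [haps[k] for k in sorted(haps)]
    if not hap_seqs:
        raise ValueError("no truth haplotypes provided")
    genome_size = len(hap_seqs[0])
    lengths = [len(s) for s in contigs.values()]
    metrics = {"ng50": ev.ng50(lengths, genome_size) if lengths else 0,
               "n_contigs": len(contigs),
               "total_length": sum(lengths)}
    if lengths:
        truth = ev.truth_kmer_set(hap_seqs, p.eval_k)
        metrics["qv"] = round(ev.kmer_qv(list(contigs.values()), truth,
                                         p.eval_k, p.qv_cap), 2)
    report = None
    if len(hap_seqs) == 2 and lengths:
        markers = ev.haplotype_marker_kmers(hap_seqs[0], hap_seqs[1], p.eval_k)
        report = ev.phase_blocks(contigs, markers, p.eval_k,
                                 p.phase_block_tolerance)
        metrics["switch_rate"] = round(report.switch_rate, 6)
        metrics["block_ng50"] = report.block_ng50(genome_size)
    resolved_rows = []
    for name, seq in (regions or []):
        alns = ev.align_region_to_contigs(seq, contigs)
        resolved_rows.append((name, len(seq),
                              resolved := ev.resolved_check(len(seq), alns, p)))
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "metrics.tsv", "w") as fh:
            for k in sorted(metrics):
                fh.write(f"{k}\t{metrics[k]}\n")
        if report is not None:
            with open(out / "phase_blocks.tsv", "w") as fh:
                fh.write("contig\tstart\tend\thaplotype\tmarkers\tdiscordant\n")
                for b in report.blocks:
                    fh.write(f"{b.contig_id}\t{b.start}\t{b.end}\t{b.haplotype}"
                             f"\t{b.n_markers}\t{b.n_discordant}\n")
        if resolved_rows:
            with open(out / "resolved.tsv", "w") as fh:
                fh.write("region\tlength\tresolved\n")
                for name, ln, ok in resolved_rows:
                    fh.write(f"{name}\t{ln}\t{ok}\n")
    return {"metrics": metrics, "phase_blocks": report, "resolved": resolved_rows}
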