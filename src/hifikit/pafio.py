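"""On-disk formats: PAF overlaps, GFA, layout/correction TSVs, FASTA/FASTQ.

Overlaps round-trip through PAF bit-exactly: the standard 12 columns carry
spans, strand, matching bases (score) and alignment length, and custom tags
carry the ppm identity (``ii:i``) and the encoded difference list (``dv:Z``).
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .layout import ContigLayout, Placement
from .oea import Correction
from .overlapper import Diff, Overlap


def overlap_to_paf(o: Overlap) -> str:
    cols = [o.a_id, o.a_len, o.a_start, o.a_end, o.strand,
            o.b_id, o.b_len, o.b_start, o.b_end, o.score, o.aln_len, 255,
            f"ii:i:{o.identity_ppm}"]
    if o.diffs:
        enc = ",".join(f"{d.a_pos}:{d.b_pos}:{d.kind}:{d.a_sym}:{d.o_sym}"
                       for d in o.diffs)
        cols.append(f"dv:Z:{enc}")
    return "\t".join(str(c) for c in cols)


def paf_to_overlap(line: str) -> Overlap:
    f = line.rstrip("\n").split("\t")
    tags = dict((t[:4], t[5:]) for t in f[12:])
    diffs = []
    if "dv:Z" in tags and tags["dv:Z"]:
        for item in tags["dv:Z"].split(","):
            ap, bp, kind, asym, osym = item.split(":")
            diffs.append(Diff(int(ap), int(bp), kind, asym, osym))
    return Overlap(f[0], f[5], f[4], int(f[2]), int(f[3]), int(f[7]), int(f[8]),
                   int(f[1]), int(f[6]), int(f[10]), int(tags["ii:i"]),
                   int(f[9]), tuple(diffs))


def write_paf(path, overlaps: list[Overlap]) -> None:
    with open(path, "w") as fh:
        for o in overlaps:
            fh.write(overlap_to_paf(o) + "\n")


def read_paf(path) -> list[Overlap]:
    with open(path) as fh:
        return [paf_to_overlap(line) for line in fh if line.strip()]


def write_corrections_tsv(path, corrections: dict[str, list[Correction]]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tpos\tkind\tfrom\tto\n")
        for rid in sorted(corrections):
            for c in corrections[rid]:
                fh.write(f"{rid}\t{c.pos}\t{c.kind}\t{c.original}\t{c.replacement}\n")


def read_corrections_tsv(path) -> dict[str, list[Correction]]:
    out: dict[str, list[Correction]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, pos, kind, orig, rep = (line.rstrip("\n").split("\t") + [""])[:5]
            out.setdefault(rid, []).append(Correction(rid, int(pos), kind, orig, rep))
    return out


def write_layouts_tsv(path, layouts: list[ContigLayout]) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tread\toffset\torient\tlength\tclass\n")
        for lay in layouts:
            for p in lay.placements:
                fh.write(f"{lay.id}\t{p.read_id}\t{p.offset}\t{p.orient}"
                         f"\t{p.length}\t{lay.cls}\n")


def read_layouts_tsv(path) -> list[ContigLayout]:
    by_id: dict[str, ContigLayout] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            cid, rid, off, orient, length, cls = line.rstrip("\n").split("\t")
            lay = by_id.setdefault(cid, ContigLayout(cid, [], cls=cls))
            lay.cls = cls
            lay.placements.append(Placement(rid, int(off), orient, int(length)))
    return [by_id[k] for k in sorted(by_id)]


def write_trim_tsv(path, reads) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrim_start\ttrim_end\tflags\n")
        for rid in sorted(reads):
            r = reads[rid]
            fh.write(f"{rid}\t{r.trim[0]}\t{r.trim[1]}\t"
                     f"{','.join(sorted(r.flags))}\n")


def apply_trim_tsv(path, reads) -> None:
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, s, e, flags = (line.rstrip("\n").split("\t") + [""])[:4]
            if rid in reads:
                reads[rid].trim = (int(s), int(e))
                reads[rid].flags = set(f for f in flags.split(",") if f)


def write_gfa(path, contigs, layouts: list[ContigLayout]) -> None:
    """GFA 1.0: one segment per contig; links attach bubbles to their host."""
    hosts = {lay.id: lay.host for lay in layouts if lay.host}
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for c in contigs:
            fh.write(f"S\t{c.contig_id}\t{c.seq or '*'}\tLN:i:{len(c.seq)}\n")
        for cid, (host_id, h0, h1) in sorted(hosts.items()):
            fh.write(f"L\t{cid}\t+\t{host_id}\t+\t0M\tbp:i:{h0}\tbe:i:{h1}\n")


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, max(1, len(seq)), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastx(path) -> dict[str, str]:
    """FASTA or FASTQ by extension (Biopython parser)."""
    p = Path(path)
    suffix = p.suffix.lower()
    fmt = "fastq" if suffix in (".fastq", ".fq") else "fasta"
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(p), fmt)}


def write_bed(path, rows) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
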