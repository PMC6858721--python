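"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, GFF3 ingestion through gffutils (in-memory db);
BED12 (exon chains, blockStarts relative to chromStart), the junction-support
BED and the per-read PID sidecar TSV are simple line formats written directly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AlignedRead,
    Annotation,
    Exon,
    GenomeSequence,
    Intron,
    Segment,
    Transcript,
)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Parse a (multi-record) FASTA into GenomeSequence objects, order preserved."""
    out: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: empty sequence for record {rec.id!r}")
        out[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(genome: Mapping[str, GenomeSequence], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.chrom_id, description="")
        for g in genome.values()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> Annotation:
    """Load gene/mRNA/exon(/CDS) features; 1-based inclusive -> 0-based half-open."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: dict[str, Transcript] = {}
    gene_of: dict[str, str] = {}
    cds_span: dict[str, tuple[int, int]] = {}
    extra: dict[str, dict[str, str]] = {}
    for mrna in db.features_of_type(("mRNA", "transcript"), order_by="start"):
        parents = list(db.parents(mrna, featuretype="gene"))
        if not parents:
            raise ValueError(f"{path}: mRNA {mrna.id} has no parent gene")
        exons = []
        for ex in db.children(mrna, featuretype="exon", order_by="start"):
            if ex.start > ex.end:
                raise ValueError(f"{path}: exon of {mrna.id} has start > end")
            exons.append(Exon(ex.start - 1, ex.end))
        if not exons:
            raise ValueError(f"{path}: mRNA {mrna.id} has no exons")
        cds = [(c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")]
        tid = mrna.id
        transcripts[tid] = Transcript(tid, mrna.seqid, mrna.strand, tuple(exons))
        gene_of[tid] = parents[0].id
        if cds:
            cds_span[tid] = (min(s for s, _ in cds), max(e for _, e in cds))
        attrs = {
            k: v[0]
            for k, v in mrna.attributes.items()
            if k not in ("ID", "Parent") and v
        }
        if attrs:
            extra[tid] = attrs
    # orphan exon check: every exon must descend from an mRNA/transcript
    for ex in db.features_of_type("exon"):
        if not list(db.parents(ex, featuretype=("mRNA", "transcript"))):
            raise ValueError(f"{path}: exon {ex.id} has no parent mRNA")
    ann = Annotation(transcripts, gene_of, cds_span)
    ann.attributes = extra  # type: ignore[attr-defined]
    return ann


def _fmt_attrs(attrs: Mapping[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(
    annotation: Annotation,
    path: str | Path,
    attributes: Mapping[str, Mapping[str, str]] | None = None,
    source: str = "flanno",
) -> None:
    """Emit gene/mRNA/exon(/CDS) features; extra per-transcript attributes allowed."""
    attributes = attributes or {}
    genes = annotation.genes()
    lines = ["##gff-version 3"]
    for gid in sorted(genes, key=lambda g: (genes[g][0].chrom, min(t.start for t in genes[g]), g)):
        ts = sorted(genes[gid], key=lambda t: (t.start, t.id))
        chrom, strand = ts[0].chrom, ts[0].strand
        gstart = min(t.start for t in ts)
        gend = max(t.end for t in ts)
        lines.append(
            f"{chrom}\t{source}\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\tID={gid}"
        )
        for t in ts:
            attrs = {"ID": t.id, "Parent": gid}
            attrs.update(attributes.get(t.id, {}))
            lines.append(
                f"{chrom}\t{source}\tmRNA\t{t.start + 1}\t{t.end}\t.\t{strand}\t.\t"
                + _fmt_attrs(attrs)
            )
            for i, e in enumerate(t.exons, 1):
                lines.append(
                    f"{chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t"
                    f"ID={t.id}.exon{i};Parent={t.id}"
                )
            if t.id in annotation.cds_span:
                cs, ce = annotation.cds_span[t.id]
                for i, e in enumerate(t.exons, 1):
                    lo, hi = max(e.start, cs), min(e.end, ce)
                    if lo < hi:
                        lines.append(
                            f"{chrom}\t{source}\tCDS\t{lo + 1}\t{hi}\t.\t{strand}\t0\t"
                            f"ID={t.id}.cds{i};Parent={t.id}"
                        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED12 exon chains + PID sidecar


def _bed12_line(name: str, chrom: str, strand: str, exons: Sequence[Exon]) -> str:
    start = exons[0].start
    end = exons[-1].end
    sizes = ",".join(str(e.length) for e in exons) + ","
    starts = ",".join(str(e.start - start) for e in exons) + ","
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{start}\t{end}\t0,0,0\t"
        f"{len(exons)}\t{sizes}\t{starts}"
    )


def write_alignments_bed12(
    reads: Iterable[AlignedRead], bed_path: str | Path, pid_path: str | Path
) -> None:
    """One BED12 line per aligned segment (name = read_id|segN for chimeras) plus a
    sidecar TSV carrying per-read global PID and per-segment local PID/read span."""
    bed_lines = []
    pid_rows = []
    for read in reads:
        multi = read.is_chimeric
        for i, seg in enumerate(read.segments, 1):
            name = f"{read.read_id}|seg{i}" if multi else read.read_id
            bed_lines.append(_bed12_line(name, seg.chrom, seg.strand, seg.exons))
            pid_rows.append(
                (
                    read.read_id,
                    i,
                    len(read.segments),
                    f"{read.global_pid:.3f}",
                    f"{seg.local_pid:.3f}",
                    "" if seg.read_start is None else seg.read_start,
                    "" if seg.read_end is None else seg.read_end,
                )
            )
    Path(bed_path).write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    with open(pid_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["read_id", "segment", "n_segments", "global_pid", "local_pid", "read_start", "read_end"]
        )
        w.writerows(pid_rows)


def _parse_bed12_row(fields: list[str]) -> tuple[str, str, str, tuple[Exon, ...]]:
    chrom, start, _end, name, _score, strand = fields[:6]
    start = int(start)
    n = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n or len(offsets) != n:
        raise ValueError(f"BED12 block count mismatch for {name}")
    exons = tuple(Exon(start + o, start + o + s) for o, s in zip(offsets, sizes))
    return name, chrom, strand, exons


def read_alignments_bed12(
    bed_path: str | Path, pid_path: str | Path | None = None
) -> list[AlignedRead]:
    """Rebuild AlignedReads from BED12 (+ optional PID sidecar; defaults 100%)."""
    pid: dict[tuple[str, int], dict] = {}
    if pid_path is not None:
        with open(pid_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                pid[(row["read_id"], int(row["segment"]))] = row
    segments: dict[str, list[tuple[int, Segment]]] = {}
    gpid: dict[str, float] = {}
    order: list[str] = []
    for line in Path(bed_path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        name, chrom, strand, exons = _parse_bed12_row(line.split("\t"))
        read_id, _, seg = name.partition("|seg")
        idx = int(seg) if seg else 1
        row = pid.get((read_id, idx))
        local = float(row["local_pid"]) if row else 100.0
        rs = int(row["read_start"]) if row and row["read_start"] != "" else None
        re_ = int(row["read_end"]) if row and row["read_end"] != "" else None
        if read_id not in segments:
            order.append(read_id)
        segments.setdefault(read_id, []).append(
            (idx, Segment(chrom, strand, exons, local, rs, re_))
        )
        if row:
            gpid[read_id] = float(row["global_pid"])
    return [
        AlignedRead(
            rid,
            tuple(s for _, s in sorted(segments[rid])),
            gpid.get(rid, 100.0),
        )
        for rid in order
    ]


# ---------------------------------------------------------------------------
# junction-support BED (BED6; score column = short-read support count)


def write_junction_bed(
    junctions: Mapping[Intron, int] | Iterable[Intron], path: str | Path
) -> None:
    if not isinstance(junctions, Mapping):
        junctions = {j: 1 for j in junctions}
    lines = [
        f"{j.chrom}\t{j.start}\t{j.end}\tSJ\t{count}\t{j.strand}"
        for j, count in sorted(junctions.items())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_junction_bed(path: str | Path) -> dict[Intron, int]:
    out: dict[Intron, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        out[Intron(f[0], f[5], int(f[1]), int(f[2]))] = int(f[4])
    return out
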