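"""End-to-end orchestration: filter -> classify -> fusion -> splice -> polya ->
merge/report, with a flat key=value config file and a JSON run manifest.

Re-running with an identical config reproduces byte-identical outputs (no
timestamps or absolute-path dependencies enter any output file).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, fields
from pathlib import Path
from typing import Any

from . import __version__
from . import io as fio
from .core import Annotation, introns_of
from .filtering import JunctionSupportIndex, group_identical_structures, retained_with_groups
from .fusion import call_fusions, fusion_type_counts
from .library import merge_library
from .loci import build_loci, partition_counts
from .polya import call_apa, call_polya_sites
from .splicing import (
    as_gene_counts,
    as_type_percentages,
    detect_as_events,
    exon_count_by_as_status,
    sj_context,
    splice_site_census,
)


@dataclass
class PipelineConfig:
    """Paths and stage thresholds; unknown keys in a config file are rejected."""

    genome: str
    annotation: str
    alignments: str
    junctions: str
    outdir: str
    pid_table: str | None = None
    seed: int = 0
    min_reads: int = 2
    min_pid: float = 99.0
    min_frac: float = 0.20
    counting_mode: str = "disjoint"
    fuzz: int = 10
    max_locus_overlap: int = 10
    min_distance: int = 50_000
    min_global_pid: float = 10.0
    min_local_pid: float = 90.0
    min_support_reads: int = 2
    cluster_radius: int = 24
    min_polya_support: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_frac < 1.0:
            raise ValueError("min_frac must be in [0, 1)")
        for name in ("min_reads", "fuzz", "max_locus_overlap", "min_distance",
                     "min_support_reads", "cluster_radius", "min_polya_support"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.counting_mode not in ("disjoint", "overlapping"):
            raise ValueError(f"unknown counting_mode {self.counting_mode!r}")
        for name in ("genome", "annotation", "alignments", "junctions"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs: dict[str, Any] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not sep or key not in known:
                raise ValueError(f"{path}:{lineno}: unknown or malformed key {key!r}")
            typ = known[key].type
            if "int" in str(typ):
                kwargs[key] = int(value)
            elif "float" in str(typ):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every stage in order and return (and write) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": asdict(cfg),
        "stages": {},
        "outputs": {},
    }

    genome = fio.read_fasta(cfg.genome)
    annotation = fio.read_gff3(cfg.annotation)
    reads = fio.read_alignments_bed12(cfg.alignments, cfg.pid_table)
    junction_counts = fio.read_junction_bed(cfg.junctions)
    junctions = JunctionSupportIndex.from_counts(junction_counts)
    manifest["stages"]["input"] = {
        "n_reads": len(reads),
        "n_annotation_transcripts": len(annotation),
        "n_junctions": len(junction_counts),
    }

    # --- filter -----------------------------------------------------------
    linear = [r for r in reads if not r.is_chimeric]
    chimeric = [r for r in reads if r.is_chimeric]
    groups = group_identical_structures(linear)
    kept = retained_with_groups(
        groups, junctions, annotation, cfg.min_reads, cfg.min_pid
    )
    isoforms = [t for t, _ in kept]
    retained_path = outdir / "retained.gff3"
    _write_transcripts(isoforms, retained_path)
    manifest["stages"]["filter"] = {
        "n_linear_reads": len(linear),
        "n_chimeric_reads": len(chimeric),
        "n_groups": len(groups),
        "n_retained": len(isoforms),
    }
    manifest["outputs"]["retained"] = retained_path.name

    # --- classify ---------------------------------------------------------
    loci, warnings = build_loci(isoforms, annotation, cfg.min_frac)
    report = partition_counts(loci, cfg.counting_mode)
    loci_path = outdir / "loci.gff3"
    _write_loci(loci, loci_path)
    table1_path = outdir / "table1.tsv"
    _write_table1(report, table1_path)
    manifest["stages"]["classify"] = {
        "partition": {k: list(v) for k, v in report.as_dict().items()},
        "counting_mode": report.counting_mode,
        "warnings": warnings,
    }
    manifest["outputs"]["loci"] = loci_path.name
    manifest["outputs"]["table1"] = table1_path.name

    # --- fusion -----------------------------------------------------------
    calls = call_fusions(
        chimeric,
        annotation,
        junctions,
        cfg.max_locus_overlap,
        cfg.min_distance,
        cfg.min_global_pid,
        cfg.min_local_pid,
        cfg.min_support_reads,
    )
    fusion_path = outdir / "fusions.tsv"
    _write_fusions(calls, fusion_path)
    manifest["stages"]["fusion"] = fusion_type_counts(calls)
    manifest["outputs"]["fusions"] = fusion_path.name

    # --- splice -----------------------------------------------------------
    events_by_locus = {
        locus.locus_id: detect_as_events(locus, cfg.fuzz)
        for locus in loci
        if len(locus.transcripts()) > 1
    }
    all_events = [ev for evs in events_by_locus.values() for ev in evs]
    census = splice_site_census(
        [t for t, _ in kept] + list(annotation.transcripts.values()), genome
    )
    discovered_junctions = sorted(
        {j for t in isoforms for j in introns_of(t)}
    )
    context = sj_context(discovered_junctions, annotation)
    exon_counts = exon_count_by_as_status(loci, cfg.fuzz)
    events_path = outdir / "events.tsv"
    _write_events(all_events, events_path)
    census_path = outdir / "census.tsv"
    _write_kv(census.counts, census_path)
    context_path = outdir / "context.tsv"
    _write_kv(context.counts, context_path)
    manifest["stages"]["splice"] = {
        "n_events": len(all_events),
        "type_percentages": as_type_percentages(all_events),
        "gene_counts": as_gene_counts(events_by_locus),
        "census_fractions": census.fractions,
        "sj_context": context.counts,
        "n_as_genes": len(exon_counts["as_genes"]),
        "n_non_as_genes": len(exon_counts["non_as_genes"]),
    }
    manifest["outputs"]["events"] = events_path.name
    manifest["outputs"]["census"] = census_path.name
    manifest["outputs"]["context"] = context_path.name

    # --- polya ------------------------------------------------------------
    sites = call_polya_sites(linear, loci, cfg.cluster_radius, cfg.min_polya_support)
    apa = call_apa(sites)
    polya_path = outdir / "polya.tsv"
    _write_polya(sites, polya_path)
    manifest["stages"]["polya"] = apa
    manifest["outputs"]["polya"] = polya_path.name

    # --- merge/report -----------------------------------------------------
    label_of = {t.id: label for locus in loci for t, label in locus.members}
    locus_of = {t.id: locus for locus in loci for t, _ in locus.members}
    novel = [t for t in isoforms if label_of[t.id] != "known_known"]
    novel_gene_of = {
        t.id: (locus_of[t.id].known_gene_id or locus_of[t.id].locus_id) for t in novel
    }
    merged, summary = merge_library(annotation, novel, novel_gene_of)
    merged_path = outdir / "merged.gff3"
    merged_ann = Annotation(
        merged,
        {tid: novel_gene_of.get(tid, annotation.gene_of.get(tid, tid)) for tid in merged},
        annotation.cds_span,
    )
    fio.write_gff3(
        merged_ann,
        merged_path,
        attributes={tid: {"provenance": merged[tid].source} for tid in merged},
    )
    summary_path = outdir / "summary.json"
    summary_dict = {
        "n_reference": summary.n_reference,
        "n_novel": summary.n_novel,
        "n_total": summary.n_total,
        "median_exon_size": summary.median_exon_size,
        "median_gene_size": summary.median_gene_size,
        "mean_coding_exons_per_gene": summary.mean_coding_exons_per_gene,
        "n_genes_without_cds": summary.n_genes_without_cds,
        "length_histogram": summary.length_histogram,
    }
    summary_path.write_text(json.dumps(summary_dict, indent=2, sort_keys=True) + "\n")
    manifest["stages"]["merge"] = {
        "n_reference": summary.n_reference,
        "n_novel": summary.n_novel,
        "n_total": summary.n_total,
    }
    manifest["outputs"]["merged"] = merged_path.name
    manifest["outputs"]["summary"] = summary_path.name

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["manifest"] = manifest_path.name
    return manifest


# ---------------------------------------------------------------------------
# writers


def _write_transcripts(transcripts, path, labels=None) -> None:
    ann = Annotation(
        {t.id: t for t in transcripts}, {t.id: t.id for t in transcripts}, {}
    )
    fio.write_gff3(ann, path, attributes=labels or {})


def _write_loci(loci, path) -> None:
    transcripts = {}
    gene_of = {}
    attrs = {}
    for locus in loci:
        for t, label in locus.members:
            transcripts[t.id] = t
            gene_of[t.id] = locus.locus_id
            attrs[t.id] = {"label": label, "locus": locus.locus_id}
    fio.write_gff3(Annotation(transcripts, gene_of, {}), path, attributes=attrs)


def _write_table1(report, path) -> None:
    lines = ["category\tn_loci\tn_isoforms"]
    for name, (nl, ni) in report.as_dict().items():
        lines.append(f"{name}\t{nl}\t{ni}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_fusions(calls, path) -> None:
    lines = ["read_id\tfusion_type\tgenes\tsegments\tillumina_support"]
    for c in calls:
        segs = ";".join(
            f"{s.chrom}:{s.exons[0].start}-{s.exons[-1].end}:{s.strand}" for s in c.segments
        )
        lines.append(
            f"{c.read_id}\t{c.fusion_type}\t{','.join(c.gene_ids)}\t{segs}\t"
            f"{','.join(map(str, c.illumina_support))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _write_events(events, path) -> None:
    lines = ["locus\ttype\tchrom\tstart\tend\tinclusion\texclusion"]
    for ev in events:
        lines.append(
            f"{ev.locus_id}\t{ev.event_type}\t{ev.chrom}\t{ev.start}\t{ev.end}\t"
            f"{ev.inclusion_id}\t{ev.exclusion_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _write_kv(counts, path) -> None:
    lines = ["key\tcount"] + [f"{k}\t{v}" for k, v in counts.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _write_polya(sites, path) -> None:
    lines = ["gene_id\tchrom\tstrand\tposition\tsupport"]
    for s in sites:
        lines.append(f"{s.gene_id}\t{s.chrom}\t{s.strand}\t{s.position}\t{s.support}")
    Path(path).write_text("\n".join(lines) + "\n")
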