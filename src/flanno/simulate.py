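"""Synthetic genomes, annotations, FLNC alignments and junction-support sets
with per-read ground truth, so every pipeline stage is testable offline.

The generator states a small but structurally faithful world: a few
100-kb-scale chromosomes carrying non-overlapping multi-exon gene models on
both strands, splice sites written with a configurable donor-acceptor
dinucleotide composition, long reads drawn from annotated isoforms plus
injected novel isoforms (one AS edit each), novel intergenic transcripts and
chimeric fusion reads, 5' truncation and 3'-end scatter around per-gene polyA
sites, and a short-read junction-support set with controllable coverage.
Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import (
    AlignedRead,
    Annotation,
    Exon,
    GenomeSequence,
    Intron,
    Segment,
    Transcript,
    introns_of,
    reverse_complement,
)
from . import io as fio

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Stated world for the simulator; the seed fully determines every output."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 400_000
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (3, 7)
    exon_length: tuple[int, int] = (120, 400)
    intron_length: tuple[int, int] = (80, 600)
    intergenic_gap: tuple[int, int] = (4_000, 10_000)
    reads_per_isoform: tuple[int, int] = (4, 8)
    p_novel_isoform: float = 0.2
    p_novel_locus: float = 0.1
    p_fusion_read: float = 0.0
    pid_global_mean: float = 98.5
    pid_global_sd: float = 0.8
    pid_local_mean: float = 99.2
    pid_local_sd: float = 0.4
    truncation_5p: tuple[int, int] = (0, 0)
    polya_sites_per_gene: tuple[int, int] = (1, 2)
    polya_site_spacing: int = 100
    polya_scatter_sd: float = 0.0
    junction_support_coverage: float = 1.0
    # donor-acceptor composition written at annotated splice sites
    dinucleotide_fractions: dict[str, float] = field(
        default_factory=lambda: {"GT-AG": 1.0}
    )

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "intergenic_gap", "reads_per_isoform", "truncation_5p",
                     "polya_sites_per_gene"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name}: empty or negative range ({lo}, {hi})")
        for name in ("p_novel_isoform", "p_novel_locus", "p_fusion_read",
                     "junction_support_coverage"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if abs(sum(self.dinucleotide_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("dinucleotide_fractions must sum to 1")


@dataclass
class SimulatedGenome:
    """Genome + annotation + construction-time truth about the splice sites."""

    sequences: dict[str, GenomeSequence]
    annotation: Annotation
    intron_classes: dict[Intron, str]  # dinucleotide class written per annotated intron
    free_space: dict[str, list[tuple[int, int]]]  # intergenic intervals per chrom


@dataclass
class GroundTruth:
    """Per-read and per-gene truth recorded while simulating."""

    read_label: dict[str, str] = field(default_factory=dict)  # known_known | known_novel | novel_locus | fusion
    read_origin: dict[str, str] = field(default_factory=dict)  # origin isoform id
    read_polya: dict[str, int | None] = field(default_factory=dict)
    gene_polya_sites: dict[str, list[int]] = field(default_factory=dict)
    gene_as_events: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    isoform_label: dict[str, str] = field(default_factory=dict)
    true_introns: set[Intron] = field(default_factory=set)


def _largest_remainder(fractions: Mapping[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` items to classes so counts/total ~ fractions exactly."""
    raw = {k: f * total for k, f in fractions.items()}
    counts = {k: math.floor(v) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: (raw[k] - counts[k], k), reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_genome(cfg: SimConfig) -> SimulatedGenome:
    """Build chromosomes with non-overlapping gene models on both strands.

    Splice-site dinucleotides are written into the sequence in transcription
    orientation according to ``cfg.dinucleotide_fractions``, apportioned by
    largest remainder so the realised composition matches the request exactly
    up to count rounding.
    """
    rng = np.random.default_rng(cfg.seed)
    seqs = {
        f"chr{i + 1}": rng.choice(_BASES, size=cfg.chrom_length)
        for i in range(cfg.n_chroms)
    }
    transcripts: dict[str, Transcript] = {}
    gene_of: dict[str, str] = {}
    cds_span: dict[str, tuple[int, int]] = {}
    free_space: dict[str, list[tuple[int, int]]] = {c: [] for c in seqs}

    cursors = {c: 0 for c in seqs}
    chrom_names = list(seqs)
    all_introns: list[Intron] = []
    for g in range(cfg.n_genes):
        chrom = chrom_names[g % cfg.n_chroms]
        gap = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        ex_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex)
        in_lens = (
            rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_ex - 1)
            if n_ex > 1
            else np.array([], dtype=int)
        )
        start = cursors[chrom] + gap
        end = start + int(ex_lens.sum() + in_lens.sum())
        if end > cfg.chrom_length:
            raise ValueError(
                f"config infeasible: gene {g + 1} would end at {end} > "
                f"chrom_length {cfg.chrom_length} on {chrom}"
            )
        if start > cursors[chrom]:
            free_space[chrom].append((cursors[chrom], start))
        exons = []
        pos = start
        for i in range(n_ex):
            exons.append(Exon(pos, pos + int(ex_lens[i])))
            pos += int(ex_lens[i])
            if i < n_ex - 1:
                pos += int(in_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{g + 1:04d}"
        tid = f"{gid}.t1"
        t = Transcript(tid, chrom, strand, tuple(exons))
        transcripts[tid] = t
        gene_of[tid] = gid
        # CDS leaves ~40 bp UTR inside the terminal exons
        utr5, utr3 = 40, 40
        cds_span[tid] = (exons[0].start + utr5, exons[-1].end - utr3)
        all_introns.extend(introns_of(t))
        cursors[chrom] = end
    for chrom in seqs:
        if cursors[chrom] < cfg.chrom_length:
            free_space[chrom].append((cursors[chrom], cfg.chrom_length))

    # write splice-site dinucleotides per the requested composition
    quotas = _largest_remainder(cfg.dinucleotide_fractions, len(all_introns))
    classes = [k for k, n in sorted(quotas.items()) for _ in range(n)]
    classes = [classes[i] for i in rng.permutation(len(classes))]
    intron_classes: dict[Intron, str] = {}
    for j, klass in zip(all_introns, classes):
        donor, acceptor = (klass.split("-") if "-" in klass else ("NN", "NN"))
        if j.strand == "-":
            left, right = reverse_complement(acceptor), reverse_complement(donor)
        else:
            left, right = donor, acceptor
        seqs[j.chrom][j.start : j.start + 2] = list(left)
        seqs[j.chrom][j.end - 2 : j.end] = list(right)
        intron_classes[j] = klass

    sequences = {c: GenomeSequence(c, "".join(a)) for c, a in seqs.items()}
    annotation = Annotation(transcripts, gene_of, cds_span)
    return SimulatedGenome(sequences, annotation, intron_classes, free_space)


# ---------------------------------------------------------------------------
# AS edits


def _edit_skip(t: Transcript, rng) -> tuple[tuple[Exon, ...], tuple[str, int, int]] | None:
    if t.n_exons < 3:
        return None
    i = int(rng.integers(1, t.n_exons - 1))
    skipped = t.exons[i]
    return t.exons[:i] + t.exons[i + 1 :], ("SKIP", skipped.start, skipped.end)


def _edit_ir(t: Transcript, rng) -> tuple[tuple[Exon, ...], tuple[str, int, int]] | None:
    if t.n_exons < 2:
        return None
    i = int(rng.integers(0, t.n_exons - 1))
    merged = Exon(t.exons[i].start, t.exons[i + 1].end)
    exons = t.exons[:i] + (merged,) + t.exons[i + 2 :]
    return exons, ("IR", t.exons[i].end, t.exons[i + 1].start)


def _edit_ae(t: Transcript, rng, delta: int = 15) -> tuple[tuple[Exon, ...], tuple[str, int, int]] | None:
    """Shift one internal donor boundary inward by ``delta`` bp."""
    if t.n_exons < 2:
        return None
    i = int(rng.integers(0, t.n_exons - 1))
    ex = t.exons[i]
    if ex.length <= delta + 20:
        return None
    shifted = Exon(ex.start, ex.end - delta)
    exons = t.exons[:i] + (shifted,) + t.exons[i + 1 :]
    return exons, ("AE", ex.end - delta, ex.end)


_EDITS = (_edit_skip, _edit_ir, _edit_ae)


# ---------------------------------------------------------------------------
# FLNC simulation


def _clip_pid(x: float) -> float:
    return float(min(100.0, max(0.0, x)))


def _gene_polya_sites(t: Transcript, k: int, spacing: int) -> list[int]:
    """Up to ``k`` polyA positions inside the terminal exon, ``spacing`` bp apart."""
    last = t.exons[-1] if t.strand == "+" else t.exons[0]
    sites = [t.three_prime_end()]
    for j in range(1, k):
        if t.strand == "+":
            p = t.three_prime_end() - j * spacing
            if p < last.start + 20:
                break
        else:
            p = t.three_prime_end() + j * spacing
            if p > last.end - 20:
                break
        sites.append(p)
    return sites


def _apply_3p_end(exons: tuple[Exon, ...], strand: str, end: int) -> tuple[Exon, ...]:
    if strand == "+":
        last = exons[-1]
        end = max(end, last.start + 1)
        return exons[:-1] + (Exon(last.start, end + 1),)
    first = exons[0]
    end = min(end, first.end - 2)
    return (Exon(max(0, end), first.end),) + exons[1:]


def _apply_truncation(exons: tuple[Exon, ...], strand: str, trunc: int) -> tuple[Exon, ...]:
    if trunc <= 0:
        return exons
    if strand == "+":
        first = exons[0]
        trunc = min(trunc, first.length - 20)
        if trunc <= 0:
            return exons
        return (Exon(first.start + trunc, first.end),) + exons[1:]
    last = exons[-1]
    trunc = min(trunc, last.length - 20)
    if trunc <= 0:
        return exons
    return exons[:-1] + (Exon(last.start, last.end - trunc),)


def simulate_flnc(
    cfg: SimConfig, sim: SimulatedGenome
) -> tuple[list[AlignedRead], GroundTruth]:
    """Draw FLNC reads from the simulated world.

    Per gene slot: with probability ``p_novel_locus`` the slot's reads come
    from a novel transcript placed in intergenic space; otherwise from the
    gene's annotated isoform, plus (with probability ``p_novel_isoform``) a
    novel variant carrying one injected AS edit.  Each emitted read is then
    replaced by a chimeric fusion read with probability ``p_fusion_read``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    annotation = sim.annotation
    genes = sorted(annotation.genes().items())
    if not genes and cfg.p_novel_locus == 0.0:
        raise ValueError("empty annotation with p_novel_locus=0: nothing to simulate")

    truth = GroundTruth()
    source_isoforms: list[tuple[Transcript, str, str, list[int]]] = []
    # (isoform, label, gene id for polyA, polyA sites)

    free = {c: list(iv) for c, iv in sim.free_space.items()}
    novel_locus_count = 0

    for gid, ts in genes:
        base = ts[0]
        if rng.random() < cfg.p_novel_locus:
            novel = _place_novel_locus(cfg, rng, free, novel_locus_count)
            if novel is not None:
                novel_locus_count += 1
                sites = [novel.three_prime_end()]
                truth.gene_polya_sites[novel.id] = sites
                truth.isoform_label[novel.id] = "novel_locus"
                truth.true_introns.update(introns_of(novel))
                source_isoforms.append((novel, "novel_locus", novel.id, sites))
            continue
        k = int(rng.integers(cfg.polya_sites_per_gene[0], cfg.polya_sites_per_gene[1] + 1))
        sites = _gene_polya_sites(base, k, cfg.polya_site_spacing)
        truth.gene_polya_sites[gid] = sites
        truth.isoform_label[base.id] = "known_known"
        truth.true_introns.update(introns_of(base))
        source_isoforms.append((base, "known_known", gid, sites))
        if rng.random() < cfg.p_novel_isoform:
            order = rng.permutation(len(_EDITS))
            for idx in order:
                result = _EDITS[idx](base, rng)
                if result is not None:
                    exons, event = result
                    vid = f"{gid}.novel"
                    variant = Transcript(vid, base.chrom, base.strand, exons, source="flnc")
                    truth.gene_as_events.setdefault(gid, []).append(event)
                    truth.isoform_label[vid] = "known_novel"
                    truth.true_introns.update(introns_of(variant))
                    source_isoforms.append((variant, "known_novel", gid, sites))
                    break

    if not source_isoforms and cfg.p_fusion_read == 0.0:
        raise ValueError("simulation produced no source isoforms")

    reads: list[AlignedRead] = []
    n_read = 0
    site_cursor: dict[str, int] = {}
    for isoform, label, gid, sites in source_isoforms:
        n_reads = int(rng.integers(cfg.reads_per_isoform[0], cfg.reads_per_isoform[1] + 1))
        for _ in range(n_reads):
            n_read += 1
            rid = f"read{n_read:06d}"
            if cfg.p_fusion_read > 0 and rng.random() < cfg.p_fusion_read:
                read = _make_fusion_read(cfg, rng, annotation, rid)
                if read is not None:
                    reads.append(read)
                    truth.read_label[rid] = "fusion"
                    truth.read_origin[rid] = "fusion"
                    truth.read_polya[rid] = None
                    continue
            # round-robin across the gene's polyA sites
            cursor = site_cursor.get(gid, 0)
            site = sites[cursor % len(sites)]
            site_cursor[gid] = cursor + 1
            end = site
            if cfg.polya_scatter_sd > 0:
                end = int(round(site + rng.normal(0.0, cfg.polya_scatter_sd)))
            exons = _apply_3p_end(isoform.exons, isoform.strand, end)
            trunc = int(rng.integers(cfg.truncation_5p[0], cfg.truncation_5p[1] + 1))
            exons = _apply_truncation(exons, isoform.strand, trunc)
            gpid = _clip_pid(rng.normal(cfg.pid_global_mean, cfg.pid_global_sd))
            lpid = _clip_pid(rng.normal(cfg.pid_local_mean, cfg.pid_local_sd))
            reads.append(
                AlignedRead(rid, (Segment(isoform.chrom, isoform.strand, exons, lpid),), gpid)
            )
            truth.read_label[rid] = label
            truth.read_origin[rid] = isoform.id
            truth.read_polya[rid] = site
    return reads, truth


def _place_novel_locus(cfg: SimConfig, rng, free, index: int) -> Transcript | None:
    """Carve a 2-4 exon transcript out of intergenic free space (with margin)."""
    n_ex = int(rng.integers(2, 5))
    ex_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex)
    in_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_ex - 1)
    need = int(ex_lens.sum() + in_lens.sum())
    margin = 500
    for chrom in sorted(free):
        for i, (lo, hi) in enumerate(free[chrom]):
            if hi - lo >= need + 2 * margin:
                start = lo + margin
                exons = []
                pos = start
                for k in range(n_ex):
                    exons.append(Exon(pos, pos + int(ex_lens[k])))
                    pos += int(ex_lens[k])
                    if k < n_ex - 1:
                        pos += int(in_lens[k])
                free[chrom][i] = (pos + margin, hi)
                strand = "+" if rng.random() < 0.5 else "-"
                return Transcript(
                    f"novelgene{index + 1:03d}.t1", chrom, strand, tuple(exons), source="flnc"
                )
    return None


def _make_fusion_read(cfg: SimConfig, rng, annotation: Annotation, rid: str) -> AlignedRead | None:
    """Chimeric read concatenating >=2-exon halves of two well-separated genes."""
    genes = sorted(annotation.genes().items())
    multi = [(gid, ts[0]) for gid, ts in genes if ts[0].n_exons >= 2]
    pairs = []
    for i in range(len(multi)):
        for j in range(len(multi)):
            if i == j:
                continue
            ga, gb = multi[i][1], multi[j][1]
            if ga.chrom != gb.chrom:
                pairs.append((i, j))
            elif max(ga.start, gb.start) - min(ga.end, gb.end) > 50_000:
                pairs.append((i, j))
    if not pairs:
        return None
    i, j = pairs[int(rng.integers(0, len(pairs)))]
    ta, tb = multi[i][1], multi[j][1]
    half_a = ta.exons[: max(2, ta.n_exons // 2)]
    half_b = tb.exons[-max(2, tb.n_exons // 2) :]
    len_a = sum(e.length for e in half_a)
    len_b = sum(e.length for e in half_b)
    lp = lambda: _clip_pid(rng.normal(cfg.pid_local_mean, cfg.pid_local_sd))
    seg_a = Segment(ta.chrom, ta.strand, tuple(half_a), lp(), read_start=0, read_end=len_a)
    seg_b = Segment(tb.chrom, tb.strand, tuple(half_b), lp(), read_start=len_a, read_end=len_a + len_b)
    gpid = _clip_pid(rng.normal(cfg.pid_global_mean, cfg.pid_global_sd))
    return AlignedRead(rid, (seg_a, seg_b), gpid)


def simulate_junction_support(
    cfg: SimConfig, truth: GroundTruth, annotation: Annotation
) -> set[Intron]:
    """Each true intron enters the short-read support set independently with
    probability ``junction_support_coverage`` (deterministic under the seed)."""
    rng = np.random.default_rng(cfg.seed + 2)
    universe = sorted(set(truth.true_introns) | annotation.all_introns())
    if cfg.junction_support_coverage >= 1.0:
        return set(universe)
    keep = rng.random(len(universe)) < cfg.junction_support_coverage
    return {j for j, k in zip(universe, keep) if k}


# ---------------------------------------------------------------------------
# one-call convenience + disk output


@dataclass
class Simulation:
    cfg: SimConfig
    genome: SimulatedGenome
    reads: list[AlignedRead]
    truth: GroundTruth
    junctions: set[Intron]


def simulate(cfg: SimConfig) -> Simulation:
    genome = simulate_genome(cfg)
    reads, truth = simulate_flnc(cfg, genome)
    junctions = simulate_junction_support(cfg, truth, genome.annotation)
    return Simulation(cfg, genome, reads, truth, junctions)


def write_simulation(sim: Simulation, outdir: str | Path, junction_support_count: int = 3) -> dict[str, str]:
    """Write FASTA/GFF3/BED12(+PID TSV)/junction BED/ground-truth TSV; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(outdir / "genome.fa"),
        "annotation": str(outdir / "annotation.gff3"),
        "alignments": str(outdir / "reads.bed12"),
        "pid_table": str(outdir / "reads.pid.tsv"),
        "junctions": str(outdir / "junctions.bed"),
        "ground_truth": str(outdir / "ground_truth.tsv"),
    }
    fio.write_fasta(sim.genome.sequences, paths["genome"])
    fio.write_gff3(sim.genome.annotation, paths["annotation"])
    fio.write_alignments_bed12(sim.reads, paths["alignments"], paths["pid_table"])
    fio.write_junction_bed({j: junction_support_count for j in sim.junctions}, paths["junctions"])
    lines = ["read_id\tlabel\torigin_isoform\ttrue_polya"]
    for rid in sorted(sim.truth.read_label):
        pa = sim.truth.read_polya.get(rid)
        lines.append(
            f"{rid}\t{sim.truth.read_label[rid]}\t{sim.truth.read_origin[rid]}\t"
            f"{'' if pa is None else pa}"
        )
    Path(paths["ground_truth"]).write_text("\n".join(lines) + "\n")
    return paths
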