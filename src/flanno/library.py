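"""Merged transcript-library construction and structural summary statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import Annotation, Transcript


@dataclass
class LibrarySummary:
    n_reference: int
    n_novel: int
    n_total: int
    length_histogram: dict[str, int] = field(default_factory=dict)
    median_exon_size: float = 0.0
    median_gene_size: float = 0.0
    mean_coding_exons_per_gene: float = 0.0
    n_genes_without_cds: int = 0  # genes whose "coding exon" count fell back to all exons

    def __post_init__(self) -> None:
        if self.n_total != self.n_reference + self.n_novel:
            raise ValueError("library counts do not conserve")


DEFAULT_BINS = (0, 500, 1000, 1500, 2000, 2500, 3000, 4000, 5000, 10_000)


def merge_library(
    annotation: Annotation,
    novel_isoforms: Sequence[Transcript],
    novel_gene_of: Mapping[str, str] | None = None,
) -> tuple[dict[str, Transcript], LibrarySummary]:
    """Union of reference transcripts and discovered novel isoforms.

    Novel isoforms never replace or deduplicate against reference entries
    (exact rediscoveries are excluded upstream by the novelty labels).
    ``novel_gene_of`` maps novel transcript ids to their gene/locus id for the
    per-gene statistics; unmapped novel transcripts count as their own gene.
    """
    collisions = sorted(set(annotation.transcripts) & {t.id for t in novel_isoforms})
    if collisions:
        raise ValueError(f"novel isoform ids collide with reference ids: {collisions}")
    merged: dict[str, Transcript] = dict(annotation.transcripts)
    gene_of: dict[str, str] = dict(annotation.gene_of)
    novel_gene_of = novel_gene_of or {}
    for t in novel_isoforms:
        merged[t.id] = Transcript(t.id, t.chrom, t.strand, t.exons, source="flnc")
        gene_of[t.id] = novel_gene_of.get(t.id, t.id)
    summary = summarize_structure(
        merged,
        gene_of,
        annotation.cds_span,
        n_reference=len(annotation.transcripts),
        n_novel=len(novel_isoforms),
    )
    return merged, summary


def summarize_structure(
    transcripts: Mapping[str, Transcript],
    gene_of: Mapping[str, str],
    cds_span: Mapping[str, tuple[int, int]] | None = None,
    n_reference: int | None = None,
    n_novel: int | None = None,
    bins: Sequence[int] = DEFAULT_BINS,
) -> LibrarySummary:
    """Structural statistics over a transcript set.

    Median exon size is over every exon of every transcript; gene size is the
    genomic span of each gene (max end - min start over its transcripts);
    coding exons per gene are exons intersecting the gene's CDS spans, falling
    back to all exons for genes without any CDS (counted separately).
    """
    cds_span = cds_span or {}
    exon_sizes: list[int] = []
    lengths: list[int] = []
    by_gene: dict[str, list[Transcript]] = {}
    for tid, t in transcripts.items():
        exon_sizes.extend(e.length for e in t.exons)
        lengths.append(t.exonic_length)
        by_gene.setdefault(gene_of.get(tid, tid), []).append(t)

    gene_sizes = []
    coding_exons = []
    n_no_cds = 0
    for gid, ts in by_gene.items():
        gene_sizes.append(max(t.end for t in ts) - min(t.start for t in ts))
        spans = [cds_span[t.id] for t in ts if t.id in cds_span]
        if spans:
            n = max(
                sum(1 for e in t.exons if t.id in cds_span and _intersects(e, cds_span[t.id]))
                for t in ts
            )
        else:
            n_no_cds += 1
            n = max(t.n_exons for t in ts)
        coding_exons.append(n)

    edges = list(bins) + [max(max(lengths, default=0) + 1, bins[-1] + 1)]
    hist, _ = np.histogram(lengths, bins=edges)
    labels = [
        f"{lo}-{hi}" if i < len(bins) - 1 else f">{bins[-1]}"
        for i, (lo, hi) in enumerate(zip(edges, edges[1:]))
    ]
    n_total = len(transcripts)
    if n_reference is None:
        n_reference, n_novel = n_total, 0
    return LibrarySummary(
        n_reference=n_reference,
        n_novel=n_novel if n_novel is not None else 0,
        n_total=n_total,
        length_histogram=dict(zip(labels, (int(c) for c in hist))),
        median_exon_size=float(np.median(exon_sizes)) if exon_sizes else 0.0,
        median_gene_size=float(np.median(gene_sizes)) if gene_sizes else 0.0,
        mean_coding_exons_per_gene=float(np.mean(coding_exons)) if coding_exons else 0.0,
        n_genes_without_cds=n_no_cds,
    )


def _intersects(exon, span: tuple[int, int]) -> bool:
    return max(exon.start, span[0]) < min(exon.end, span[1])
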