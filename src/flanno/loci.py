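"""Locus grouping and isoform novelty classification.

Retained isoforms and reference transcripts are joined into strand-specific
loci by exonic overlap (> 20% of the smaller exonic length, with at least one
exon-pair overlap > 20% of the shorter exon).  Each discovered isoform is then
labelled against the locus' reference gene:

- ``known_known``  — its intron chain exactly matches an annotated transcript
  of the gene (for monoexonic isoforms: the best-overlapping annotated
  transcript is also monoexonic);
- ``known_novel``  — it belongs to a known gene but its structure is not an
  annotated one (new splice sites, a different exon/intron chain, or a
  single-exon vs multi-exon mismatch);
- ``novel``        — its locus contains no reference transcript (no or <20%
  overlap with the annotation, or opposite strand, since loci are
  strand-specific).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .core import Annotation, Transcript, exonic_overlap, intron_chain, introns_of

Label = Literal["known_known", "known_novel", "novel"]

_NOVELTY_ORDER = {"novel": 2, "known_novel": 1, "known_known": 0}


@dataclass
class Locus:
    """A connected component of exon-overlapping, same-strand isoforms."""

    locus_id: str
    chrom: str
    strand: str
    members: list[tuple[Transcript, Label]] = field(default_factory=list)
    annotation_members: list[Transcript] = field(default_factory=list)
    known_gene_id: str | None = None

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts())

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts())

    def transcripts(self) -> list[Transcript]:
        return [t for t, _ in self.members] + self.annotation_members


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def same_locus(a: Transcript, b: Transcript, min_frac: float = 0.20) -> bool:
    """The locus edge criterion (strict > on both fractions)."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    rep = exonic_overlap(a, b)
    return min(rep.frac_a, rep.frac_b) > min_frac and rep.max_single_exon_frac > min_frac


def build_loci(
    isoforms: Sequence[Transcript],
    annotation: Annotation,
    min_frac: float = 0.20,
) -> tuple[list[Locus], list[str]]:
    """Group isoforms and reference transcripts into loci (connected components).

    Reference transcripts of one gene are pre-joined (the annotation already
    asserts they are one gene).  A component containing reference transcripts
    of more than one gene is kept as a merged locus and reported in the
    returned warning list.  Labels are assigned via :func:`classify_isoform`.
    """
    ann_ts = sorted(annotation.transcripts.values(), key=lambda t: (t.chrom, t.start, t.id))
    nodes: list[Transcript] = list(isoforms) + ann_ts
    n_iso = len(isoforms)
    uf = _UnionFind(len(nodes))

    gene_first: dict[str, int] = {}
    for i, t in enumerate(ann_ts, start=n_iso):
        gid = annotation.gene_of[t.id]
        if gid in gene_first:
            uf.union(gene_first[gid], i)
        else:
            gene_first[gid] = i

    # sweep per chrom+strand: only span-overlapping pairs can share exonic bp
    order = sorted(range(len(nodes)), key=lambda i: (nodes[i].chrom, nodes[i].strand, nodes[i].start))
    active: list[int] = []
    prev_key = None
    for i in order:
        t = nodes[i]
        key = (t.chrom, t.strand)
        if key != prev_key:
            active = []
            prev_key = key
        active = [j for j in active if nodes[j].end > t.start]
        for j in active:
            if same_locus(t, nodes[j], min_frac):
                uf.union(i, j)
        active.append(i)

    components: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        components.setdefault(uf.find(i), []).append(i)

    loci: list[Locus] = []
    warnings: list[str] = []
    comp_list = sorted(
        components.values(), key=lambda c: (nodes[c[0]].chrom, min(nodes[i].start for i in c))
    )
    for idx, comp in enumerate(comp_list, 1):
        iso_members = [nodes[i] for i in comp if i < n_iso]
        ann_members = [nodes[i] for i in comp if i >= n_iso]
        if not iso_members and not ann_members:
            continue
        ref = (iso_members + ann_members)[0]
        gene_ids = sorted({annotation.gene_of[t.id] for t in ann_members})
        locus = Locus(
            locus_id=f"LOC{idx:06d}",
            chrom=ref.chrom,
            strand=ref.strand,
            annotation_members=sorted(ann_members, key=lambda t: (t.start, t.id)),
            known_gene_id=gene_ids[0] if gene_ids else None,
        )
        if len(gene_ids) > 1:
            warnings.append(
                f"{locus.locus_id}: merged locus spans annotated genes {','.join(gene_ids)}"
            )
        for t in sorted(iso_members, key=lambda t: (t.start, t.id)):
            locus.members.append((t, classify_isoform(t, locus, annotation)))
        loci.append(locus)
    return loci, warnings


def classify_isoform(t: Transcript, locus: Locus, annotation: Annotation) -> Label:
    """Assign the three-way novelty label of one discovered isoform."""
    if locus.known_gene_id is None:
        return "novel"
    candidates = locus.annotation_members
    if t.n_exons == 1:
        best = max(candidates, key=lambda a: (exonic_overlap(t, a).shared_bp, a.id))
        return "known_known" if best.n_exons == 1 else "known_novel"
    chain = intron_chain(t)
    for a in candidates:
        if intron_chain(a) == chain:
            return "known_known"
    return "known_novel"


def new_splice_sites(t: Transcript, annotation_members: Iterable[Transcript]) -> int:
    """Count intron boundaries of ``t`` absent from the gene's annotated boundaries."""
    known: set[int] = set()
    for a in annotation_members:
        for j in introns_of(a):
            known.update((j.start, j.end))
    n = 0
    for j in introns_of(t):
        n += (j.start not in known) + (j.end not in known)
    return n


@dataclass
class Table1Report:
    """The loci/isoform partition: (n_loci, n_isoforms) per novelty category."""

    known_known: tuple[int, int]
    known_novel: tuple[int, int]
    novel: tuple[int, int]
    total: tuple[int, int]
    counting_mode: str = "disjoint"

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {
            "known_known": self.known_known,
            "known_novel": self.known_novel,
            "novel": self.novel,
            "total": self.total,
        }


def partition_counts(
    loci: Sequence[Locus], counting_mode: str = "disjoint"
) -> Table1Report:
    """Tabulate discovered loci and isoforms per novelty category.

    ``disjoint`` (default): each locus counted once, by its most novel member,
    so the three locus rows sum to the total.  ``overlapping``: a locus counts
    toward every category it has a member of (rows may sum to more than the
    total).  Loci without discovered members are not reported.
    """
    if counting_mode not in ("disjoint", "overlapping"):
        raise ValueError(f"unknown counting_mode {counting_mode!r}")
    iso = {"known_known": 0, "known_novel": 0, "novel": 0}
    loc = {"known_known": 0, "known_novel": 0, "novel": 0}
    n_loci = 0
    for locus in loci:
        if not locus.members:
            continue
        n_loci += 1
        labels = {label for _, label in locus.members}
        for _, label in locus.members:
            iso[label] += 1
        if counting_mode == "disjoint":
            top = max(labels, key=lambda l: _NOVELTY_ORDER[l])
            loc[top] += 1
        else:
            for label in labels:
                loc[label] += 1
    n_iso = sum(iso.values())
    return Table1Report(
        known_known=(loc["known_known"], iso["known_known"]),
        known_novel=(loc["known_novel"], iso["known_novel"]),
        novel=(loc["novel"], iso["novel"]),
        total=(n_loci, n_iso),
        counting_mode=counting_mode,
    )
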