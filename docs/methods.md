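# Methods

`flanno` re-implements, as a tested library, the structural-annotation stage
of a long-read (Iso-Seq / FLNC) transcriptome study: given spliced FLNC
alignments, a reference genome and annotation, and a short-read-supported
junction list, it retains credible isoforms, collapses redundancy, groups
isoforms into gene loci, labels novelty, calls fusion transcripts, types
alternative-splicing (AS) events, censuses splice-site dinucleotides, and
calls polyA sites / alternative polyadenylation (APA).

## Coordinates and containers

All internal coordinates are 0-based half-open; the GFF3 reader/writer
converts to and from the 1-based inclusive standard at the boundary, BED12 is
native. A `Transcript` (strand-aware exon chain) is the single unit shared by
annotation entries, collapsed isoforms and merged-library records; an
`AlignedRead` is one FLNC read: one or more genomic segments plus
aligner-reported percent-identity (PID) values. PID is consumed as metadata,
never recomputed — the library models what an aligner reports, not base-level
error.

## Retention (FLNC filter)

Reads are first grouped into candidate isoforms. For multi-exon reads the
intron chain is the identity key (the usual long-read collapse convention);
terminal-end agreement within a fuzz window can be required additionally
(`fuzz=` bp, off by default). Single-exon reads are clustered by both
endpoints with a 10 bp single-linkage tolerance. A candidate is retained if
any of three OR-ed clauses holds:

1. ≥ `min_reads` (default 2) supporting reads;
2. any member read's **global** PID strictly above `min_pid` (default 99%, so
   exactly 99.0 fails);
3. every splice junction of the representative is present, with exact
   boundary equality, in the short-read junction set or among annotated
   introns (vacuously true for single-exon candidates).

Retention is monotone in the junction-support set. The representative of a
group is its longest member (ties by read id).

## Loci and novelty labels

Discovered isoforms and reference transcripts are nodes of a graph with an
edge when two same-chromosome, same-strand transcripts overlap exonically by
more than `min_frac` (default 0.20) of the *smaller* exonic length **and**
some exon pair overlaps by more than `min_frac` of the shorter exon.
Connected components are loci; reference transcripts of one gene are
pre-joined (the annotation already asserts they are one gene), and a
component spanning several annotated genes is kept but reported as a merged-
locus warning. Because loci are strand-specific, an antisense isoform can
never join a known gene, which realises the opposite-strand novelty rule for
free.

Labels per discovered isoform:

- **novel** — the locus contains no reference transcript;
- **known_known** — multi-exon: the intron chain exactly equals an annotated
  transcript's chain of the gene; single-exon: the best-overlapping annotated
  transcript is also single-exon. Terminal-end (TSS/TTS) differences alone
  never make an isoform novel.
- **known_novel** — everything else at a known locus: new splice sites, a
  different exon/intron chain (skipped exon, retained intron, shifted
  boundary), or a single-/multi-exon mismatch.

Chain-level identity was chosen deliberately: the narrower "has a new splice
site" indicator cannot see exon-skipping or intron-retention variants (both
boundaries of a skip junction are already annotated donors/acceptors), yet
such variants are plainly not annotated structures. The boundary-level
indicator remains available as `new_splice_sites()`.

Partition reporting supports two locus-counting modes. The default
`disjoint` mode counts each locus once by its most novel member, so the three
locus rows sum to the total; `overlapping` counts a locus toward every
category it has a member of.

## Fusion calling

Only multi-segment (chimeric) reads can produce calls; all four rules must
hold: (1) the segments hit ≥ 2 distinct annotated genes and adjacent segments
overlap < 10 bp **on read coordinates** (a near-clean breakpoint — the
literal per-locus genomic reading is available via `genomic_overlap_mode`);
(2) every pair of hit genes is on different chromosomes or > 50 kb apart;
(3) global PID ≥ 10% and every segment's local PID ≥ 90% (the 10% global
threshold is implemented as printed in the source study, though it most
likely denoted per-locus read coverage in the original pipeline); (4) each
segment's breakpoint-adjacent splice junction carries ≥ 2 short-read support
(single-exon segments have no such junction and count as unsupported).
Calls are classified inter- vs intra-chromosome; tightening any threshold
can only shrink the call set.

## AS event taxonomy

Events are detected between all isoform pairs of a locus (discovered and
reference alike) and deduplicated by (type, coordinates):

- **SKIP/MSKIP** — one (or several consecutive) exon(s) of one isoform lie
  strictly inside an intron of the other, with the flanking junction outer
  boundaries matching exactly;
- **IR/MIR** — one isoform's exon spans one (or more) intron(s) of the other
  with matching outer ends;
- **AE** — two overlapping introns share exactly one boundary; the event
  span covers the differing boundary pair. An AE candidate is suppressed
  when a skipped exon inside either intron explains the difference (that is
  SKIP territory).
- **X-variants** — the same topologies with boundary matching relaxed to
  ≤ `fuzz` bp (default 10). A candidate that matches exactly keeps its plain
  type, so `fuzz=0` leaves every X category empty and increasing `fuzz` can
  only add events (monotone total count).

Both an event counter and a per-gene counter (`as_gene_counts`) are emitted,
since published AS tables are usually by gene.

## Splice-site census and SJ context

For each unique junction, donor and acceptor 2-mers are read in transcription
orientation (reverse-complemented on minus-strand introns) and classified
GT-AG / GC-AG / AT-AC / other; `N` bases stay literal and fall into "other".
Junction genomic context is assigned at the donor position with precedence
CDS > UTR > intron > intergenic; "CDS" requires the position to be exonic and
inside the transcript's CDS span, UTR side follows the host transcript's
strand relative to its CDS (transcripts without a CDS fall back to the
transcript midpoint — a documented approximation for non-coding models).

## PolyA and APA

Single-segment reads are assigned to loci by best exonic overlap; per gene,
read 3' ends (last aligned base in transcription orientation) are
single-linkage clustered, splitting where the adjacent gap exceeds
`cluster_radius` (default 24 bp — the convention of the clustering approach
this module follows; the source study names no parameters). Clusters with
≥ `min_support` (default 2) reads become sites; the representative is the
modal position, ties resolved downstream. A gene with ≥ 2 sites exhibits
APA. Site count is antitone in `min_support`; it is antitone in
`cluster_radius` when every cluster is supported (at `min_support` 1 it is a
theorem; with larger `min_support`, merging two unsupported clusters can
create one supported site).

## The simulator: what it states and what it does not

The generator emulates the *structure* of the data, not its error process:
3 chromosomes of 400 kb, 30 non-overlapping genes of 3–7 exons (120–400 bp)
with 80–600 bp introns, 4–10 kb intergenic gaps, both strands. Splice-site
dinucleotides are apportioned across introns by largest-remainder quota (not
per-intron draws) so a constructed composition is realised exactly. Per gene
slot: with probability `p_novel_locus` the slot's reads come from a fresh
intergenic transcript; otherwise from the annotated isoform plus, with
probability `p_novel_isoform`, a variant carrying exactly one AS edit
(skipped exon, retained intron, or a 15 bp boundary shift) so ground-truth
events stay unambiguous. Each emitted read is replaced by a two-gene chimera
with probability `p_fusion_read`; chimeric segments always carry ≥ 2 exons,
never share exon overlap between source genes, and satisfy the fusion
distance rule by construction. 4–8 reads per isoform are drawn round-robin
across the gene's 1–2 polyA sites (spaced 100 bp inside the terminal exon,
so every site clears the default support threshold), 3' ends scattered with
`polya_scatter_sd` (0 by default — the noise-free stated world), 5'
truncation per `truncation_5p` (0 by default). PID values are sampled
metadata (global ~ N(98.5, 0.8), local ~ N(99.2, 0.4), clipped to [0, 100]).

Consequently a green recovery test establishes that the *rules* reproduce
the construction — it says nothing about alignment artifacts, degraded RNA,
internal priming, or base-level error, none of which are modelled.

## Numerical and tie-break choices

- Overlap fractions are reported against both transcripts' own exonic
  lengths; the locus rule thresholds the smaller fraction (strict `>`).
- PID retention is strict (`> 99`), fusion thresholds are inclusive (`>=`),
  matching the source wording of each rule.
- Locus ids are ordinal along (chromosome, start); group representatives,
  modal polyA positions and AE tie-breaks are all deterministic, so a fixed
  config reproduces byte-identical outputs.
- Degenerate inputs: empty read sets yield empty outputs everywhere; an
  empty annotation makes every locus novel; `partition_counts` ignores loci
  with no discovered members.

## Known limitations

- No quantitative splicing (PSI) or expression; events are structural only.
- Fusion support uses junction-level short-read counts; no breakpoint
  sequence assembly.
- PolyA calling does not scan for AAUAAA motifs or filter internal priming.
- The merged-locus warning is advisory; no automatic re-splitting of genes.
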