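import numpy as np
import pytest

from flanno.core import Annotation, Exon, Transcript


def T(tid, exons, chrom="chr1", strand="+", source="flnc"):
    """Shorthand transcript constructor for fixtures."""
    return Transcript(tid, chrom, strand, tuple(Exon(*e) for e in exons), source=source)


def make_annotation(transcripts, gene_of=None, cds_span=None):
    ts = {t.id: t for t in transcripts}
    gene_of = gene_of or {t.id: f"g_{t.id}" for t in transcripts}
    return Annotation(ts, dict(gene_of), dict(cds_span or {}))


def random_exon_chain(rng, max_exons=6, lo=0, hi=5000):
    """Random valid exon chain: sorted unique cut points taken pairwise."""
    n = int(rng.integers(1, max_exons + 1))
    cuts = np.sort(rng.choice(np.arange(lo, hi), size=2 * n, replace=False))
    return tuple(Exon(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n))


def exonic_bases(t):
    """Per-base oracle: the set of genomic positions covered by exons."""
    out = set()
    for e in t.exons:
        out.update(range(e.start, e.end))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
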