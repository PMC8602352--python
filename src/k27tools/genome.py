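"""Gene models and genome containers.

Internally every interval is 0-based half-open. GTF input/output converts at
the boundary (GTF is 1-based closed). One TSS per gene: when a GTF carries
several transcripts for a gene, the longest transcript is taken as canonical
and its exon/UTR records define the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["GeneModel", "Genome", "read_gtf", "write_gtf", "read_chrom_sizes", "write_chrom_sizes"]


@dataclass
class GeneModel:
    """One gene: coordinates, strand, exon structure and optional UTR intervals."""

    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty gene span for {self.gene_id}")
        if not self.exons:
            self.exons = [(self.start, self.end)]

    @property
    def tss(self) -> int:
        """Strand-resolved transcription start: leftmost base on '+', rightmost on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def exonic_length(self) -> int:
        return int(sum(e - s for s, e in self.exons))

    @property
    def length(self) -> int:
        return self.end - self.start


class Genome:
    """Chromosome sizes plus a set of gene models, indexed by gene id."""

    def __init__(self, chrom_sizes: dict[str, int], genes: list[GeneModel]):
        self.chrom_sizes = dict(chrom_sizes)
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        self.by_id = {g.gene_id: g for g in self.genes}
        if len(self.by_id) != len(self.genes):
            raise ValueError("duplicate gene ids")
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > self.chrom_sizes[g.chrom]:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def gene_lengths(self) -> pd.Series:
        """Exonic length per gene (bp), the length used for TPM."""
        return pd.Series({g.gene_id: g.exonic_length for g in self.genes}, name="length")

    def gene_table(self) -> pd.DataFrame:
        rows = [
            dict(gene_id=g.gene_id, chrom=g.chrom, start=g.start, end=g.end,
                 strand=g.strand, tss=g.tss, tes=g.tes, exonic_length=g.exonic_length)
            for g in self.genes
        ]
        return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# GTF / chrom.sizes I/O


def write_gtf(genome: Genome, path) -> None:
    """Write gene models as GTF (1-based closed), with transcript/exon/UTR records."""
    with open(path, "w") as fh:
        for g in genome.genes:
            attrs = f'gene_id "{g.gene_id}";'
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            rows = [("gene", g.start, g.end, attrs), ("transcript", g.start, g.end, tattrs)]
            rows += [("exon", s, e, tattrs) for s, e in g.exons]
            rows += [("five_prime_utr", s, e, tattrs) for s, e in g.utr5]
            rows += [("three_prime_utr", s, e, tattrs) for s, e in g.utr3]
            for feat, s, e, a in rows:
                fh.write(f"{g.chrom}\tk27tools\t{feat}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{a}\n")


def read_gtf(path, chrom_sizes: dict[str, int] | None = None) -> Genome:
    """Load a GTF into a :class:`Genome`.

    If ``chrom_sizes`` is not given, each chromosome's size is taken as the
    rightmost annotated coordinate (sufficient for promoter-window clipping on
    synthetic genomes; pass real sizes for real data).
    """
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    if df.empty:
        raise ValueError(f"no records in GTF {path}")
    genes: list[GeneModel] = []
    for gid, sub in df.groupby("gene_id", sort=True):
        grow = sub[sub.Feature == "gene"]
        if len(grow):
            chrom = str(grow.Chromosome.iloc[0])
            start, end = int(grow.Start.iloc[0]), int(grow.End.iloc[0])
            strand = str(grow.Strand.iloc[0])
        else:
            chrom = str(sub.Chromosome.iloc[0])
            start, end = int(sub.Start.min()), int(sub.End.max())
            strand = str(sub.Strand.iloc[0])
        # canonical transcript: longest span
        tx = sub[sub.Feature == "transcript"]
        tx_id = None
        if len(tx):
            spans = (tx.End - tx.Start).to_numpy()
            tx_id = tx.transcript_id.iloc[int(np.argmax(spans))]
        sub_tx = sub if tx_id is None else sub[sub.transcript_id.isin([tx_id])]

        def ivals(feature: str) -> list[tuple[int, int]]:
            f = sub_tx[sub_tx.Feature == feature]
            return sorted((int(s), int(e)) for s, e in zip(f.Start, f.End))

        exons = ivals("exon")
        utr5 = ivals("five_prime_utr") + ivals("5UTR")
        utr3 = ivals("three_prime_utr") + ivals("3UTR")
        genes.append(GeneModel(str(gid), chrom, start, end, strand, exons, utr5, utr3))
    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
        log.info("chrom sizes inferred from annotation extents")
    return Genome(chrom_sizes, genes)


def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for c, n in chrom_sizes.items():
            fh.write(f"{c}\t{n}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                c, n = line.split()[:2]
                out[c] = int(n)
    return out
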