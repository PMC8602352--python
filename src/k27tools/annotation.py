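"""Genomic annotation of called domains and promoter-modified gene sets.

A domain is classified by its midpoint with fixed precedence
``promoter > 5'UTR > 3'UTR > exon > intron > intergenic``; the promoter is
the +/-``flank`` window around the strand-resolved TSS. The per-stage sets of
genes with a retained promoter domain are decomposed into Venn cells
(shared / stage-specific) and pooled into the "modified" universe used for
the HDEG intersection.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneModel, Genome

log = logging.getLogger(__name__)

__all__ = [
    "FEATURE_CLASSES",
    "promoter_windows",
    "annotate_peaks",
    "genomic_distribution",
    "promoter_gene_sets",
    "PromoterGeneSets",
]

FEATURE_CLASSES = ["promoter", "5'UTR", "3'UTR", "exon", "intron", "intergenic"]


def promoter_windows(genome: Genome, flank: int = 5000) -> pd.DataFrame:
    """Per-gene promoter window ``[TSS - flank, TSS + flank)`` clipped to the
    chromosome; indexed by gene id with chrom/start/end/tss/strand columns."""
    rows = []
    for g in genome.genes:
        L = genome.chrom_sizes[g.chrom]
        if not (0 <= g.tss < L):
            raise ValueError(f"TSS of {g.gene_id} outside chromosome")
        rows.append((g.gene_id, g.chrom, max(g.tss - flank, 0), min(g.tss + flank, L),
                     g.tss, g.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "tss", "strand"]
                        ).set_index("gene_id")


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _classify_in_gene(pos: int, g: GeneModel) -> str | None:
    """Feature of a position inside gene g's span (UTR/exon/intron), else None."""
    if not (g.start <= pos < g.end):
        return None
    if _in_any(pos, g.utr5):
        return "5'UTR"
    if _in_any(pos, g.utr3):
        return "3'UTR"
    if _in_any(pos, g.exons):
        return "exon"
    return "intron"


def annotate_peaks(
    islands: pd.DataFrame,
    genome: Genome,
    windows: pd.DataFrame | None = None,
    flank: int = 5000,
) -> pd.DataFrame:
    """Assign each island a single feature class, its nearest gene (by
    midpoint-to-TSS distance, ties to the smaller gene id) and the signed
    distance to that TSS (negative = upstream in gene orientation)."""
    if windows is None:
        windows = promoter_windows(genome, flank)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genome.genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    win_by_chrom = {str(c): sub for c, sub in windows.groupby("chrom", sort=False)}

    feats, nearest, dist = [], [], []
    for _, r in islands.iterrows():
        chrom = str(r["chrom"])
        if chrom not in genome.chrom_sizes:
            raise ValueError(f"island on unknown chromosome {chrom}")
        mid = (int(r["start"]) + int(r["end"])) // 2
        glist = genes_by_chrom.get(chrom, [])
        # precedence search over promoter windows, then gene-body features
        feature = "intergenic"
        sub = win_by_chrom.get(chrom)
        if sub is not None and bool(((sub["start"] <= mid) & (mid < sub["end"])).any()):
            feature = "promoter"
        else:
            best = None
            for g in glist:
                f = _classify_in_gene(mid, g)
                if f is not None:
                    rank = FEATURE_CLASSES.index(f)
                    if best is None or rank < best[0] or (rank == best[0] and g.gene_id < best[1]):
                        best = (rank, g.gene_id, f)
            if best is not None:
                feature = best[2]
        feats.append(feature)
        if glist:
            d = np.array([abs(mid - g.tss) for g in glist])
            cand = np.flatnonzero(d == d.min())
            gid = min(glist[i].gene_id for i in cand)
            gsel = genome.by_id[gid]
            signed = (mid - gsel.tss) * (1 if gsel.strand == "+" else -1)
            nearest.append(gid)
            dist.append(int(signed))
        else:
            nearest.append("")
            dist.append(np.nan)
    out = islands.copy()
    out["feature"] = pd.Categorical(feats, categories=FEATURE_CLASSES)
    out["nearest_gene"] = nearest
    out["distance_to_tss"] = dist
    return out


def genomic_distribution(annotated: pd.DataFrame) -> pd.Series:
    """Fraction of islands per feature class (six classes, summing to 1)."""
    if not len(annotated):
        raise ValueError("no annotated peaks")
    counts = annotated["feature"].value_counts().reindex(FEATURE_CLASSES, fill_value=0)
    return counts / counts.sum()


@dataclass
class PromoterGeneSets:
    """Per-stage promoter-modified gene sets with their Venn decomposition."""

    stage_sets: dict[str, set[str]]
    venn: dict[str, set[str]]  # keyed by '&'-joined stage names
    union: set[str]

    @property
    def specific(self) -> dict[str, set[str]]:
        """Genes modified at exactly one stage."""
        return {s: self.venn[s] for s in self.stage_sets}

    def summary(self) -> dict:
        return {
            "per_stage": {s: len(v) for s, v in self.stage_sets.items()},
            "specific": {s: len(v) for s, v in self.specific.items()},
            "venn": {k: len(v) for k, v in self.venn.items()},
            "union": len(self.union),
        }


def promoter_gene_sets(
    stage_islands: dict[str, pd.DataFrame],
    windows: pd.DataFrame,
) -> PromoterGeneSets:
    """Genes with >= 1 retained island midpoint inside their promoter window,
    per stage, with the full Venn decomposition and the across-stage union."""
    stage_sets: dict[str, set[str]] = {}
    for stage, islands in stage_islands.items():
        hit: set[str] = set()
        if len(islands):
            mids = ((islands["start"].to_numpy() + islands["end"].to_numpy()) // 2)
            chroms = islands["chrom"].to_numpy()
            for gid, w in windows.iterrows():
                inside = (chroms == w["chrom"]) & (mids >= w["start"]) & (mids < w["end"])
                if inside.any():
                    hit.add(str(gid))
        stage_sets[stage] = hit
    stages = list(stage_sets)
    venn: dict[str, set[str]] = {}
    for r in range(1, len(stages) + 1):
        for combo in itertools.combinations(stages, r):
            inside = set.intersection(*(stage_sets[s] for s in combo)) if combo else set()
            outside = set.union(set(), *(stage_sets[s] for s in stages if s not in combo))
            venn["&".join(combo)] = inside - outside
    union = set.union(set(), *stage_sets.values())
    assert union == set.union(set(), *venn.values())
    return PromoterGeneSets(stage_sets=stage_sets, venn=venn, union=union)
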