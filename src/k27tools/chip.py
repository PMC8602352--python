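"""ChIP fragment handling: filtering, binning, promoter quantification and meta-profiles.

Conventions
-----------
* Fragments are 0-based half-open intervals; a fragment belongs to a window or
  bin iff its midpoint does (midpoint dialect: unambiguous, conserves totals).
* Promoter density is RPKM: fragments per kb of window per million retained
  fragments in the library.
* The repressive-mark level of a promoter is the IP/input RPKM ratio,
  pseudocount-stabilised with ``eps`` and averaged over replicates
  (ratio-then-average by default; average-then-ratio available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome

log = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "BinnedTrack",
    "filter_fragments",
    "bin_counts",
    "promoter_rpkm",
    "h3k27me3_level",
    "tss_profile",
    "scaled_metagene",
    "write_bedgraph",
]


@dataclass
class FragmentSet:
    """One sample's aligned fragment intervals after filtering."""

    df: pd.DataFrame  # columns: chrom, start, end [, mapq]
    stage: str = ""
    replicate: int = 0
    channel: str = "IP"
    n_malformed: int = 0
    n_lowmapq: int = 0
    n_duplicates: int = 0

    @property
    def library_size(self) -> int:
        return len(self.df)

    @property
    def label(self) -> str:
        return f"{self.stage}_r{self.replicate + 1}_{self.channel}"

    def midpoints_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted fragment midpoints per chromosome (integer division)."""
        out: dict[str, np.ndarray] = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
            mids.sort()
            out[str(chrom)] = mids
        return out


@dataclass
class BinnedTrack:
    """Per-chromosome window counts on a fixed grid of width ``w``."""

    w: int
    counts: dict[str, np.ndarray]
    channel: str = ""
    library_size: int = 0

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def filter_fragments(
    raw: pd.DataFrame,
    mapq_min: int = 20,
    *,
    stage: str = "",
    replicate: int = 0,
    channel: str = "IP",
) -> FragmentSet:
    """Apply the read-level filters: drop malformed intervals, fragments with
    MAPQ below ``mapq_min``, and exact-coordinate duplicates.

    A missing ``mapq`` column means every fragment passes the MAPQ filter
    (logged). Duplicates are rows identical on (chrom, start, end) and strand
    when a strand column is present.
    """
    df = raw.copy()
    ok = df["start"] < df["end"]
    n_malformed = int((~ok).sum())
    if n_malformed:
        log.warning("rejected %d malformed intervals (start >= end)", n_malformed)
        df = df[ok]
    if "mapq" in df.columns:
        keep = df["mapq"] >= mapq_min
        n_lowmapq = int((~keep).sum())
        df = df[keep]
    else:
        n_lowmapq = 0
        log.info("no MAPQ column: all fragments pass the MAPQ filter")
    dup_cols = [c for c in ("chrom", "start", "end", "strand") if c in df.columns]
    before = len(df)
    df = df.drop_duplicates(subset=dup_cols)
    n_dup = before - len(df)
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return FragmentSet(df, stage=stage, replicate=replicate, channel=channel,
                       n_malformed=n_malformed, n_lowmapq=n_lowmapq, n_duplicates=n_dup)


def bin_counts(fs: FragmentSet, chrom_sizes: dict[str, int], w: int = 200) -> BinnedTrack:
    """Count fragments into fixed windows of width ``w`` by midpoint.

    Every fragment lands in exactly one bin; the last bin of a chromosome may
    be short. Fragments beyond the chromosome end are an error.
    """
    counts: dict[str, np.ndarray] = {
        c: np.zeros(int(np.ceil(L / w)), dtype=np.int64) for c, L in chrom_sizes.items()
    }
    for chrom, sub in fs.df.groupby("chrom", sort=True):
        chrom = str(chrom)
        if chrom not in chrom_sizes:
            raise ValueError(f"fragment on unknown chromosome {chrom}")
        if int(sub["end"].max()) > chrom_sizes[chrom]:
            raise ValueError(f"fragment beyond end of {chrom}")
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        counts[chrom] += np.bincount(mids // w, minlength=len(counts[chrom]))
    return BinnedTrack(w=w, counts=counts, channel=fs.channel, library_size=fs.library_size)


def write_bedgraph(track: BinnedTrack, chrom_sizes: dict[str, int], path,
                   normalise: bool = True) -> None:
    """Write a binned track as bedGraph; values are counts per million
    retained fragments when ``normalise`` is set, raw counts otherwise.
    Zero-valued runs are skipped."""
    scale = 1e6 / track.library_size if (normalise and track.library_size) else 1.0
    with open(path, "w") as fh:
        for chrom, counts in track.counts.items():
            L = chrom_sizes[chrom]
            for i in np.flatnonzero(counts):
                start = int(i) * track.w
                fh.write(f"{chrom}\t{start}\t{min(start + track.w, L)}\t"
                         f"{counts[i] * scale:.6g}\n")


def _window_counts(fs: FragmentSet, windows: pd.DataFrame) -> pd.Series:
    """Fragments (by midpoint) per window; ``windows`` has chrom/start/end, gene index."""
    mids = fs.midpoints_by_chrom()
    out = pd.Series(0, index=windows.index, dtype=np.int64)
    for chrom, sub in windows.groupby("chrom", sort=False):
        m = mids.get(str(chrom), np.empty(0, dtype=np.int64))
        lo = np.searchsorted(m, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(m, sub["end"].to_numpy(), side="left")
        out.loc[sub.index] = hi - lo
    return out


def promoter_rpkm(fs: FragmentSet, windows: pd.DataFrame) -> pd.Series:
    """Promoter fragment density in RPKM.

    ``RPKM_g = n_g / (L_g/1000 * library_size/10^6)`` with ``n_g`` the number
    of fragments whose midpoint lies in gene g's promoter window of length
    ``L_g``.
    """
    if fs.library_size == 0:
        raise ValueError("empty library: RPKM undefined")
    n = _window_counts(fs, windows).astype(float)
    L_kb = (windows["end"] - windows["start"]).astype(float) / 1e3
    return n / (L_kb * fs.library_size / 1e6)


def h3k27me3_level(
    ip_rpkm: pd.DataFrame,
    input_rpkm: pd.DataFrame,
    eps: float = 0.1,
    mode: str = "ratio_then_average",
) -> pd.Series:
    """Promoter mark level: pseudocount-stabilised IP/input ratio averaged
    over index-paired replicates.

    ``ip_rpkm`` and ``input_rpkm`` are genes x replicates; replicate r of IP is
    paired with replicate r of input.
    """
    if ip_rpkm.shape != input_rpkm.shape:
        raise ValueError("replicate count mismatch between IP and input")
    ip = ip_rpkm.to_numpy(dtype=float)
    inp = input_rpkm.to_numpy(dtype=float)
    if mode == "ratio_then_average":
        level = ((ip + eps) / (inp + eps)).mean(axis=1)
    elif mode == "average_then_ratio":
        level = (ip.mean(axis=1) + eps) / (inp.mean(axis=1) + eps)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(level, index=ip_rpkm.index, name="level")


def _pooled_mids(sets: list[FragmentSet]) -> tuple[dict[str, np.ndarray], int]:
    mids: dict[str, list[np.ndarray]] = {}
    lib = 0
    for fs in sets:
        lib += fs.library_size
        for chrom, m in fs.midpoints_by_chrom().items():
            mids.setdefault(chrom, []).append(m)
    pooled = {c: np.sort(np.concatenate(v)) for c, v in mids.items()}
    return pooled, lib


def _gene_bin_counts(mids: dict[str, np.ndarray], genome: Genome, gene_ids: list[str],
                     edge_fn) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene counts and bin widths on gene-specific (ascending) edges.

    ``edge_fn(gene) -> ndarray`` of genomic bin edges. Counts are reversed for
    minus-strand genes so that column 0 is the gene's 5'-most bin.
    """
    n_bins = len(edge_fn(genome.by_id[gene_ids[0]])) - 1
    counts = np.zeros((len(gene_ids), n_bins), dtype=float)
    widths = np.zeros_like(counts)
    for i, gid in enumerate(gene_ids):
        g = genome.by_id[gid]
        edges = edge_fn(g)
        m = mids.get(g.chrom, np.empty(0, dtype=np.int64))
        c = np.diff(np.searchsorted(m, edges, side="left")).astype(float)
        wdt = np.diff(edges).astype(float)
        if g.strand == "-":
            c = c[::-1]
            wdt = wdt[::-1]
        counts[i] = c
        widths[i] = wdt
    return counts, widths


def _log2_ratio_curves(ip_counts, ip_widths, ip_lib, in_counts, in_widths, in_lib, eps):
    ipd = ip_counts / (ip_widths / 1e3) / (ip_lib / 1e6)
    ind = in_counts / (in_widths / 1e3) / (in_lib / 1e6)
    return np.log2((ipd + eps) / (ind + eps))


def tss_profile(
    ip_sets: list[FragmentSet],
    input_sets: list[FragmentSet],
    genome: Genome,
    strata: pd.Series,
    flank: int = 5000,
    profile_bin: int = 100,
    eps: float = 0.1,
) -> pd.DataFrame:
    """Strand-oriented TSS-anchored enrichment profile per expression class.

    Returns a DataFrame (class x position) of the mean, over genes in the
    class, of the library-normalised log2 IP/input density ratio in
    ``profile_bin``-bp bins across ``[-flank, +flank)`` around the TSS
    (upstream on the left for both strands). Replicates are pooled.
    """
    if 2 * flank % profile_bin:
        raise ValueError("2*flank must be a multiple of profile_bin")
    ip_mids, ip_lib = _pooled_mids(ip_sets)
    in_mids, in_lib = _pooled_mids(input_sets)
    rel = np.arange(-flank, flank + 1, profile_bin)
    gene_ids = [g.gene_id for g in genome.genes if g.gene_id in strata.index]

    def edges(g):
        return g.tss + rel

    ipc, ipw = _gene_bin_counts(ip_mids, genome, gene_ids, edges)
    inc, inw = _gene_bin_counts(in_mids, genome, gene_ids, edges)
    curves = _log2_ratio_curves(ipc, ipw, ip_lib, inc, inw, in_lib, eps)
    pos = rel[:-1] + profile_bin // 2
    mat = pd.DataFrame(curves, index=gene_ids, columns=pos)
    rows = {}
    for cls, sub in mat.groupby(strata.loc[gene_ids]):
        if len(sub) == 0:
            log.warning("empty stratum %s omitted from TSS profile", cls)
            continue
        rows[cls] = sub.mean(axis=0)
    return pd.DataFrame(rows).T


def scaled_metagene(
    ip_sets: list[FragmentSet],
    input_sets: list[FragmentSet],
    genome: Genome,
    flank: int = 2000,
    profile_bin: int = 100,
    n_body_bins: int = 30,
    eps: float = 0.1,
    gene_ids: list[str] | None = None,
) -> tuple[pd.Series, int]:
    """TSS->TES meta-profile: fixed-bp flanks, gene body rescaled to
    ``n_body_bins`` equal-width bins; mean log2 IP/input density ratio over
    genes. Genes shorter than ``n_body_bins`` bp are skipped (count returned).
    """
    ip_mids, ip_lib = _pooled_mids(ip_sets)
    in_mids, in_lib = _pooled_mids(input_sets)
    if gene_ids is None:
        gene_ids = [g.gene_id for g in genome.genes]
    usable = [gid for gid in gene_ids if genome.by_id[gid].length >= n_body_bins]
    n_skipped = len(gene_ids) - len(usable)
    if n_skipped:
        log.info("skipped %d genes shorter than %d bp", n_skipped, n_body_bins)
    n_flank = flank // profile_bin
    up = np.arange(-n_flank, 0) * profile_bin  # offsets of left-flank edges
    down = np.arange(1, n_flank + 1) * profile_bin

    def edges(g):
        body = np.linspace(g.start, g.end, n_body_bins + 1)
        return np.concatenate([g.start + up, body, g.end + down])

    labels = (
        [f"up{i}" for i in range(n_flank, 0, -1)]
        + [f"body{i}" for i in range(1, n_body_bins + 1)]
        + [f"down{i}" for i in range(1, n_flank + 1)]
    )
    if not usable:
        return pd.Series(np.nan, index=labels, name="log2_ratio"), n_skipped
    ipc, ipw = _gene_bin_counts(ip_mids, genome, usable, edges)
    inc, inw = _gene_bin_counts(in_mids, genome, usable, edges)
    curves = _log2_ratio_curves(ipc, ipw, ip_lib, inc, inw, in_lib, eps)
    return pd.Series(curves.mean(axis=0), index=labels, name="log2_ratio"), n_skipped
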