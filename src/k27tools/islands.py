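"""Broad-domain ("island") calling for diffuse histone marks.

The caller scores gap-tolerant runs of Poisson-enriched windows of IP signal
against the input channel:

1. ``eligible_windows`` — a window with k fragments is eligible iff
   ``P(X >= k | Poisson(lambda_w)) <= p0`` and ``k >= 1``, where ``lambda_w``
   is the genome-wide expected IP count per window.
2. ``merge_islands`` — maximal runs of eligible windows tolerating up to
   ``gap`` consecutive ineligible windows inside; candidates start and end on
   eligible windows.
3. ``score_islands`` — each candidate's IP count is tested against an
   input-scaled expectation (with a background floor), giving a Poisson upper
   tail p, a fold enrichment, and a BH q over all candidates.

Retained islands satisfy ``q <= q_max`` and ``fold > 1``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .chip import BinnedTrack, FragmentSet, bin_counts
from .stats import bh_adjust, poisson_tail

log = logging.getLogger(__name__)

__all__ = ["eligible_windows", "merge_islands", "score_islands", "call_islands"]

ISLAND_COLUMNS = ["chrom", "start", "end", "ip_count", "input_count", "expected", "fold", "p", "q"]


def eligible_windows(ip_track: BinnedTrack, lam: float, p0: float = 0.2) -> dict[str, np.ndarray]:
    """Boolean eligibility mask per chromosome (see module docstring)."""
    if lam <= 0:
        raise ValueError("expected per-window count must be positive")
    masks = {}
    for chrom, counts in ip_track.counts.items():
        masks[chrom] = (counts >= 1) & (poisson_tail(counts, lam) <= p0)
    return masks


def merge_islands(mask: np.ndarray, gap_windows: int = 3) -> list[tuple[int, int]]:
    """Merge eligible windows into candidate runs tolerating up to
    ``gap_windows`` consecutive ineligible windows inside a run.

    Returns half-open window-index intervals; each candidate starts and ends
    on an eligible window.
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > gap_windows + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def score_islands(
    candidates: dict[str, list[tuple[int, int]]],
    ip_track: BinnedTrack,
    input_track: BinnedTrack,
    chrom_sizes: dict[str, int],
    floor_factor: float = 1.25,
    effective_fraction: float = 1.0,
) -> pd.DataFrame:
    """Score window-grid candidates: input-scaled expectation, Poisson p, fold, BH q."""
    if ip_track.library_size <= 0 or input_track.library_size <= 0:
        raise ValueError("both channels need a positive library size")
    w = ip_track.w
    genome_len = sum(chrom_sizes.values()) * effective_fraction
    scale = ip_track.library_size / input_track.library_size
    ip_rate_bp = ip_track.library_size / genome_len  # fragments per bp
    rows = []
    for chrom, runs in candidates.items():
        ipc = ip_track.counts[chrom]
        inc = input_track.counts[chrom]
        L = chrom_sizes[chrom]
        for a, b in runs:
            start, end = a * w, min(b * w, L)
            ip_n = int(ipc[a:b].sum())
            in_n = int(inc[a:b].sum())
            expected = max(in_n * scale, floor_factor * (end - start) * ip_rate_bp)
            rows.append((chrom, start, end, ip_n, in_n, expected,
                         ip_n / expected, float(poisson_tail(ip_n, expected))))
    df = pd.DataFrame(rows, columns=ISLAND_COLUMNS[:-1])
    if len(df):
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def call_islands(
    ip: FragmentSet,
    input_: FragmentSet,
    chrom_sizes: dict[str, int],
    w: int = 200,
    gap: int = 3,
    p0: float = 0.2,
    q_max: float = 0.05,
    floor_factor: float = 1.25,
    effective_fraction: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full broad-domain call: bin -> eligibility -> merge -> score -> filter.

    Returns ``(retained, candidates)``; retained islands satisfy
    ``q <= q_max`` and ``fold > 1``, sorted by coordinate.
    """
    empty = pd.DataFrame(columns=ISLAND_COLUMNS)
    if ip.library_size == 0:
        log.warning("empty IP fragment set: no islands called")
        return empty.copy(), empty.copy()
    ip_track = bin_counts(ip, chrom_sizes, w)
    in_track = bin_counts(input_, chrom_sizes, w)
    genome_len = sum(chrom_sizes.values()) * effective_fraction
    lam = ip.library_size * w / genome_len
    masks = eligible_windows(ip_track, lam, p0)
    candidates = {c: merge_islands(m, gap) for c, m in masks.items()}
    scored = score_islands(candidates, ip_track, in_track, chrom_sizes,
                           floor_factor, effective_fraction)
    if not len(scored):
        return empty.copy(), scored
    retained = scored[(scored["q"] <= q_max) & (scored["fold"] > 1.0)]
    retained = retained.sort_values(["chrom", "start"]).reset_index(drop=True)
    assert bool(((retained["q"] <= q_max) & (retained["fold"] > 1.0)).all())
    return retained, scored


def pool_fragments(sets: list[FragmentSet], stage: str = "", channel: str = "") -> FragmentSet:
    """Pool replicate fragment sets (stage-level calling uses pooled replicates)."""
    df = pd.concat([fs.df for fs in sets], ignore_index=True)
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return FragmentSet(df, stage=stage, channel=channel or sets[0].channel)


def write_islands_bed(islands: pd.DataFrame, path) -> None:
    """Write retained islands as BED6+ (score = -10*log10 q, capped at 1000)."""
    with open(path, "w") as fh:
        for i, r in islands.reset_index(drop=True).iterrows():
            score = min(1000.0, -10.0 * np.log10(max(r["q"], 1e-100)))
            fh.write(
                f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\tisland_{i + 1}\t"
                f"{score:.1f}\t.\t{int(r['ip_count'])}\t{r['expected']:.3f}\t"
                f"{r['fold']:.4f}\t{r['p']:.4g}\t{r['q']:.4g}\n"
            )
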