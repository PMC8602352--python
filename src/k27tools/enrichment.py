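"""Gene-set enrichment: hypergeometric over-representation (ORA) with the
fold-enrichment statistic, and a weighted running-sum GSEA with a gene-label
permutation null.

Fold enrichment is the proportion of a set's genes in the query list divided
by its proportion in the background: ``(k/n) / (K/N)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, hypergeom_tail

log = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "read_gmt", "fold_enrichment", "ora_test", "gsea"]


@dataclass
class GeneSetCollection:
    """Named gene sets with the background universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str]

    def effective_sets(self) -> dict[str, set[str]]:
        """Sets intersected with the universe; empty results are skipped (logged)."""
        out = {}
        for name, members in self.sets.items():
            eff = members & self.universe
            if not eff:
                log.warning("gene set %s has no members in the universe; skipped", name)
                continue
            out[name] = eff
        return out


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, tab-separated name, description, members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description] + sorted(members)) + "\n")


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """``(k/n) / (K/N)``: list proportion over background proportion."""
    if n <= 0 or N <= 0:
        raise ValueError("list and background must be nonempty")
    if K <= 0:
        raise ValueError("set has no background members; fold enrichment undefined")
    return (k / n) / (K / N)


def ora_test(gene_list, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    Genes outside the universe are dropped (logged); p is the inclusive upper
    tail P(X >= k); q is BH across the tested sets.
    """
    query = set(gene_list)
    dropped = query - collection.universe
    if dropped:
        log.warning("%d query genes outside the background dropped", len(dropped))
        query &= collection.universe
    if not query:
        raise ValueError("empty query list after background intersection")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name, members in collection.effective_sets().items():
        K = len(members)
        k = len(query & members)
        rows.append((name, k, n, K, N, fold_enrichment(k, n, K, N),
                     hypergeom_tail(k, N, K, n)))
    df = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "fold_enrichment", "p"]
                      ).set_index("set")
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else pd.Series(dtype=float)
    return df.sort_values("p")


def _running_sum_es(in_set: np.ndarray, scores: np.ndarray, p: float) -> float:
    """ES of one labelling: extreme deviation of the weighted running sum.

    ``in_set`` is a boolean mask over the (already ranked) gene list.
    """
    w = np.abs(scores) ** p
    hit_tot = w[in_set].sum()
    n_miss = (~in_set).sum()
    if hit_tot == 0:  # all-zero scores inside the set: fall back to equal weights
        w = np.ones_like(w)
        hit_tot = float(in_set.sum())
    steps = np.where(in_set, w / hit_tot, -1.0 / n_miss)
    rs = np.cumsum(steps)
    return float(rs[np.argmax(np.abs(rs))])


def gsea(
    ranked: pd.Series,
    gene_set,
    p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Weighted running-sum gene-set enrichment on a ranked list.

    ``ranked`` maps gene id -> ranking score (sorted internally, descending).
    Hits increment the running sum proportionally to ``|score|^p`` and misses
    decrement by ``1/(N-K)``; ES is the extreme deviation. The null permutes
    gene labels (random K-subsets of the ranked genes); NES divides ES by the
    mean |null ES| of matching sign and the permutation p-value uses +1
    smoothing over same-sign nulls.
    """
    ranked = ranked.sort_values(ascending=False)
    scores = ranked.to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    in_set = ranked.index.isin(set(gene_set)).astype(bool)
    K = int(in_set.sum())
    if K == 0 or K == len(ranked):
        raise ValueError("gene set must overlap the ranked list strictly")
    es = _running_sum_es(in_set, scores, p)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n_genes = len(ranked)
    for i in range(n_perm):
        mask = np.zeros(n_genes, dtype=bool)
        mask[rng.choice(n_genes, size=K, replace=False)] = True
        null[i] = _running_sum_es(mask, scores, p)
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same.size == 0:
        nes, perm_p = np.nan, 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(same))
        perm_p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)
    return {"es": es, "nes": float(nes), "perm_p": float(perm_p), "k": K, "n": n_genes}
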