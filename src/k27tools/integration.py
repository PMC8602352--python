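"""ChIP-RNA integration: transition clusters, the negative-correlation set,
and the HDEG intersection.

For each stage transition, significant DEGs are split by the sign of their
promoter-mark change ``dlevel = log2(level_later / level_earlier)``:

* cluster 1 (first transition) / 3 (second): up-regulated, mark decreasing;
* cluster 2 (first transition) / 4 (second): down-regulated, mark increasing.

The negative-correlation set is the union of genes holding >= 1 cluster
label; intersecting it with the promoter-modified gene universe gives the
HDEGs (DEGs whose promoter mark change opposes their expression change and
that carry a significant promoter domain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["transition_clusters", "negative_correlation_set", "hdeg_set", "IntegrationResult"]


def transition_clusters(
    de_results: dict[str, pd.DataFrame],
    levels: pd.DataFrame,
    delta: float = 0.0,
) -> pd.DataFrame:
    """Per-gene cluster labels from DE calls and promoter-mark levels.

    ``de_results`` maps each transition (in stage order) to a `de_test` frame;
    ``levels`` is genes x stages of epsilon-stabilised promoter levels. A DEG
    enters a cluster only when ``|dlevel| > delta`` with the opposing sign.
    Genes tested for DE but missing a promoter level are excluded (logged).
    """
    stages = list(levels.columns)
    transitions = list(de_results)
    if len(transitions) != len(stages) - 1:
        raise ValueError("need one DE result per successive stage pair")
    genes = sorted(set().union(*(df.index for df in de_results.values())))
    missing = [g for g in genes if g not in levels.index]
    if missing:
        log.warning("%d DE-tested genes lack promoter signal; excluded", len(missing))
        genes = [g for g in genes if g in levels.index]
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    cluster_sets: list[set] = []
    for t, tr in enumerate(transitions):
        df = de_results[tr]
        lev_a = levels.loc[genes, stages[t]].to_numpy(dtype=float)
        lev_b = levels.loc[genes, stages[t + 1]].to_numpy(dtype=float)
        dlevel = np.log2(lev_b / lev_a)
        sig = df["is_deg"].reindex(genes, fill_value=False).to_numpy()
        lfc = df["log2fc"].reindex(genes).to_numpy()
        up_cluster = sig & (lfc > 0) & (dlevel < -delta)
        down_cluster = sig & (lfc < 0) & (dlevel > delta)
        out[f"is_deg_{tr}"] = sig
        out[f"log2fc_{tr}"] = lfc
        out[f"dlevel_{tr}"] = dlevel
        out[f"cluster{2 * t + 1}"] = up_cluster
        out[f"cluster{2 * t + 2}"] = down_cluster
        cluster_sets += [set(out.index[up_cluster]), set(out.index[down_cluster])]
    out["n_clusters"] = sum(out[c] for c in out.columns if c.startswith("cluster"))
    out.attrs["cluster_sizes"] = {f"cluster{i + 1}": len(s) for i, s in enumerate(cluster_sets)}
    return out


def negative_correlation_set(clusters: pd.DataFrame) -> set[str]:
    """Genes holding at least one transition-cluster label."""
    cols = [c for c in clusters.columns if c.startswith("cluster") and c != "n_clusters"]
    mask = clusters[cols].any(axis=1)
    return set(clusters.index[mask])


@dataclass
class IntegrationResult:
    """HDEG call with its supporting sets and the per-gene record table."""

    hdegs: set[str]
    negcorr: set[str]
    modified: set[str]
    degs: set[str]
    discordant: set[str]  # modified DEGs outside the negative-correlation set
    records: pd.DataFrame = field(default=None)

    def audit(self) -> None:
        """Set-logic invariants asserted on every run."""
        assert self.hdegs <= self.negcorr <= self.degs
        assert self.hdegs <= self.modified
        assert self.discordant.isdisjoint(self.negcorr)

    def summary(self) -> dict:
        return {
            "n_deg": len(self.degs),
            "n_negcorr": len(self.negcorr),
            "n_modified": len(self.modified),
            "n_hdeg": len(self.hdegs),
            "n_discordant_modified_deg": len(self.discordant),
        }


def hdeg_set(
    clusters: pd.DataFrame,
    modified: set[str],
) -> IntegrationResult:
    """Intersect the negative-correlation set with the promoter-modified
    universe; also report the discordant class (modified DEGs that are not
    negatively correlated)."""
    negcorr = negative_correlation_set(clusters)
    deg_cols = [c for c in clusters.columns if c.startswith("is_deg_")]
    degs = set(clusters.index[clusters[deg_cols].any(axis=1)])
    universe = set(clusters.index)
    if modified and universe and not (modified & universe):
        raise ValueError("promoter-modified set shares no gene ids with the DE universe")
    hdegs = negcorr & modified
    discordant = (modified & degs) - negcorr
    rec = clusters.copy()
    rec["negcorr"] = rec.index.isin(negcorr)
    rec["modified"] = rec.index.isin(modified)
    rec["hdeg"] = rec.index.isin(hdegs)
    res = IntegrationResult(hdegs=hdegs, negcorr=negcorr, modified=set(modified),
                            degs=degs, discordant=discordant, records=rec)
    res.audit()
    return res
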