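"""Expression quantification, classification and differential testing.

TPM normalisation, the expressed-gene rule (TPM >= 0.5 in at least one
sample), per-stage quartile classes (high / medium / low / silent), a
negative-binomial Wald test between successive stages, DEG calling at
``padj <= 0.05`` and ``|log2FC| >= 1``, stage-maximal DEG assignment,
level-transition flow tables, and the 2^-ddCt qPCR utility.

The DE engine
-------------
A deliberately compact NB fixed-dispersion Wald test:

* size factors by median-of-ratios over genes nonzero in every sample;
* per-gene method-of-moments dispersion from the pooled within-group variance
  of normalised counts, shrunk 50/50 toward a ``a0 + a1/mu`` trend fitted
  across genes;
* per-group NB mean MLE by Newton iteration; the Wald SE from the Fisher
  information is inflated by ``sqrt(nu/(nu-2))`` with
  ``nu = residual df / shrink_weight^2`` to absorb dispersion-estimation
  noise (see docs/methods.md for the calibration argument);
* reported log2FC is the ratio of size-factor-normalised group means with a
  0.5 pseudocount; BH adjustment over tested genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .stats import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ExpressionTable",
    "tpm",
    "classify_expression",
    "size_factors",
    "deg_rule",
    "de_test",
    "call_degs",
    "stage_max_assignment",
    "level_transition_table",
    "relative_expression",
]

LEVELS = ["high", "medium", "low", "silent"]


@dataclass
class CountMatrix:
    """Gene x sample integer counts with exonic gene lengths and sample labels."""

    counts: pd.DataFrame  # genes x samples, non-negative ints
    lengths: pd.Series  # bp per gene
    samples: pd.DataFrame  # index sample id; columns: stage, replicate

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("missing gene lengths")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if list(self.samples.index) != list(self.counts.columns):
            raise ValueError("sample metadata does not match count columns")

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.samples["stage"]))

    def stage_columns(self, stage: str) -> list[str]:
        return list(self.samples.index[self.samples["stage"] == stage])

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, lengths: pd.Series, samples: pd.DataFrame | None = None
                 ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if samples is None:
            # sample ids of the form <stage>_r<k>
            stage = [c.rsplit("_r", 1)[0] for c in df.columns]
            rep = [int(c.rsplit("_r", 1)[1]) - 1 for c in df.columns]
            samples = pd.DataFrame({"stage": stage, "replicate": rep}, index=df.columns)
        return cls(df, lengths, samples)


@dataclass
class ExpressionTable:
    """Per-gene expression summary: stage means, expressed flag, level classes."""

    stage_mean: pd.DataFrame  # genes x stages, mean TPM over replicates
    expressed: pd.Series  # bool per gene (global rule)
    levels: pd.DataFrame  # genes x stages, one of LEVELS
    quartiles: pd.DataFrame = field(default=None)  # stages x (q1, q3)

    @property
    def stages(self) -> list[str]:
        return list(self.stage_mean.columns)


def deg_rule(padj, log2fc, padj_max: float = 0.05, lfc_min: float = 1.0):
    """The DEG decision: ``padj <= padj_max`` and ``|log2FC| >= lfc_min``,
    both thresholds inclusive."""
    return (np.asarray(padj) <= padj_max) & (np.abs(np.asarray(log2fc)) >= lfc_min)


def tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts per kilobase million; every nonzero sample column sums to 1e6."""
    rate = cm.counts.div(cm.lengths / 1e3, axis=0)
    tot = rate.sum(axis=0)
    zero = tot == 0
    if zero.any():
        log.warning("all-zero samples: %s", list(tot.index[zero]))
        tot = tot.replace(0, np.nan)
    out = rate.div(tot, axis=1) * 1e6
    return out.fillna(0.0)


def stage_mean(values: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean per stage over replicate columns, preserving stage order."""
    stages = list(dict.fromkeys(samples["stage"]))
    return pd.DataFrame(
        {s: values[samples.index[samples["stage"] == s]].mean(axis=1) for s in stages}
    )


def classify_expression(
    tpm_df: pd.DataFrame,
    samples: pd.DataFrame,
    expressed_threshold: float = 0.5,
    quantile_method: str = "linear",
) -> ExpressionTable:
    """Expressed/silent flag and per-stage quartile classes.

    A gene is expressed iff its TPM reaches ``expressed_threshold`` in at
    least one sample of any stage; otherwise it is silent at every stage.
    Within each stage, quartiles of the stage-mean TPM of expressed genes
    split them into high (>= Q3), low (<= Q1) and medium (strictly between).
    """
    expressed = (tpm_df >= expressed_threshold).any(axis=1)
    if int(expressed.sum()) < 4:
        raise ValueError("fewer than 4 expressed genes: quartiles undefined")
    sm = stage_mean(tpm_df, samples)
    levels = pd.DataFrame("silent", index=sm.index, columns=sm.columns)
    qs = {}
    for s in sm.columns:
        vals = sm.loc[expressed, s]
        q1, q3 = np.quantile(vals.to_numpy(), [0.25, 0.75], method=quantile_method)
        qs[s] = (q1, q3)
        lab = np.where(vals >= q3, "high", np.where(vals <= q1, "low", "medium"))
        levels.loc[expressed, s] = lab
    quart = pd.DataFrame(qs, index=["q1", "q3"]).T
    return ExpressionTable(stage_mean=sm, expressed=expressed, levels=levels, quartiles=quart)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = per-gene geometric mean over
    genes with no zero count in any sample)."""
    arr = counts.to_numpy(dtype=float)
    ok = (arr > 0).all(axis=1)
    if not ok.any():
        raise ValueError("no gene with nonzero counts in all samples")
    logc = np.log(arr[ok])
    logratio = logc - logc.mean(axis=1, keepdims=True)
    return pd.Series(np.exp(np.median(logratio, axis=0)), index=counts.columns,
                     name="size_factor")


def _mom_dispersion(q: np.ndarray, sf: np.ndarray, group_idx: list[np.ndarray]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-group method-of-moments dispersion on normalised counts.

    Var(y/s) = mu * E[1/s] + alpha * mu^2  =>  alpha from the excess variance.
    """
    var_w = np.zeros(q.shape[0])
    for idx in group_idx:
        var_w += q[:, idx].var(axis=1, ddof=1)
    var_w /= len(group_idx)
    m = q.mean(axis=1)
    pois = m * np.mean(1.0 / sf)
    alpha = (var_w - pois) / np.maximum(m, 1e-8) ** 2
    return m, np.clip(alpha, 1e-8, 10.0)


def _dispersion_trend(m: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mu across genes, evaluated at each mu."""
    ok = m > 1
    if ok.sum() < 10:
        ok = m > 0
    X = np.column_stack([np.ones(int(ok.sum())), 1.0 / m[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha[ok], rcond=None)
    a0, a1 = max(float(coef[0]), 1e-8), max(float(coef[1]), 0.0)
    return a0 + a1 / np.maximum(m, 1e-8)


def _nb_group_mle(y: np.ndarray, s: np.ndarray, alpha: np.ndarray, iters: int = 50
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene NB mean MLE for one group (Newton) and its Fisher information.

    Solves ``sum_j (y_j - s_j mu) / (1 + alpha s_j mu) = 0`` for mu.
    """
    mu = np.maximum((y / s).mean(axis=1), 1e-8)
    for _ in range(iters):
        smu = s[None, :] * mu[:, None]
        denom = 1.0 + alpha[:, None] * smu
        f = ((y - smu) / denom).sum(axis=1)
        fp = (-s[None, :] * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
        mu = np.maximum(mu - f / fp, 1e-10)
    smu = s[None, :] * mu[:, None]
    info = (smu / (1.0 + alpha[:, None] * smu)).sum(axis=1)
    return mu, info


def de_test(
    cm: CountMatrix,
    stage_a: str,
    stage_b: str,
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
    shrink_weight: float = 0.5,
    pseudocount: float = 0.5,
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """NB Wald differential test of ``stage_b`` vs ``stage_a``.

    Positive log2FC means higher in the later stage (``stage_b``). Genes with
    zero counts in every sample of both stages are excluded from testing;
    pass ``genes`` to restrict the tested universe (e.g. expressed genes).
    Returns a per-gene frame with base means, log2FC, p, BH padj and the DEG
    flag at ``padj <= padj_max`` and ``|log2FC| >= lfc_min`` (inclusive).
    """
    cols_a, cols_b = cm.stage_columns(stage_a), cm.stage_columns(stage_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each stage needs at least 2 replicates")
    sub = cm.counts[cols_a + cols_b]
    if genes is not None:
        sub = sub.loc[sub.index.intersection(genes)]
    sub = sub.loc[sub.sum(axis=1) > 0]
    y = sub.to_numpy(dtype=float)
    sf = size_factors(sub).to_numpy()
    q = y / sf
    ia = np.arange(len(cols_a))
    ib = np.arange(len(cols_a), len(cols_a) + len(cols_b))
    m, a_raw = _mom_dispersion(q, sf, [ia, ib])
    alpha = shrink_weight * a_raw + (1 - shrink_weight) * _dispersion_trend(m, a_raw)
    mu_a, info_a = _nb_group_mle(y[:, ia], sf[ia], alpha)
    mu_b, info_b = _nb_group_mle(y[:, ib], sf[ib], alpha)
    # effective dispersion df: residual df scaled by the inverse squared shrink weight
    nu = (len(cols_a) + len(cols_b) - 2) / shrink_weight**2
    se = np.sqrt((1.0 / info_a + 1.0 / info_b) * nu / (nu - 2))
    z = (np.log(mu_b) - np.log(mu_a)) / se
    p = 2.0 * _st.norm.sf(np.abs(z))
    mean_a, mean_b = q[:, ia].mean(axis=1), q[:, ib].mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    padj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "log2fc": lfc,
            "stat": z,
            "p": p,
            "padj": padj,
            "is_deg": deg_rule(padj, lfc, padj_max, lfc_min),
        },
        index=sub.index,
    )
    out.attrs["transition"] = f"{stage_a}->{stage_b}"
    return out


def call_degs(de_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union DEG table over transitions with per-transition direction.

    Direction per transition is 'up' / 'down' for significant genes and
    'none' otherwise; a gene is a DEG if significant in >= 1 transition.
    """
    genes = sorted(set().union(*(df.index for df in de_results.values())))
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    any_deg = pd.Series(False, index=out.index)
    for tr, df in de_results.items():
        sig = df["is_deg"].reindex(out.index, fill_value=False)
        direction = pd.Series("none", index=out.index)
        direction[sig & (df["log2fc"].reindex(out.index) > 0)] = "up"
        direction[sig & (df["log2fc"].reindex(out.index) < 0)] = "down"
        out[f"direction_{tr}"] = direction
        any_deg |= sig
    out["is_deg"] = any_deg
    return out


def stage_max_assignment(expr: ExpressionTable, deg_genes) -> pd.Series:
    """Assign each DEG to the stage of its maximal stage-mean TPM (ties to the
    earliest stage). The result partitions the DEG set."""
    sm = expr.stage_mean.loc[list(deg_genes)]
    idx = sm.to_numpy().argmax(axis=1)  # argmax takes the first maximum
    return pd.Series([expr.stages[i] for i in idx], index=sm.index, name="stage_max")


def level_transition_table(
    expr: ExpressionTable, deg_genes, stage_a: str, stage_b: str
) -> pd.DataFrame:
    """4x4 flow matrix of DEG level classes from ``stage_a`` to ``stage_b``."""
    sub = expr.levels.loc[list(deg_genes)]
    tab = pd.crosstab(sub[stage_a], sub[stage_b])
    return tab.reindex(index=LEVELS, columns=LEVELS, fill_value=0)


def relative_expression(dct_treated: float, dct_control: float) -> float:
    """Relative expression by the 2^-ddCt method."""
    if not (np.isfinite(dct_treated) and np.isfinite(dct_control)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-(dct_treated - dct_control)))
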