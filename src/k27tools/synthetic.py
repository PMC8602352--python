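"""Synthetic miniature dataset generator with a ground-truth manifest.

Emulates the study design the pipeline targets: a small multi-chromosome
genome with gene models; IP/input ChIP fragment sets per stage and replicate
containing planted broad enriched domains over a homogeneous Poisson
background; and negative-binomial RNA count matrices with planted fold
changes. A configurable subset of genes are true HDEGs — their expression
change at one stage transition is anti-coupled to the presence change of a
broad domain planted over their promoter — plus decoys violating the
coupling (half expression-shift-only with no planted promoter domain, half
domain-flip-only with no expression shift).

All generators are deterministic under (config, seed): each output sample
draws from its own RNG stream derived from the master seed by a stable
hashed label, so adding a sample never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chip import FragmentSet
from .expression import CountMatrix
from .genome import GeneModel, Genome, write_chrom_sizes, write_gtf

__all__ = ["SyntheticConfig", "GroundTruth", "generate_genome", "generate_chip",
           "generate_counts", "generate_dataset", "write_dataset", "stage_names"]


def substream(seed: int, *labels) -> np.random.Generator:
    """RNG for a labelled substream of the master seed (stable across runs)."""
    digest = hashlib.sha256("/".join(map(str, labels)).encode()).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *words]))


def stage_names(n_stages: int) -> list[str]:
    """Stage labels; the canonical three-stage design uses gestational days."""
    if n_stages == 3:
        return ["d33", "d65", "d90"]
    return [f"s{i + 1}" for i in range(n_stages)]


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic dataset (defaults = the design the
    pipeline's recovery properties are stated under)."""

    n_chroms: int = 4
    chrom_length: int = 15_000_000
    n_genes: int = 2000
    n_stages: int = 3
    reps_chip: int = 2  # per channel
    reps_rna: int = 3
    bg_rate: float = 0.01  # Poisson background, fragments per bp
    domain_fold: float = 8.0
    domain_width: int = 10_000
    n_true_hdegs: int = 100
    n_decoys: int = 100
    lfc_planted: float = 2.0
    nb_dispersion: float = 0.05
    depth_sigma: float = 0.15  # lognormal sd of per-sample RNA depth factors
    frag_len: int = 150
    frac_lowmapq: float = 0.05
    dup_frac: float = 0.05
    frac_silent: float = 0.15
    n_background_domains: int = 20  # constant intergenic domains
    class_domain_prob: tuple[float, float, float, float] | None = None  # (high, med, low, silent)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_hdegs + self.n_decoys > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if self.domain_fold < 1:
            raise ValueError("domain_fold must be >= 1")
        for f in ("n_chroms", "chrom_length", "n_genes", "n_stages", "reps_chip",
                  "reps_rna", "domain_width", "frag_len"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.bg_rate < 0:
            raise ValueError("bg_rate must be non-negative")

    @property
    def stages(self) -> list[str]:
        return stage_names(self.n_stages)


@dataclass
class GroundTruth:
    """Planted structure: domains, expression shifts, and the true gene classes."""

    planted_domains: pd.DataFrame  # chrom, start, end, presence (tuple), gene_id, kind
    planted_degs: dict[str, tuple[int, int, float]]  # gene -> (transition, sign, lfc)
    true_hdegs: set[str]
    decoys_expression: set[str]
    decoys_domain: set[str]
    silent_genes: set[str] = field(default_factory=set)

    @property
    def decoys(self) -> set[str]:
        return self.decoys_expression | self.decoys_domain

    def to_json(self, path) -> None:
        doc = {
            "planted_domains": [
                dict(chrom=r.chrom, start=int(r.start), end=int(r.end),
                     presence=list(r.presence), gene_id=r.gene_id, kind=r.kind)
                for r in self.planted_domains.itertuples()
            ],
            "planted_degs": {g: [int(t), int(s), float(l)]
                             for g, (t, s, l) in self.planted_degs.items()},
            "true_hdegs": sorted(self.true_hdegs),
            "decoys_expression": sorted(self.decoys_expression),
            "decoys_domain": sorted(self.decoys_domain),
            "silent_genes": sorted(self.silent_genes),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        dom = pd.DataFrame(doc["planted_domains"]) if doc["planted_domains"] else pd.DataFrame(
            columns=["chrom", "start", "end", "presence", "gene_id", "kind"])
        if len(dom):
            dom["presence"] = dom["presence"].map(tuple)
        return cls(
            planted_domains=dom,
            planted_degs={g: (int(t), int(s), float(l))
                          for g, (t, s, l) in doc["planted_degs"].items()},
            true_hdegs=set(doc["true_hdegs"]),
            decoys_expression=set(doc["decoys_expression"]),
            decoys_domain=set(doc["decoys_domain"]),
            silent_genes=set(doc.get("silent_genes", [])),
        )


# ---------------------------------------------------------------------------
# genome


def generate_genome(cfg: SyntheticConfig) -> Genome:
    """Random non-overlapping gene models on ``n_chroms`` chromosomes.

    Genes are placed in equal slots along each chromosome with a random
    offset, random strand, 2-6 exons, and first/last exon fractions marked as
    UTRs so every annotation class is exercisable.
    """
    rng = substream(cfg.seed, "genome")
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    genes: list[GeneModel] = []
    if cfg.n_genes == 0:
        return Genome(chrom_sizes, genes)
    per_chrom = [cfg.n_genes // cfg.n_chroms + (1 if i < cfg.n_genes % cfg.n_chroms else 0)
                 for i in range(cfg.n_chroms)]
    gid = 0
    for ci, (chrom, n_here) in enumerate(zip(chrom_sizes, per_chrom)):
        if n_here == 0:
            continue
        slot = cfg.chrom_length // n_here
        max_gene_len = min(12_000, slot - 2_000)  # 1 kb margin on both sides
        if max_gene_len < 500:
            raise ValueError(
                f"infeasible packing: {n_here} genes do not fit on a "
                f"{cfg.chrom_length} bp chromosome")
        min_gene_len = max(200, min(2_000, max_gene_len // 2))
        for k in range(n_here):
            gid += 1
            glen = int(rng.integers(min_gene_len, max_gene_len + 1))
            lo = k * slot + 1_000
            hi = min((k + 1) * slot, cfg.chrom_length) - glen - 1_000
            start = int(rng.integers(lo, hi + 1))
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 7))
            weights = rng.dirichlet(np.ones(2 * n_ex - 1))
            bounds = np.concatenate([[0], np.cumsum(weights)]) * glen
            bounds = start + np.round(bounds).astype(int)
            bounds[-1] = end
            exons = [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, 2 * n_ex - 1, 2)]
            exons = [(s, e) for s, e in exons if e - s >= 20] or [(start, end)]
            first, last = exons[0], exons[-1]
            cut5 = first[0] + max(1, int(0.3 * (first[1] - first[0])))
            cut3 = last[1] - max(1, int(0.3 * (last[1] - last[0])))
            if strand == "+":
                utr5, utr3 = [(first[0], cut5)], [(cut3, last[1])]
            else:
                utr5, utr3 = [(cut3, last[1])], [(first[0], cut5)]
            genes.append(GeneModel(f"g{gid:05d}", chrom, start, end, strand, exons, utr5, utr3))
    return Genome(chrom_sizes, genes)


# ---------------------------------------------------------------------------
# ground truth planning


def _presence_vector(transition: int, sign: int, n_stages: int) -> tuple[int, ...]:
    """Domain presence per stage, flipping opposite to the expression sign at
    ``transition`` (expression up => domain lost after the transition)."""
    before = 1 if sign > 0 else 0
    return tuple(before if i <= transition else 1 - before for i in range(n_stages))


def plan_truth(cfg: SyntheticConfig, genome: Genome) -> GroundTruth:
    """Choose planted genes, their transitions/signs, and domain intervals."""
    rng = substream(cfg.seed, "truth")
    gene_ids = [g.gene_id for g in genome.genes]
    order = list(rng.permutation(gene_ids))
    n_h, n_d = cfg.n_true_hdegs, cfg.n_decoys
    hdegs = order[:n_h]
    d_expr = order[n_h:n_h + n_d // 2]
    d_dom = order[n_h + n_d // 2:n_h + n_d]
    rest = order[n_h + n_d:]
    n_silent = int(round(cfg.frac_silent * len(rest)))
    silent = set(rest[:n_silent])

    n_tr = max(cfg.n_stages - 1, 1)
    planted_degs: dict[str, tuple[int, int, float]] = {}
    rows = []

    def add_domain(gid: str, presence: tuple[int, ...], kind: str) -> None:
        g = genome.by_id[gid]
        L = genome.chrom_sizes[g.chrom]
        start = max(g.tss - cfg.domain_width // 2, 0)
        end = min(g.tss + cfg.domain_width // 2, L)
        if end <= start:
            raise ValueError(f"planted domain for {gid} outside chromosome")
        rows.append(dict(chrom=g.chrom, start=start, end=end, presence=presence,
                         gene_id=gid, kind=kind))

    for gid in hdegs:
        t = int(rng.integers(0, n_tr))
        sign = 1 if rng.random() < 0.5 else -1
        planted_degs[gid] = (t, sign, cfg.lfc_planted)
        add_domain(gid, _presence_vector(t, sign, cfg.n_stages), "hdeg")
    for gid in d_expr:  # expression shift, no planted promoter domain
        t = int(rng.integers(0, n_tr))
        sign = 1 if rng.random() < 0.5 else -1
        planted_degs[gid] = (t, sign, cfg.lfc_planted)
    for gid in d_dom:  # domain flip, no expression shift
        t = int(rng.integers(0, n_tr))
        sign = 1 if rng.random() < 0.5 else -1
        add_domain(gid, _presence_vector(t, sign, cfg.n_stages), "decoy_domain")

    # constant intergenic background domains, centred in inter-gene gaps
    gaps: list[tuple[str, int, int]] = []
    for chrom in genome.chrom_sizes:
        spans = [(g.start, g.end) for g in genome.genes if g.chrom == chrom]
        prev = 0
        margin = 6_000  # keep clear of promoter windows
        for s, e in spans + [(genome.chrom_sizes[chrom], genome.chrom_sizes[chrom])]:
            if s - margin - (prev + margin) >= cfg.domain_width:
                gaps.append((chrom, prev + margin, s - margin))
            prev = e
    if cfg.n_background_domains and gaps:
        pick = rng.integers(0, len(gaps), size=cfg.n_background_domains)
        for i in pick:
            chrom, lo, hi = gaps[int(i)]
            start = int(rng.integers(lo, hi - cfg.domain_width + 1))
            rows.append(dict(chrom=chrom, start=start, end=start + cfg.domain_width,
                             presence=tuple([1] * cfg.n_stages), gene_id=None,
                             kind="background"))

    # optional expression-class-coupled constant promoter domains
    if cfg.class_domain_prob is not None:
        p_high, p_med, p_low, p_silent = cfg.class_domain_prob
        planted = set(hdegs) | set(d_expr) | set(d_dom)
        free = [gid for gid in gene_ids if gid not in planted]
        # expected expression rank uses the same mu stream as generate_counts
        mu_bg, _ = _base_means(cfg, genome)
        expr_rate = {gid: mu_bg[gid] / genome.by_id[gid].exonic_length for gid in free
                     if gid not in silent}
        vals = np.array(list(expr_rate.values()))
        q1, q3 = np.quantile(vals, [0.25, 0.75]) if len(vals) else (0, 0)
        for gid in free:
            if gid in silent:
                prob = p_silent
            else:
                r = expr_rate[gid]
                prob = p_high if r >= q3 else (p_low if r <= q1 else p_med)
            if rng.random() < prob:
                add_domain(gid, tuple([1] * cfg.n_stages), "class_coupled")

    dom = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "presence", "gene_id", "kind"])
    return GroundTruth(planted_domains=dom, planted_degs=planted_degs,
                       true_hdegs=set(hdegs), decoys_expression=set(d_expr),
                       decoys_domain=set(d_dom), silent_genes=silent)


# ---------------------------------------------------------------------------
# ChIP fragments


def _sample_fragments(rng: np.random.Generator, cfg: SyntheticConfig,
                      genome: Genome, domains: pd.DataFrame, fold: float) -> pd.DataFrame:
    """Homogeneous Poisson background plus extra rate inside present domains."""
    chroms, starts = [], []
    for chrom, L in genome.chrom_sizes.items():
        span = max(L - cfg.frag_len, 1)
        n_bg = rng.poisson(cfg.bg_rate * L)
        if n_bg:
            chroms.append(np.full(n_bg, chrom, dtype=object))
            starts.append(rng.integers(0, span, size=n_bg))
    for r in domains.itertuples():
        extra = (fold - 1.0) * cfg.bg_rate * (r.end - r.start)
        n_ex = rng.poisson(extra) if extra > 0 else 0
        if n_ex:
            hi = max(r.end - cfg.frag_len, r.start + 1)
            chroms.append(np.full(n_ex, r.chrom, dtype=object))
            starts.append(rng.integers(r.start, hi, size=n_ex))
    if not chroms:
        return pd.DataFrame(columns=["chrom", "start", "end", "mapq"])
    chrom = np.concatenate(chroms)
    start = np.concatenate(starts).astype(np.int64)
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": start + cfg.frag_len})
    low = rng.random(len(df)) < cfg.frac_lowmapq
    mapq = np.where(low, rng.integers(0, 20, size=len(df)), rng.integers(20, 61, size=len(df)))
    df["mapq"] = mapq
    if cfg.dup_frac > 0 and len(df):
        n_dup = int(round(cfg.dup_frac * len(df)))
        if n_dup:
            df = pd.concat([df, df.iloc[rng.integers(0, len(df), size=n_dup)]],
                           ignore_index=True)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def generate_chip(
    cfg: SyntheticConfig, genome: Genome, truth: GroundTruth | None = None
) -> tuple[dict[tuple[str, int, str], FragmentSet], GroundTruth]:
    """Raw (unfiltered) fragment sets per (stage, replicate, channel).

    The input channel is homogeneous Poisson at ``bg_rate``; the IP channel
    multiplies the rate by ``domain_fold`` inside domains present at the
    stage. Fragments carry MAPQ values (a ``frac_lowmapq`` fraction below 20)
    and a ``dup_frac`` fraction of exact duplicates, to exercise filtering.
    """
    if truth is None:
        truth = plan_truth(cfg, genome)
    for r in truth.planted_domains.itertuples():
        if r.chrom not in genome.chrom_sizes or r.start < 0 or r.end > genome.chrom_sizes[r.chrom]:
            raise ValueError(f"planted domain outside chromosome: {r.chrom}:{r.start}-{r.end}")
    out: dict[tuple[str, int, str], FragmentSet] = {}
    dom = truth.planted_domains
    for si, stage in enumerate(cfg.stages):
        present = dom[dom["presence"].map(lambda p: bool(p[si]))] if len(dom) else dom
        for rep in range(cfg.reps_chip):
            for channel in ("IP", "input"):
                rng = substream(cfg.seed, "chip", stage, rep, channel)
                fold = cfg.domain_fold if channel == "IP" else 1.0
                df = _sample_fragments(rng, cfg, genome, present, fold)
                out[(stage, rep, channel)] = FragmentSet(
                    df, stage=stage, replicate=rep, channel=channel)
    return out, truth


# ---------------------------------------------------------------------------
# RNA counts


def _base_means(cfg: SyntheticConfig, genome: Genome) -> tuple[pd.Series, pd.Series]:
    """Per-gene baseline NB means: the background lognormal draw and the
    high-count draw used for planted genes (so the planted fold change is
    detectable at the configured replication)."""
    rng = substream(cfg.seed, "rna", "means")
    gene_ids = [g.gene_id for g in genome.genes]
    mu = rng.lognormal(mean=4.0, sigma=1.2, size=len(gene_ids))
    planted_mu = rng.uniform(200.0, 1000.0, size=len(gene_ids))
    return pd.Series(mu, index=gene_ids), pd.Series(planted_mu, index=gene_ids)


def generate_counts(cfg: SyntheticConfig, genome: Genome, truth: GroundTruth) -> CountMatrix:
    """NB count matrix (genes x stages x replicates) with the planted
    expression structure; non-planted genes share their mean across stages."""
    gene_ids = [g.gene_id for g in genome.genes]
    mu_bg, mu_planted = _base_means(cfg, genome)
    base = mu_bg.copy()
    base[list(truth.silent_genes)] = 0.0
    for gid in truth.planted_degs:
        base[gid] = mu_planted[gid]
    stage_mu = pd.DataFrame({s: base for s in cfg.stages})
    for gid, (t, sign, lfc) in truth.planted_degs.items():
        factor = 2.0 ** (sign * lfc)
        for si in range(t + 1, cfg.n_stages):
            stage_mu.loc[gid, cfg.stages[si]] *= factor
    cols, data, meta = [], [], []
    alpha = max(cfg.nb_dispersion, 0.0)
    for stage in cfg.stages:
        for rep in range(cfg.reps_rna):
            rng = substream(cfg.seed, "rna", stage, rep)
            depth = rng.lognormal(0.0, cfg.depth_sigma) if cfg.depth_sigma > 0 else 1.0
            mu = stage_mu[stage].to_numpy() * depth
            if alpha < 1e-8:
                y = rng.poisson(mu)
            else:
                r = 1.0 / alpha
                y = np.where(mu > 0, rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12))), 0)
            name = f"{stage}_r{rep + 1}"
            cols.append(name)
            data.append(y.astype(np.int64))
            meta.append((name, stage, rep))
    counts = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    samples = pd.DataFrame([(s, r) for _, s, r in meta], index=cols,
                           columns=["stage", "replicate"])
    return CountMatrix(counts, genome.gene_lengths(), samples)


# ---------------------------------------------------------------------------
# convenience: full dataset + writers


def generate_dataset(cfg: SyntheticConfig):
    """Generate genome, ChIP fragment sets, ground truth and counts in one call."""
    genome = generate_genome(cfg)
    truth = plan_truth(cfg, genome)
    chip, truth = generate_chip(cfg, genome, truth)
    counts = generate_counts(cfg, genome, truth)
    return genome, chip, counts, truth


def write_dataset(cfg: SyntheticConfig, outdir) -> None:
    """Persist a synthetic dataset: chrom.sizes, GTF, fragment BEDs (the BED
    name column carries the MAPQ), counts TSV, config and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, chip, counts, truth = generate_dataset(cfg)
    write_chrom_sizes(genome.chrom_sizes, outdir / "chrom.sizes")
    write_gtf(genome, outdir / "genes.gtf")
    for (stage, rep, channel), fs in chip.items():
        path = outdir / f"{stage}_r{rep + 1}_{channel}.bed"
        with open(path, "w") as fh:
            for r in fs.df.itertuples():
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.mapq}\t0\t+\n")
    counts.to_tsv(outdir / "counts.tsv")
    truth.to_json(outdir / "truth.json")
    (outdir / "config.json").write_text(json.dumps(asdict(cfg), indent=1))
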