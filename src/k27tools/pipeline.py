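"""End-to-end orchestration: synthetic or file-based runs from one config.

The run order is: (synthetic generation) -> expression (TPM, classes, DE) ->
ChIP filtering -> stage-level island calling on pooled replicates ->
annotation (promoter windows, feature classes, promoter gene sets) ->
promoter signal -> integration (clusters, negative correlation, HDEGs) ->
optional enrichment. Every intermediate is persisted as TSV/BED/JSON and the
machine-readable :class:`RunSummary` is cross-checked against the module
outputs before being written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, chip, enrichment, expression, integration, islands, synthetic
from .genome import Genome, read_chrom_sizes, read_gtf

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "recovery_metrics",
           "audit_counts", "audit_summary"]


@dataclass
class Thresholds:
    padj: float = 0.05
    lfc: float = 1.0
    tpm: float = 0.5
    flank: int = 5000
    w: int = 200
    gap: int = 3
    q_max: float = 0.05
    eps: float = 0.1
    delta: float = 0.0
    p0: float = 0.2
    mapq_min: int = 20


@dataclass
class RunConfig:
    """One declarative run description (YAML-serialisable)."""

    synthetic: synthetic.SyntheticConfig | None = None
    gtf: str | None = None
    chrom_sizes: str | None = None
    fragments: dict | None = None  # {stage: {"IP": [paths], "input": [paths]}}
    counts: str | None = None
    gmt: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    outdir: str = "k27_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        syn = doc.get("synthetic")
        thr = doc.get("thresholds") or {}
        return cls(
            synthetic=synthetic.SyntheticConfig(**syn) if syn is not None else None,
            gtf=doc.get("gtf"), chrom_sizes=doc.get("chrom_sizes"),
            fragments=doc.get("fragments"), counts=doc.get("counts"), gmt=doc.get("gmt"),
            thresholds=Thresholds(**thr), seed=int(doc.get("seed", 0)),
            outdir=doc.get("outdir", "k27_run"),
        )


@dataclass
class RunSummary:
    """Machine-readable run tallies (every count re-derivable from the
    persisted tables)."""

    stages: list[str]
    peak_counts: dict[str, int]
    feature_fractions: dict[str, dict[str, float]]
    n_expressed: int
    n_deg: int
    stage_max_counts: dict[str, int]
    cluster_sizes: dict[str, int]
    n_negcorr: int
    n_modified: int
    n_hdeg: int
    n_discordant: int
    promoter_specific: dict[str, int]
    recovery: dict | None = None
    config: dict | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def recovery_metrics(called_hdegs: set[str], truth: synthetic.GroundTruth) -> dict:
    """Sensitivity and false-discovery proportion of the HDEG call against the
    planted truth."""
    tp = len(called_hdegs & truth.true_hdegs)
    sens = tp / len(truth.true_hdegs) if truth.true_hdegs else float("nan")
    fdp = (len(called_hdegs) - tp) / max(len(called_hdegs), 1)
    return {
        "sensitivity": sens,
        "fdp": fdp,
        "n_called": len(called_hdegs),
        "n_true": len(truth.true_hdegs),
        "n_decoys_called": len(called_hdegs & truth.decoys),
    }


def _load_inputs(cfg: RunConfig):
    """Resolve the run inputs: (genome, raw chip dict, CountMatrix, truth|None)."""
    if cfg.synthetic is not None:
        syn = cfg.synthetic
        genome, chip_sets, counts, truth = synthetic.generate_dataset(syn)
        raw = {k: fs.df for k, fs in chip_sets.items()}
        return genome, raw, counts, truth
    sizes = read_chrom_sizes(cfg.chrom_sizes) if cfg.chrom_sizes else None
    genome = read_gtf(cfg.gtf, sizes)
    raw = {}
    for stage, channels in (cfg.fragments or {}).items():
        for channel, paths in channels.items():
            for rep, path in enumerate(paths):
                raw[(stage, rep, channel)] = read_fragments_bed(path)
    counts = expression.CountMatrix.from_tsv(cfg.counts, genome.gene_lengths())
    return genome, raw, counts, None


def read_fragments_bed(path) -> pd.DataFrame:
    """Read a fragment BED; the name column (4th) carries the MAPQ when numeric."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] > 3:
        name = df[3]
        if pd.to_numeric(name, errors="coerce").notna().all():
            df["mapq"] = pd.to_numeric(name).astype(int)
    keep = [c for c in ("chrom", "start", "end", "mapq") if c in df.columns]
    return df[keep]


def run_pipeline(cfg: RunConfig) -> RunSummary:
    """Execute the full route and persist artifacts under ``cfg.outdir``."""
    thr = cfg.thresholds
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, raw_chip, counts, truth = _load_inputs(cfg)
    stages = counts.stages

    # --- expression ---------------------------------------------------------
    log.info("expression: %d genes, %d samples", *counts.counts.shape)
    tpm_df = expression.tpm(counts)
    expr = expression.classify_expression(tpm_df, counts.samples, thr.tpm)
    expressed_genes = set(expr.expressed.index[expr.expressed])
    de_results: dict[str, pd.DataFrame] = {}
    for a, b in zip(stages[:-1], stages[1:]):
        tr = f"{a}->{b}"
        de_results[tr] = expression.de_test(
            counts, a, b, padj_max=thr.padj, lfc_min=thr.lfc,
            genes=pd.Index(sorted(expressed_genes)))
        de_results[tr].rename_axis("gene_id").to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t")
    degs_tab = expression.call_degs(de_results)
    deg_genes = set(degs_tab.index[degs_tab["is_deg"]])
    stage_max = expression.stage_max_assignment(expr, deg_genes) if deg_genes else pd.Series(dtype=object)
    tpm_df.rename_axis("gene_id").to_csv(out / "tpm.tsv", sep="\t")
    expr.levels.rename_axis("gene_id").to_csv(out / "levels.tsv", sep="\t")
    for a, b in zip(stages[:-1], stages[1:]):
        if deg_genes:
            expression.level_transition_table(expr, deg_genes, a, b).to_csv(
                out / f"transition_{a}_to_{b}.tsv", sep="\t")

    # --- ChIP filtering + stage-level islands -------------------------------
    filtered: dict[tuple[str, int, str], chip.FragmentSet] = {}
    for (stage, rep, channel), df in raw_chip.items():
        filtered[(stage, rep, channel)] = chip.filter_fragments(
            df, thr.mapq_min, stage=stage, replicate=rep, channel=channel)
    reps = sorted({k[1] for k in filtered})
    stage_islands: dict[str, pd.DataFrame] = {}
    for stage in stages:
        ip = islands.pool_fragments([filtered[(stage, r, "IP")] for r in reps], stage, "IP")
        ctrl = islands.pool_fragments([filtered[(stage, r, "input")] for r in reps], stage, "input")
        retained, _cand = islands.call_islands(
            ip, ctrl, genome.chrom_sizes, w=thr.w, gap=thr.gap, p0=thr.p0, q_max=thr.q_max)
        stage_islands[stage] = retained
        islands.write_islands_bed(retained, out / f"islands_{stage}.bed")
        log.info("islands %s: %d retained", stage, len(retained))

    # --- annotation ---------------------------------------------------------
    windows = annotation.promoter_windows(genome, thr.flank)
    feature_fractions: dict[str, dict[str, float]] = {}
    for stage, isl in stage_islands.items():
        if len(isl):
            ann = annotation.annotate_peaks(isl, genome, windows)
            ann.to_csv(out / f"annotated_{stage}.tsv", sep="\t", index=False)
            feature_fractions[stage] = annotation.genomic_distribution(ann).to_dict()
        else:
            feature_fractions[stage] = {}
    psets = annotation.promoter_gene_sets(stage_islands, windows)
    (out / "promoter_sets.json").write_text(json.dumps(psets.summary(), indent=1))

    # --- promoter signal ----------------------------------------------------
    levels = {}
    for si, stage in enumerate(stages):
        ip_rpkm = pd.DataFrame({
            r: chip.promoter_rpkm(filtered[(stage, r, "IP")], windows) for r in reps})
        in_rpkm = pd.DataFrame({
            r: chip.promoter_rpkm(filtered[(stage, r, "input")], windows) for r in reps})
        levels[stage] = chip.h3k27me3_level(ip_rpkm, in_rpkm, eps=thr.eps)
    levels_df = pd.DataFrame(levels)
    levels_df.rename_axis("gene_id").to_csv(out / "promoter_levels.tsv", sep="\t")

    # --- integration --------------------------------------------------------
    clusters = integration.transition_clusters(de_results, levels_df, delta=thr.delta)
    result = integration.hdeg_set(clusters, psets.union)
    result.records.rename_axis("gene_id").to_csv(out / "integration.tsv", sep="\t")

    # --- enrichment (optional) ----------------------------------------------
    if cfg.gmt and result.hdegs:
        coll = enrichment.GeneSetCollection(enrichment.read_gmt(cfg.gmt), expressed_genes)
        try:
            enrichment.ora_test(result.hdegs, coll).to_csv(out / "ora_hdegs.tsv", sep="\t")
        except ValueError as exc:
            log.warning("enrichment skipped: %s", exc)

    # --- summary (+ cross-checks) -------------------------------------------
    stage_max_counts = {s: int((stage_max == s).sum()) for s in stages}
    assert sum(stage_max_counts.values()) == len(deg_genes)
    summary = RunSummary(
        stages=stages,
        peak_counts={s: len(isl) for s, isl in stage_islands.items()},
        feature_fractions=feature_fractions,
        n_expressed=len(expressed_genes),
        n_deg=len(deg_genes),
        stage_max_counts=stage_max_counts,
        cluster_sizes=clusters.attrs["cluster_sizes"],
        n_negcorr=len(result.negcorr),
        n_modified=len(result.modified),
        n_hdeg=len(result.hdegs),
        n_discordant=len(result.discordant),
        promoter_specific={s: len(v) for s, v in psets.specific.items()},
        recovery=recovery_metrics(result.hdegs, truth) if truth is not None else None,
        config={"seed": cfg.seed, "thresholds": asdict(cfg.thresholds),
                "synthetic": asdict(cfg.synthetic) if cfg.synthetic else None},
    )
    audit_summary(summary)
    summary.to_json(out / "summary.json")
    with open(out / "hdegs.txt", "w") as fh:
        fh.write("\n".join(sorted(result.hdegs)) + ("\n" if result.hdegs else ""))
    return summary


def audit_counts(
    n_deg: int,
    n_negcorr: int,
    n_modified: int,
    n_hdeg: int,
    cluster_sizes: dict[str, int] | None = None,
) -> None:
    """Arithmetic consistency of headline tallies: the HDEG set is inside the
    negative-correlation set, which is inside the DEG set; HDEGs are modified;
    per-transition cluster tallies can only overcount the deduplicated union
    while each single cluster is inside it."""
    if not (0 <= n_hdeg <= n_negcorr <= n_deg):
        raise AssertionError("set-logic violation: HDEG <= negcorr <= DEG")
    if n_hdeg > n_modified:
        raise AssertionError("set-logic violation: HDEG <= modified")
    if cluster_sizes:
        if n_negcorr > sum(cluster_sizes.values()):
            raise AssertionError("negcorr exceeds the sum of cluster sizes")
        if any(c > n_negcorr for c in cluster_sizes.values()):
            raise AssertionError("a single cluster exceeds the negcorr union")


def audit_summary(s: RunSummary) -> None:
    """Consistency of a run's tallies (see :func:`audit_counts`), plus the
    stage-maximal partition of the DEG set and feature-fraction normalisation."""
    audit_counts(s.n_deg, s.n_negcorr, s.n_modified, s.n_hdeg, s.cluster_sizes)
    if sum(s.stage_max_counts.values()) != s.n_deg:
        raise AssertionError("stage-maximal assignment does not partition the DEG set")
    for stage, fr in s.feature_fractions.items():
        if fr and abs(sum(fr.values()) - 1.0) > 1e-9:
            raise AssertionError(f"feature fractions of {stage} do not sum to 1")
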