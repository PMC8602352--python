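import numpy as np
import pandas as pd
import pytest

from k27tools import RunConfig, SyntheticConfig, run_pipeline
from k27tools.genome import GeneModel, Genome
from k27tools.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A compact but sparse study: 300 genes on 2 x 5.5 Mb chromosomes, 20 true
    HDEGs, 20 decoys, otherwise the default study conditions."""
    return SyntheticConfig(n_chroms=2, chrom_length=5_500_000, n_genes=300,
                           n_true_hdegs=20, n_decoys=20, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """(genome, chip fragment sets, counts, truth) for the small study."""
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_run(small_cfg, tmp_path_factory):
    """Full pipeline summary on the small study."""
    out = tmp_path_factory.mktemp("small_run")
    return run_pipeline(RunConfig(synthetic=small_cfg, outdir=str(out), seed=1)), out


@pytest.fixture()
def toy_genome() -> Genome:
    """Two genes on one 100 kb chromosome, one per strand, with UTRs."""
    plus = GeneModel("gA", "chr1", 10_000, 20_000, "+",
                     exons=[(10_000, 12_000), (18_000, 20_000)],
                     utr5=[(10_000, 10_600)], utr3=[(19_400, 20_000)])
    minus = GeneModel("gB", "chr1", 60_000, 70_000, "-",
                      exons=[(60_000, 62_000), (68_000, 70_000)],
                      utr5=[(69_400, 70_000)], utr3=[(60_000, 60_600)])
    return Genome({"chr1": 100_000}, [plus, minus])


def frags(rows) -> pd.DataFrame:
    """Fragment frame from (chrom, start, end[, mapq]) tuples."""
    cols = ["chrom", "start", "end", "mapq"][: len(rows[0])] if rows else ["chrom", "start", "end"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
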