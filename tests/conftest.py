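import numpy as np
import pandas as pd
import pytest

from repeatdensity import (
    ExpressionMatrix,
    GeneRecord,
    GenomeSequence,
    SimulationConfig,
)

FIXTURE_SEED = 101

# config of the committed demo bundle under tests/fixtures/demo
DEMO_CONFIG = dict(
    seed=FIXTURE_SEED,
    n_chroms=2,
    n_genes=24,
    class_sizes=(5, 14, 5),
    upstream=1000,
    downstream=1000,
    bin_width=100,
    gene_spacing=2100,
    background_runs_per_window=2.0,
    enrichment_factor=3.0,
    effect_size=1.5,
    shared_fraction=1.0,
)


@pytest.fixture(scope="session")
def demo_config():
    return SimulationConfig(**DEMO_CONFIG)


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """Path of the committed fixture bundle."""
    from pathlib import Path

    return Path(__file__).parent / "fixtures" / "demo"


@pytest.fixture
def small_genome():
    # chr1: a 15-bp A run at [10, 25) and a 13-bp T run at [40, 53)
    chr1 = "C" * 10 + "A" * 15 + "G" * 15 + "T" * 13 + "GC" * 10
    return GenomeSequence({"chr1": chr1, "chr2": "ACGT" * 25})


def make_expression(values, test, control):
    """Build an ExpressionMatrix from a dict gene -> list of sample values."""
    cols = test + control
    df = pd.DataFrame.from_dict(values, orient="index", columns=cols).astype(float)
    df.index.name = "gene_id"
    groups = {s: "test" for s in test} | {s: "control" for s in control}
    return ExpressionMatrix(values=df, group_of=groups)


@pytest.fixture
def four_sample_matrix():
    rng = np.random.default_rng(0)
    genes = {f"g{i}": rng.normal(8, 1, 4) for i in range(10)}
    genes["flat"] = [5.0, 5.0, 5.0, 5.0]
    return make_expression(genes, ["t1", "t2"], ["c1", "c2"])


def plus_gene(tss, chrom="chr1", gene_id="g1"):
    return GeneRecord(gene_id, chrom, "+", tss, tss + 10_000)


def minus_gene(tss, chrom="chr1", gene_id="g1"):
    return GeneRecord(gene_id, chrom, "-", tss, tss - 10_000)
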