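import numpy as np
import pandas as pd
import pytest

from dgekit.config import RunConfig, SimulationConfig
from dgekit.pipeline import run_profiling
from dgekit.reference import build_tag_catalog
from dgekit.simulate import simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """2 x 4000 bp genome with 12 transcripts; substrate for catalog tests."""
    return simulate_genome(2, 4000, 12, seed=11)


@pytest.fixture(scope="session")
def small_catalog(small_genome):
    genome, annotation = small_genome
    return build_tag_catalog(genome, annotation)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full profiling run at the default synthetic scale (500 genes,
    10 patients, 5e4 tags/library, 50 planted DEGs in 7/10 patients)."""
    outdir = tmp_path_factory.mktemp("profiling_default")
    cfg = RunConfig(outdir=str(outdir), seed=1, simulation=SimulationConfig(seed=1))
    report = run_profiling(cfg)
    return cfg, report, outdir


def toy_annotation(rows):
    """Annotation frame from (chrom, start, end, tx, strand, gene) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "transcript_id", "strand", "gene_id"]
    )
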