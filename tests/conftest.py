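import numpy as np
import pandas as pd
import pytest

from caprameth import synthetic


@pytest.fixture(scope="session")
def genome100k():
    genome, cgis = synthetic.generate_genome(
        n_chrom=1, chrom_length=100_000, gc_fraction=0.42, cgi_density=10.0, seed=1)
    return genome, cgis


@pytest.fixture(scope="session")
def planted_methylomes(genome100k):
    """Four samples (2 vs 2) with 8 planted CG DMRs of both signs."""
    genome, _ = genome100k
    samples, truth = synthetic.generate_methylomes(
        genome, n_dmr=8, dmr_delta=0.5, dmr_length=500, mean_depth=30, seed=3)
    manifest = {name: name.rsplit("-", 1)[0] for name in samples}
    return samples, truth, manifest


@pytest.fixture(scope="session")
def null_methylomes(genome100k):
    """Matched-baseline samples with no planted signal."""
    genome, _ = genome100k
    samples, truth = synthetic.generate_methylomes(genome, n_dmr=0, seed=4)
    manifest = {name: name.rsplit("-", 1)[0] for name in samples}
    assert truth.empty
    return samples, manifest


@pytest.fixture(scope="session")
def small_annotation(genome100k):
    genome, _ = genome100k
    genes, tes, term_map = synthetic.generate_annotation(
        genome, n_genes=10, n_tes=4, seed=2)
    return genes, tes, term_map
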