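import numpy as np
import pandas as pd
import pytest

from mchtools import simulate
from mchtools.methylome import GeneAnnotation, SiteRecord


@pytest.fixture
def toy_sites():
    """Handful of sites on two contigs, both context classes."""
    return [
        SiteRecord("chr1", 100, "+", "CAC", 3, 10),
        SiteRecord("chr1", 150, "-", "CAT", 1, 20),
        SiteRecord("chr1", 200, "+", "CCC", 0, 10),
        SiteRecord("chr1", 250, "+", "CGA", 7, 7),
        SiteRecord("chr1", 900, "-", "CGT", 2, 10),
        SiteRecord("chr2", 50, "+", "CAC", 0, 5),
        SiteRecord("chr2", 60, "+", "CAG", 0, 10),
    ]


@pytest.fixture
def toy_genes():
    return [
        GeneAnnotation("geneA", "chr1", 50, 300),
        GeneAnnotation("geneB", "chr1", 150, 1000, "-"),  # overlaps geneA
        GeneAnnotation("geneC", "chr2", 0, 100),
        GeneAnnotation("geneD", "chr3", 0, 500),  # contig without sites
    ]


@pytest.fixture(scope="session")
def default_params():
    return simulate.SimulationParams(seed=11)


@pytest.fixture(scope="session")
def small_methylome():
    """Reduced-scale methylome simulation shared across tests."""
    params = simulate.SimulationParams(n_genes=2000, seed=11)
    return params, simulate.simulate_methylomes(params)


@pytest.fixture(scope="session")
def small_expression(small_methylome):
    params, mt = small_methylome
    return params, mt, simulate.simulate_expression(mt, params)
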