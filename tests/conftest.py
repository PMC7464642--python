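import numpy as np
import pandas as pd
import pytest

from methyldef import CpGCallTable, GeneratorConfig, RegionSet, simulate_methylome


@pytest.fixture
def toy_survival():
    """Eight subjects with mixed censoring; times are distinct."""
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            "event": [1, 1, 1, 1, 0, 0, 1, 0],
        },
        index=pd.Index([f"S{i}" for i in range(8)], name="sample_id"),
    )


@pytest.fixture
def small_regions():
    return RegionSet(
        pd.DataFrame(
            {
                "region_id": ["geneA", "geneB", "cgi1"],
                "gene_id": ["geneA", "geneB", "geneA"],
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [100, 1000, 80],
                "end": [600, 1600, 180],
                "kind": ["gene_body", "gene_body", "cgi"],
            }
        )
    )


def make_calls(sample_id, positions, betas, depths, chrom="chr1"):
    return CpGCallTable(
        sample_id,
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.asarray(positions, int),
                "beta": np.asarray(betas, float),
                "depth": np.asarray(depths, float),
            }
        ),
    )


@pytest.fixture(scope="session")
def small_methylome():
    """One small simulated dataset shared by read-only tests."""
    config = GeneratorConfig(n_samples=8, n_genes=40, seed=11)
    calls, regions, truth = simulate_methylome(config)
    return config, calls, regions, truth
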