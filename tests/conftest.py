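import numpy as np
import pandas as pd
import pytest

from nestnet.matrix import ExpressionMatrix
from nestnet.network import ModulePartition


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_matrix(values, scale="log2tpm", gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale)


def factor_module(rng, n_genes, n_samples, loading, noise_sd=1.0):
    """One-factor module block: loading * f + noise."""
    f = rng.standard_normal(n_samples)
    return loading * f[None, :] + rng.normal(0.0, noise_sd, (n_genes, n_samples))


def loading_for(rho, noise_sd=1.0):
    """Loading that yields expected intra-module correlation rho."""
    return noise_sd * np.sqrt(rho / (1.0 - rho))


@pytest.fixture
def two_group_module(rng):
    """A 50-gene module observed in two 10-sample groups (corr 0.6 vs 0.3)."""
    G, n = 50, 10
    X = np.hstack([
        factor_module(rng, G, n, loading_for(0.6)),
        factor_module(rng, G, n, loading_for(0.3)),
    ])
    m = make_matrix(X)
    part = ModulePartition(pd.Series(["mod"] * G, index=m.gene_ids))
    return m, part, m.sample_ids[:n], m.sample_ids[n:]
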