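"""Shared fixtures: small synthetic cohorts and hand-built AnnData objects."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import deconvbench as db


@pytest.fixture(scope="session")
def small_config():
    return db.CohortConfig(n_tumors=2, cells_per_tumor=300, n_genes=400, rng_seed=0)


@pytest.fixture(scope="session")
def small_ref(small_config):
    return db.generate_reference(small_config, seed=11)


@pytest.fixture(scope="session")
def default_ref():
    """Full-scale default cohort: 8 tumors x 2000 cells, 10 cell types."""
    return db.generate_reference(db.CohortConfig(rng_seed=7), seed=7)


def make_adata(counts, cell_types, sample_ids, gene_ids=None):
    """Hand-built annotated dataset from a dense count array."""
    counts = np.asarray(counts, dtype=np.int64)
    n, g = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(g)]
    obs = pd.DataFrame({
        "cell_type": pd.Categorical(cell_types),
        "sample_id": pd.Categorical(sample_ids),
    }, index=pd.Index([f"bc{i:05d}" for i in range(n)], name="barcode"))
    obs["library_size"] = counts.sum(axis=1)
    return ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene")),
    )


@pytest.fixture
def two_type_adata():
    """Type A cells with exactly 100 reads each, type B with exactly 300."""
    rng = np.random.default_rng(5)
    n_a, n_b, g = 40, 40, 20
    counts = np.zeros((n_a + n_b, g), dtype=np.int64)
    for i in range(n_a):
        counts[i] = np.bincount(rng.integers(0, g, 100), minlength=g)
    for i in range(n_b):
        counts[n_a + i] = np.bincount(rng.integers(0, g, 300), minlength=g)
    return make_adata(
        counts,
        ["A"] * n_a + ["B"] * n_b,
        ["s1"] * (n_a + n_b),
    )
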