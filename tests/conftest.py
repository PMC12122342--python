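import numpy as np
import pytest
import scipy.sparse as sp

from nichecoloc import ExpressionMatrix, SimConfig, normalize_cp10k_log1p, simulate_spatial
from nichecoloc.io_core import LOG1P_CP10K


def make_matrix(counts, genes=None, barcodes=None, layer_tag="raw"):
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    barcodes = barcodes or [f"cell{j}" for j in range(counts.shape[1])]
    return ExpressionMatrix(
        np.array(genes, dtype=object),
        np.array(barcodes, dtype=object),
        sp.csr_array(counts),
        layer_tag=layer_tag,
    )


@pytest.fixture
def small_raw():
    rng = np.random.default_rng(42)
    counts = rng.poisson(2.0, size=(30, 20))
    return make_matrix(counts)


@pytest.fixture
def small_norm(small_raw):
    return normalize_cp10k_log1p(small_raw)


@pytest.fixture(scope="session")
def sim_spatial_null():
    """One default (beta=0, delta=0) spatial simulation, shared across tests."""
    return simulate_spatial(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_spatial_effect():
    """Spatial simulation with planted co-occurrence and coupling."""
    return simulate_spatial(SimConfig(beta=2.0, delta=3.0, seed=11))
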