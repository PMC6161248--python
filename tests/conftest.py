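import numpy as np
import pytest

from metaboquant.io_flatfile import parse_flatfile
from metaboquant.synthetic import simulate_batch, small_preset


@pytest.fixture(scope="session")
def small_batch():
    """One rendered small synthetic batch (10 metabolites, 2 groups x 6)."""
    config, panel = small_preset(seed=7)
    return simulate_batch(config, panel)


@pytest.fixture(scope="session")
def parsed_batch(small_batch, tmp_path_factory):
    d = tmp_path_factory.mktemp("batch")
    flat, _ = small_batch.write(d)
    return parse_flatfile(flat, small_batch.panel, metadata=small_batch.metadata)


def wls_poly_oracle(x, y, w, order):
    """Independent weighted-least-squares oracle via explicit normal equations.

    Builds the moment matrix with plain Python loops — no shared code path
    with the package's design-matrix/lstsq implementation.
    """
    k = order + 1
    A = np.zeros((k, k))
    b = np.zeros(k)
    for xi, yi, wi in zip(x, y, w):
        for i in range(k):
            for j in range(k):
                A[i, j] += wi * xi ** (i + j)
            b[i] += wi * yi * xi**i
    return np.linalg.solve(A, b)
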