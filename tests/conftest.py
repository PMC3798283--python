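import numpy as np
import pandas as pd
import pytest

from brainstates.atlas import ConnectivityMatrix, ROIAtlas
from brainstates.thresholding import BrainGraph


@pytest.fixture
def toy_atlas() -> ROIAtlas:
    """Six ROIs spanning four subdivisions with easy coordinates."""
    table = pd.DataFrame({
        "roi_id": range(6),
        "name": ["Fcx_a", "Fcx_b", "Pcx_a", "Thl_a", "BG_a", "Crbl_a"],
        "subdivision": ["Fcx", "Fcx", "Pcx", "Thl", "BG", "Crbl"],
        "x": [0.0, 3.0, 0.0, 10.0, -10.0, 5.0],
        "y": [0.0, 4.0, 10.0, 0.0, 0.0, -30.0],
        "z": [0.0, 0.0, 0.0, 5.0, 5.0, -20.0],
    })
    return ROIAtlas(table)


def random_correlation(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random valid correlation matrix via a random factor model."""
    b = rng.standard_normal((n, max(2, n // 2)))
    s = b @ b.T + np.diag(rng.uniform(0.5, 1.5, n))
    d = np.sqrt(np.diag(s))
    c = s / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def random_weighted_graph(n: int, density: float, rng: np.random.Generator,
                          connected_bias: bool = False) -> BrainGraph:
    """Random symmetric positive-weighted graph at approximately the density."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m = len(iu[0])
    k = max(2, int(round(density * m)))
    pick = rng.choice(m, size=k, replace=False)
    vals = rng.uniform(0.05, 1.0, size=k)
    w[iu[0][pick], iu[1][pick]] = vals
    w += w.T
    if connected_bias:
        # chain through all nodes so the graph is connected
        for i in range(n - 1):
            if w[i, i + 1] == 0:
                v = rng.uniform(0.05, 1.0)
                w[i, i + 1] = w[i + 1, i] = v
    dens = np.count_nonzero(np.triu(w, 1)) / m
    return BrainGraph(w, density=dens)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng) -> ConnectivityMatrix:
    return ConnectivityMatrix(random_correlation(12, rng), subject="s1", condition="W")
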