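import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sigmodules.contexts import CHANNELS

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def disjoint_catalog() -> pd.DataFrame:
    """Two signatures with disjoint channel support (first/last 48 channels)."""
    p1 = np.zeros(96)
    p1[:48] = 1 / 48
    p2 = np.zeros(96)
    p2[48:] = 1 / 48
    return pd.DataFrame({"A": p1, "B": p2}, index=list(CHANNELS))


@pytest.fixture(scope="session")
def overlap_catalog() -> pd.DataFrame:
    """Two spiky, partially overlapping signatures (seeded Dirichlet draws)."""
    rng = np.random.default_rng(12345)
    p1 = rng.dirichlet(np.full(96, 0.3))
    p2 = rng.dirichlet(np.full(96, 0.3))
    return pd.DataFrame({"A": p1, "B": p2}, index=list(CHANNELS))


@pytest.fixture()
def toy_instance():
    """Small deterministic module-search instance: path network a-b-c-d."""
    import networkx as nx

    genes = ["a", "b", "c", "d"]
    G = nx.Graph()
    G.add_edges_from([("a", "b"), ("b", "c"), ("c", "d")])
    patients = [f"P{j}" for j in range(6)]
    M = pd.DataFrame(0, index=genes, columns=patients)
    M.loc["a", ["P0", "P1"]] = 1
    M.loc["b", ["P2"]] = 1
    M.loc["c", ["P3", "P0"]] = 1
    M.loc["d", ["P4"]] = 1
    w = pd.Series([1.0, 0.8, 0.6, -0.2, -0.7, -1.5], index=patients)
    return M, w, G
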