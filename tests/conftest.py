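import numpy as np
import pytest

from immunoconverge import DiseaseGeneCatalog, default_config
from immunoconverge.synthetic_data import gen_catalog


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=0)


@pytest.fixture(scope="session")
def default_catalog(default_cfg):
    return gen_catalog(default_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_catalog():
    return DiseaseGeneCatalog(
        {
            "AS": frozenset({"A", "B", "C"}),
            "CD": frozenset({"B", "C", "D"}),
            "UC": frozenset({"C", "E"}),
        }
    )


def random_catalog(rng, n_diseases=9, pool=120, max_size=40):
    """Random disease catalog over a shared gene pool (for oracle tests)."""
    pool_genes = np.array([f"G{i:04d}" for i in range(pool)])
    entries = {}
    for d in range(n_diseases):
        size = int(rng.integers(3, max_size))
        entries[f"D{d}"] = frozenset(rng.choice(pool_genes, size=size, replace=False))
    return DiseaseGeneCatalog(entries)
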