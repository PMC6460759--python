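import numpy as np
import pytest

from mtme import MTMEDataset, build_design, compound_symmetry_grm


def toy_dataset(I, J, L, seed=0, Y=None):
    """Small balanced dataset with one row per (environment, line) cell."""
    rng = np.random.default_rng(seed)
    env_ids = [f"E{i + 1}" for i in range(I)]
    line_ids = [f"L{j + 1}" for j in range(J)]
    rows = [(env_ids[i], line_ids[j]) for i in range(I) for j in range(J)]
    if Y is None:
        Y = rng.normal(size=(I * J, L))
    return MTMEDataset(env_ids, line_ids, Y, [f"T{l + 1}" for l in range(L)], rows)


@pytest.fixture
def toy_factory():
    return toy_dataset


@pytest.fixture
def small_design():
    ds = toy_dataset(2, 4, 2, seed=1)
    return ds, build_design(ds), compound_symmetry_grm(4, 0.5, 0.5)
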