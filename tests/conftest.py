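import numpy as np
import pytest

from mbnipals import MultiBlockDataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_dataset(rng, n=10, widths=(5, 3), names=None):
    names = list(names) if names else [f"b{k+1}" for k in range(len(widths))]
    blocks = [rng.standard_normal((n, p)) for p in widths]
    return MultiBlockDataset(
        block_names=names,
        blocks=blocks,
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=[[f"{nm}_f{j}" for j in range(p)] for nm, p in zip(names, widths)],
    )


@pytest.fixture
def two_block_dataset(rng):
    return make_dataset(rng)


def centered_blocks(rng, n, widths):
    out = []
    for p in widths:
        X = rng.standard_normal((n, p))
        out.append(X - X.mean(axis=0))
    return out
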