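import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_edges(tmp_path):
    """Three-node weighted toy network on disk."""
    path = tmp_path / "toy.tsv"
    path.write_text("x1\tx2\t0.5\nx1\tx3\t-0.2\nx2\tx3\t0.1\n")
    return path
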