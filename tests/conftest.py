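import numpy as np
import pytest

from defold.synthetic import make_toy_fold


@pytest.fixture(scope="session")
def hairpin16():
    return make_toy_fold("hairpin", 16, seed=0)


@pytest.fixture(scope="session")
def bundle20():
    return make_toy_fold("helix-bundle", 20, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_fasta(path, rows, names=None):
    with open(path, "w") as fh:
        for i, row in enumerate(rows):
            fh.write(f">{names[i] if names else f's{i}'}\n{row}\n")
    return path
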