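import numpy as np
import pytest

from scatterfit.datacore import DataCollection, DataSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_dataset(rng: np.random.Generator) -> DataSet:
    """Random shape, attributes (scalar/vector/string), comments, roles."""
    nrows = int(rng.integers(1, 30))
    ncols = int(rng.integers(2, 6))
    data = rng.normal(scale=10.0 ** rng.integers(-3, 4), size=(nrows, ncols))
    attrs = {}
    for i in range(rng.integers(0, 5)):
        name = f"attr_{i}"
        kind = rng.integers(0, 3)
        if kind == 0:
            attrs[name] = float(rng.normal())
        elif kind == 1:
            attrs[name] = rng.normal(size=int(rng.integers(2, 5)))
        else:
            attrs[name] = "text value " + str(int(rng.integers(0, 100)))
    comments = [f"comment line {i}" for i in range(rng.integers(0, 3))]
    roles = {"X": 0, "Y": 1}
    if ncols >= 3 and rng.random() < 0.5:
        roles["eY"] = int(rng.integers(2, ncols))
    return DataSet(data, attrs, comments, roles)


@pytest.fixture
def random_collection(rng):
    def make(n=5):
        return DataCollection(random_dataset(rng) for _ in range(n))
    return make
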