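import numpy as np
import pytest

from edgeshare.preprocess import EdgeUniverse, ExpressionMatrix, GeneUniverse


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix(rng):
    return ExpressionMatrix(
        values=rng.uniform(0, 50, size=(30, 6)),
        gene_ids=[f"G{i}" for i in range(6)],
        cell_ids=[f"cell{i}" for i in range(30)],
        cell_type_label="alpha",
    )


@pytest.fixture
def tiny_universe():
    return EdgeUniverse(edges=[("G0", "G1"), ("G0", "G2"), ("G1", "G0"), ("G1", "G2")])


@pytest.fixture
def gene_universe():
    return GeneUniverse(
        genes=["G0", "G1", "G2", "G3"], regulators=["G0", "G1"]
    )
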