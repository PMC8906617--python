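import numpy as np
import pytest

from iqgrn.io import ExpressionDataset
from iqgrn.logic import BooleanRule, GrnModel
from iqgrn.preprocess import BinarizedDataset


def make_dataset(values, pseudotime=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ExpressionDataset(
        cell_ids=[f"c{i}" for i in range(n)],
        gene_ids=gene_ids or [f"g{j}" for j in range(g)],
        values=values,
        pseudotime=(np.arange(n, dtype=float) if pseudotime is None
                    else np.asarray(pseudotime, dtype=float)))


def make_binarized(calls, gene_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, g = calls.shape
    return BinarizedDataset(
        cell_ids=[f"c{i}" for i in range(n)],
        gene_ids=gene_ids or [f"g{j}" for j in range(g)],
        calls=calls, thresholds=np.full(g, 0.5),
        mu_off=np.zeros(g), mu_on=np.ones(g), method="kmeans",
        pseudotime=np.arange(n, dtype=float))


@pytest.fixture
def toggle_model():
    """Mutual repression: g1 = g1 & !g2, g2 = g2 & !g1."""
    return GrnModel(
        genes=["g1", "g2"],
        rules={"g1": BooleanRule("g1", activators=("g1",), repressors=("g2",)),
               "g2": BooleanRule("g2", activators=("g2",), repressors=("g1",))})


@pytest.fixture
def cascade_model():
    """Three-gene activating cascade with a terminal repression."""
    return GrnModel(
        genes=["a", "b", "c"],
        rules={"a": BooleanRule("a", activators=("a",)),
               "b": BooleanRule("b", activators=("a",)),
               "c": BooleanRule("c", activators=("b",), repressors=("a",))})
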