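import numpy as np
import pandas as pd
import pytest

from pathtopo.pathway import build_pathway
from pathtopo.preprocess import ExpressionMatrix, GroupLabels


@pytest.fixture
def triangle():
    return build_pathway(
        "tri", ["A", "B", "C"],
        [("A", "B", True, 1), ("B", "C", True, 1), ("A", "C", True, -1)],
    )


@pytest.fixture
def chain3():
    return build_pathway(
        "chain", ["A", "B", "C"], [("A", "B", True, 1), ("B", "C", True, 1)]
    )


def make_expr(values, genes, samples, kind="normalized"):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), kind)


def make_groups(n1, n2):
    samples = [f"s{i}" for i in range(n1 + n2)]
    return GroupLabels(
        pd.Series(["a"] * n1 + ["b"] * n2, index=samples), reference="a"
    ), samples


@pytest.fixture
def gaussian_data():
    """8-sample null Gaussian expression over 30 genes."""
    rng = np.random.default_rng(42)
    genes = [f"g{i:03d}" for i in range(30)]
    groups, samples = make_groups(4, 4)
    expr = make_expr(rng.standard_normal((30, 8)), genes, samples)
    return expr, groups
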