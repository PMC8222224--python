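import numpy as np
import pandas as pd
import pytest

from icbnotch.io_formats import ClonotypeTable, ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4-gene, 1-sample matrix with a strict expression ordering."""
    return ExpressionMatrix(
        values=pd.DataFrame({"s1": [4.0, 3.0, 2.0, 1.0]}, index=["A", "B", "C", "D"]),
        unit="CPM",
    )


@pytest.fixture
def random_counts() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    vals = rng.poisson(60.0, size=(50, 10)).astype(float)
    return ExpressionMatrix(
        values=pd.DataFrame(
            vals,
            index=[f"G{i:03d}" for i in range(50)],
            columns=[f"S{j}" for j in range(10)],
        ),
        unit="counts",
    )


def _rep(sample_id: str, counts: dict, **kw) -> ClonotypeTable:
    return ClonotypeTable(sample_id=sample_id, counts=pd.Series(counts), **kw)


@pytest.fixture
def expansion_pair() -> tuple[ClonotypeTable, ClonotypeTable]:
    """Equal-depth pre/on pair where exactly A (4-fold growth) and C
    (absent pre, 12 on-treatment reads) satisfy the expansion rule."""
    pre = _rep("pre", {"A": 5, "B": 100, "D": 95}, timepoint="pre")
    on = _rep("on", {"A": 20, "B": 150, "C": 12, "D": 18}, timepoint="on-cycle-1")
    assert pre.total == on.total == 200
    return pre, on


@pytest.fixture
def make_repertoire():
    return _rep
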