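import numpy as np
import pandas as pd
import pytest

from lipidomix import ConcentrationTable, parse_lipid_name


def make_table(values: dict[str, list[float]], groups: list[str],
               experiment: str = "exp1", matrix: str = "liver",
               samples: list[str] | None = None) -> ConcentrationTable:
    """Small helper: build a ConcentrationTable from a column dict."""
    n = len(groups)
    index = pd.Index(samples or [f"S{i+1}" for i in range(n)], name="sample")
    frame = pd.DataFrame(values, index=index, dtype=float)
    meta = pd.DataFrame(
        {"group": groups, "experiment": experiment, "matrix": matrix},
        index=index,
    )
    return ConcentrationTable(values=frame,
                              species=[parse_lipid_name(c) for c in frame.columns],
                              sample_meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_table():
    return make_table(
        {
            "FA 16:0": [4.0, 5.0, 4.5, 8.0, 9.0, 8.5],
            "FA 16:1 n-7": [1.0, 1.2, 1.1, 2.4, 2.6, 2.5],
            "FA 20:4 n-6": [3.0, 3.3, 2.9, 3.1, 3.2, 3.0],
        },
        groups=["GF"] * 3 + ["SPF"] * 3,
    )
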