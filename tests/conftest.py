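import numpy as np
import pandas as pd
import pytest

from metasig.preprocessing import PanelMatrix


@pytest.fixture
def tiny_panel():
    """4 samples x 3 proteins, hand-sized for pair enumeration."""
    values = pd.DataFrame(
        [[1.0, 5.0, 2.0], [2.0, 6.0, 1.0], [7.0, 1.0, 4.0], [8.0, 2.0, 5.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A", "B", "C"],
    )
    labels = pd.Series(["case", "case", "control", "control"], index=values.index)
    return PanelMatrix(values=values, labels=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_panel(X, labels, sample_prefix="s", columns=None):
    X = np.asarray(X, dtype=float)
    ids = [f"{sample_prefix}{i}" for i in range(X.shape[0])]
    cols = columns or [f"f{j}" for j in range(X.shape[1])]
    return PanelMatrix(
        values=pd.DataFrame(X, index=ids, columns=cols),
        labels=pd.Series(list(labels), index=ids),
    )
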