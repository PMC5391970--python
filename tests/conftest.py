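import numpy as np
import pandas as pd
import pytest

from concord.io import ExpressionMatrix, ScreenResult


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_matrix():
    """4 genes x 4 samples, two per group, continuous values."""
    values = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [5.0, 6.0, 7.0, 8.0],
                [2.5, 1.5, 0.5, 3.5],
                [9.0, 8.5, 7.5, 6.5],
            ]
        ),
        index=["g1", "g2", "g3", "g4"],
        columns=["v1", "v2", "r1", "r2"],
    )
    groups = pd.Series(
        ["vulnerable", "vulnerable", "resistant", "resistant"],
        index=values.columns,
    )
    return ExpressionMatrix(values, groups)


def make_screen(screen_id, rows, species="mouse"):
    """rows: iterable of (gene, log2fc, q)."""
    records = pd.DataFrame(
        [(g, fc, q, q) for g, fc, q in rows], columns=["gene", "log2fc", "p", "q"]
    )
    return ScreenResult(screen_id, species, records)


def random_continuous_matrix(rng, n_genes=50, n_per_group=3):
    cols = [f"v{i}" for i in range(n_per_group)] + [f"r{i}" for i in range(n_per_group)]
    values = pd.DataFrame(
        rng.normal(8, 2, size=(n_genes, 2 * n_per_group)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
    )
    groups = pd.Series(
        ["vulnerable"] * n_per_group + ["resistant"] * n_per_group, index=cols
    )
    return ExpressionMatrix(values, groups)
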