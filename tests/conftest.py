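import numpy as np
import pandas as pd
import pytest

from rsikit.containers import CountMatrix, ExpressionMatrix, plain_sample_table
from rsikit.synthetic import SimulationConfig, generate_counts


def make_expr(values: np.ndarray, gene_prefix: str = "g", sample_prefix: str = "s",
              conditions: list[str] | None = None) -> ExpressionMatrix:
    """Wrap a plain array as an ExpressionMatrix with minimal metadata."""
    g, n = values.shape
    genes = [f"{gene_prefix}{i + 1:03d}" for i in range(g)]
    samples = [f"{sample_prefix}{j + 1}" for j in range(n)]
    meta = plain_sample_table(samples, source="src", condition="cond")
    if conditions is not None:
        meta["condition"] = conditions
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)


def make_counts(values: np.ndarray, conditions: list[str] | None = None) -> CountMatrix:
    g, n = values.shape
    genes = [f"g{i + 1:03d}" for i in range(g)]
    samples = [f"s{j + 1}" for j in range(n)]
    meta = plain_sample_table(samples, source="src", condition="cond")
    if conditions is not None:
        meta["condition"] = conditions
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)


@pytest.fixture(scope="session")
def small_study():
    """A modest planted study shared by read-only tests."""
    return generate_counts(SimulationConfig(n_genes=600, seed=3))


@pytest.fixture(scope="session")
def two_group_design():
    design = pd.DataFrame(
        {"intercept": np.ones(6), "group": [0, 0, 0, 1, 1, 1]},
        index=[f"s{j + 1}" for j in range(6)],
    )
    contrast = pd.Series({"intercept": 0.0, "group": 1.0})
    return design, contrast
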