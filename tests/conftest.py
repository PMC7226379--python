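import numpy as np
import pandas as pd
import pytest

from sigmark.data_io import CohortTable, ExpressionMatrix


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 6 samples, log2 scale, first 3 samples 'treated'."""
    rng = np.random.default_rng(42)
    vals = rng.normal(8.0, 1.0, size=(3, 6))
    return ExpressionMatrix(pd.DataFrame(
        vals,
        index=["GA", "GB", "GC"],
        columns=[f"S{i}" for i in range(6)],
    ))


@pytest.fixture
def small_cohort() -> CohortTable:
    rng = np.random.default_rng(7)
    n = 12
    return CohortTable(pd.DataFrame(
        {
            "time": rng.uniform(1, 60, size=n),
            "event": rng.integers(0, 2, size=n),
            "stage_group": rng.integers(0, 2, size=n),
            "marker": rng.normal(6.0, 1.5, size=n),
        },
        index=pd.Index([f"PT{i:02d}" for i in range(n)], name="sample_id"),
    ))


def make_diff_table(genes, z, p, effect=None):
    """Assemble a DifferentialTable from explicit vectors (test helper)."""
    import pandas as pd

    from sigmark.differential import DifferentialTable

    effect = effect if effect is not None else z
    df = pd.DataFrame({"effect": effect, "z": z, "p": p},
                      index=pd.Index(genes, name="gene_id"))
    return DifferentialTable(df, n_treated=3, n_control=3)
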