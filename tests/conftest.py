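import numpy as np
import pandas as pd
import pytest

from cernascope.matrix import ExpressionMatrix
from cernascope.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic study, reused across read-only tests."""
    return generate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_de(default_dataset):
    from cernascope.diffexpr import differential_expression
    return differential_expression(default_dataset.matrix)


@pytest.fixture()
def tiny_matrix():
    """Hand-sized 6-gene, 4+4-sample matrix for direct assertions."""
    rng = np.random.default_rng(42)
    genes = [f"M{i}" for i in range(4)] + ["L0", "L1"]
    samples = [f"c{i}" for i in range(4)] + [f"n{i}" for i in range(4)]
    values = pd.DataFrame(rng.normal(8.0, 0.3, (6, 8)), index=genes,
                          columns=samples)
    values.loc["M0", samples[:4]] += 2.0    # planted up mRNA
    values.loc["L0", samples[:4]] -= 2.0    # planted down lncRNA
    return ExpressionMatrix(
        values,
        biotypes=pd.Series(["mRNA"] * 4 + ["lncRNA"] * 2, index=genes),
        groups=pd.Series(["case"] * 4 + ["control"] * 4, index=samples),
    )
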