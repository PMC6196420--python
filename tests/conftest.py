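import numpy as np
import pandas as pd
import pytest

import scpquant as sq


@pytest.fixture(scope="session")
def small_experiment():
    """Two TMT-10 sets, 100 proteins, alternating A/B cells — shared across
    tests that only read from it."""
    cfg = sq.SimulationConfig(n_sets=2, n_proteins=100, seed=42)
    truth, designs, records = sq.simulate_experiment(cfg)
    return cfg, truth, designs, records


@pytest.fixture
def tiny_design():
    anns = [
        sq.CellAnnotation(cell_id=f"c{i}", cell_type="A" if i % 2 == 0 else "B", day=0)
        for i in range(8)
    ]
    return sq.make_tmt10_design("set1", anns)


def make_quant(values: np.ndarray, row_prefix="f", col_prefix="c", level="protein",
               col_meta=None) -> sq.QuantMatrix:
    """QuantMatrix from a raw array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{row_prefix}{i}" for i in range(values.shape[0])],
        columns=[f"{col_prefix}{j}" for j in range(values.shape[1])],
    )
    return sq.QuantMatrix(values=df, level=level, col_meta=col_meta)
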