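import numpy as np
import pandas as pd
import pytest

from allomap import sim


@pytest.fixture(scope="session")
def small_panel():
    """A modest mixed-category expression panel with ground truth."""
    cfg = sim.ExpressionSimConfig(n_genes=400, seed=11)
    counts, samples, truth = sim.simulate_expression_panel(cfg)
    return counts, samples, truth


@pytest.fixture()
def step_track():
    """Noiseless allele-ratio track: human fraction 0.5 then 1.0 after feature 50."""
    n = 100
    pos = np.arange(1, n + 1) * 1_000_000
    human = np.where(np.arange(n) < 50, 50, 100)
    chimp = np.where(np.arange(n) < 50, 50, 0)
    return pd.DataFrame({"position": pos, "count_human": human, "count_chimp": chimp})
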