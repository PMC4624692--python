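import numpy as np
import pytest

from ghrelin_rhythms import RHYTHMIC_PANEL, SeriesParams, SimulationConfig, simulate_expression

HYPOTHALAMUS_PPG = RHYTHMIC_PANEL[0]  # mesor 2.7, amplitude 1.2, acrophase 16.3
GI_PPG = RHYTHMIC_PANEL[2]  # mesor 3.9, amplitude 3.3, acrophase 17.4


@pytest.fixture
def noiseless_hypothalamus():
    """Exact cosinor-mean data for the hypothalamic preproghrelin series."""
    config = SimulationConfig(series=(HYPOTHALAMUS_PPG,), noise_sd=0.0, seed=0)
    return simulate_expression(config)


@pytest.fixture
def noisy_series():
    """One noisy simulated series (fixed seed) plus its generative truth."""
    config = SimulationConfig(series=(HYPOTHALAMUS_PPG,), noise_sd=1.0, seed=123)
    df = simulate_expression(config)
    return df, HYPOTHALAMUS_PPG


def replicate_seeds(master: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds for Monte-Carlo tests."""
    return np.random.default_rng(master).integers(2**31, size=n)
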