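import numpy as np
import pandas as pd
import pytest

from endofluct import DecisionParams, SyntheticConfig
from endofluct.design import build_calibration_trials


@pytest.fixture
def params():
    return DecisionParams(alpha=0.9, mu=3.0, kappa=0.5)


@pytest.fixture
def base_params():
    return DecisionParams(alpha=0.9, mu=3.0, kappa=0.0)


@pytest.fixture
def synth_config():
    return SyntheticConfig(seed=7)


def make_offer_grid(n_repeats: int, seed: int = 0) -> pd.DataFrame:
    """Calibration-style offer grid repeated to the requested trial count."""
    blocks = [
        build_calibration_trials(repeats=5, seed=seed + i)
        for i in range(int(np.ceil(n_repeats / 5)))
    ]
    return pd.concat(blocks, ignore_index=True)
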