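import numpy as np
import pytest

import drnlha


@pytest.fixture(scope="session")
def defaults() -> drnlha.CircuitParameters:
    return drnlha.default_parameters()


@pytest.fixture(scope="session")
def baseline(defaults) -> drnlha.SteadyState:
    """Analytic baseline fixed point of the reference circuit."""
    return drnlha.steady_state(defaults)


#: Baseline rates frozen from the exact solve of the all-active linear
#: fixed-point system (cross-checked by long RK2 integration).
BASELINE_RATES = np.array([5.0028991, 15.0116836, 5.0245204, 5.0272870])

#: 5-HT rate after removing every orexin-sourced connection (exact solve of
#: the reduced 2-population DRN system).
KNOCKOUT_5HT_RATE = 3.5741170
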