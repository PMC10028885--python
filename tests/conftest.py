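import numpy as np
import pytest

from aancolumn import (SimulationConfig, build_default_column,
                       default_connectivity, set_connectivity)
from aancolumn.fitting import build_variant, simulate_condition


@pytest.fixture(scope="session")
def column():
    """A fresh default column (geometry is deterministic)."""
    return build_default_column(seed=0, scale=300)


@pytest.fixture(scope="session")
def wired_column():
    net = build_default_column(seed=0, scale=300)
    set_connectivity(net, default_connectivity())
    return net


@pytest.fixture(scope="session")
def preferred_batches():
    """Preferred-model 10-trial batches for both conditions (seed 42).

    Shared across the spiking-contrast and waveform tests to keep the
    suite within budget.
    """
    cfg = SimulationConfig(n_trials=10, base_seed=42)
    out = {}
    for condition in ("undetected", "detected"):
        avg, trials, net = simulate_condition(build_variant("preferred"),
                                              condition, cfg,
                                              return_trials=True)
        out[condition] = {"avg": avg, "trials": trials, "net": net}
    return out
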