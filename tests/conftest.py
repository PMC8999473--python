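import numpy as np
import pytest

from ctcsim.engine import IntegrationSettings, integrate
from ctcsim.network import build_default_network
from ctcsim.neuromodulation import condition_state
from ctcsim.observables import decimate_to, eeg_proxy


@pytest.fixture(scope="session")
def topology():
    return build_default_network()


@pytest.fixture(scope="session")
def condition_bank(topology):
    """Decimated analysis channels for the four conditions x 10 paired seeds.

    Shared by the directional band-power and phase-locking suites so the
    (condition, seed)-paired simulations are run once per test session.
    """
    bank = {}
    for cond in ("control", "atdcs", "ketamine", "ketamine+atdcs"):
        state = condition_state(cond)
        for seed in range(10):
            res = integrate(
                topology, state,
                IntegrationSettings(duration=60.0, burn_in=5.0, seed=seed),
            )
            channels = {}
            for name, series in (
                ("EEG", eeg_proxy(res)),
                ("GIG_E", res.series("GIG_E")),
                ("RELAY_E", res.series("RELAY_E")),
                ("RETIC_I", res.series("RETIC_I")),
            ):
                y, fs = decimate_to(series, res.sample_rate)
                channels[name] = y
            channels["fs"] = fs
            bank[(cond, seed)] = channels
    return bank
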