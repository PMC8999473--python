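"""YAML/JSON configuration loading for networks, conditions and protocols.

The configuration dialect is a nested mapping with optional sections:

.. code-block:: yaml

    network:            # overrides of the default network parameters
      populations: {GIG_E: {resting_offset: 4.5}}
      synapses: {"GIG_E->RELAY_E": {efficacy: 0.1}}
      aras: {mean_input: 7.0}
    condition: ketamine # or control / atdcs / ketamine+atdcs
    modulation:         # explicit parameter bundles (override `condition`)
      short_tdcs: {I_tDCS: 0.8}
      long_tdcs: {f_tDCS: 1.2, f_tDCS_resp: 1.2}
      ketamine: {f_ketamine_loop: 0.7, f_ketamine_SG: 0.8, aras_disinhibition_gain: 1.3}
    integration: {dt: 1.0e-4, duration: 100.0, burn_in: 5.0, seed: 1, noise_on: true}

The committed file ``data/default_network.yaml`` holds the calibrated
default network; :func:`load_default_network_config` reads it.
"""

from __future__ import annotations

import json
from dataclasses import replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .engine import IntegrationSettings
from .network import NetworkTopology, build_default_network
from .neuromodulation import (
    KetamineParams,
    LongTDCSParams,
    ModulationState,
    ShortTDCSParams,
    condition_state,
)

__all__ = [
    "load_config",
    "load_default_network_config",
    "topology_from_config",
    "modulation_from_config",
    "settings_from_config",
]


def load_config(path) -> dict:
    """Load a YAML or JSON configuration document."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def load_default_network_config() -> dict:
    """The calibrated default network parameters shipped with the package."""
    with resources.files("ctcsim.data").joinpath("default_network.yaml").open() as fh:
        return yaml.safe_load(fh)


def topology_from_config(cfg: Mapping) -> NetworkTopology:
    return build_default_network(cfg.get("network"))


def modulation_from_config(cfg: Mapping) -> ModulationState:
    """Resolve the condition bundle of a configuration document."""
    state = condition_state(cfg.get("condition", "control"))
    mod = cfg.get("modulation") or {}
    kwargs = {}
    if "short_tdcs" in mod:
        kwargs["short_tdcs"] = ShortTDCSParams(**mod["short_tdcs"])
    if "long_tdcs" in mod:
        kwargs["long_tdcs"] = LongTDCSParams(**mod["long_tdcs"])
    if "ketamine" in mod:
        kwargs["ketamine"] = KetamineParams(**mod["ketamine"])
    return replace(state, **kwargs) if kwargs else state


def settings_from_config(cfg: Mapping, seed: int | None = None) -> IntegrationSettings:
    integ = dict(cfg.get("integration") or {})
    if seed is not None:
        integ["seed"] = seed
    return IntegrationSettings(**integ)
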