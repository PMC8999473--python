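"""Intervention models: short- and long-duration tDCS and ketamine.

Three pure transformations of the network:

* **Short-duration tDCS** (seconds to minutes) shifts cortical excitability
  transiently: a constant input ``input_gain * I_tDCS`` (mV) is added to
  all four cortical populations and their sigmoid steepness is rescaled by
  ``1 - kappa * I_tDCS``.  Anodal currents (``I_tDCS > 0``) raise the input
  and flatten the sigmoid; cathodal currents do the opposite.  The
  co-modulation of input and steepness reflects the extra Poisson spiking
  noise the current injects into the population.

* **Long-duration anodal tDCS** leaves an LTP-like after-effect: every
  excitatory efficacy targeting a cortical population is multiplied by
  ``f_tDCS >= 1`` and the ARAS afferent efficacy by ``f_tDCS_resp``.  The
  factor itself evolves in time: logistic (Verhulst) growth toward a
  saturation ``f_sat`` during stimulation and slow exponential relaxation
  back to 1 afterwards.

* **Ketamine** models NMDA-receptor hypofunction at GABAergic neurons as
  effective disinhibition: inhibitory efficacies in the cortico-thalamic
  loop and in the supragranular layer are scaled down by factors <= 1 and
  the ARAS mean input is scaled up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .network import (
    ARAS_SOURCE,
    CORTICAL_POPULATIONS,
    NetworkTopology,
    SynapseSpec,
)

__all__ = [
    "ShortTDCSParams",
    "LongTDCSParams",
    "KetamineParams",
    "PlasticityParams",
    "StimulationProtocol",
    "ModulationState",
    "apply_short_tdcs",
    "apply_long_tdcs",
    "apply_ketamine",
    "plasticity_step",
    "plasticity_decay",
    "plasticity_trajectory",
    "calibrate_growth_seed",
    "CONDITIONS",
    "condition_state",
]

#: Supported model-current range for the short-duration tDCS transform.
MAX_ABS_CURRENT = 1.0


@dataclass(frozen=True)
class ShortTDCSParams:
    """Transient excitability model of a weak direct current.

    ``I_tDCS`` is the signed model current (>0 anodal, <0 cathodal),
    ``input_gain`` converts it to a cortical input potential (mV per unit
    current) and ``steepness_coupling`` (kappa) sets the relative
    steepness change per unit current.
    """

    I_tDCS: float = 0.0
    input_gain: float = 1.5
    steepness_coupling: float = 0.2

    def __post_init__(self) -> None:
        if not self.input_gain > 0:
            raise ValueError("input_gain must be positive")
        if abs(self.I_tDCS) > MAX_ABS_CURRENT:
            raise ValueError(
                f"|I_tDCS| = {abs(self.I_tDCS)} outside supported range "
                f"[-{MAX_ABS_CURRENT}, {MAX_ABS_CURRENT}]"
            )
        if 1.0 - self.steepness_coupling * self.I_tDCS <= 0:
            raise ValueError("steepness scale 1 - kappa*I must stay positive")


@dataclass(frozen=True)
class LongTDCSParams:
    """LTP-like after-effect factors of long anodal stimulation."""

    f_tDCS: float = 1.0
    f_tDCS_resp: float = 1.0

    def __post_init__(self) -> None:
        if self.f_tDCS < 1.0 or self.f_tDCS_resp < 1.0:
            raise ValueError(
                "long-duration factors must be >= 1 (cathodal long-term "
                "effects are not modelled)"
            )


@dataclass(frozen=True)
class KetamineParams:
    """NMDA-hypofunction factors (inhibitory-efficacy scalings <= 1)."""

    f_ketamine_loop: float = 1.0
    f_ketamine_SG: float = 1.0
    aras_disinhibition_gain: float = 1.0

    def __post_init__(self) -> None:
        for name, v in (
            ("f_ketamine_loop", self.f_ketamine_loop),
            ("f_ketamine_SG", self.f_ketamine_SG),
        ):
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1] (ketamine never strengthens inhibition)")
        if self.aras_disinhibition_gain < 1:
            raise ValueError("aras_disinhibition_gain must be >= 1")


@dataclass(frozen=True)
class PlasticityParams:
    """Kinetics of the plasticity factor f(t).

    Growth during stimulation is logistic in ``g = f - 1`` with carrying
    capacity ``f_sat - 1`` and time constant ``tau_plast / rate(current)``;
    decay after offset is exponential with ``tau_decay >> tau_plast``.
    ``seed_fraction`` (epsilon0 / (f_sat - 1)) seeds the growth away from
    the unstable g = 0 equilibrium; the default value is calibrated so a
    12 min stimulation yields f = 1.2 and a 4 min stimulation f = 1.05 at
    tau_plast = 1 min (see :func:`calibrate_growth_seed`).
    """

    f_sat: float = 1.2
    tau_plast: float = 3.0 * 3600.0   # s
    tau_decay: float = 500.0 * 3600.0  # s
    current_ref: float = 1.0
    seed_fraction: float = 1.0 / 164.77
    f_baseline: float = 1.0

    def __post_init__(self) -> None:
        if not self.f_sat > self.f_baseline == 1.0:
            raise ValueError("need f_sat > f_baseline = 1")
        if not self.tau_plast > 0:
            raise ValueError("tau_plast must be positive")
        if not self.tau_decay > self.tau_plast:
            raise ValueError("tau_decay must exceed tau_plast (decay is much slower)")
        if not 0 < self.seed_fraction < 1:
            raise ValueError("seed_fraction must lie in (0, 1)")

    def growth_rate(self, current: float) -> float:
        """Linear current dependence: higher current grows faster."""
        if current <= 0:
            raise ValueError("plasticity growth requires an anodal (positive) current")
        return current / self.current_ref

    @property
    def epsilon0(self) -> float:
        return self.seed_fraction * (self.f_sat - 1.0)


@dataclass(frozen=True)
class StimulationProtocol:
    """Ordered, non-overlapping stimulation blocks (onset, duration, current)."""

    blocks: tuple[tuple[float, float, float], ...]
    total_horizon: float

    def __post_init__(self) -> None:
        last_end = -math.inf
        for onset, dur, cur in self.blocks:
            if dur < 0:
                raise ValueError("block duration must be non-negative")
            if onset < last_end:
                raise ValueError("blocks must be sorted and non-overlapping")
            last_end = onset + dur
        if self.total_horizon < last_end:
            raise ValueError("total_horizon shorter than the last block")

    @classmethod
    def repeated(
        cls,
        duration: float,
        pause: float,
        repetitions: int,
        final_period: float,
        current: float = 1.0,
        start: float = 0.0,
    ) -> "StimulationProtocol":
        """Equally spaced blocks: ``repetitions`` of ``duration`` separated
        by ``pause``, followed by a final observation period."""
        blocks = tuple(
            (start + k * (duration + pause), duration, current)
            for k in range(repetitions)
        )
        horizon = blocks[-1][0] + duration + final_period if blocks else final_period
        return cls(blocks=blocks, total_horizon=horizon)


@dataclass(frozen=True)
class ModulationState:
    """The intervention triple applied to a topology at a given time."""

    short_tdcs: ShortTDCSParams | None = None
    long_tdcs: LongTDCSParams | None = None
    ketamine: KetamineParams | None = None

    def resolve(
        self, topology: NetworkTopology
    ) -> tuple[NetworkTopology, dict[str, float], dict[str, float]]:
        """Return (modulated topology, input_add, steepness_scale)."""
        topo = topology
        if self.ketamine is not None:
            topo = apply_ketamine(topo, self.ketamine)
        if self.long_tdcs is not None:
            topo = apply_long_tdcs(topo, self.long_tdcs)
        input_add: dict[str, float] = {}
        steep: dict[str, float] = {}
        if self.short_tdcs is not None:
            input_add, steep = apply_short_tdcs(topo, self.short_tdcs)
        return topo, input_add, steep


# ---------------------------------------------------------------------------
# Short-duration tDCS
# ---------------------------------------------------------------------------

def apply_short_tdcs(
    topology: NetworkTopology, p: ShortTDCSParams
) -> tuple[dict[str, float], dict[str, float]]:
    """Cortical input shift and steepness rescale for a model current.

    Returns ``(input_add, steepness_scale)`` keyed by population name;
    thalamic populations are untouched.  ``I_tDCS = 0`` is the identity.
    """
    scale = 1.0 - p.steepness_coupling * p.I_tDCS
    if scale <= 0:
        raise ValueError("steepness scale must remain positive")
    input_add = {name: p.input_gain * p.I_tDCS for name in CORTICAL_POPULATIONS}
    steep = {name: scale for name in CORTICAL_POPULATIONS}
    return input_add, steep


# ---------------------------------------------------------------------------
# Long-duration tDCS and ketamine (diagonal efficacy scalings)
# ---------------------------------------------------------------------------

def _cortical_target(s: SynapseSpec) -> bool:
    return s.target in CORTICAL_POPULATIONS


def apply_long_tdcs(topology: NetworkTopology, p: LongTDCSParams) -> NetworkTopology:
    """Scale cortical excitatory efficacies by ``f_tDCS``; ARAS by ``f_tDCS_resp``.

    Every excitatory synapse whose target lies in SG or GIG is multiplied
    by ``f_tDCS``; inhibitory efficacies and thalamic-target efficacies are
    unchanged.  The ARAS afferent gain is multiplied by ``f_tDCS_resp``.
    """
    new_syn = []
    for s in topology.synapses:
        if s.source == ARAS_SOURCE:
            new_syn.append(s)  # handled through the drive gain below
        elif s.is_excitatory and _cortical_target(s):
            new_syn.append(replace(s, efficacy=s.efficacy * p.f_tDCS))
        else:
            new_syn.append(s)
    out = topology.replace_synapses(new_syn)
    out.aras = replace(
        topology.aras, efficacy_gain=topology.aras.efficacy_gain * p.f_tDCS_resp
    )
    return out


def apply_ketamine(topology: NetworkTopology, p: KetamineParams) -> NetworkTopology:
    """Disinhibition transform of NMDA hypofunction at GABAergic neurons.

    Inhibitory output efficacies in the cortico-thalamic loop (GIG_I,
    RETIC_I sources) are scaled by ``f_ketamine_loop``; supragranular
    inhibitory outputs (SG_I) by ``f_ketamine_SG``; the ARAS mean input is
    amplified by ``aras_disinhibition_gain``.
    """
    new_syn = []
    for s in topology.synapses:
        if s.is_excitatory:
            new_syn.append(s)
        elif s.source == "SG_I":
            new_syn.append(replace(s, efficacy=s.efficacy * p.f_ketamine_SG))
        else:  # GIG_I and RETIC_I outputs live in the cortico-thalamic loop
            new_syn.append(replace(s, efficacy=s.efficacy * p.f_ketamine_loop))
    out = topology.replace_synapses(new_syn)
    out.aras = replace(
        topology.aras,
        disinhibition_gain=topology.aras.disinhibition_gain * p.aras_disinhibition_gain,
    )
    return out


# ---------------------------------------------------------------------------
# Plasticity kinetics
# ---------------------------------------------------------------------------

def plasticity_decay(f0: float, t: float, p: PlasticityParams) -> float:
    """Closed-form post-offset decay ``f(t) = 1 + (f0 - 1) exp(-t/tau_decay)``."""
    return 1.0 + (f0 - 1.0) * math.exp(-t / p.tau_decay)


def plasticity_step(
    f: float,
    stimulating: bool,
    current: float,
    dt: float,
    p: PlasticityParams,
) -> float:
    """Advance the plasticity factor by ``dt`` seconds.

    Uses the exact per-phase flow maps (logistic growth during
    stimulation, exponential decay otherwise), so the step is accurate for
    any ``dt``.  At stimulation onset the factor is seeded to
    ``1 + epsilon0`` if it sits below the seed, because g = f - 1 = 0 is a
    (unstable) equilibrium of the pure growth law.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if f < 1.0 - 1e-9:
        raise ValueError("plasticity factor below baseline 1")
    g = max(f - 1.0, 0.0)
    if stimulating:
        g = max(g, p.epsilon0)
        gsat = p.f_sat - 1.0
        rho = p.growth_rate(current) / p.tau_plast
        # exact logistic flow map
        g = gsat / (1.0 + (gsat / g - 1.0) * math.exp(-rho * dt))
    else:
        g *= math.exp(-dt / p.tau_decay)
    return 1.0 + g


def plasticity_trajectory(
    protocol: StimulationProtocol,
    p: PlasticityParams,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Plasticity factor time series f(t) over a stimulation protocol.

    Piecewise application of :func:`plasticity_step` on a uniform grid;
    continuous in t and fully deterministic.  Returns ``(t, f)``.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    n = int(round(protocol.total_horizon / dt)) + 1
    t = np.arange(n) * dt
    f = np.ones(n)
    cur_f = 1.0
    for i in range(1, n):
        mid = 0.5 * (t[i - 1] + t[i])
        stim_cur = 0.0
        for onset, dur, cur in protocol.blocks:
            if onset <= mid < onset + dur:
                stim_cur = cur
                break
        cur_f = plasticity_step(cur_f, stim_cur > 0, stim_cur, dt, p)
        f[i] = cur_f
    return t, f


def time_to_factor(
    target_f: float, current: float, p: PlasticityParams, dt: float = 1.0,
    max_time: float | None = None,
) -> float:
    """Stimulation time needed to reach a target factor at a given current."""
    g_target = target_f - 1.0
    gsat = p.f_sat - 1.0
    if not 0 < g_target < gsat:
        raise ValueError("target factor must lie strictly between 1 and f_sat")
    # invert the logistic flow map from the seed
    rho = p.growth_rate(current) / p.tau_plast
    g0 = p.epsilon0
    return math.log((gsat / g0 - 1.0) / (gsat / g_target - 1.0)) / rho


def calibrate_growth_seed(
    pairs: Sequence[tuple[float, float]],
    p: PlasticityParams,
    current: float = 1.0,
) -> tuple[float, dict]:
    """Fit the growth seed fraction to printed (duration, factor) pairs.

    Least-squares over ``log(seed_fraction)`` so the logistic growth law
    reproduces the anchor points, e.g. (12 min, 1.2) and (4 min, 1.05) at
    ``tau_plast = 1`` min.  Returns the fitted fraction and a report with
    per-pair residuals.
    """
    from scipy.optimize import minimize_scalar

    gsat = p.f_sat - 1.0

    def predict(frac: float, Ts: float) -> float:
        g0 = frac * gsat
        rho = p.growth_rate(current) / p.tau_plast
        return 1.0 + gsat / (1.0 + (gsat / g0 - 1.0) * math.exp(-rho * Ts))

    def loss(log_frac: float) -> float:
        frac = math.exp(log_frac)
        return sum((predict(frac, Ts) - f) ** 2 for Ts, f in pairs)

    res = minimize_scalar(loss, bounds=(math.log(1e-8), math.log(0.5)), method="bounded")
    frac = math.exp(res.x)
    report = {
        "seed_fraction": frac,
        "epsilon0": frac * gsat,
        "residuals": {
            f"Ts={Ts}": predict(frac, Ts) - f for Ts, f in pairs
        },
    }
    return frac, report


# ---------------------------------------------------------------------------
# Named experimental conditions
# ---------------------------------------------------------------------------

#: Factor bundles of the four experimental conditions: ketamine factors
#: 0.7 in the cortico-thalamic loop and 0.8 in SG, and, for the combined
#: condition, the after-effect of a 4-minute anodal stimulation
#: (f_tDCS = 1.05) with a doubled ARAS response (f_tDCS_resp = 2.0).
CONDITIONS: dict[str, ModulationState] = {
    "control": ModulationState(),
    "atdcs": ModulationState(long_tdcs=LongTDCSParams(f_tDCS=1.2, f_tDCS_resp=1.2)),
    "ketamine": ModulationState(
        ketamine=KetamineParams(
            f_ketamine_loop=0.7, f_ketamine_SG=0.8, aras_disinhibition_gain=1.3
        )
    ),
    "ketamine+atdcs": ModulationState(
        ketamine=KetamineParams(
            f_ketamine_loop=0.7, f_ketamine_SG=0.8, aras_disinhibition_gain=1.3
        ),
        long_tdcs=LongTDCSParams(f_tDCS=1.05, f_tDCS_resp=2.0),
    ),
}


def condition_state(name: str, **overrides) -> ModulationState:
    """Look up a named condition, optionally overriding its parameters."""
    if name not in CONDITIONS:
        raise KeyError(f"unknown condition {name!r}; choose from {sorted(CONDITIONS)}")
    state = CONDITIONS[name]
    if overrides:
        state = replace(state, **overrides)
    return state
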