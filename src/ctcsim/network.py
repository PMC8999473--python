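"""Cortico-thalamo-cortical (CTC) population network with ARAS drive.

The network lumps six neural populations: an excitatory/inhibitory pair in
the supragranular cortical layers I-III (``SG_E``/``SG_I``), an E/I pair for
the granular+infragranular layers IV-VI (``GIG_E``/``GIG_I``), thalamic
relay cells (``RELAY_E``) and the inhibitory thalamic reticular nucleus
(``RETIC_I``).  Each population converts its mean membrane potential into a
mean firing rate through a sigmoid transfer function; each synapse filters
the delayed presynaptic rate through a critically damped second-order
("alpha") kernel of unit area, so a constant rate ``r`` through efficacy
``w`` (mV s) asymptotically contributes ``w * r`` mV to the target
potential.  The brainstem arousal system (ARAS) drives the supragranular
layer with a tonic mean plus Gaussian white noise, filtered by the same
kernel type.

Rhythm placement follows the hypothesis that the delta and sigma (sleep
spindle) rhythms arise in the cortico-thalamic loop while the gamma rhythm
is generated in the supragranular E-I circuit: the loop carries 15 ms
conduction delays each way (sigma resonance of the delayed excitatory
GIG<->relay loop), the reticular afferents use slow kernels (delta
resonance of the relay<->reticular inhibitory loop) and the SG E-I pair
uses fast kernels (gamma resonance).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "POPULATION_NAMES",
    "CORTICAL_POPULATIONS",
    "REGION_OF",
    "PopulationSpec",
    "SynapseSpec",
    "ARASDrive",
    "ExternalDrive",
    "NetworkTopology",
    "CompiledNetwork",
    "ModelState",
    "sigmoid_rate",
    "build_default_network",
    "compile_network",
    "network_rhs",
    "fixed_point",
    "fixed_point_iterate",
    "linear_power_spectrum",
    "alpha_kernel_response",
]

#: Canonical population order used by every array interface of the package.
POPULATION_NAMES = ("SG_E", "SG_I", "GIG_E", "GIG_I", "RELAY_E", "RETIC_I")

#: Anatomical region of each population.
REGION_OF = {
    "SG_E": "SG",
    "SG_I": "SG",
    "GIG_E": "GIG",
    "GIG_I": "GIG",
    "RELAY_E": "relay",
    "RETIC_I": "reticular",
}

CORTICAL_POPULATIONS = ("SG_E", "SG_I", "GIG_E", "GIG_I")
THALAMIC_POPULATIONS = ("RELAY_E", "RETIC_I")

#: Populations belonging to the cortico-thalamic loop sub-circuit.
LOOP_POPULATIONS = ("GIG_E", "GIG_I", "RELAY_E", "RETIC_I")

ARAS_SOURCE = "ARAS"

#: Directed edges (source, target, sign) that the topology must contain.
REQUIRED_EDGES = (
    ("GIG_E", "RELAY_E", +1),
    ("GIG_E", "RETIC_I", +1),
    ("RELAY_E", "GIG_E", +1),
    ("RELAY_E", "RETIC_I", +1),
    ("RETIC_I", "RELAY_E", -1),
    ("RELAY_E", "SG_E", +1),
    (ARAS_SOURCE, "SG_E", +1),
    ("SG_E", "SG_I", +1),
    ("SG_I", "SG_E", -1),
    ("GIG_E", "GIG_I", +1),
    ("GIG_I", "GIG_E", -1),
)

#: Edges that must be absent: the reticular nucleus never projects to
#: cortex and the supragranular layer never projects to the thalamus.
FORBIDDEN_EDGES = (
    ("RETIC_I", "SG_E"),
    ("RETIC_I", "SG_I"),
    ("RETIC_I", "GIG_E"),
    ("RETIC_I", "GIG_I"),
    ("SG_E", "RELAY_E"),
    ("SG_E", "RETIC_I"),
    ("SG_I", "RELAY_E"),
    ("SG_I", "RETIC_I"),
)


@dataclass(frozen=True)
class PopulationSpec:
    """Static description of one neural population.

    Parameters
    ----------
    name
        One of :data:`POPULATION_NAMES`.
    polarity
        ``"excitatory"`` or ``"inhibitory"``; fixes the sign of all
        efferent synaptic efficacies.
    Smax
        Maximum population firing rate (1/s).
    theta
        Inflection potential of the sigmoid transfer function (mV).
    steepness
        Sigmoid slope parameter c (1/mV).
    resting_offset
        Tonic input potential (mV) added to the synaptic drive.
    """

    name: str
    polarity: str
    Smax: float
    theta: float
    steepness: float
    resting_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in POPULATION_NAMES:
            raise ValueError(f"unknown population name {self.name!r}")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        if self.name.endswith("_E") and self.polarity != "excitatory":
            raise ValueError(f"{self.name} must be excitatory")
        if self.name.endswith("_I") and self.polarity != "inhibitory":
            raise ValueError(f"{self.name} must be inhibitory")
        if not self.Smax > 0:
            raise ValueError("Smax must be positive")
        if not self.steepness > 0:
            raise ValueError("steepness must be positive")

    @property
    def region(self) -> str:
        return REGION_OF[self.name]


@dataclass(frozen=True)
class SynapseSpec:
    """One delayed synaptic connection.

    ``efficacy`` is signed by the source polarity (mV s); ``rise_rate`` is
    the alpha-kernel rate constant a (1/s); ``delay`` the conduction delay
    (s).  ``region_tag`` classifies the synapse for the pharmacology
    transforms: ``cortico_thalamic_loop``, ``SG`` or ``ARAS_afferent``.
    """

    source: str
    target: str
    efficacy: float
    rise_rate: float
    delay: float = 0.0
    region_tag: str = "cortico_thalamic_loop"

    def __post_init__(self) -> None:
        if self.target not in POPULATION_NAMES:
            raise ValueError(f"unknown target population {self.target!r}")
        if self.source not in POPULATION_NAMES + (ARAS_SOURCE,):
            raise ValueError(f"unknown source {self.source!r}")
        if self.region_tag not in ("cortico_thalamic_loop", "SG", "ARAS_afferent"):
            raise ValueError(f"unknown region_tag {self.region_tag!r}")
        if not self.rise_rate > 0:
            raise ValueError("rise_rate must be positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        sign = -1 if self.source.endswith("_I") else +1
        if self.efficacy * sign < 0:
            raise ValueError(
                f"efficacy sign of {self.source}->{self.target} contradicts "
                f"source polarity"
            )

    @property
    def is_excitatory(self) -> bool:
        return not self.source.endswith("_I")


@dataclass(frozen=True)
class ARASDrive:
    """Brainstem / arousal-system input to the supragranular layer.

    ``mean_input`` (mV) and ``noise_intensity`` (mV sqrt(s)) describe the
    tonic and stochastic components of the drive before it is filtered by
    the ARAS afferent kernel.  ``efficacy_gain`` multiplies the ARAS
    afferent efficacy (dimensionless; the long-duration tDCS response
    factor acts here) and ``disinhibition_gain`` multiplies ``mean_input``
    under ketamine.
    """

    mean_input: float
    noise_intensity: float
    efficacy_gain: float = 1.0
    disinhibition_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_intensity < 0:
            raise ValueError("noise_intensity must be non-negative")
        if not self.efficacy_gain > 0:
            raise ValueError("efficacy_gain must be positive")
        if self.disinhibition_gain < 1:
            raise ValueError("disinhibition_gain must be >= 1")

    @property
    def effective_mean(self) -> float:
        return self.mean_input * self.disinhibition_gain


@dataclass(frozen=True)
class ExternalDrive:
    """A filtered external input channel (tonic mean + white noise)."""

    target: str
    gain: float        # dimensionless multiplier on (mean + noise)
    mean: float        # mV
    sigma: float       # mV sqrt(s)
    rise_rate: float   # 1/s
    label: str = "drive"


@dataclass
class NetworkTopology:
    """Populations, signed delayed connections and the ARAS drive.

    ``relay_noise_sigma`` adds a weak independent noise drive onto the
    thalamic relay population (same kernel form as the ARAS afferent);
    stochastic input is otherwise localised to the ARAS.
    """

    populations: dict[str, PopulationSpec]
    synapses: list[SynapseSpec]
    aras: ARASDrive
    relay_noise_sigma: float = 0.0
    relay_noise_rise_rate: float = 60.0
    population_noise: dict = field(default_factory=dict)
    population_noise_rise_rate: float = 60.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        problems: list[str] = []
        missing = set(POPULATION_NAMES) - set(self.populations)
        if missing:
            problems.append(f"missing populations: {sorted(missing)}")
        edges = {(s.source, s.target): s for s in self.synapses}
        for src, tgt, sign in REQUIRED_EDGES:
            syn = edges.get((src, tgt))
            if syn is None:
                problems.append(f"missing required edge {src}->{tgt}")
            elif syn.efficacy * sign < 0:
                problems.append(f"edge {src}->{tgt} has wrong sign")
        for src, tgt in FORBIDDEN_EDGES:
            if (src, tgt) in edges and edges[src, tgt].efficacy != 0.0:
                problems.append(f"forbidden edge {src}->{tgt} present")
        if problems:
            raise ValueError("invalid network topology: " + "; ".join(problems))

    def synapse(self, source: str, target: str) -> SynapseSpec:
        for s in self.synapses:
            if s.source == source and s.target == target:
                return s
        raise KeyError(f"no synapse {source}->{target}")

    def replace_synapses(self, new: Iterable[SynapseSpec]) -> "NetworkTopology":
        out = copy.copy(self)
        out.synapses = list(new)
        out.validate()
        return out

    def drives(self) -> list[ExternalDrive]:
        """External drive channels (ARAS, optional relay noise)."""
        aras_syn = self.synapse(ARAS_SOURCE, "SG_E")
        out = [
            ExternalDrive(
                target="SG_E",
                gain=aras_syn.efficacy * self.aras.efficacy_gain,
                mean=self.aras.effective_mean,
                sigma=self.aras.noise_intensity,
                rise_rate=aras_syn.rise_rate,
                label="ARAS",
            )
        ]
        if self.relay_noise_sigma > 0:
            out.append(
                ExternalDrive(
                    target="RELAY_E",
                    gain=1.0,
                    mean=0.0,
                    sigma=self.relay_noise_sigma,
                    rise_rate=self.relay_noise_rise_rate,
                    label="relay_noise",
                )
            )
        for name, sigma in self.population_noise.items():
            if sigma > 0:
                out.append(
                    ExternalDrive(
                        target=name,
                        gain=1.0,
                        mean=0.0,
                        sigma=float(sigma),
                        rise_rate=self.population_noise_rise_rate,
                        label=f"{name}_noise",
                    )
                )
        return out

    def sign_matrix(self) -> np.ndarray:
        """6x6 matrix of edge signs (target row, source column); ARAS excluded."""
        n = len(POPULATION_NAMES)
        idx = {p: i for i, p in enumerate(POPULATION_NAMES)}
        m = np.zeros((n, n), dtype=int)
        for s in self.synapses:
            if s.source == ARAS_SOURCE:
                continue
            m[idx[s.target], idx[s.source]] = int(np.sign(s.efficacy))
        return m


def sigmoid_rate(V, pop: PopulationSpec, steepness_scale: float = 1.0):
    """Population firing rate (1/s) for membrane potential ``V`` (mV).

    ``Smax / (1 + exp(-c * steepness_scale * (V - theta)))``.  The
    short-duration tDCS model rescales the steepness through
    ``steepness_scale``.
    """
    if not steepness_scale > 0:
        raise ValueError("steepness_scale must be positive")
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise FloatingPointError(
            "non-finite membrane potential: integration has blown up"
        )
    x = -pop.steepness * steepness_scale * (V - pop.theta)
    out = pop.Smax / (1.0 + np.exp(x))
    return out if out.ndim else float(out)


def sigmoid_slope(V: float, pop: PopulationSpec, steepness_scale: float = 1.0) -> float:
    """Derivative dS/dV (1/(s mV)) of the transfer function at ``V``."""
    c = pop.steepness * steepness_scale
    s = sigmoid_rate(V, pop, steepness_scale)
    return c * s * (1.0 - s / pop.Smax)


# ---------------------------------------------------------------------------
# Default calibrated parameter set
# ---------------------------------------------------------------------------

#: Default network parameters.  The operating points, kernel rates and
#: efficacies are the calibrated set produced by scripts/tune_network.py:
#: the control condition places the reticular-population spectral peak in
#: the delta band (slow reticular afferent kernels plus the slow
#: cortico-thalamic loop), a sigma-band spindle resonance in the
#: relay<->reticular pair (~14 Hz), and a gamma peak (~39 Hz) in the
#: supragranular E-I circuit driven by ARAS noise.  The pharmacology and
#: stimulation transforms then shift every band power in the direction
#: reported experimentally, without further adjustment.
DEFAULT_CONFIG: dict = {
    "populations": {
        # name: polarity, Smax (1/s), theta (mV), steepness (1/mV), offset (mV)
        "SG_E": {"polarity": "excitatory", "Smax": 100.0, "theta": 6.0, "steepness": 0.25, "resting_offset": -6.3559},
        "SG_I": {"polarity": "inhibitory", "Smax": 100.0, "theta": 6.0, "steepness": 0.25, "resting_offset": -8.0092},
        "GIG_E": {"polarity": "excitatory", "Smax": 100.0, "theta": 5.0, "steepness": 0.1095, "resting_offset": 7.5323},
        "GIG_I": {"polarity": "inhibitory", "Smax": 100.0, "theta": 5.0, "steepness": 0.1095, "resting_offset": 0.7317},
        "RELAY_E": {"polarity": "excitatory", "Smax": 100.0, "theta": 0.0, "steepness": 0.12, "resting_offset": -36.6135},
        "RETIC_I": {"polarity": "inhibitory", "Smax": 100.0, "theta": 24.3601, "steepness": 0.1627, "resting_offset": -52.0578},
    },
    "synapses": {
        # src->tgt: efficacy (mV s), rise_rate (1/s), delay (s), region_tag
        # supragranular gamma-generating E-I loop (fast kernels)
        "SG_E->SG_I": {"efficacy": 0.4248, "rise_rate": 280.0, "delay": 0.0, "region_tag": "SG"},
        "SG_I->SG_E": {"efficacy": -0.3161, "rise_rate": 230.0, "delay": 0.0, "region_tag": "SG"},
        # thalamic afference to the supragranular layer
        "RELAY_E->SG_E": {"efficacy": 0.0822, "rise_rate": 100.0, "delay": 0.015, "region_tag": "SG"},
        # GIG local E-I pair (stabilising feedback)
        "GIG_E->GIG_I": {"efficacy": 0.1449, "rise_rate": 150.0, "delay": 0.0, "region_tag": "cortico_thalamic_loop"},
        "GIG_I->GIG_E": {"efficacy": -0.2856, "rise_rate": 150.0, "delay": 0.0, "region_tag": "cortico_thalamic_loop"},
        # cortico-thalamic loop (15 ms conduction delay each way)
        "GIG_E->RELAY_E": {"efficacy": 0.7673, "rise_rate": 80.0, "delay": 0.015, "region_tag": "cortico_thalamic_loop"},
        "RELAY_E->GIG_E": {"efficacy": 0.3782, "rise_rate": 80.0, "delay": 0.015, "region_tag": "cortico_thalamic_loop"},
        # slow cortical afference to the reticular nucleus (delta pathway)
        "GIG_E->RETIC_I": {"efficacy": 0.6, "rise_rate": 15.042, "delay": 0.015, "region_tag": "cortico_thalamic_loop"},
        # relay<->reticular spindle pair (sigma resonance)
        "RELAY_E->RETIC_I": {"efficacy": 0.6411, "rise_rate": 83.6072, "delay": 0.0, "region_tag": "cortico_thalamic_loop"},
        "RETIC_I->RELAY_E": {"efficacy": -0.3114, "rise_rate": 83.6072, "delay": 0.0, "region_tag": "cortico_thalamic_loop"},
        # ARAS afferent (efficacy is a dimensionless gain on the mV drive)
        "ARAS->SG_E": {"efficacy": 1.0, "rise_rate": 100.0, "delay": 0.0, "region_tag": "ARAS_afferent"},
    },
    "aras": {
        "mean_input": 13.0278,     # mV
        "noise_intensity": 0.0705,  # mV sqrt(s)
        "efficacy_gain": 1.0,
        "disinhibition_gain": 1.0,
    },
    "relay_noise_sigma": 0.005,    # mV sqrt(s)
    "relay_noise_rise_rate": 60.0,
    # weak intrinsic background noise of the granular/infragranular pool
    "population_noise": {"GIG_E": 0.089},
    "population_noise_rise_rate": 60.0,
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def build_default_network(config: Mapping | None = None) -> NetworkTopology:
    """Build the CTC + ARAS topology, optionally overriding defaults.

    ``config`` is a (possibly partial) nested mapping with the same shape
    as :data:`DEFAULT_CONFIG`; missing entries fall back to the calibrated
    default parameter set.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    pops = {
        name: PopulationSpec(name=name, **spec)
        for name, spec in cfg["populations"].items()
    }
    synapses = []
    for edge, spec in cfg["synapses"].items():
        src, tgt = edge.split("->")
        synapses.append(SynapseSpec(source=src, target=tgt, **spec))
    aras = ARASDrive(**cfg["aras"])
    return NetworkTopology(
        populations=pops,
        synapses=synapses,
        aras=aras,
        relay_noise_sigma=cfg.get("relay_noise_sigma", 0.0),
        relay_noise_rise_rate=cfg.get("relay_noise_rise_rate", 60.0),
        population_noise=dict(cfg.get("population_noise", {})),
        population_noise_rise_rate=cfg.get("population_noise_rise_rate", 60.0),
    )


# ---------------------------------------------------------------------------
# Compiled array form consumed by the integrator and the linear analysis
# ---------------------------------------------------------------------------

@dataclass
class CompiledNetwork:
    """Struct-of-arrays form of a (modulated) topology.

    Synapse arrays exclude the ARAS afferent, which appears (with the
    optional relay noise channel) in the external-drive arrays.
    ``input_add`` and ``steepness_scale`` carry the short-duration tDCS
    modulation; both are identity for an unmodulated network.
    """

    pop_names: tuple
    Smax: np.ndarray
    theta: np.ndarray
    steepness: np.ndarray
    offset: np.ndarray
    steepness_scale: np.ndarray
    input_add: np.ndarray
    syn_src: np.ndarray
    syn_tgt: np.ndarray
    syn_w: np.ndarray
    syn_a: np.ndarray
    syn_delay: np.ndarray
    ext_tgt: np.ndarray
    ext_gain: np.ndarray
    ext_mean: np.ndarray
    ext_sigma: np.ndarray
    ext_a: np.ndarray

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)

    @property
    def n_syn(self) -> int:
        return len(self.syn_w)

    def index(self, name: str) -> int:
        return self.pop_names.index(name)


def compile_network(
    topology: NetworkTopology,
    input_add: Mapping[str, float] | None = None,
    steepness_scale: Mapping[str, float] | None = None,
) -> CompiledNetwork:
    """Flatten a topology (plus optional short-tDCS modulation) to arrays."""
    idx = {p: i for i, p in enumerate(POPULATION_NAMES)}
    pops = [topology.populations[p] for p in POPULATION_NAMES]
    syns = [s for s in topology.synapses if s.source != ARAS_SOURCE]
    drives = topology.drives()
    inp = np.zeros(len(pops))
    scale = np.ones(len(pops))
    for name, v in (input_add or {}).items():
        inp[idx[name]] = v
    for name, v in (steepness_scale or {}).items():
        if not v > 0:
            raise ValueError("steepness_scale must stay positive")
        scale[idx[name]] = v
    return CompiledNetwork(
        pop_names=tuple(POPULATION_NAMES),
        Smax=np.array([p.Smax for p in pops]),
        theta=np.array([p.theta for p in pops]),
        steepness=np.array([p.steepness for p in pops]),
        offset=np.array([p.resting_offset for p in pops]),
        steepness_scale=scale,
        input_add=inp,
        syn_src=np.array([idx[s.source] for s in syns], dtype=np.int64),
        syn_tgt=np.array([idx[s.target] for s in syns], dtype=np.int64),
        syn_w=np.array([s.efficacy for s in syns]),
        syn_a=np.array([s.rise_rate for s in syns]),
        syn_delay=np.array([s.delay for s in syns]),
        ext_tgt=np.array([idx[d.target] for d in drives], dtype=np.int64),
        ext_gain=np.array([d.gain for d in drives]),
        ext_mean=np.array([d.mean for d in drives]),
        ext_sigma=np.array([d.sigma for d in drives]),
        ext_a=np.array([d.rise_rate for d in drives]),
    )


def _rates(net: CompiledNetwork, V: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite membrane potential")
    x = -net.steepness * net.steepness_scale * (V - net.theta)
    return net.Smax / (1.0 + np.exp(x))


def potentials(net: CompiledNetwork, syn_y: np.ndarray, ext_y: np.ndarray,
               external_input: np.ndarray | None = None) -> np.ndarray:
    """Membrane potentials = summed afferent kernel outputs + inputs."""
    V = net.offset + net.input_add.copy()
    np.add.at(V, net.syn_tgt, syn_y)
    np.add.at(V, net.ext_tgt, ext_y)
    if external_input is not None:
        V = V + external_input
    return V


# ---------------------------------------------------------------------------
# Model state and deterministic right-hand side
# ---------------------------------------------------------------------------

class RateHistory:
    """Ring buffer of per-population firing rates on a fixed time grid."""

    def __init__(self, n_pops: int, horizon_steps: int, initial: np.ndarray):
        self.horizon = int(horizon_steps) + 1
        self.buf = np.tile(np.asarray(initial, dtype=float), (self.horizon, 1))
        self.head = 0  # index of the most recent sample

    def push(self, rates: np.ndarray) -> None:
        self.head = (self.head + 1) % self.horizon
        self.buf[self.head] = rates

    def delayed(self, pop: int, steps_back: int) -> float:
        if steps_back >= self.horizon:
            raise ValueError(
                f"requested history {steps_back} steps back exceeds stored "
                f"horizon of {self.horizon - 1} steps"
            )
        return self.buf[(self.head - steps_back) % self.horizon, pop]


@dataclass
class ModelState:
    """Dynamic state: per-synapse and per-drive kernel pairs (y, z).

    ``y`` is the kernel's potential component (mV), ``z`` its rate
    component (mV/s); the membrane potential of each population is derived
    via :func:`potentials`.
    """

    syn_y: np.ndarray
    syn_z: np.ndarray
    ext_y: np.ndarray
    ext_z: np.ndarray
    t: float = 0.0
    history: RateHistory | None = None


def network_rhs(
    state: ModelState,
    net: CompiledNetwork,
    external_input: np.ndarray | None = None,
    delayed_rates: np.ndarray | None = None,
    dt: float | None = None,
) -> ModelState:
    """Deterministic time derivative of every kernel state.

    Each synaptic kernel obeys the critically damped second-order response
    ``y'' + 2a y' + a^2 y = a^2 w r(t - d)`` to the delayed presynaptic
    rate.  ``delayed_rates`` (one entry per synapse) may be supplied
    directly; otherwise they are read from ``state.history`` (``dt``
    required to convert delays to steps).

    Returns a :class:`ModelState` holding the derivatives.
    """
    if delayed_rates is None:
        if state.history is None or dt is None:
            raise ValueError("need delayed_rates, or a history buffer plus dt")
        delayed_rates = np.array(
            [
                state.history.delayed(int(net.syn_src[k]), int(round(net.syn_delay[k] / dt)))
                for k in range(net.n_syn)
            ]
        )
    dy = state.syn_z.copy()
    dz = (
        net.syn_a**2 * (net.syn_w * delayed_rates - state.syn_y)
        - 2.0 * net.syn_a * state.syn_z
    )
    dey = state.ext_z.copy()
    dez = (
        net.ext_a**2 * (net.ext_gain * net.ext_mean - state.ext_y)
        - 2.0 * net.ext_a * state.ext_z
    )
    return ModelState(syn_y=dy, syn_z=dz, ext_y=dey, ext_z=dez, t=1.0)


# ---------------------------------------------------------------------------
# Deterministic fixed point
# ---------------------------------------------------------------------------

def _fp_residual(V: np.ndarray, net: CompiledNetwork) -> np.ndarray:
    r = _rates(net, V)
    syn_y = net.syn_w * r[net.syn_src]
    ext_y = net.ext_gain * net.ext_mean
    return potentials(net, syn_y, ext_y) - V

def fixed_point(net: CompiledNetwork, V0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic fixed point (V*, r*) via root finding.

    At steady state every kernel satisfies ``y = w r`` so the potentials
    obey the 6-dimensional algebraic system solved here with a hybrid
    Powell method.  The recurrent excitatory cortico-thalamic loop makes
    the network multistable (a collapsed low-rate state coexists with the
    operating state); when several roots exist the highest-activity one is
    returned — that is the branch the calibrated model operates on.
    """
    from scipy.optimize import root

    if V0 is not None:
        starts = [np.asarray(V0, dtype=float)]
    else:
        high = net.offset + net.input_add.copy()
        np.add.at(high, net.ext_tgt, net.ext_gain * net.ext_mean)
        pos = net.syn_w > 0
        np.add.at(high, net.syn_tgt[pos], net.syn_w[pos] * net.Smax[net.syn_src[pos]])
        mid = net.offset + net.input_add.copy()
        np.add.at(mid, net.ext_tgt, net.ext_gain * net.ext_mean)
        np.add.at(mid, net.syn_tgt, net.syn_w * 0.5 * net.Smax[net.syn_src])
        starts = [high, mid, fixed_point_iterate(net)]
    best: tuple[np.ndarray, np.ndarray] | None = None
    for s in starts:
        sol = root(_fp_residual, s, args=(net,), method="hybr", tol=1e-13)
        if sol.success and np.max(np.abs(_fp_residual(sol.x, net))) <= 1e-8:
            r = _rates(net, sol.x)
            if best is None or r.sum() > best[1].sum() + 1e-9:
                best = (sol.x, r)
    if best is None:
        raise RuntimeError("fixed-point search failed from every start")
    return best


def fixed_point_iterate(
    net: CompiledNetwork, damping: float = 0.2, max_iter: int = 20000, tol: float = 1e-12
) -> np.ndarray:
    """Damped fixed-point iteration V <- V + damping * residual(V).

    Starts from an optimistic upper bound (every excitatory afferent at its
    maximal rate, inhibition ignored) so that, when the recurrent
    excitatory loops make the network multistable, the iteration settles
    on the high-activity operating branch rather than the collapsed one.
    """
    V = net.offset + net.input_add.copy()
    np.add.at(V, net.ext_tgt, net.ext_gain * net.ext_mean)
    pos = net.syn_w > 0
    np.add.at(V, net.syn_tgt[pos], net.syn_w[pos] * net.Smax[net.syn_src[pos]])
    for _ in range(max_iter):
        res = _fp_residual(V, net)
        V = V + damping * res
        if np.max(np.abs(res)) < tol:
            break
    return V


# ---------------------------------------------------------------------------
# Linearized spectral analysis (calibration / diagnostics)
# ---------------------------------------------------------------------------

def alpha_kernel_response(a: float, omega: np.ndarray) -> np.ndarray:
    """Frequency response ``a^2 / (a + i w)^2`` of the unit-area kernel."""
    return a**2 / (a + 1j * omega) ** 2


def linear_power_spectrum(
    net: CompiledNetwork, freqs: np.ndarray, V_star: np.ndarray | None = None
) -> np.ndarray:
    """One-sided PSD (mV^2/Hz) of each population from the linearized model.

    Linearizes the transfer functions around the deterministic fixed point
    and propagates the white-noise drives through the closed loop:
    ``S_V(w) = sum_e |(I - M(w))^-1 u_e|^2 * 2 sigma_e^2 |H_e(w)|^2 g_e^2``
    where ``M_ij(w) = sum_{syn j->i} w_s S'_j H_s(w) exp(-i w d_s)``.

    Returns an array of shape ``(n_freqs, n_pops)``.  Used for network
    calibration and as an independent cross-check of the stochastic
    integrator.
    """
    if V_star is None:
        V_star, _ = fixed_point(net)
    slopes = (
        net.steepness
        * net.steepness_scale
        * _rates(net, V_star)
        * (1.0 - _rates(net, V_star) / net.Smax)
    )
    n = net.n_pops
    out = np.zeros((len(freqs), n))
    for fi, f in enumerate(np.asarray(freqs, dtype=float)):
        w = 2.0 * math.pi * f
        M = np.zeros((n, n), dtype=complex)
        for k in range(net.n_syn):
            j, i = int(net.syn_src[k]), int(net.syn_tgt[k])
            H = alpha_kernel_response(net.syn_a[k], np.array(w))
            M[i, j] += net.syn_w[k] * slopes[j] * H * np.exp(-1j * w * net.syn_delay[k])
        A = np.linalg.inv(np.eye(n) - M)
        for e in range(len(net.ext_tgt)):
            He = alpha_kernel_response(net.ext_a[e], np.array(w))
            u = A[:, int(net.ext_tgt[e])] * net.ext_gain[e] * He
            # two-sided input PSD sigma^2 -> one-sided output PSD 2 sigma^2 |T|^2
            out[fi] += 2.0 * net.ext_sigma[e] ** 2 * np.abs(u) ** 2
    return out
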