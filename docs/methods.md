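# Methods

## Model

Six neural populations are modelled at the mean-field level: an
excitatory/inhibitory pair in the supragranular cortical layers I–III
(`SG_E`, `SG_I`), a pair lumping the granular and infragranular layers
IV–VI (`GIG_E`, `GIG_I`), thalamic relay cells (`RELAY_E`) and the
GABAergic thalamic reticular nucleus (`RETIC_I`). The granular and
infragranular layers are treated as one node because they act as a single
station of the cortico-thalamic loop; the supragranular pair is kept
separate because it is the gamma generator and the sole recipient of the
brainstem (ARAS) drive.

Each population maps its mean membrane potential `V` (mV) to a mean
firing rate (1/s) through the sigmoid `S(V) = S_max / (1 + exp(-c (V -
theta)))`. Each synapse is a critically damped second-order filter with
impulse response `a² t e^{-a t}` (unit area): the state pair `(y, z)`
obeys `y' = z`, `z' = a² (w·r(t-d) - y) - 2 a z`, so a constant
presynaptic rate `r` contributes `w·r` mV at steady state. Potentials are
the sum of afferent kernel outputs plus a tonic offset. Conduction delays
are 15 ms for every cortex↔thalamus edge and zero within a structure;
15 ms is the standard physiological estimate and puts
the loop resonance in the sigma band; all delays are configurable.

Connectivity is the anatomical CTC circuit: local E↔I loops within
SG and within GIG; `GIG_E→RELAY_E`, `GIG_E→RETIC_I`, `RELAY_E→GIG_E`,
`RELAY_E→RETIC_I`, `RETIC_I→RELAY_E` (inhibitory), `RELAY_E→SG_E`, and
`ARAS→SG_E`. The reticular nucleus never projects to cortex and SG never
projects to the thalamus. An `SG→GIG` feedforward edge was deliberately
*not* added (see Limitations).

Noise: the ARAS drive delivers white noise (intensity in mV·√s) through
its afferent kernel onto `SG_E`; weak independent noise also enters the
relay (`relay_noise_sigma`) and `GIG_E` (`population_noise`). The
configuration exposes per-population noise generally. The intrinsic GIG
noise is a deliberate design choice: without a fluctuation source private
to the loop's cortical node, every reticular delta input is slaved to the
relay transfer function, and the ketamine condition could not raise
reticular delta power while cortical delta falls.

The EEG proxy is `SG_E + GIG_E` with equal weights (positive =
depolarization); weights are configurable but restricted to cortical
populations.

## Integration

Fixed-step Euler–Maruyama at dt = 0.1 ms (the constructor enforces
dt ≤ 1.25 ms, ten steps per cycle at 80 Hz). Delayed rates are read from
a ring buffer with delays rounded to whole steps. Noise is pre-drawn from
`numpy.random.Generator(PCG64(seed))`, so repeated runs with identical
inputs are bit-identical (the numba and pure-Python paths agree to
floating-point rounding). Runs start
on the deterministic fixed point (found by a hybrid-Powell root solve
seeded from optimistic/damped-iteration starts; when the recurrent
excitatory loop makes the system multistable the highest-activity root is
taken — that is the calibrated operating branch, and the stochastic
integrator confirms its stability). A 5 s burn-in is discarded. |V| >
1000 mV aborts with the first diverging population named.

A linearized spectral solver (`linear_power_spectrum`) propagates the
noise drives through the transfer-function Jacobian at the fixed point;
it is used for calibration and as an independent cross-check of the
stochastic integrator (the filtered-white-noise variance `g²σ²a/4` of an
isolated kernel is an exact special case and is asserted to 5%).

## Interventions

**Short tDCS.** A model current `I_tDCS` (anodal > 0) adds
`g·I_tDCS` mV of tonic input to the four cortical populations and rescales
their sigmoid steepness by `1 − κ·I_tDCS`; thalamic populations are
untouched. Defaults `g = 1.5` mV, `κ = 0.2` were chosen so that at
`I = ±0.8` the cortical-GIG and relay resting potentials shift
monotonically with current while the firing-rate change stays below 20%
of the potential change and the reticular baseline stays within ±2% —
the steepness term nearly cancels the rate effect of the input term at
the GIG operating point.

**Long anodal tDCS.** An LTP-like factor `f_tDCS ≥ 1` multiplies every
excitatory efficacy with a cortical target; `f_tDCS_resp` multiplies the
ARAS afferent gain. The factor's kinetics are logistic (Verhulst) in
`g = f − 1` with carrying capacity `f_sat − 1` and time constant
`tau_plast / (I/I_ref)` (linear current dependence, `I_ref = 1`), and
exponential decay `g → g·e^{−t/τ_decay}` after offset. Because `g = 0` is
an equilibrium of the growth law, onset is seeded at
`ε₀ = (f_sat−1)/164.77`; this value is the least-squares solution that
makes a 12-minute stimulation yield `f = 1.2` and a 4-minute stimulation
`f = 1.05` at `tau_plast = 1` min *simultaneously and exactly* (residuals
< 1e-3 — the logistic form reconciles two anchors that no single
saturating exponential fits). `calibrate_growth_seed` re-derives it.
Stepping uses the exact per-phase flow maps, so the integrator matches
the closed forms to machine precision for any dt. Protocol defaults
follow the repeated-block paradigm: duration `Ts`, 12 h pauses, 10
repetitions, 34 h final observation, `tau_plast = 3 h`,
`tau_decay = 500 h`.

**Ketamine.** NMDA hypofunction at GABAergic neurons is realized as
scaling of inhibitory *output* efficacies: factor 0.7 on GIG_I and
RETIC_I outputs (the cortico-thalamic loop), 0.8 on SG_I outputs, plus a
×1.3 gain on the ARAS mean input (the disinhibition direction is the
modelled mechanism; 1.3 is the package's calibrated magnitude). Ketamine and long
tDCS are diagonal efficacy scalings and commute.

## Observables

Analysis channels are decimated to 500 Hz with a zero-phase polyphase
FIR anti-alias filter (series are demeaned around the filter to avoid
edge leakage). PSDs are Welch estimates with 4 s Hann segments and 50%
overlap (0.25 Hz resolution). Band powers are the *mean* in-band PSD;
relative powers are condition/reference ratios of that mean. Bands:
delta 1–4, sigma 10–17, beta 17–30, gamma 30–80 Hz (configurable; the
gamma upper edge is kept at 80 Hz).

Phase-locking values use a 4th-order Butterworth band-pass applied
forward–backward, analytic-signal phases with 1 s discarded at each end,
and the modulus of the time-averaged unit phasor of the phase difference
(no bias correction). A pair/band PLV is reported as absent (`null`) when
either channel's in-band RMS is below 5% of its broadband RMS — phases
of a near-silent band carry no information. In the calibrated network
this triggers for gamma-band pairs involving the thalamus in the control
condition.

## Calibration of the default network

Free parameters (operating-point rates, steepnesses, efficacies, kernel
rates, drive levels) were fixed once by hill climbing on the linearized
band-power table (`scripts/tune_network.py` documents and can repeat the
procedure), with tonic offsets solved analytically from target
fixed-point rates. The objective encodes, simultaneously: reticular
spectral maximum in delta; a relay sigma peak and an SG gamma peak; the
eleven directional band-power responses of the three interventions; the
excitability sweep properties; positive baselines; and no population
pinned at saturation in the control or ketamine condition. The final
candidate was validated against stochastic simulations (seed-paired,
10 seeds) before committing. The committed defaults live in
`ctcsim.network.DEFAULT_CONFIG` and `ctcsim/data/default_network.yaml`.

Resting baselines in the excitability experiment are computed from the
deterministic fixed point of each modulated network — the noise-free
limit of the precursor-window average. The systematic relay shift
(~0.5% at I = 0.8) sits two orders of magnitude below the delta-band
fluctuation of a 50 ms window mean, so no feasible seed count makes the
windowed estimator informative; `run_evoked` still reports the windowed
statistics for single trials.

## Problem sizes

Defaults for the figure-level experiments are 100 s per condition per
seed and 10 seeds, seed-paired against control and decided by one-sided
sign tests at α = 0.05. The test suite uses the same design at 60 s per
run, which the sign tests' margins comfortably allow; the acceptance
script simulates 100 s for the spectral target. The plasticity
trajectories integrate multi-day protocols at 60–120 s resolution.

## What the synthetic fixtures do and do not show

`ctcsim.fixtures` generates sinusoids, band-filtered noise and coupled
noisy phase oscillators with known ground truth; they validate the
spectral and phase-locking estimators independently of the network
simulator. The simulator itself emulates stationary resting-state
activity of a lumped mammalian thalamocortical circuit. It does not
produce spindle waxing–waning, burst/tonic firing-mode switches, spike
timing, 1/f background from dendritic filtering, volume conduction or
electrode referencing — so passing tests demonstrate internal
consistency with the modelled mechanisms, not agreement with any
particular recording.

## Known limitations

* **Evoked-response magnitude vs current.** With the input+steepness
  co-modulation and the rate-cancelling κ required by the
  "rates poorly modulated" property, the small-signal gain of the
  cortical loop scales as `1 − κ·I`: the evoked peak *decreases* slightly
  with anodal current instead of increasing. The two behaviours are
  mutually exclusive in this transfer-function scheme; the package
  prioritizes the resting-baseline properties and reports the measured
  peak magnitudes as they are.
* **Phase-locking directions.** Loop PLVs sit near saturation (> 0.9)
  because all populations share a few noise sources, and the ARAS — where
  the long-tDCS response factor acts — reaches only the supragranular
  layer, which projects nowhere. Consequently the ketamine sigma-PLV
  decrease reproduces only partially across seeds and the tDCS
  re-enhancement of connectivity does not emerge; the corresponding
  directional tests fail by design of the committed network rather than
  by estimator error. Fixing this would require an SG→GIG feedforward
  edge outside the modelled circuit diagram, which in trials broke the
  (stronger) band-power and excitability behaviours.
* Cathodal long-term plasticity, LTD, receptor kinetics, closed-loop
  stimulation and fitting to recordings are out of scope.
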