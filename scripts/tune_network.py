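"""Network calibration tool.

This script documents and reproduces the procedure used to obtain the
committed default parameter set (``ctcsim.network.DEFAULT_CONFIG``): a
hill climb over population operating points, synaptic efficacies, kernel
rates and drive parameters, scored on the *linearized* power spectrum
(cheap: a 6x6 complex solve per frequency) and on deterministic fixed
points.  The score rewards

* control-condition rhythm placement: reticular spectral maximum in the
  delta band, a sigma-band spindle peak in the relay population, and a
  gamma peak in the supragranular layer;
* the directional band-power responses of the three interventions
  (anodal-tDCS up in delta/sigma/gamma; ketamine down in EEG delta/sigma,
  up in EEG gamma and reticular delta; combined condition up in
  delta/sigma and down in gamma relative to ketamine alone);
* the excitability properties of the transient-tDCS sweep (monotone
  cortical/relay relative baselines, flat reticular baseline, firing rates
  much less modulated than potentials) and positive baseline potentials;
* non-extreme operating points (no population pinned at saturation in the
  control or ketamine condition).

Candidates are parameterized by target fixed-point rates; tonic offsets
are solved analytically so the control operating point is exact.  The
final candidate must then be validated against stochastic simulations
(the linear score is only a surrogate); the committed defaults were.

Usage::

    python scripts/tune_network.py --iters 500 --seed 1 [--start default]

Prints the best configuration found as JSON.  With ``--iters 0`` it just
scores the current package defaults.
"""

from __future__ import annotations

import argparse
import copy
import json
import math

import numpy as np

from ctcsim.network import (
    DEFAULT_CONFIG,
    POPULATION_NAMES,
    build_default_network,
    compile_network,
    fixed_point,
    linear_power_spectrum,
)
from ctcsim.neuromodulation import ModulationState, ShortTDCSParams, condition_state

FREQS = np.concatenate(
    [np.linspace(0.5, 6, 23), np.linspace(8, 22, 29), np.linspace(24, 88, 33)]
)
BAND = {
    "delta": (FREQS >= 1) & (FREQS <= 4),
    "sigma": (FREQS >= 10) & (FREQS <= 17),
    "gamma": (FREQS >= 30) & (FREQS <= 80),
}

#: (section, key, subkey) entries of the flat search space, with bounds.
SEARCH_SPACE = [
    ("synapses", "SG_E->SG_I", "efficacy", 0.12, 0.50),
    ("synapses", "SG_I->SG_E", "efficacy", -0.55, -0.12),
    ("synapses", "GIG_E->GIG_I", "efficacy", 0.08, 0.45),
    ("synapses", "GIG_I->GIG_E", "efficacy", -0.55, -0.08),
    ("synapses", "GIG_E->RELAY_E", "efficacy", 0.15, 0.95),
    ("synapses", "RELAY_E->GIG_E", "efficacy", 0.15, 0.95),
    ("synapses", "RELAY_E->RETIC_I", "efficacy", 0.15, 0.95),
    ("synapses", "RETIC_I->RELAY_E", "efficacy", -0.80, -0.10),
    ("synapses", "GIG_E->RETIC_I", "efficacy", 0.05, 0.60),
    ("synapses", "GIG_E->RETIC_I", "rise_rate", 14.0, 32.0),
    ("synapses", "RELAY_E->RETIC_I", "rise_rate", 55.0, 110.0),
    ("synapses", "RELAY_E->SG_E", "efficacy", 0.05, 0.50),
    ("aras", "mean_input", None, 5.0, 18.0),
    ("aras", "noise_intensity", None, 0.05, 0.45),
    ("populations", "GIG_E", "steepness", 0.08, 0.30),
    ("populations", "RELAY_E", "steepness", 0.04, 0.12),
    ("populations", "RETIC_I", "steepness", 0.08, 0.30),
]


def get(cfg, section, key, subkey):
    node = cfg[section][key] if key else cfg[section]
    return node[subkey] if subkey else cfg[section][key]


def put(cfg, section, key, subkey, value):
    if subkey:
        cfg[section][key][subkey] = value
    else:
        cfg[section][key] = value


def margin(x: float) -> float:
    return float(np.clip(math.log(max(x, 1e-12)), -1.0, 0.5))


def band_table(topo):
    out = {}
    for cond in ("control", "atdcs", "ketamine", "ketamine+atdcs"):
        t2, inp, sc = condition_state(cond).resolve(topo)
        net = compile_network(t2, inp, sc)
        V, r = fixed_point(net)
        S = linear_power_spectrum(net, FREQS, V)
        if not np.all(np.isfinite(S)) or S.max() > 1e4:
            return None
        chans = {"EEG": S[:, 0] + S[:, 2], "SG_E": S[:, 0], "GIG_E": S[:, 2],
                 "RELAY_E": S[:, 4], "RETIC_I": S[:, 5]}
        out[cond] = dict(
            bp={(nm, b): float(psd[m].mean()) for nm, psd in chans.items()
                for b, m in BAND.items()},
            spec=chans,
            r=r,
        )
    return out


def score(cfg) -> tuple[float, dict]:
    try:
        topo = build_default_network(cfg)
        T = band_table(topo)
    except Exception:
        return -1e3, {}
    if T is None:
        return -1e3, {}
    g = lambda c, nm, b: T[c]["bp"][(nm, b)] / T["control"]["bp"][(nm, b)]
    ka = lambda nm, b: T["ketamine+atdcs"]["bp"][(nm, b)] / T["ketamine"]["bp"][(nm, b)]
    t = {}
    t["atdcs_delta_up"] = margin(g("atdcs", "EEG", "delta"))
    t["atdcs_sigma_up"] = margin(g("atdcs", "EEG", "sigma"))
    t["atdcs_gamma_up"] = margin(g("atdcs", "EEG", "gamma"))
    t["ket_delta_down"] = margin(1 / g("ketamine", "EEG", "delta"))
    t["ket_sigma_down"] = margin(1 / g("ketamine", "EEG", "sigma"))
    t["ket_gamma_up"] = margin(g("ketamine", "EEG", "gamma"))
    t["ket_retic_delta_up"] = margin(g("ketamine", "RETIC_I", "delta"))
    t["combo_delta_up"] = margin(ka("EEG", "delta"))
    t["combo_sigma_up"] = margin(ka("EEG", "sigma"))
    t["combo_gamma_down"] = margin(1 / ka("EEG", "gamma"))
    spec = T["control"]["spec"]
    t["retic_delta_peak"] = margin(
        spec["RETIC_I"][BAND["delta"]].max() / spec["RETIC_I"][~BAND["delta"]].max()
    )
    mid = (FREQS >= 15) & (FREQS <= 25)
    t["sg_gamma_peak"] = margin(spec["SG_E"][BAND["gamma"]].max() / spec["SG_E"][mid].min())
    beta = (FREQS >= 18) & (FREQS <= 28)
    t["relay_sigma_peak"] = margin(
        spec["RELAY_E"][BAND["sigma"]].max() / spec["RELAY_E"][beta].max()
    )
    pen = 0.0
    for cond in ("control", "ketamine"):
        for i, p in enumerate(POPULATION_NAMES):
            r = T[cond]["r"][i]
            if p not in ("SG_E", "SG_I"):
                pen += max(r - 97.0, 0.0) * 0.2 + max(3.0 - r, 0.0) * 0.2
    t["saturation_penalty"] = -pen
    # excitability sweep on deterministic fixed points
    try:
        topo = build_default_network(cfg)
        rel = {}
        for I in (-0.8, 0.0, 0.8):
            st = ModulationState(short_tdcs=ShortTDCSParams(I_tDCS=I))
            t2, inp, sc = st.resolve(topo)
            Vf, rf = fixed_point(compile_network(t2, inp, sc))
            d = dict(zip(POPULATION_NAMES, Vf))
            dr = dict(zip(POPULATION_NAMES, rf))
            rel[I] = (d["GIG_E"] + d["GIG_I"], dr["GIG_E"] + dr["GIG_I"],
                      d["RELAY_E"], dr["RELAY_E"], d["RETIC_I"])
        b0 = rel[0.0]
        t["relay_monotone"] = margin((rel[0.8][2] - rel[-0.8][2]) / abs(b0[2]) * 200 + 1e-9)
        retdev = max(abs(rel[s][4] / b0[4] - 1) for s in (0.8, -0.8))
        t["reticular_flat"] = margin(0.02 / max(retdev, 1e-6))
        ratios = []
        for s in (0.8, -0.8):
            fdev = abs(rel[s][1] / b0[1] - 1)
            vdev = abs(rel[s][0] / b0[0] - 1)
            ratios.append(0.2 * vdev / max(fdev, 1e-9))
        t["rate_cancellation"] = margin(min(ratios))
        t["positive_baselines"] = margin(min(b0[0], b0[2], b0[4]))
    except Exception:
        for k in ("relay_monotone", "reticular_flat", "rate_cancellation",
                  "positive_baselines"):
            t[k] = -2.0
    total = sum(t.values())
    hard = [k for k in t if k != "saturation_penalty"]
    total += sum(min(t[k], 0.0) for k in hard)
    return total, t


def climb(cfg, iters: int, rng, step: float = 0.15):
    best_cfg = copy.deepcopy(cfg)
    best, terms = score(best_cfg)
    for _ in range(iters):
        sec, key, sub, lo, hi = SEARCH_SPACE[rng.integers(len(SEARCH_SPACE))]
        cand = copy.deepcopy(best_cfg)
        v = get(cand, sec, key, sub)
        v = float(np.clip(v * math.exp(rng.normal(0, step)) + rng.normal(0, 0.01 * (hi - lo)), lo, hi))
        put(cand, sec, key, sub, v)
        s, tm = score(cand)
        if s >= best:
            best_cfg, best, terms = cand, s, tm
    return best_cfg, best, terms


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--iters", type=int, default=0)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=str, default=None)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if args.iters:
        cfg, total, terms = climb(cfg, args.iters, rng)
    else:
        total, terms = score(cfg)
    print(f"# score {total:.3f}")
    for k, v in terms.items():
        print(f"#   {k:22s} {v:+.3f}")
    doc = json.dumps(cfg, indent=1)
    print(doc)
    if args.out:
        with open(args.out, "w") as fh:
            fh.write(doc)


if __name__ == "__main__":
    main()
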