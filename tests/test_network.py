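import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctcsim.network import (
    ARAS_SOURCE,
    ModelState,
    POPULATION_NAMES,
    PopulationSpec,
    SynapseSpec,
    build_default_network,
    compile_network,
    fixed_point,
    fixed_point_iterate,
    network_rhs,
    sigmoid_rate,
)
from ctcsim.neuromodulation import (
    KetamineParams,
    LongTDCSParams,
    apply_ketamine,
    apply_long_tdcs,
)


def make_pop(Smax=100.0, theta=0.0, steepness=0.5):
    return PopulationSpec("SG_E", "excitatory", Smax, theta, steepness)


class TestSigmoidRate:
    def test_midpoint_is_half_max(self):
        pop = make_pop(Smax=80.0, theta=3.0)
        assert sigmoid_rate(3.0, pop) == pytest.approx(40.0)
        assert sigmoid_rate(3.0, pop, steepness_scale=2.7) == pytest.approx(40.0)

    def test_saturation_limits(self):
        pop = make_pop(Smax=80.0)
        assert sigmoid_rate(1e3, pop) == pytest.approx(80.0)
        assert sigmoid_rate(-1e3, pop) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_evaluation(self):
        # Smax=100, theta=0, c=0.5, V=2 -> 100 / (1 + e^{-1})
        pop = make_pop(Smax=100.0, theta=0.0, steepness=0.5)
        assert sigmoid_rate(2.0, pop) == pytest.approx(100.0 / (1 + math.exp(-1)), rel=1e-9)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_bounded(self, v1, v2):
        pop = make_pop()
        r1, r2 = sigmoid_rate(v1, pop), sigmoid_rate(v2, pop)
        assert 0.0 < r1 < pop.Smax
        # strict ordering checked away from the float-underflow tails
        if v1 + 1e-6 < v2 and max(abs(v1), abs(v2)) < 25:
            assert r1 < r2

    def test_nonfinite_potential_raises(self):
        with pytest.raises(FloatingPointError):
            sigmoid_rate(float("nan"), make_pop())

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_rate(0.0, make_pop(), steepness_scale=0.0)


#: Expected Fig-1 sign pattern (target row, source column) of the default
#: network, ARAS excluded.
EXPECTED_SIGNS = {
    ("SG_I", "SG_E"): +1,
    ("SG_E", "SG_I"): -1,
    ("SG_E", "RELAY_E"): +1,
    ("GIG_I", "GIG_E"): +1,
    ("GIG_E", "GIG_I"): -1,
    ("RELAY_E", "GIG_E"): +1,
    ("RETIC_I", "GIG_E"): +1,
    ("GIG_E", "RELAY_E"): +1,
    ("RETIC_I", "RELAY_E"): +1,
    ("RELAY_E", "RETIC_I"): -1,
}


class TestDefaultTopology:
    def test_six_populations(self, topology):
        assert set(topology.populations) == set(POPULATION_NAMES)

    def test_edge_sign_matrix_matches_circuit(self, topology):
        m = topology.sign_matrix()
        idx = {p: i for i, p in enumerate(POPULATION_NAMES)}
        expected = np.zeros_like(m)
        for (tgt, src), sign in EXPECTED_SIGNS.items():
            expected[idx[tgt], idx[src]] = sign
        np.testing.assert_array_equal(m, expected)

    def test_reticular_never_projects_to_cortex(self, topology):
        for s in topology.synapses:
            if s.source == "RETIC_I":
                assert s.target == "RELAY_E"

    def test_aras_afferent_targets_supragranular(self, topology):
        aras = [s for s in topology.synapses if s.source == ARAS_SOURCE]
        assert len(aras) == 1 and aras[0].target == "SG_E" and aras[0].efficacy > 0

    def test_config_override(self):
        topo = build_default_network({"aras": {"mean_input": 5.0}})
        assert topo.aras.mean_input == 5.0

    def test_missing_required_edge_rejected(self, topology):
        pruned = [s for s in topology.synapses
                  if not (s.source == "GIG_E" and s.target == "RELAY_E")]
        with pytest.raises(ValueError, match="GIG_E->RELAY_E"):
            topology.replace_synapses(pruned)

    def test_wrong_polarity_sign_rejected(self):
        with pytest.raises(ValueError, match="polarity"):
            SynapseSpec(source="SG_I", target="SG_E", efficacy=0.1, rise_rate=100.0)


class TestDynamicsCore:
    def _state_at_fixed_point(self, net):
        V, r = fixed_point(net)
        return ModelState(
            syn_y=net.syn_w * r[net.syn_src],
            syn_z=np.zeros(net.n_syn),
            ext_y=net.ext_gain * net.ext_mean,
            ext_z=np.zeros(len(net.ext_gain)),
        ), r

    def test_rhs_vanishes_at_algebraic_fixed_point(self, topology):
        """Root-found steady state satisfies the ODE right-hand side ~ 0."""
        net = compile_network(topology)
        state, r = self._state_at_fixed_point(net)
        deriv = network_rhs(state, net, delayed_rates=r[net.syn_src])
        for arr in (deriv.syn_y, deriv.syn_z, deriv.ext_y, deriv.ext_z):
            assert np.max(np.abs(arr)) < 1e-9

    def test_homogeneous_decay(self, topology):
        """With all rates clamped to zero every kernel relaxes toward 0."""
        net = compile_network(topology)
        rng = np.random.default_rng(0)
        state = ModelState(
            syn_y=rng.normal(size=net.n_syn),
            syn_z=np.zeros(net.n_syn),
            ext_y=np.zeros(len(net.ext_gain)),
            ext_z=np.zeros(len(net.ext_gain)),
        )
        zero_net = compile_network(topology)
        zero_net.ext_mean = np.zeros_like(zero_net.ext_mean)
        deriv = network_rhs(state, zero_net, delayed_rates=np.zeros(net.n_syn))
        # z' = -a^2 y pushes y back toward zero
        assert np.all(np.sign(deriv.syn_z) == -np.sign(state.syn_y))

    def test_kernel_linearity(self, topology):
        """The synaptic kernels are linear filters in their rate input."""
        net = compile_network(topology)
        rng = np.random.default_rng(1)
        mk = lambda: ModelState(
            syn_y=rng.normal(size=net.n_syn), syn_z=rng.normal(size=net.n_syn),
            ext_y=rng.normal(size=len(net.ext_gain)), ext_z=rng.normal(size=len(net.ext_gain)),
        )
        s1, s2 = mk(), mk()
        r1 = rng.uniform(0, 100, size=net.n_syn)
        r2 = rng.uniform(0, 100, size=net.n_syn)
        zero_net = compile_network(topology)
        zero_net.ext_mean = np.zeros_like(zero_net.ext_mean)
        d1 = network_rhs(s1, zero_net, delayed_rates=r1)
        d2 = network_rhs(s2, zero_net, delayed_rates=r2)
        s12 = ModelState(syn_y=s1.syn_y + s2.syn_y, syn_z=s1.syn_z + s2.syn_z,
                         ext_y=s1.ext_y + s2.ext_y, ext_z=s1.ext_z + s2.ext_z)
        d12 = network_rhs(s12, zero_net, delayed_rates=r1 + r2)
        np.testing.assert_allclose(d12.syn_z, d1.syn_z + d2.syn_z, atol=1e-10)
        np.testing.assert_allclose(d12.syn_y, d1.syn_y + d2.syn_y, atol=1e-10)

    def test_history_horizon_error(self, topology):
        from ctcsim.network import RateHistory

        hist = RateHistory(6, horizon_steps=10, initial=np.zeros(6))
        with pytest.raises(ValueError, match="horizon"):
            hist.delayed(0, 11)

    @pytest.mark.parametrize("edge", [("GIG_E", "RELAY_E"), ("RELAY_E", "GIG_E")])
    def test_monotone_excitation(self, topology, edge):
        """Scaling an excitatory efficacy up weakly raises the target's
        fixed-point potential over a +-20% grid."""
        src, tgt = edge
        values = []
        for scale in (0.8, 0.9, 1.0, 1.1, 1.2):
            syns = []
            for s in topology.synapses:
                if s.source == src and s.target == tgt:
                    from dataclasses import replace

                    syns.append(replace(s, efficacy=s.efficacy * scale))
                else:
                    syns.append(s)
            net = compile_network(topology.replace_synapses(syns))
            V, _ = fixed_point(net)
            values.append(V[net.index(tgt)])
        diffs = np.diff(values)
        assert np.all(diffs > -1e-9)

    @given(
        f_loop=st.floats(0.6, 1.0), f_sg=st.floats(0.6, 1.0),
        f_tdcs=st.floats(1.0, 1.4),
    )
    @settings(max_examples=25, deadline=None)
    def test_sign_preservation_under_modulation(self, f_loop, f_sg, f_tdcs):
        """Pharmacology and plasticity never flip an efficacy's sign."""
        topo = build_default_network()
        topo = apply_ketamine(topo, KetamineParams(
            f_ketamine_loop=f_loop, f_ketamine_SG=f_sg, aras_disinhibition_gain=1.1))
        topo = apply_long_tdcs(topo, LongTDCSParams(f_tDCS=f_tdcs, f_tDCS_resp=f_tdcs))
        for s in topo.synapses:
            if s.source.endswith("_I"):
                assert s.efficacy <= 0
            else:
                assert s.efficacy >= 0


def test_fixed_point_agrees_with_damped_iteration(topology):
    """The hybrid-root fixed point matches the independent damped iteration."""
    net = compile_network(topology)
    V_root, _ = fixed_point(net)
    V_iter = fixed_point_iterate(net, damping=0.05, max_iter=200000, tol=1e-13)
    np.testing.assert_allclose(V_root, V_iter, atol=1e-6)
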