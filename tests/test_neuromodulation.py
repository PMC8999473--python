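import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctcsim.network import ARAS_SOURCE, CORTICAL_POPULATIONS, build_default_network
from ctcsim.neuromodulation import (
    KetamineParams,
    LongTDCSParams,
    PlasticityParams,
    ShortTDCSParams,
    StimulationProtocol,
    apply_ketamine,
    apply_long_tdcs,
    apply_short_tdcs,
    calibrate_growth_seed,
    plasticity_decay,
    plasticity_step,
    plasticity_trajectory,
    time_to_factor,
)

MIN = 60.0


class TestShortTDCS:
    def test_zero_current_is_identity(self, topology):
        inputs, steep = apply_short_tdcs(topology, ShortTDCSParams(I_tDCS=0.0))
        assert all(v == 0.0 for v in inputs.values())
        assert all(v == 1.0 for v in steep.values())

    def test_anodal_raises_input_and_flattens(self, topology):
        p = ShortTDCSParams(I_tDCS=0.8)
        inputs, steep = apply_short_tdcs(topology, p)
        assert set(inputs) == set(CORTICAL_POPULATIONS)
        assert all(v > 0 for v in inputs.values())
        assert all(v < 1 for v in steep.values())
        assert "RELAY_E" not in inputs and "RETIC_I" not in steep

    def test_cathodal_lowers_input_and_steepens(self, topology):
        inputs, steep = apply_short_tdcs(topology, ShortTDCSParams(I_tDCS=-0.5))
        assert all(v < 0 for v in inputs.values())
        assert all(v > 1 for v in steep.values())

    def test_current_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            ShortTDCSParams(I_tDCS=1.5)


class TestEfficacyTransforms:
    def test_long_tdcs_identity(self, topology):
        out = apply_long_tdcs(topology, LongTDCSParams(1.0, 1.0))
        for a, b in zip(out.synapses, topology.synapses):
            assert a.efficacy == b.efficacy
        assert out.aras.efficacy_gain == topology.aras.efficacy_gain

    def test_long_tdcs_scales_cortical_excitatory_only(self, topology):
        out = apply_long_tdcs(topology, LongTDCSParams(f_tDCS=1.2, f_tDCS_resp=2.0))
        for a, b in zip(out.synapses, topology.synapses):
            cortical_target = b.target in CORTICAL_POPULATIONS
            if b.source == ARAS_SOURCE:
                assert a.efficacy == b.efficacy  # handled via the drive gain
            elif b.is_excitatory and cortical_target:
                assert a.efficacy == pytest.approx(1.2 * b.efficacy)
            else:
                assert a.efficacy == b.efficacy
        assert out.aras.efficacy_gain == pytest.approx(2.0 * topology.aras.efficacy_gain)

    def test_cathodal_long_term_rejected(self):
        with pytest.raises(ValueError):
            LongTDCSParams(f_tDCS=0.9)

    def test_ketamine_scales_inhibition_down(self, topology):
        out = apply_ketamine(topology, KetamineParams(
            f_ketamine_loop=0.7, f_ketamine_SG=0.8, aras_disinhibition_gain=1.3))
        for a, b in zip(out.synapses, topology.synapses):
            if b.source == "SG_I":
                assert a.efficacy == pytest.approx(0.8 * b.efficacy)
            elif b.source in ("GIG_I", "RETIC_I"):
                assert a.efficacy == pytest.approx(0.7 * b.efficacy)
            else:
                assert a.efficacy == b.efficacy
        assert out.aras.effective_mean == pytest.approx(1.3 * topology.aras.mean_input)

    def test_ketamine_never_strengthens_inhibition(self):
        with pytest.raises(ValueError):
            KetamineParams(f_ketamine_loop=1.2)

    @given(f_loop=st.floats(0.5, 1.0), f_sg=st.floats(0.5, 1.0),
           f_t=st.floats(1.0, 1.5), f_r=st.floats(1.0, 2.5))
    @settings(max_examples=25, deadline=None)
    def test_ketamine_and_long_tdcs_commute(self, f_loop, f_sg, f_t, f_r):
        topo = build_default_network()
        ket = KetamineParams(f_ketamine_loop=f_loop, f_ketamine_SG=f_sg,
                             aras_disinhibition_gain=1.2)
        tdcs = LongTDCSParams(f_tDCS=f_t, f_tDCS_resp=f_r)
        ab = apply_long_tdcs(apply_ketamine(topo, ket), tdcs)
        ba = apply_ketamine(apply_long_tdcs(topo, tdcs), ket)
        for sa, sb in zip(ab.synapses, ba.synapses):
            assert sa.efficacy == pytest.approx(sb.efficacy, rel=1e-12)
        assert ab.aras == ba.aras


class TestPlasticityKinetics:
    def test_decay_matches_closed_form(self):
        p = PlasticityParams(tau_plast=MIN, tau_decay=30 * MIN)
        f = 1.2
        dt = p.tau_decay / 5000.0
        n = int(round(40 * MIN / dt))
        for _ in range(n):
            f = plasticity_step(f, stimulating=False, current=0.0, dt=dt, p=p)
        assert abs(f - plasticity_decay(1.2, n * dt, p)) < 1e-6

    def test_decay_reaches_printed_factors(self):
        """1.2 decays to ~1.1 after 20 min and ~1.05 after 40 min (tau 30 min)."""
        p = PlasticityParams(tau_plast=MIN, tau_decay=30 * MIN)
        assert round(plasticity_decay(1.2, 20 * MIN, p), 2) == 1.10
        assert round(plasticity_decay(1.2, 40 * MIN, p), 2) == 1.05
        assert plasticity_decay(1.2, 20 * MIN, p) == pytest.approx(
            1 + 0.2 * math.exp(-2 / 3), rel=1e-12)

    def test_growth_saturates_and_zero_duration_is_baseline(self):
        p = PlasticityParams(tau_plast=MIN, tau_decay=30 * MIN)
        assert plasticity_step(1.0, True, 1.0, 1000 * p.tau_plast, p) == pytest.approx(p.f_sat, rel=1e-6)
        proto = StimulationProtocol(blocks=(), total_horizon=10.0)
        t, f = plasticity_trajectory(proto, p, dt=1.0)
        np.testing.assert_array_equal(f, 1.0)

    def test_calibrated_growth_hits_both_anchor_durations(self):
        """12 min -> 1.2 and 4 min -> 1.05 at tau_plast = 1 min (within 0.01)."""
        p = PlasticityParams(tau_plast=MIN, tau_decay=30 * MIN)
        f12 = plasticity_step(1.0, True, 1.0, 12 * MIN, p)
        f4 = plasticity_step(1.0, True, 1.0, 4 * MIN, p)
        assert abs(f12 - 1.2) < 0.01
        assert abs(f4 - 1.05) < 0.01

    def test_calibration_recovers_seed(self):
        p = PlasticityParams(tau_plast=MIN, tau_decay=30 * MIN, seed_fraction=0.1)
        frac, report = calibrate_growth_seed([(12 * MIN, 1.2), (4 * MIN, 1.05)], p)
        assert frac == pytest.approx(1 / 164.77, rel=0.02)
        assert all(abs(r) < 5e-3 for r in report["residuals"].values())

    @given(ts1=st.floats(10, 2000), ts2=st.floats(10, 2000),
           c1=st.floats(0.2, 2.0), c2=st.floats(0.2, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_growth_monotone_in_duration_and_current(self, ts1, ts2, c1, c2):
        p = PlasticityParams(tau_plast=MIN, tau_decay=30 * MIN)
        if ts1 > ts2:
            ts1, ts2 = ts2, ts1
        if c1 > c2:
            c1, c2 = c2, c1
        f_short = plasticity_step(1.0, True, c1, ts1, p)
        f_long = plasticity_step(1.0, True, c1, ts2, p)
        assert 1.0 <= f_short <= f_long <= p.f_sat + 1e-12
        assert plasticity_step(1.0, True, c2, ts1, p) >= f_short - 1e-12

    def test_lower_current_needs_more_time(self):
        p = PlasticityParams(tau_plast=MIN, tau_decay=30 * MIN)
        assert time_to_factor(1.1, 0.5, p) > time_to_factor(1.1, 1.0, p)

    def test_trajectory_monotone_during_single_block(self):
        p = PlasticityParams(tau_plast=MIN, tau_decay=30 * MIN)
        proto = StimulationProtocol(blocks=((0.0, 30 * MIN, 1.0),), total_horizon=30 * MIN)
        t, f = plasticity_trajectory(proto, p, dt=5.0)
        assert np.all(np.diff(f) >= -1e-12)
        assert f[-1] <= p.f_sat + 1e-9

    def test_repeated_protocol_accumulates(self):
        """Stimulation blocks with long pauses ratchet plasticity upward when
        decay is much slower than growth."""
        h = 3600.0
        p = PlasticityParams(f_sat=1.2, tau_plast=3 * h, tau_decay=500 * h)
        proto = StimulationProtocol.repeated(duration=1 * h, pause=12 * h,
                                             repetitions=10, final_period=34 * h)
        t, f = plasticity_trajectory(proto, p, dt=120.0)
        peaks = [f[np.searchsorted(t, k * 13 * h + 1 * h)] for k in range(10)]
        assert np.all(np.diff(peaks) > 0)
        assert f[-1] > 1.01

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            StimulationProtocol(blocks=((0.0, 10.0, 1.0), (5.0, 10.0, 1.0)),
                                total_horizon=100.0)
        with pytest.raises(ValueError):
            StimulationProtocol(blocks=((0.0, 10.0, 1.0),), total_horizon=5.0)
        p = PlasticityParams()
        with pytest.raises(ValueError):
            plasticity_step(1.1, True, 1.0, -1.0, p)
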