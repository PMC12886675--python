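"""Forward-model contracts: linearity, Nernstian response, interference,
artifacts and readout extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from empatch import sensors
from empatch.sensors import (
    ENZYMATIC_INTERFERENT_PANEL,
    ION_INTERFERENT_PANEL,
    add_artifacts,
    amperometric_forward,
    apply_interference,
    noiseless,
    potentiometric_forward,
    steady_state,
)


@pytest.fixture(scope="module")
def params():
    return sensors.device_channel_params()


class TestAmperometric:
    def test_zero_input_zero_current(self, params):
        p = noiseless(params["glucose"])
        tr = amperometric_forward(0.0, p)
        assert steady_state(tr, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_unit_concentration_gives_printed_sensitivity(self, params):
        p = noiseless(params["glucose"])
        tr = amperometric_forward(1.0, p)
        assert steady_state(tr, 10.0) == pytest.approx(0.1122, rel=1e-12)

    def test_linearity_ratio(self, params):
        p = noiseless(params["glucose"])
        y10 = steady_state(amperometric_forward(10.0, p), 10.0)
        y5 = steady_state(amperometric_forward(5.0, p), 10.0)
        assert y10 / y5 == pytest.approx(2.0, rel=1e-12)

    @pytest.mark.parametrize("channel", ["glucose", "ua", "cholesterol"])
    def test_monotone_in_concentration(self, params, channel):
        p = noiseless(params[channel])
        lo, hi = p.linear_range
        ladder = np.linspace(lo, hi, 9)
        ys = [steady_state(amperometric_forward(c, p), 10.0) for c in ladder]
        assert np.all(np.diff(ys) > 0)

    def test_saturation_flag_and_edge_value(self, params):
        p = noiseless(params["glucose"])
        tr = amperometric_forward(25.0, p)  # above the 20 mM range
        assert tr.saturated
        assert steady_state(tr, 10.0) == pytest.approx(0.1122 * 20.0, rel=1e-12)

    def test_wrong_modality_rejected(self, params):
        with pytest.raises(ValueError):
            amperometric_forward(1.0, params["na"])

    def test_seeded_reproducibility(self, params):
        a = amperometric_forward(5.0, params["glucose"], seed=42)
        b = amperometric_forward(5.0, params["glucose"], seed=42)
        assert np.array_equal(a.y, b.y)
        c = amperometric_forward(5.0, params["glucose"], seed=43)
        assert not np.array_equal(a.y, c.y)


class TestPotentiometric:
    def test_reference_concentration_gives_intercept(self, params):
        p = noiseless(params["na"])
        tr = potentiometric_forward(p.ref_conc, p)
        assert steady_state(tr, 10.0) == pytest.approx(p.intercept, rel=1e-12)

    def test_decade_step_is_printed_slope(self, params):
        p = noiseless(params["na"])
        e10 = steady_state(potentiometric_forward(10.0, p), 10.0)
        e100 = steady_state(potentiometric_forward(100.0, p), 10.0)
        assert e100 - e10 == pytest.approx(52.87, rel=1e-12)

    def test_potassium_full_range_step(self, params):
        p = noiseless(params["k"])
        e1 = steady_state(potentiometric_forward(1.0, p), 10.0)
        e32 = steady_state(potentiometric_forward(32.0, p), 10.0)
        assert e32 - e1 == pytest.approx(58.46 * np.log10(32.0), rel=1e-12)

    @given(conc=st.floats(min_value=5.0, max_value=16.0))
    @settings(max_examples=25, deadline=None)
    def test_nernstian_decade_property(self, conc):
        # E(10·C) − E(C) equals the slope exactly for any in-range C
        p = noiseless(sensors.device_channel_params()["na"])
        e1 = steady_state(potentiometric_forward(conc, p), 10.0)
        e2 = steady_state(potentiometric_forward(10.0 * conc, p), 10.0)
        assert e2 - e1 == pytest.approx(p.slope, rel=1e-9)

    def test_nonpositive_ion_concentration_rejected(self, params):
        with pytest.raises(ValueError):
            potentiometric_forward(0.0, params["na"])

    def test_ph_response_is_negative_going(self, params):
        p = noiseless(params["ph"])
        e4 = steady_state(potentiometric_forward(4.0, p), 10.0)
        e7 = steady_state(potentiometric_forward(7.0, p), 10.0)
        assert e4 - e7 == pytest.approx(3 * 57.61, rel=1e-12)


class TestInterference:
    def test_empty_map_is_zero(self, params):
        assert apply_interference(5.0, {}, params["glucose"]) == 0.0

    def test_single_term_product(self, params):
        p = params["glucose"]
        p2 = sensors.ChannelParams(
            channel="glucose", modality="amperometric", slope=p.slope,
            interference_coeffs={"aa_uM": 0.001}, linear_range=p.linear_range,
        )
        assert apply_interference(5.0, {"aa_uM": 300.0}, p2) == pytest.approx(0.3)

    def test_unknown_interferent_lists_known_names(self, params):
        with pytest.raises(KeyError, match="aa_uM"):
            apply_interference(5.0, {"mystery_uM": 1.0}, params["glucose"])

    @pytest.mark.parametrize(
        "channel,target",
        [("glucose", 5.0), ("ua", 300.0), ("cholesterol", 5.0)],
    )
    def test_enzymatic_panel_within_selectivity_budget(self, params, channel, target):
        # each single addition from the bench panel drifts the signal <= 6%
        p = params[channel]
        signal = p.slope * target
        for name, conc in ENZYMATIC_INTERFERENT_PANEL.items():
            if name not in p.interference_coeffs:
                continue
            delta = apply_interference(target, {name: conc}, p)
            assert abs(delta) / signal <= 0.06

    @pytest.mark.parametrize(
        "channel,target", [("na", 140.0), ("k", 4.2), ("ph", 7.0)]
    )
    def test_ion_panel_within_selectivity_budget(self, params, channel, target):
        p = params[channel]
        signal = abs(sensors.steady_value(target, p))
        for name, conc in ION_INTERFERENT_PANEL.items():
            if name not in p.interference_coeffs:
                continue
            delta = apply_interference(target, {name: conc}, p)
            assert abs(delta) / signal <= 0.06


class TestArtifacts:
    def _flat_trace(self, value=1.0, n=121):
        t = np.arange(n, dtype=float)
        return sensors.SensorTrace(channel="glucose", t=t,
                                   y=np.full(n, value),
                                   sample_rate_hz=1.0, unit="uA_cm2")

    def test_no_drift_no_motion_is_identity(self):
        tr = self._flat_trace()
        out = add_artifacts(tr)
        assert np.array_equal(out.y, tr.y)

    def test_linear_drift_arithmetic(self):
        tr = self._flat_trace(value=5.0, n=121)  # 120 s span
        out = add_artifacts(tr, drift_rate=1.0)
        assert out.y[-1] - out.y[0] == pytest.approx(2.0)

    def test_motion_amplitude_ratio_scenario(self):
        # stiff-backing vs elastomer-backing scenario: 4x amplitude ratio;
        # 10 Hz sampling resolves the 8 Hz artifact oscillation
        t = np.arange(1200) * 0.1
        tr = sensors.SensorTrace(channel="glucose", t=t, y=np.ones(1200),
                                 sample_rate_hz=10.0, unit="uA_cm2")
        soft = add_artifacts(tr, motion={"amplitude": 0.5, "times": [60.0, 90.0]},
                             seed=5)
        stiff = add_artifacts(tr, motion={"amplitude": 2.0, "times": [60.0, 90.0]},
                              seed=5)
        ratio = np.ptp(stiff.y - tr.y) / np.ptp(soft.y - tr.y)
        assert ratio == pytest.approx(4.0, rel=0.05)


class TestSteadyState:
    def test_constant_trace(self):
        t = np.arange(60.0)
        tr = sensors.SensorTrace("glucose", t, np.full(60, 5.0), 1.0, "uA_cm2")
        assert steady_state(tr, 10.0) == 5.0

    def test_transient_settles_to_asymptote(self, params):
        p = noiseless(params["glucose"])
        tr = amperometric_forward(2.0, p, duration_s=90.0, transient_amp=1.0)
        # readout window entirely after the 30 s settle time
        assert steady_state(tr, 20.0) == pytest.approx(0.1122 * 2.0, rel=1e-3)

    def test_noise_averages_toward_mean(self):
        rng_sd = 0.3
        n = 400
        t = np.arange(float(n))
        y = np.random.default_rng(9).normal(0.0, rng_sd, n)
        tr = sensors.SensorTrace("glucose", t, y, 1.0, "uA_cm2")
        assert abs(steady_state(tr, float(n))) < 4 * rng_sd / np.sqrt(n)

    def test_window_longer_than_trace_rejected(self):
        t = np.arange(10.0)
        tr = sensors.SensorTrace("glucose", t, np.ones(10), 1.0, "uA_cm2")
        with pytest.raises(ValueError):
            steady_state(tr, 60.0)


def test_params_yaml_round_trip(tmp_path, params):
    path = tmp_path / "params.yaml"
    sensors.params_to_yaml(params, path)
    back = sensors.params_from_yaml(path)
    for ch, p in params.items():
        assert back[ch].slope == p.slope
        assert back[ch].interference_coeffs == p.interference_coeffs
        assert back[ch].linear_range == p.linear_range
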