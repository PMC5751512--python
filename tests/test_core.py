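"""Sensor LTI model: closed forms, ZOH simulation, steady states, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minicalor import (
    SensorCalibration,
    TimeSeries,
    simulate_outputs,
    steady_state_outputs,
    tf_step_response,
)
from minicalor.core import CHANNELS, GridMismatchError, InvalidModelError, MeasurementRecord


def _unit_cal(**kw):
    base = dict(K1=1.0, K2=-1.0, K3=1.0, K4=1.0, tau1=80.0, tau2=9.0)
    base.update(kw)
    return SensorCalibration(**base)


# ---------------------------------------------------------------------------
# TimeSeries / record validation
# ---------------------------------------------------------------------------

class TestTimeSeries:
    def test_rejects_bad_dt_and_nonfinite(self):
        with pytest.raises(ValueError):
            TimeSeries(np.zeros(5), dt=0.0)
        with pytest.raises(ValueError):
            TimeSeries(np.array([1.0, np.nan]))

    def test_time_axis_and_unit_conversion(self):
        ts = TimeSeries(np.array([1.0, 2.0]), dt=2.0, t0=10.0, units="mW")
        assert np.allclose(ts.t, [10.0, 12.0])
        assert np.allclose(ts.to("W").values, [1e-3, 2e-3])
        back = ts.to("W").to("mW")
        assert np.allclose(back.values, ts.values)


class TestMeasurementRecord:
    def test_misaligned_channels_rejected(self):
        a = TimeSeries(np.zeros(10), units="mV")
        b = TimeSeries(np.zeros(11), units="degC")
        with pytest.raises(GridMismatchError):
            MeasurementRecord(y1=a, y2=b, W2=TimeSeries(np.zeros(10), units="mW"))

    def test_overlapping_phases_rejected(self):
        a = TimeSeries(np.zeros(10), units="mV")
        with pytest.raises(ValueError, match="overlap"):
            MeasurementRecord(
                y1=a, y2=a.copy(units="degC"), W2=a.copy(units="mW"),
                phases=[("x", 0, 6), ("y", 4, 10)],
            )


# ---------------------------------------------------------------------------
# Closed-form step response
# ---------------------------------------------------------------------------

class TestStepResponse:
    def test_unit_steady_gain(self):
        cal = _unit_cal()
        t = TimeSeries(np.zeros(5000), dt=1.0)
        y = tf_step_response(cal, "TF1", 1.0, t)
        assert y.values[0] == pytest.approx(0.0, abs=1e-12)
        assert y.values[-1] == pytest.approx(1.0, rel=1e-9)

    def test_s1_tf1_steady_value(self, s1):
        t = TimeSeries(np.zeros(8000), dt=1.0)
        y = tf_step_response(s1, "TF1", 0.3, t)
        assert y.values[-1] == pytest.approx(35.394, abs=1e-3)

    def test_pole_zero_cancellation(self):
        # zero on the slow pole leaves a single-exponential rise on the fast one
        cal = _unit_cal(tau1_star=80.0)
        tv = np.arange(200.0)
        y = tf_step_response(cal, "TF1", 1.0, tv)
        expected = 1.0 - np.exp(-tv / cal.tau2)
        assert np.allclose(y.values, expected, atol=1e-12)

    def test_repeated_pole_confluent_form(self):
        cal = _unit_cal(tau1=20.0, tau2=20.0, tau1_star=5.0)
        tv = np.arange(300.0)
        y = tf_step_response(cal, "TF1", 1.0, tv)
        tau, tstar = 20.0, 5.0
        expected = 1.0 - np.exp(-tv / tau) * (1.0 + (1.0 - tstar / tau) * tv / tau)
        assert np.allclose(y.values, expected, atol=1e-12)
        # the ZOH integrator must agree without special casing
        step = TimeSeries(np.ones(300), units="W")
        sim, _ = simulate_outputs(cal, step, None, init="rest")
        assert np.allclose(sim.values, expected, atol=1e-8)

    def test_negative_pole_rejected(self):
        with pytest.raises(InvalidModelError):
            _unit_cal(tau2=-1.0)


# ---------------------------------------------------------------------------
# ZOH simulation vs closed form (oracle equivalence)
# ---------------------------------------------------------------------------

class TestSimulation:
    @pytest.mark.parametrize("channel", CHANNELS)
    @pytest.mark.parametrize("sensor", ["s1", "s2"])
    def test_matches_closed_form_step(self, channel, sensor, request):
        cal = request.getfixturevalue(sensor)
        n = 1200
        step = TimeSeries(np.full(n, 0.3), units="W")
        w1 = step if channel in ("TF1", "TF3") else None
        w2 = step if channel in ("TF2", "TF4") else None
        y1, y2 = simulate_outputs(cal, w1, w2, init="rest")
        sim = y1 if channel in ("TF1", "TF2") else y2
        ref = tf_step_response(cal, channel, 0.3, TimeSeries(np.zeros(n), dt=1.0))
        scale = np.max(np.abs(ref.values))
        assert np.max(np.abs(sim.values - ref.values)) / scale < 1e-6

    def test_zero_inputs_zero_outputs(self, s1):
        z = TimeSeries(np.zeros(100), units="W")
        y1, y2 = simulate_outputs(s1, z, z, init="steady")
        assert np.allclose(y1.values, 0.0) and np.allclose(y2.values, 0.0)

    def test_steady_init_holds_constant(self, s1):
        w1 = TimeSeries(np.full(50, 0.3), units="W")
        w2 = TimeSeries(np.full(50, 0.1), units="W")
        y1, y2 = simulate_outputs(s1, w1, w2, init="steady")
        dy1, dy2 = steady_state_outputs(s1, 0.3, 0.1)
        assert np.allclose(y1.values, dy1, rtol=1e-9)
        assert np.allclose(y2.values, dy2, rtol=1e-9)

    def test_final_value_theorem(self, s1):
        # after >= 10 tau1 a step has settled to the steady gains within 0.1%
        n = int(10 * s1.tau1) + 2
        w1 = TimeSeries(np.full(n, 0.3), units="W")
        w2 = TimeSeries(np.full(n, -0.05), units="W")
        y1, y2 = simulate_outputs(s1, w1, w2, init="rest")
        dy1, dy2 = steady_state_outputs(s1, 0.3, -0.05)
        assert y1.values[-1] == pytest.approx(dy1, rel=1e-3)
        assert y2.values[-1] == pytest.approx(dy2, rel=1e-3)

    def test_mW_and_W_inputs_agree(self, s1):
        w_W = TimeSeries(np.full(50, 0.3), units="W")
        w_mW = TimeSeries(np.full(50, 300.0), units="mW")
        ya, _ = simulate_outputs(s1, w_W, None)
        yb, _ = simulate_outputs(s1, w_mW, None)
        assert np.allclose(ya.values, yb.values)

    def test_grid_mismatch_rejected(self, s1):
        with pytest.raises(GridMismatchError):
            simulate_outputs(
                s1,
                TimeSeries(np.zeros(10), units="W"),
                TimeSeries(np.zeros(11), units="W"),
            )

    def test_saturation_flagging(self, s1, caplog):
        w2 = TimeSeries(np.linspace(0.0, 2.0, 50), units="W")
        with caplog.at_level("WARNING"):
            y1, _ = simulate_outputs(s1, None, w2, w2_bounds=(0.0, 1.0))
        assert y1.saturated.sum() == np.sum(w2.values > 1.0)
        assert "saturation" in caplog.text


# ---------------------------------------------------------------------------
# Steady-state sensitivity equations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sensor,dW,expected",
    [
        ("s1", (0.0, 0.0), (0.0, 0.0)),
        ("s1", (0.3, 0.0), (35.394, 2.694)),
        ("s2", (0.0, 1.0), (-42.22, 9.82)),
    ],
)
def test_steady_state_outputs_reference_values(sensor, dW, expected, request):
    cal = request.getfixturevalue(sensor)
    got = steady_state_outputs(cal, *dW)
    assert got == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# LTI property suites
# ---------------------------------------------------------------------------

@st.composite
def piecewise_input(draw, n=240):
    """Random piecewise-constant power signal (W) on an n-sample grid."""
    k = draw(st.integers(2, 5))
    edges = sorted(draw(st.lists(st.integers(1, n - 1), min_size=k - 1,
                                 max_size=k - 1, unique=True)))
    levels = draw(st.lists(st.floats(-0.5, 0.5), min_size=k, max_size=k))
    out = np.empty(n)
    prev = 0
    for edge, level in zip(edges + [n], levels):
        out[prev:edge] = level
        prev = edge
    return out


class TestLTIProperties:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(u=piecewise_input(), v=piecewise_input(),
           a=st.floats(-2, 2), b=st.floats(-2, 2))
    def test_superposition(self, s1, u, v, a, b):
        mk = lambda arr: TimeSeries(arr, units="W")
        y_u, _ = simulate_outputs(s1, mk(u), None, init="steady")
        y_v, _ = simulate_outputs(s1, mk(v), None, init="steady")
        y_ab, _ = simulate_outputs(s1, mk(a * u + b * v), None, init="steady")
        assert np.allclose(y_ab.values, a * y_u.values + b * y_v.values,
                           atol=1e-9, rtol=1e-7)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(u=piecewise_input(), k=st.integers(1, 40))
    def test_time_invariance(self, s1, u, k):
        # shifting a constant-padded input by k samples shifts the output by k
        mk = lambda arr: TimeSeries(arr, units="W")
        shifted = np.concatenate([np.full(k, u[0]), u[:-k]]) if k else u
        y, _ = simulate_outputs(s1, mk(u), None, init="steady")
        y_s, _ = simulate_outputs(s1, mk(shifted), None, init="steady")
        assert np.allclose(y_s.values[k:], y.values[:-k], atol=1e-9, rtol=1e-7)
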