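"""Calibration chain: baselines, steady zones, sensitivities, dynamics fit."""

import numpy as np
import pytest

from minicalor import (
    MeasurementRecord,
    SensorCalibration,
    SensorDynamicsModel,
    TimeSeries,
    correct_baseline,
    extract_steady_states,
    solve_sensitivities,
    steady_state_outputs,
)
from minicalor.calibration import (
    OptimizerOptions,
    SingularProtocolError,
    SteadyStateSet,
    SteadyZone,
    ZoneError,
    auto_delta,
    fit_dynamics,
    fit_dynamics_varpro,
)
from minicalor.synthetic import NoiseSpec, ProtocolSchedule, generate_calibration_run

from conftest import S1_TRUTH


def _record(values_by_channel, phases=()):
    n = len(next(iter(values_by_channel.values())))
    units = {"y1": "mV", "y2": "degC", "W1": "mW", "W2": "mW"}
    chans = {
        k: TimeSeries(np.asarray(v, float), units=units[k])
        for k, v in values_by_channel.items()
    }
    chans.setdefault("y1", TimeSeries(np.zeros(n), units="mV"))
    chans.setdefault("y2", TimeSeries(np.zeros(n), units="degC"))
    chans.setdefault("W2", TimeSeries(np.zeros(n), units="mW"))
    return MeasurementRecord(phases=list(phases), **chans)


# ---------------------------------------------------------------------------
# Baseline correction
# ---------------------------------------------------------------------------

class TestCorrectBaseline:
    def test_constant_signal_goes_to_zero(self):
        rec = _record({"y1": np.full(100, 7.3)})
        out = correct_baseline(rec, (0, 20), (80, 100))
        assert np.allclose(out.y1.values, 0.0, atol=1e-12)
        assert out.delta

    def test_linear_drift_removed(self):
        t = np.arange(200.0)
        rec = _record({"y1": 2.0 + 0.01 * t})
        out = correct_baseline(rec, (0, 30), (170, 200))
        assert np.allclose(out.y1.values, 0.0, atol=1e-9)

    def test_pre_only_subtracts_mean(self):
        rec = _record({"y1": np.full(50, 5.0)})
        out = correct_baseline(rec, (0, 20))
        assert np.allclose(out.y1.values, 0.0, atol=1e-12)

    def test_short_window_rejected(self):
        rec = _record({"y1": np.zeros(100)})
        with pytest.raises(ValueError, match="10 samples"):
            correct_baseline(rec, (0, 5))

    def test_window_in_active_phase_rejected(self):
        rec = _record({"y1": np.zeros(100)}, phases=[("contact", 30, 60)])
        with pytest.raises(ValueError, match="active"):
            correct_baseline(rec, (25, 45))

    def test_y2_units_become_kelvin_delta(self):
        rec = _record({"y2": np.full(50, 24.0)})
        out = correct_baseline(rec, (0, 20))
        assert out.y2.units == "K"

    def test_drift_does_not_bias_sensitivities(self, s1):
        """A 0.01 mV/s baseline drift must not move the recovered gains."""
        clean = generate_calibration_run(s1, noise=NoiseSpec.noiseless())
        drifty = generate_calibration_run(
            s1, noise=NoiseSpec.noiseless(), y1_drift=0.01
        )
        gains = []
        for rec in (clean, drifty):
            ss = extract_steady_states(
                auto_delta(rec), ProtocolSchedule.calibration_default()
            )
            gains.append(solve_sensitivities(ss).gains)
        for a, b in zip(*gains):
            assert a == pytest.approx(b, rel=5e-3)


# ---------------------------------------------------------------------------
# Steady-state extraction
# ---------------------------------------------------------------------------

def _piecewise_steady_record(cal, zones, dW_pairs):
    """Record that jumps instantly between exact steady states."""
    n = zones[-1][2]
    y1 = np.zeros(n)
    y2 = np.zeros(n)
    w1 = np.zeros(n)
    w2 = np.zeros(n)
    for (label, a, b), (dw1, dw2) in zip(zones, dW_pairs):
        dy1, dy2 = steady_state_outputs(cal, dw1, dw2)
        y1[a:b], y2[a:b] = dy1, dy2
        w1[a:b], w2[a:b] = dw1 * 1e3, dw2 * 1e3
    return MeasurementRecord(
        y1=TimeSeries(y1, units="mV"), y2=TimeSeries(y2, units="K"),
        W1=TimeSeries(w1, units="mW"), W2=TimeSeries(w2, units="mW"),
        delta=True,
    )


ZONES = [("a", 0, 200), ("b", 200, 400), ("c", 400, 600)]
DW = [(0.0, 0.0), (0.0, 0.3), (0.3, 0.1)]


class TestExtractSteadyStates:
    def test_exact_on_piecewise_steady_record(self, s1):
        rec = _piecewise_steady_record(s1, ZONES, DW)
        ss = extract_steady_states(rec, ZONES, settle_multiplier=1.0, tau_rough=100)
        for zone, (dw1, dw2) in zip(ss, DW):
            dy1, dy2 = steady_state_outputs(s1, dw1, dw2)
            assert zone.dy1 == pytest.approx(dy1, abs=1e-9)
            assert zone.dy2 == pytest.approx(dy2, abs=1e-9)
            assert zone.dW1 == pytest.approx(dw1, abs=1e-12)
            assert zone.dW2 == pytest.approx(dw2, abs=1e-12)
            assert not zone.flagged

    def test_zone_shorter_than_settle_cut_errors(self, s1):
        rec = _piecewise_steady_record(s1, ZONES, DW)
        with pytest.raises(ZoneError, match="settle"):
            extract_steady_states(rec, ZONES, settle_multiplier=3.0, tau_rough=100)

    def test_non_delta_record_rejected(self, s1):
        rec = _piecewise_steady_record(s1, ZONES, DW)
        rec.delta = False
        with pytest.raises(ValueError, match="delta"):
            extract_steady_states(rec, ZONES)

    def test_noisy_zone_means_near_truth(self, s1, rng):
        """With instrument-level noise the zone estimates stay within 3 s.e."""
        rec = _piecewise_steady_record(s1, ZONES, DW)
        spec = NoiseSpec(seed=11)
        rec.y1.values += spec.draw(rng, len(rec), spec.y1_half_amp)
        rec.y2.values += spec.draw(rng, len(rec), spec.y2_half_amp) * 1e-3
        ss = extract_steady_states(rec, ZONES, settle_multiplier=1.0,
                                   tau_rough=100, method="mean")
        n_avg = 100
        se_y1 = (spec.y1_half_amp / 2) / np.sqrt(n_avg / 5)  # smoothing correlates 5 samples
        for zone, (dw1, dw2) in zip(ss, DW):
            dy1, _ = steady_state_outputs(s1, dw1, dw2)
            assert abs(zone.dy1 - dy1) < 3 * se_y1


# ---------------------------------------------------------------------------
# Sensitivity solving
# ---------------------------------------------------------------------------

def _zones_from_gains(cal, dW_pairs, noise1=None, noise2=None):
    zones = []
    for i, (dw1, dw2) in enumerate(dW_pairs):
        dy1, dy2 = steady_state_outputs(cal, dw1, dw2)
        if noise1 is not None:
            dy1 += noise1[i]
            dy2 += noise2[i]
        zones.append(SteadyZone(chr(97 + i), 0, 1, dy1, dy2, dw1, dw2))
    return SteadyStateSet(zones)


class TestSolveSensitivities:
    def test_exact_recovery_noiseless(self, s1):
        ss = _zones_from_gains(s1, [(0, 0), (0, 0.33), (0.3, 0.11), (0, 0.34), (0, 0)])
        sens = solve_sensitivities(ss)
        for got, name in zip(sens.gains, ("K1", "K2", "K3", "K4")):
            assert got == pytest.approx(S1_TRUTH[name], rel=1e-9)

    def test_proportional_zones_raise_singularity(self, s1):
        ss = _zones_from_gains(s1, [(0.1, 0.2), (0.2, 0.4)])
        with pytest.raises(SingularProtocolError, match="proportional"):
            solve_sensitivities(ss)

    def test_single_zone_rejected(self, s1):
        ss = _zones_from_gains(s1, [(0.3, 0.1)])
        with pytest.raises(SingularProtocolError):
            solve_sensitivities(ss)

    def test_mean_K1_within_uncertainty_band_under_noise(self, s1, rng):
        """100 noisy replicates: mean K1 inside the published +-0.33 mV/W."""
        dW = [(0, 0), (0, 0.336), (0.3, 0.11), (0, 0.336), (0, 0)]
        se_y1 = 0.1 / np.sqrt(180 / 5)   # zone-mean noise after smoothing
        se_y2 = 2.5e-3 / np.sqrt(180 / 5)
        k1 = []
        for _ in range(100):
            n1 = rng.normal(0, se_y1, len(dW))
            n2 = rng.normal(0, se_y2, len(dW))
            sens = solve_sensitivities(_zones_from_gains(s1, dW, n1, n2))
            k1.append(sens.K1)
        assert abs(np.mean(k1) - S1_TRUTH["K1"]) < 0.33


# ---------------------------------------------------------------------------
# Dynamics fitting
# ---------------------------------------------------------------------------

class TestFitDynamics:
    def test_staged_fit_recovers_poles_with_true_gains(self, s1):
        """Gains fixed at truth, init at 2x: poles within 1%, sigma tiny."""
        rec = auto_delta(generate_calibration_run(s1, noise=NoiseSpec.noiseless()))
        gains = (s1.K1, s1.K2, s1.K3, s1.K4)
        init = (2 * s1.tau1, 2 * s1.tau2,
                2 * s1.tau1_star, 2 * s1.tau2_star, 0.0, 2 * s1.tau4_star)
        cal, sig1, sig2, trace, n_eval = fit_dynamics(rec, gains, init_guess=init)
        assert cal.tau1 == pytest.approx(s1.tau1, rel=1e-2)
        assert cal.tau2 == pytest.approx(s1.tau2, rel=1e-2)
        assert sig1 <= 1e-3
        assert n_eval > 0

    def test_zero_zero_stays_at_boundary(self, s1):
        """tau3* initialized at 0 with true value 0 stays snapped to 0."""
        rec = auto_delta(generate_calibration_run(s1, noise=NoiseSpec.noiseless()))
        gains = (s1.K1, s1.K2, s1.K3, s1.K4)
        init = (s1.tau1, s1.tau2, s1.tau1_star, s1.tau2_star, 0.0, s1.tau4_star)
        cal, *_ = fit_dynamics(rec, gains, init_guess=init,
                               opts=OptimizerOptions(maxfev=800, n_restarts=0))
        assert cal.tau3_star == 0.0

    def test_objective_trace_monotone(self, s1):
        rec = auto_delta(generate_calibration_run(s1, noise=NoiseSpec.noiseless()))
        _, _, _, trace, _ = fit_dynamics_varpro(rec, init_taus=(30.0, 3.0))
        vals = np.array(trace.values)
        assert len(vals) > 3
        assert np.all(np.diff(vals) <= 1e-12)

    def test_scale_equivariance(self, s1):
        """Scaling y1 rescales K1, K2 but leaves the time constants alone."""
        rec = auto_delta(generate_calibration_run(s1, noise=NoiseSpec.noiseless()))
        res_a = fit_dynamics_varpro(rec)
        rec_scaled = MeasurementRecord(
            y1=TimeSeries(rec.y1.values * 3.0, units="mV"),
            y2=rec.y2.copy(), W2=rec.W2.copy(), W1=rec.W1.copy(), delta=True,
        )
        res_b = fit_dynamics_varpro(rec_scaled)
        assert res_b[0].tau1 == pytest.approx(res_a[0].tau1, rel=1e-6)
        assert res_b[0].tau2 == pytest.approx(res_a[0].tau2, rel=1e-6)
        assert res_b[0].K1 == pytest.approx(3.0 * res_a[0].K1, rel=1e-6)
        assert res_b[0].K2 == pytest.approx(3.0 * res_a[0].K2, rel=1e-6)

    @pytest.mark.parametrize("draw", range(5))
    def test_identifiability_round_trip_random_truths(self, draw):
        """Noiseless generate -> calibrate recovers all 10 parameters <1%."""
        rng = np.random.default_rng(500 + draw)
        truth = SensorCalibration(
            K1=rng.uniform(100, 140), K2=-rng.uniform(40, 60),
            K3=rng.uniform(7, 10), K4=rng.uniform(9, 13),
            tau1=rng.uniform(40, 120), tau2=rng.uniform(4, 15),
            tau1_star=rng.uniform(20, 90), tau2_star=rng.uniform(60, 120),
            tau3_star=0.0, tau4_star=rng.uniform(5, 30),
        )
        rec = generate_calibration_run(truth, noise=NoiseSpec.noiseless())
        result = SensorDynamicsModel(rec).fit()
        fitted = result.calibration.as_dict()
        for name, true_val in truth.as_dict().items():
            if name == "label":
                continue
            if true_val == 0.0:
                assert abs(fitted[name]) < 0.5
            else:
                assert fitted[name] == pytest.approx(true_val, rel=1e-2), name

    def test_summary_mentions_all_parameters(self, s1):
        rec = generate_calibration_run(s1, noise=NoiseSpec.noiseless())
        res = SensorDynamicsModel(rec).fit()
        text = res.summary()
        for token in ("K1", "tau1", "sigma_y1", "zones"):
            assert token in text
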