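"""Linear time-invariant model of the heat-conduction calorimetry minisensor.

The minisensor is a thermopile stack between a 2 x 2 cm measurement plate and a
temperature-regulated thermostat block.  It behaves, to a very good
approximation, as a linear time-invariant system with two inputs and two
outputs:

* inputs  — ``W1``: heat power crossing the measurement face (the Joule
  calibration resistor or the body surface, W) and ``W2``: Joule power
  dissipated in the thermostat to hold its temperature (W);
* outputs — ``y1``: calorimetric (thermopile) voltage (mV) and ``y2``: the
  thermostat temperature excess (K).

Each of the four input→output transfer functions ``TF1..TF4`` shares the same
pair of real poles and has a single zero and its own steady-state gain::

    TF_i(s) = K_i (1 + s tau_i*) / ((1 + s tau_1)(1 + s tau_2))

``TF1, TF2`` map ``W1, W2`` to ``y1``; ``TF3, TF4`` map them to ``y2``.

The module provides the closed-form step response, an exact zero-order-hold
(ZOH) discrete simulation of arbitrary sampled inputs, and a stateful
per-sample stepper used by the synthetic thermostat control loop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

CHANNELS = ("TF1", "TF2", "TF3", "TF4")

#: unit label -> factor converting stored samples to the SI base unit
_UNIT_TO_SI = {
    "mV": 1e-3, "V": 1.0,
    "mW": 1e-3, "W": 1.0,
    "mK": 1e-3, "K": 1.0, "degC": 1.0, "°C": 1.0, "C": 1.0,
}


class InvalidModelError(ValueError):
    """Raised when calibration parameters describe an unstable/degenerate sensor."""


class GridMismatchError(ValueError):
    """Raised when time series meant to be synchronous disagree on t0/dt/length."""


# ---------------------------------------------------------------------------
# TimeSeries
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array_like
        Ordered samples.  Must be finite.
    dt : float, default 1.0
        Sampling interval in seconds (the instrument samples at 1 s).
    t0 : float, default 0.0
        Time of the first sample, seconds.
    units : str
        Unit label of the samples (``mV``, ``degC``, ``K``, ``mW``, ``W``).
    """

    values: np.ndarray
    dt: float = 1.0
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("TimeSeries contains non-finite samples")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t(self) -> np.ndarray:
        """Sample times ``t0 + k*dt``."""
        return self.t0 + self.dt * np.arange(len(self.values))

    def copy(self, **changes) -> "TimeSeries":
        ts = replace(self, **changes)
        ts.values = np.array(ts.values, copy=True)
        return ts

    def same_grid(self, other: "TimeSeries", tol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and abs(self.dt - other.dt) <= tol
            and abs(self.t0 - other.t0) <= tol
        )

    def to(self, units: str) -> "TimeSeries":
        """Return a copy converted to another unit of the same kind."""
        if units == self.units:
            return self.copy()
        try:
            factor = _UNIT_TO_SI[self.units] / _UNIT_TO_SI[units]
        except KeyError as exc:
            raise ValueError(f"unknown unit in conversion {self.units!r}->{units!r}") from exc
        return TimeSeries(self.values * factor, dt=self.dt, t0=self.t0, units=units)


def _as_watts(ts: TimeSeries) -> np.ndarray:
    if ts.units in ("W", ""):
        return ts.values
    if ts.units == "mW":
        return ts.values * 1e-3
    raise ValueError(f"expected a power series (W/mW), got units {ts.units!r}")


# ---------------------------------------------------------------------------
# SensorCalibration
# ---------------------------------------------------------------------------

@dataclass
class SensorCalibration:
    """Full parameter set of the two-pole/one-zero four-channel sensor model.

    Gains are stored in the instrument's natural units (``K1, K2`` in mV/W,
    ``K3, K4`` in K/W); time constants in seconds.  ``tau1 >= tau2`` is the
    slow-pole-first convention.
    """

    K1: float   # mV/W, W1 -> y1
    K2: float   # mV/W, W2 -> y1 (negative for these devices)
    K3: float   # K/W,  W1 -> y2
    K4: float   # K/W,  W2 -> y2
    tau1: float             # s, slow pole
    tau2: float             # s, fast pole
    tau1_star: float = 0.0  # s, zero of TF1
    tau2_star: float = 0.0  # s, zero of TF2
    tau3_star: float = 0.0  # s, zero of TF3
    tau4_star: float = 0.0  # s, zero of TF4
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.tau1 > 0 and self.tau2 > 0):
            raise InvalidModelError(
                f"poles must be positive (stable sensor): tau1={self.tau1}, tau2={self.tau2}"
            )
        for name in ("tau1_star", "tau2_star", "tau3_star", "tau4_star"):
            if getattr(self, name) < 0:
                raise InvalidModelError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (self.K1 > 0 and self.K3 > 0 and self.K4 > 0):
            warnings.warn(
                "expected K1, K3, K4 > 0 (heat into the measurement face raises "
                "the signal; thermostat power raises thermostat temperature)",
                stacklevel=2,
            )
        if self.K2 >= 0:
            warnings.warn(
                "expected K2 < 0 for these devices (thermostat heating lowers the "
                "thermopile signal)",
                stacklevel=2,
            )

    # -- channel bookkeeping -------------------------------------------------
    def gain(self, channel: str) -> float:
        return {"TF1": self.K1, "TF2": self.K2, "TF3": self.K3, "TF4": self.K4}[channel]

    def zero(self, channel: str) -> float:
        return {
            "TF1": self.tau1_star, "TF2": self.tau2_star,
            "TF3": self.tau3_star, "TF4": self.tau4_star,
        }[channel]

    @property
    def gain_matrix(self) -> np.ndarray:
        """Steady-state sensitivity matrix [[K1, K2], [K3, K4]] (mixed units)."""
        return np.array([[self.K1, self.K2], [self.K3, self.K4]])

    def as_dict(self) -> dict:
        return {"label": self.label} | {
            k: float(getattr(self, k))
            for k in ("K1", "K2", "K3", "K4", "tau1", "tau2",
                      "tau1_star", "tau2_star", "tau3_star", "tau4_star")
        }

    def tf(self, channel: str) -> tuple[np.ndarray, np.ndarray]:
        """Continuous transfer function (num, den) of one channel."""
        K, tstar = self.gain(channel), self.zero(channel)
        num = np.array([K * tstar, K]) if tstar > 0 else np.array([K])
        den = np.array([self.tau1 * self.tau2, self.tau1 + self.tau2, 1.0])
        return num, den


# ---------------------------------------------------------------------------
# MeasurementRecord
# ---------------------------------------------------------------------------

@dataclass
class MeasurementRecord:
    """Synchronized channel bundle of one instrument run.

    ``y1`` (mV), ``y2`` (degC, or K excess in delta form) and ``W2`` (mW) are
    mandatory; ``W1`` (mW) is present only when the dissipated power is known
    (calibration runs), ``Troom`` (degC) is optional.  ``phases`` mark
    half-open index intervals ``(label, start, stop)``.
    """

    y1: TimeSeries
    y2: TimeSeries
    W2: TimeSeries
    W1: TimeSeries | None = None
    Troom: TimeSeries | None = None
    phases: list[tuple[str, int, int]] = field(default_factory=list)
    Tcal: float | list[float] | None = None
    delta: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = self.y1
        for name in ("y2", "W2", "W1", "Troom"):
            ch = getattr(self, name)
            if ch is not None and not ref.same_grid(ch):
                raise GridMismatchError(f"channel {name} is not on the y1 grid")
        prev_stop = 0
        n = len(ref)
        for label, start, stop in self.phases:
            if not (0 <= start < stop <= n):
                raise ValueError(f"phase {label!r} interval ({start}, {stop}) out of bounds")
            if start < prev_stop:
                raise ValueError(f"phase {label!r} overlaps the previous phase")
            prev_stop = stop

    def __len__(self) -> int:
        return len(self.y1)

    @property
    def dt(self) -> float:
        return self.y1.dt

    def channels(self) -> dict[str, TimeSeries]:
        out = {"y1": self.y1, "y2": self.y2, "W2": self.W2}
        if self.W1 is not None:
            out["W1"] = self.W1
        if self.Troom is not None:
            out["Troom"] = self.Troom
        return out

    def phase(self, label: str) -> tuple[int, int]:
        for lab, start, stop in self.phases:
            if lab == label:
                return start, stop
        raise KeyError(f"record has no phase {label!r}")


# ---------------------------------------------------------------------------
# Closed-form step response
# ---------------------------------------------------------------------------

def tf_step_response(
    cal: SensorCalibration,
    channel: str,
    amplitude: float,
    t: TimeSeries | np.ndarray,
) -> TimeSeries:
    """Closed-form response of one channel to a step ``amplitude`` (W) at t=0.

    For distinct poles::

        y(t) = K A [1 - c1 e^(-t/tau1) - c2 e^(-t/tau2)]
        c1 = (tau1 - tau*)/(tau1 - tau2),  c2 = (tau* - tau2)/(tau1 - tau2)

    so that ``y(0) = 0`` (strictly proper system) and ``y(inf) = K A``.  For a
    repeated pole ``tau1 = tau2 = tau`` the confluent form
    ``K A [1 - e^(-t/tau) (1 + (1 - tau*/tau) t/tau)]`` is used.

    Returns the response in the channel's output units (mV for TF1/TF2, K for
    TF3/TF4).
    """
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
    if not np.isfinite(amplitude):
        raise ValueError("step amplitude must be finite")
    grid = t if isinstance(t, TimeSeries) else TimeSeries(np.asarray(t, float), dt=1.0)
    tv = grid.t if isinstance(t, TimeSeries) else np.asarray(t, float)
    K, tstar = cal.gain(channel), cal.zero(channel)
    tau1, tau2 = cal.tau1, cal.tau2
    if np.isclose(tau1, tau2, rtol=1e-12, atol=0.0):
        tau = tau1
        y = K * amplitude * (1.0 - np.exp(-tv / tau) * (1.0 + (1.0 - tstar / tau) * tv / tau))
    else:
        c1 = (tau1 - tstar) / (tau1 - tau2)
        c2 = (tstar - tau2) / (tau1 - tau2)
        y = K * amplitude * (1.0 - c1 * np.exp(-tv / tau1) - c2 * np.exp(-tv / tau2))
    units = "mV" if channel in ("TF1", "TF2") else "K"
    dt = grid.dt if isinstance(t, TimeSeries) else (tv[1] - tv[0] if len(tv) > 1 else 1.0)
    t0 = grid.t0 if isinstance(t, TimeSeries) else tv[0]
    return TimeSeries(y, dt=dt, t0=t0, units=units)


# ---------------------------------------------------------------------------
# ZOH discrete simulation
# ---------------------------------------------------------------------------

_DTF_CACHE: dict = {}


def _discrete_tf(cal: SensorCalibration, channel: str, dt: float):
    """ZOH-discretized (b, a) polynomial pair of one channel (memoized)."""
    key = (
        cal.gain(channel), cal.zero(channel), cal.tau1, cal.tau2, channel, dt,
    )
    hit = _DTF_CACHE.get(key)
    if hit is not None:
        return hit
    num, den = cal.tf(channel)
    bz, az, _ = signal.cont2discrete((num, den), dt, method="zoh")
    out = np.atleast_1d(np.squeeze(bz)), np.atleast_1d(np.squeeze(az))
    if len(_DTF_CACHE) > 8192:
        _DTF_CACHE.clear()
    _DTF_CACHE[key] = out
    return out


def _lfilter_steady(b: np.ndarray, a: np.ndarray, u: np.ndarray, steady: bool) -> np.ndarray:
    """Filter ``u`` through (b, a); optionally start in steady state for u[0]."""
    if steady:
        zi = signal.lfilter_zi(b, a) * u[0]
        y, _ = signal.lfilter(b, a, u, zi=zi)
    else:
        y = signal.lfilter(b, a, u)
    return y


def simulate_outputs(
    cal: SensorCalibration,
    W1: TimeSeries | None,
    W2: TimeSeries | None,
    init: str = "steady",
    w2_bounds: tuple[float, float] | None = None,
) -> tuple[TimeSeries, TimeSeries]:
    """Simulate both sensor outputs for sampled inputs (delta form).

    The outputs solve the shared-denominator pair of second-order ODEs

    ``tau1 tau2 y1'' + (tau1+tau2) y1' + y1 = K1(tau1* W1' + W1) + K2(tau2* W2' + W2)``

    and the analogue for ``y2`` with ``K3, tau3*`` and ``K4, tau4*``.  Each
    channel is advanced with an exact zero-order-hold discretization (matrix
    exponential of the 2x2 companion form, via ``scipy.signal.cont2discrete``),
    treating the inputs as piecewise constant over each sampling interval; the
    numerator (zero) terms enter through the output matrix, so no numerical
    differentiation of the inputs is performed.

    Parameters
    ----------
    W1, W2 : TimeSeries or None
        Input powers in W or mW (delta form).  ``None`` stands for an
        identically zero input; at least one input must be given.
    init : {"steady", "rest"}
        ``steady`` starts each channel in the steady state matching its first
        input sample; ``rest`` starts from zero state (a step experiment).
    w2_bounds : (float, float), optional
        Saturation interval for the *absolute* thermostat power in W.  Samples
        where W2 leaves it are flagged (log warning + boolean mask in the
        returned series metadata); the dynamics are not clipped.

    Returns
    -------
    (y1, y2) : TimeSeries in mV and K (delta form).
    """
    if W1 is None and W2 is None:
        raise ValueError("at least one input series is required")
    ref = W1 if W1 is not None else W2
    if W1 is not None and W2 is not None and not W1.same_grid(W2):
        raise GridMismatchError("W1 and W2 are not on the same grid")
    if init not in ("steady", "rest"):
        raise ValueError("init must be 'steady' or 'rest'")
    dt = ref.dt
    n = len(ref)
    u1 = _as_watts(W1) if W1 is not None else np.zeros(n)
    u2 = _as_watts(W2) if W2 is not None else np.zeros(n)

    steady = init == "steady"
    y1 = np.zeros(n)
    y2 = np.zeros(n)
    for channel, u, out in (
        ("TF1", u1, y1), ("TF2", u2, y1), ("TF3", u1, y2), ("TF4", u2, y2),
    ):
        if not np.any(u) and not steady:
            continue
        b, a = _discrete_tf(cal, channel, dt)
        out += _lfilter_steady(b, a, u, steady)

    ts1 = TimeSeries(y1, dt=dt, t0=ref.t0, units="mV")
    ts2 = TimeSeries(y2, dt=dt, t0=ref.t0, units="K")
    if w2_bounds is not None and W2 is not None:
        lo, hi = w2_bounds
        mask = (u2 < lo) | (u2 > hi)
        if mask.any():
            logger.warning(
                "thermostat power leaves [%g, %g] W on %d samples (sensor saturation)",
                lo, hi, int(mask.sum()),
            )
        ts1.saturated = mask  # type: ignore[attr-defined]
        ts2.saturated = mask  # type: ignore[attr-defined]
    return ts1, ts2


def steady_state_outputs(cal: SensorCalibration, dW1: float, dW2: float) -> tuple[float, float]:
    """Steady-state output excesses for sustained input excesses (W).

    Returns ``(dy1, dy2) = (K1 dW1 + K2 dW2, K3 dW1 + K4 dW2)`` in (mV, K) —
    the sensitivity equations applied at one steady state.
    """
    return cal.K1 * dW1 + cal.K2 * dW2, cal.K3 * dW1 + cal.K4 * dW2


# ---------------------------------------------------------------------------
# Per-sample stepper (for feedback loops)
# ---------------------------------------------------------------------------

class SensorStepper:
    """Stateful one-sample-at-a-time simulator of the full 2x2 sensor.

    Holds one 2-dimensional companion-form state per input; both outputs are
    linear reads of the two states.  Used by the synthetic thermostat control
    loop, which must close feedback through ``y2`` each sample.
    """

    def __init__(self, cal: SensorCalibration, dt: float = 1.0):
        self.cal = cal
        self.dt = dt
        t1t2 = cal.tau1 * cal.tau2
        A = np.array([[0.0, 1.0], [-1.0 / t1t2, -(cal.tau1 + cal.tau2) / t1t2]])
        B = np.array([[0.0], [1.0]])
        Ad, Bd, *_ = signal.cont2discrete((A, B, np.eye(2), np.zeros((2, 1))), dt, method="zoh")
        self.Ad, self.Bd = Ad, Bd[:, 0]
        self._A = A
        # output rows: y = [b0, b1] @ x with b0 = K/(t1 t2), b1 = K tau*/(t1 t2)
        def row(channel):
            K, tstar = cal.gain(channel), cal.zero(channel)
            return np.array([K / t1t2, K * tstar / t1t2])
        self.C1, self.C2 = row("TF1"), row("TF2")
        self.C3, self.C4 = row("TF3"), row("TF4")
        self.x1 = np.zeros(2)
        self.x2 = np.zeros(2)

    def reset_steady(self, u1: float, u2: float) -> None:
        """Place both states at the steady state for constant inputs (W)."""
        x_unit = np.linalg.solve(-self._A, np.array([0.0, 1.0]))
        self.x1 = x_unit * u1
        self.x2 = x_unit * u2

    def outputs(self) -> tuple[float, float]:
        """Current (y1 mV, y2 K) before advancing."""
        y1 = self.C1 @ self.x1 + self.C2 @ self.x2
        y2 = self.C3 @ self.x1 + self.C4 @ self.x2
        return float(y1), float(y2)

    def advance(self, u1: float, u2: float) -> None:
        """Advance one sampling interval with inputs held constant (W)."""
        self.x1 = self.Ad @ self.x1 + self.Bd * u1
        self.x2 = self.Ad @ self.x2 + self.Bd * u2
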