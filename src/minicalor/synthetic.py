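"""Synthetic instrument: generates complete calibration and body measurement runs.

Every analysis stage in this package can be exercised without hardware: this
module emulates the minisensor (through :mod:`minicalor.core`), its PI(D)
thermostat regulation, the Joule calibration protocol and the three-phase
body-measurement protocol, with measurement noise at the amplitudes the
instrument exhibits in its steady states.

The generator's defaults ARE the study conditions: a 1 s sampling period, the
24→28→24 degC calibration program with a 300 mW, 5-minute Joule pulse, noise
half-amplitudes (0.2 mV on y1, 5 mK on y2, 0.1 mW on W1), a body surface at
≈32 degC and a biexponential body flux with ~3 s and ~70 s time constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bodyflux import ExponentialFluxModel, evaluate_flux
from .core import (
    MeasurementRecord,
    SensorCalibration,
    SensorStepper,
    TimeSeries,
)

TROOM_C = 24.7  # degC, constant emitted room-temperature channel


class UnstableLoopError(RuntimeError):
    """Raised when the simulated thermostat control loop diverges."""


# ---------------------------------------------------------------------------
# Protocol and noise descriptions
# ---------------------------------------------------------------------------

@dataclass
class ProtocolSchedule:
    """Thermostat setpoint program plus known power events.

    ``segments`` is a list of ``(setpoint degC, duration s)``; ``W1_events``
    lists Joule dissipations ``(start s, duration s, power W)`` applied on the
    calibration base; ``contact_window`` gives ``(start s, duration s)`` of
    skin contact for a body run.
    """

    segments: list[tuple[float, float]]
    W1_events: list[tuple[float, float, float]] = field(default_factory=list)
    contact_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one setpoint segment")
        for _, dur in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
        total = self.total_duration
        for start, dur, _ in self.W1_events:
            if dur <= 0 or start < 0 or start + dur > total:
                raise ValueError("W1 event outside the schedule span")
        if self.contact_window is not None:
            start, dur = self.contact_window
            if dur <= 0 or start < 0 or start + dur > total:
                raise ValueError("contact window outside the schedule span")

    @property
    def total_duration(self) -> float:
        return sum(dur for _, dur in self.segments)

    def setpoint_series(self, dt: float = 1.0) -> TimeSeries:
        """Per-sample programmed thermostat temperature (degC)."""
        n = int(round(self.total_duration / dt))
        t = dt * np.arange(n)
        out = np.empty(n)
        edge = 0.0
        for setpoint, dur in self.segments:
            out[(t >= edge) & (t < edge + dur)] = setpoint
            edge += dur
        return TimeSeries(out, dt=dt, units="degC")

    def w1_series(self, dt: float = 1.0) -> TimeSeries:
        """Per-sample known dissipated power (W) from the Joule events."""
        n = int(round(self.total_duration / dt))
        t = dt * np.arange(n)
        out = np.zeros(n)
        for start, dur, power in self.W1_events:
            out[(t >= start) & (t < start + dur)] += power
        return TimeSeries(out, dt=dt, units="W")

    @classmethod
    def calibration_default(cls) -> "ProtocolSchedule":
        """The standard calibration program.

        Thermostat at 24 degC to t=150 s, 28 degC to t=1050 s, back to 24 degC
        until t=1500 s; 300 mW dissipated on the calibration base from t=451 s
        for 5 minutes.
        """
        return cls(
            segments=[(24.0, 150.0), (28.0, 900.0), (24.0, 450.0)],
            W1_events=[(451.0, 300.0, 0.300)],
        )

    @classmethod
    def body_default(cls, tcal: float, phase_s: float = 300.0) -> "ProtocolSchedule":
        """Three equal phases (baseline / contact / return) at one setpoint."""
        return cls(
            segments=[(tcal, 3 * phase_s)],
            contact_window=(phase_s, phase_s),
        )

    def calibration_zones(self, dt: float = 1.0) -> list[tuple[str, int, int]]:
        """The five steady-state zones a–e of the calibration program.

        a: initial baseline; b: after the setpoint step, before the Joule
        pulse; c: during the pulse; d: after the pulse; e: final baseline.
        Requires exactly three segments and one Joule event.
        """
        if len(self.segments) != 3 or len(self.W1_events) != 1:
            raise ValueError("a–e zones are defined for the 3-segment, 1-pulse program")
        t1 = self.segments[0][1]
        t2 = t1 + self.segments[1][1]
        p0, pdur, _ = self.W1_events[0]
        p1 = p0 + pdur
        idx = lambda t: int(round(t / dt))
        return [
            ("a", 0, idx(t1)),
            ("b", idx(t1), idx(p0)),
            ("c", idx(p0), idx(p1)),
            ("d", idx(p1), idx(t2)),
            ("e", idx(t2), idx(self.total_duration)),
        ]


@dataclass
class NoiseSpec:
    """Measurement-noise description.

    Half-amplitudes are the peak excursions observed on the instrument's
    steady-state traces.  ``kind='smoothed'`` draws white Gaussian noise with
    sigma = half_amp/2 and applies a 5-sample moving average (band-limited,
    like the real traces); ``kind='uniform'`` draws U(-half, +half).  The
    ``drift`` option adds a slow sinusoid (amplitude mW, period s) to the body
    flux to emulate low-frequency physiological oscillation.
    """

    y1_half_amp: float = 0.2     # mV
    y2_half_amp: float = 5.0     # mK
    W1_half_amp: float = 0.1     # mW
    W2_half_amp: float = 10.0    # mW (used only when noise is injected on W2
                                 # directly; in closed loop the controller's
                                 # response to y2 noise produces the W2 ripple)
    kind: str = "smoothed"
    drift: tuple[float, float] | None = None  # (amplitude mW, period s)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.y1_half_amp, self.y2_half_amp, self.W1_half_amp, self.W2_half_amp) < 0:
            raise ValueError("noise half-amplitudes must be >= 0")
        if self.kind not in ("smoothed", "uniform"):
            raise ValueError("noise kind must be 'smoothed' or 'uniform'")

    def draw(self, rng: np.random.Generator, n: int, half_amp: float) -> np.ndarray:
        if half_amp == 0:
            return np.zeros(n)
        if self.kind == "uniform":
            return rng.uniform(-half_amp, half_amp, n)
        white = rng.normal(0.0, half_amp / 2.0, n + 4)
        return np.convolve(white, np.full(5, 0.2), mode="valid")

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        return cls(y1_half_amp=0.0, y2_half_amp=0.0, W1_half_amp=0.0, W2_half_amp=0.0)


# ---------------------------------------------------------------------------
# Body flux ground truth
# ---------------------------------------------------------------------------

@dataclass
class CouplingRule:
    """Linear thermostat-temperature coupling of the body flux ground truth.

    Encodes the steady-flux law ``A0 = (Tcore - Tcal)/R_T`` (W) together with
    a contact-discontinuity amplitude proportional to the skin/thermostat
    temperature gap, ``A1 = g1 (Tbody_surface - Tcal)``, and an adaptation
    amplitude on a straight line in Tcal.  Defaults reproduce the fitted
    coefficient-versus-temperature lines of a healthy adult hand series
    (A0 = 556.21 - 13.91 Tcal mW, A2 = 393.95 - 12.41 Tcal mW) with the
    canonical 3 s / 70 s time constants.
    """

    Tcore: float = 39.99          # degC; A0 vanishes at Tcal = Tcore
    R_T: float = 1000.0 / 13.91   # K/W total thermostat-to-core resistance
    g1: float = 90.49             # mW/K contact-term slope
    a2_intercept: float = 393.95  # mW
    a2_slope: float = -12.41      # mW/degC
    taus: tuple[float, float] = (3.0, 70.0)

    def flux_at(self, tcal: float, tbody_surface: float) -> ExponentialFluxModel:
        a0 = (self.Tcore - tcal) / self.R_T * 1000.0          # mW
        a1 = self.g1 * (tbody_surface - tcal)                  # mW
        a2 = self.a2_intercept + self.a2_slope * tcal          # mW
        return ExponentialFluxModel(
            A0=a0, terms=[(a1, self.taus[0]), (a2, self.taus[1])]
        )


@dataclass
class BodyModel:
    """Ground-truth body heat flux for synthetic body runs.

    Either a fixed :class:`ExponentialFluxModel` (one thermostat temperature)
    or a :class:`CouplingRule` evaluated at each requested Tcal.
    """

    Tbody_surface: float = 32.0
    flux: ExponentialFluxModel | None = None
    coupling: CouplingRule | None = None

    def __post_init__(self) -> None:
        if (self.flux is None) == (self.coupling is None):
            raise ValueError("give exactly one of flux or coupling")

    def flux_at(self, tcal: float) -> ExponentialFluxModel:
        if self.flux is not None:
            return self.flux
        return self.coupling.flux_at(tcal, self.Tbody_surface)


# ---------------------------------------------------------------------------
# Closed-loop thermostat simulation
# ---------------------------------------------------------------------------

#: default PI(D) gains: Kp W/K, Ki W/(K s), Kd W s/K.  Artifact tuning chosen
#: to settle a +4 K setpoint step within +-5 mK in under 300 s.
DEFAULT_PID_GAINS = (2.0, 0.05, 0.0)
DEFAULT_W2_BASE = 0.4   # W, absolute thermostat power at the initial setpoint
DEFAULT_W2_MAX = 1.0    # W, actuator ceiling


def _closed_loop(
    cal: SensorCalibration,
    setpoints_delta: np.ndarray,
    disturbance_w1: np.ndarray,
    y2_noise: np.ndarray,
    gains: tuple[float, float, float] = DEFAULT_PID_GAINS,
    bounds: tuple[float, float] = (0.0, DEFAULT_W2_MAX),
    w2_base: float = DEFAULT_W2_BASE,
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step the sensor + PID thermostat jointly, one sample at a time.

    All quantities are in delta form (W, K) relative to the initial steady
    state; ``w2_base`` only locates the actuator saturation interval.  The
    controller acts on the *measured* y2 (true + noise), so its output carries
    the characteristic ripple of the real W2 traces.

    Returns ``(w2_delta, y1_true, y2_true)`` arrays.
    """
    kp, ki, kd = gains
    if min(kp, ki, kd) < 0:
        raise ValueError("PID gains must be >= 0")
    n = len(setpoints_delta)
    lo, hi = bounds[0] - w2_base, bounds[1] - w2_base
    stepper = SensorStepper(cal, dt)
    stepper.reset_steady(disturbance_w1[0], 0.0)
    w2 = np.zeros(n)
    y1 = np.zeros(n)
    y2 = np.zeros(n)
    integ = 0.0
    e_prev = 0.0
    err_scale = max(1.0, np.max(np.abs(setpoints_delta)) if n else 1.0)
    for k in range(n):
        y1[k], y2[k] = stepper.outputs()
        e = setpoints_delta[k] - (y2[k] + y2_noise[k])
        if abs(e) > 50.0 * err_scale:
            raise UnstableLoopError(
                f"thermostat loop diverged at sample {k} with gains "
                f"(Kp={kp}, Ki={ki}, Kd={kd})"
            )
        u = kp * e + ki * integ + kd * (e - e_prev) / dt
        u_clamped = min(max(u, lo), hi)
        # anti-windup: integrate only when not pushing further into saturation
        if u == u_clamped or (u > hi and e < 0) or (u < lo and e > 0):
            integ += e * dt
        e_prev = e
        w2[k] = u_clamped
        stepper.advance(disturbance_w1[k], w2[k])
    return w2, y1, y2


def pid_thermostat(
    cal: SensorCalibration,
    setpoints: TimeSeries,
    disturbance_W1: TimeSeries | None = None,
    gains: tuple[float, float, float] = DEFAULT_PID_GAINS,
    bounds: tuple[float, float] = (0.0, DEFAULT_W2_MAX),
    w2_base: float = DEFAULT_W2_BASE,
) -> TimeSeries:
    """Simulate the thermostat regulation loop and return the W2 command (W).

    ``setpoints`` is the programmed thermostat temperature (degC, absolute);
    the initial setpoint defines the operating point, so the returned series
    is the absolute thermostat power ``w2_base + delta``.  ``disturbance_W1``
    is an exogenous power on the measurement face (W or mW).
    """
    sp = setpoints.values - setpoints.values[0]
    n = len(sp)
    dist = np.zeros(n)
    if disturbance_W1 is not None:
        if not setpoints.same_grid(disturbance_W1):
            raise ValueError("setpoints and disturbance must share the grid")
        dist = disturbance_W1.to("W").values if disturbance_W1.units else disturbance_W1.values
    w2, _, _ = _closed_loop(
        cal, sp, dist, np.zeros(n), gains=gains, bounds=bounds, w2_base=w2_base,
        dt=setpoints.dt,
    )
    return TimeSeries(w2 + w2_base, dt=setpoints.dt, t0=setpoints.t0, units="W")


# ---------------------------------------------------------------------------
# Record generators
# ---------------------------------------------------------------------------

def _assemble_record(
    cal,
    schedule,
    noise,
    rng,
    w1_true_W,
    *,
    include_w1: bool,
    phases,
    tcal,
    y1_drift: float,
    gains,
    meta,
) -> MeasurementRecord:
    dt = 1.0
    sp = schedule.setpoint_series(dt)
    sp_delta = sp.values - sp.values[0]
    n = len(sp)
    noise_y2_K = noise.draw(rng, n, noise.y2_half_amp) * 1e-3
    w2_delta, y1_true, y2_true = _closed_loop(
        cal, sp_delta, w1_true_W, noise_y2_K, gains=gains, dt=dt
    )
    t = dt * np.arange(n)
    y1_mV = y1_true + noise.draw(rng, n, noise.y1_half_amp) + y1_drift * t
    y2_C = sp.values[0] + y2_true + noise_y2_K  # record what the controller saw
    w2_mW = (w2_delta + DEFAULT_W2_BASE) * 1e3
    kwargs = {}
    if include_w1:
        kwargs["W1"] = TimeSeries(
            w1_true_W * 1e3 + noise.draw(rng, n, noise.W1_half_amp),
            dt=dt, units="mW",
        )
    return MeasurementRecord(
        y1=TimeSeries(y1_mV, dt=dt, units="mV"),
        y2=TimeSeries(y2_C, dt=dt, units="degC"),
        W2=TimeSeries(w2_mW, dt=dt, units="mW"),
        Troom=TimeSeries(np.full(n, TROOM_C), dt=dt, units="degC"),
        phases=phases,
        Tcal=tcal,
        meta=meta,
        **kwargs,
    )


def generate_calibration_run(
    cal: SensorCalibration,
    schedule: ProtocolSchedule | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    gains: tuple[float, float, float] = DEFAULT_PID_GAINS,
    y1_drift: float = 0.0,
) -> MeasurementRecord:
    """Generate one complete calibration run.

    Parameters
    ----------
    cal : SensorCalibration
        Ground-truth sensor; stored in ``record.meta['truth']``.
    schedule : ProtocolSchedule, optional
        Defaults to the standard 1500 s, two-setpoint, one-pulse program.
    noise : NoiseSpec, optional
        Defaults to the instrument's stated amplitudes; pass
        ``NoiseSpec.noiseless()`` for an ideal run.
    seed : int, optional
        Overrides ``noise.seed``; identical seeds give bit-identical records.
    y1_drift : float
        Linear baseline drift injected on y1, mV/s (0 = none).
    """
    schedule = schedule or ProtocolSchedule.calibration_default()
    if len(schedule.segments) < 2 or not schedule.W1_events:
        raise ValueError("calibration schedule needs >= 2 setpoints and >= 1 Joule event")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    w1 = schedule.w1_series()
    phases = schedule.calibration_zones()
    meta = {"truth": cal.as_dict(), "kind": "calibration",
            "schedule": {"segments": schedule.segments, "W1_events": schedule.W1_events}}
    return _assemble_record(
        cal, schedule, noise, rng, w1.values,
        include_w1=True, phases=phases,
        tcal=[s for s, _ in schedule.segments], y1_drift=y1_drift,
        gains=gains, meta=meta,
    )


def generate_body_run(
    cal: SensorCalibration,
    body: BodyModel,
    Tcal: float,
    schedule: ProtocolSchedule | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    gains: tuple[float, float, float] = DEFAULT_PID_GAINS,
) -> MeasurementRecord:
    """Generate one three-phase body measurement at thermostat temperature Tcal.

    The body flux acts as the W1 input during the contact window only (zero
    outside); the thermostat loop compensates, producing the characteristic
    W2/y1 oscillation whose size grows with \\|Tcal - Tbody\\|.  The record
    omits the W1 channel (unknown in a real body run); the generating flux
    model is stored in ``record.meta['truth']``.
    """
    schedule = schedule or ProtocolSchedule.body_default(Tcal)
    if schedule.contact_window is None:
        raise ValueError("body schedule needs a contact window")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    dt = 1.0
    n = int(round(schedule.total_duration / dt))
    t = dt * np.arange(n)
    c0, cdur = schedule.contact_window
    flux = body.flux_at(Tcal)
    flux = ExponentialFluxModel(A0=flux.A0, terms=flux.terms, t_origin=c0)
    grid = TimeSeries(np.zeros(n), dt=dt, units="mW")
    w1_mW = evaluate_flux(flux, grid, t_end=c0 + cdur).values
    if noise.drift is not None:
        amp, period = noise.drift
        in_contact = (t >= c0) & (t < c0 + cdur)
        w1_mW = w1_mW + np.where(
            in_contact, amp * np.sin(2 * np.pi * (t - c0) / period), 0.0
        )
    i0, i1 = int(round(c0 / dt)), int(round((c0 + cdur) / dt))
    phases = [("baseline", 0, i0), ("contact", i0, i1), ("return", i1, n)]
    meta = {
        "truth": {
            "A0": flux.A0, "terms": list(flux.terms), "t_origin": flux.t_origin,
            "Tbody_surface": body.Tbody_surface, "Tcal": Tcal,
        },
        "kind": "body",
    }
    return _assemble_record(
        cal, schedule, noise, rng, w1_mW * 1e-3,
        include_w1=False, phases=phases, tcal=Tcal, y1_drift=0.0,
        gains=gains, meta=meta,
    )
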