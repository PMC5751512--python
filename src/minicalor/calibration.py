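"""Sensor calibration: from a recorded Joule-protocol run to a full parameter set.

The calibration chain has four stages, mirroring how the instrument is
calibrated in practice:

1. **baseline correction** — remove the pre-run baseline (and any linear
   drift between the opening and closing quiescent windows) from every
   channel, leaving the record in delta form;
2. **steady-state extraction** — locate the five quiescent zones a–e of the
   protocol and estimate each channel's steady value in each zone;
3. **sensitivity solving** — the steady values obey the linear sensitivity
   equations ``K1 dW1 + K2 dW2 = dy1`` and ``K3 dW1 + K4 dW2 = dy2``; with
   several zones this is an overdetermined system solved by least squares;
4. **dynamics fitting** — with gains fixed, the shared poles and per-channel
   zeros are found by a Nelder–Mead simplex search minimizing the RMS
   mismatch between the measured and simulated transients of both channels.

The public surface is the :class:`SensorDynamicsModel` /
:class:`CalibrationResult` pair; the individual stages are importable
functions so each can be tested and reused on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import (
    MeasurementRecord,
    SensorCalibration,
    TimeSeries,
    simulate_outputs,
)
from .synthetic import ProtocolSchedule

#: stationarity thresholds: within-zone standard deviation above these flags
#: the zone (instrument steady-state ripple is well below them)
STATIONARITY_THRESHOLDS = {"y1": 0.2, "y2": 5e-3, "W2": 20e-3}  # mV, K, W

#: fixed jitter seed for randomized simplex restarts
RESTART_SEED = 20171128

_ACTIVE_LABELS = ("c", "contact")


class ZoneError(ValueError):
    pass


class SingularProtocolError(ValueError):
    pass


class FitConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# 1. Baseline correction
# ---------------------------------------------------------------------------

def correct_baseline(
    rec: MeasurementRecord,
    pre_window: tuple[int, int],
    post_window: tuple[int, int] | None = None,
    channels: tuple[str, ...] = ("y1", "y2", "W1", "W2"),
) -> MeasurementRecord:
    """Return the record in delta form.

    For each corrected channel, the straight line joining the pre-window mean
    to the post-window mean (placed at the window centres) is subtracted —
    removing both the baseline level and any linear drift.  With no
    ``post_window`` only the pre-window mean is subtracted.  Windows are
    half-open index intervals and must lie in quiescent phases.
    """
    n = len(rec)
    windows = [pre_window] + ([post_window] if post_window is not None else [])
    for w in windows:
        a, b = w
        if not (0 <= a < b <= n):
            raise ValueError(f"window {w} out of bounds")
        if b - a < 10:
            raise ValueError(f"baseline window {w} shorter than 10 samples")
        for label, p0, p1 in rec.phases:
            if label in _ACTIVE_LABELS and a < p1 and p0 < b:
                raise ValueError(f"baseline window {w} overlaps active phase {label!r}")

    def corrected(ts: TimeSeries) -> TimeSeries:
        v = ts.values
        a0, a1 = pre_window
        pre_mean = v[a0:a1].mean()
        if post_window is None:
            out = v - pre_mean
        else:
            b0, b1 = post_window
            post_mean = v[b0:b1].mean()
            tc_pre = 0.5 * (a0 + a1 - 1)
            tc_post = 0.5 * (b0 + b1 - 1)
            k = np.arange(n)
            out = v - (pre_mean + (post_mean - pre_mean) * (k - tc_pre) / (tc_post - tc_pre))
        units = "K" if ts.units in ("degC", "°C", "C") else ts.units
        return TimeSeries(out, dt=ts.dt, t0=ts.t0, units=units)

    new = {}
    for name, ts in rec.channels().items():
        if name == "Troom":
            continue
        new[name] = corrected(ts) if name in channels else ts.copy()
    return MeasurementRecord(
        y1=new["y1"], y2=new["y2"], W2=new["W2"], W1=new.get("W1"),
        Troom=rec.Troom.copy() if rec.Troom is not None else None,
        phases=list(rec.phases), Tcal=rec.Tcal, delta=True, meta=dict(rec.meta),
    )


def auto_delta(
    rec: MeasurementRecord,
    margin: int = 40,
    width: int = 100,
    drift: bool | None = None,
) -> MeasurementRecord:
    """Baseline-correct using the record's own quiescent stretches.

    Pre-window: the first phase minus an initial ``margin``.  With
    ``drift=True`` the last ``width`` samples anchor a drift line as well.
    By default drift removal is applied to calibration-type records (known W1
    channel, long closing baseline) but not to three-phase body runs, whose
    return baseline is approached only asymptotically and would bias an
    end-anchored line.
    """
    if rec.delta:
        return rec
    if drift is None:
        drift = rec.W1 is not None
    if rec.phases:
        _, p0, p1 = rec.phases[0]
        pre = (min(margin, max(p1 - 10, 0)), p1)
    else:
        pre = (margin, margin + width)
    post = (len(rec) - width, len(rec)) if drift else None
    return correct_baseline(rec, pre, post)


# ---------------------------------------------------------------------------
# 2. Steady-state extraction
# ---------------------------------------------------------------------------

@dataclass
class SteadyZone:
    label: str
    start: int
    stop: int
    dy1: float          # mV
    dy2: float          # K
    dW1: float          # W (known input)
    dW2: float          # W (measured)
    flagged: bool = False
    note: str = ""


@dataclass
class SteadyStateSet:
    zones: list[SteadyZone]
    provenance: str = ""

    def design(self) -> np.ndarray:
        return np.array([[z.dW1, z.dW2] for z in self.zones])

    def __iter__(self):
        return iter(self.zones)

    def __len__(self) -> int:
        return len(self.zones)


def _steady_value(values: np.ndarray, dt: float, settle: int, method: str) -> float:
    """Estimate the steady level a zone approaches.

    ``mean`` averages the post-settle tail.  ``exp`` fits
    ``a + b exp(-t/tau)`` over the zone (minus a short head) and reports the
    asymptote ``a`` — this removes the residual-transient bias a plain tail
    mean carries when the zone is only a few time constants long.
    """
    tail = values[settle:]
    tail_mean = float(tail.mean())
    if method == "mean":
        return tail_mean
    head = min(30, len(values) // 4)
    seg = values[head:]
    t = dt * np.arange(len(seg))
    b0 = float(seg[0] - tail_mean)
    if abs(b0) < 1e-12:
        return tail_mean
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, b, tau: a + b * np.exp(-tt / tau),
            t, seg, p0=(tail_mean, b0, 80.0),
            bounds=([-np.inf, -np.inf, 2.0], [np.inf, np.inf, 500.0]),
            maxfev=2000,
        )
        return float(popt[0])
    except RuntimeError:
        return tail_mean


def extract_steady_states(
    rec: MeasurementRecord,
    protocol: ProtocolSchedule | list[tuple[str, int, int]] | None = None,
    settle_multiplier: float = 1.2,
    tau_rough: float = 100.0,
    method: str = "exp",
    thresholds: dict | None = None,
) -> SteadyStateSet:
    """Estimate per-zone steady values of a delta-form record.

    Zones come from the protocol schedule (the a–e zones of the calibration
    program), an explicit ``(label, start, stop)`` list, or the record's own
    phase markers.  In each zone the first ``settle_multiplier * tau_rough``
    seconds are treated as transient; the steady level of each channel is then
    estimated (see :func:`_steady_value`).  Zones whose post-settle standard
    deviation exceeds the stationarity thresholds are flagged.
    """
    if not rec.delta:
        raise ValueError("extract_steady_states needs a delta-form record")
    if protocol is None:
        zones_idx = rec.phases
    elif isinstance(protocol, ProtocolSchedule):
        zones_idx = protocol.calibration_zones(rec.dt)
    else:
        zones_idx = protocol
    if not zones_idx:
        raise ZoneError("no zones available")
    thresholds = {**STATIONARITY_THRESHOLDS, **(thresholds or {})}
    settle = int(round(settle_multiplier * tau_rough / rec.dt))

    w1 = rec.W1.to("W").values if rec.W1 is not None else np.zeros(len(rec))
    w2 = rec.W2.to("W").values
    y1 = rec.y1.values
    y2 = rec.y2.values  # K in delta form

    zones: list[SteadyZone] = []
    n_flagged = 0
    for label, start, stop in zones_idx:
        if stop - start <= settle:
            raise ZoneError(
                f"zone {label!r} ({stop - start} samples) shorter than the "
                f"settle cut ({settle} samples)"
            )
        sl = slice(start, stop)
        dy1 = _steady_value(y1[sl], rec.dt, settle, method)
        dy2 = _steady_value(y2[sl], rec.dt, settle, method)
        dw2 = _steady_value(w2[sl], rec.dt, settle, method)
        dw1 = float(w1[sl][settle:].mean())  # known step input: plain mean
        flagged = False
        notes = []
        for name, series, thr in (
            ("y1", y1, thresholds["y1"]), ("y2", y2, thresholds["y2"]),
            ("W2", w2, thresholds["W2"]),
        ):
            sd = float(series[sl][settle:].std())
            if sd > thr:
                flagged = True
                notes.append(f"{name} std {sd:.3g} > {thr:g}")
        n_flagged += flagged
        zones.append(SteadyZone(label, start, stop, dy1, dy2, dw1, dw2,
                                flagged=flagged, note="; ".join(notes)))
    if n_flagged == len(zones):
        raise ZoneError("every zone failed the stationarity thresholds")
    return SteadyStateSet(zones=zones, provenance=str(rec.meta.get("kind", "")))


# ---------------------------------------------------------------------------
# 3. Sensitivities
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    K1: float
    K2: float
    K3: float
    K4: float
    se: dict[str, float]
    residuals_y1: np.ndarray    # mV, per zone
    residuals_y2: np.ndarray    # K, per zone

    @property
    def gains(self) -> tuple[float, float, float, float]:
        return self.K1, self.K2, self.K3, self.K4


def solve_sensitivities(ss: SteadyStateSet) -> SensitivityResult:
    """Least-squares gains from the steady-state sensitivity equations.

    The (K1, K2) and (K3, K4) rows are solved independently against dy1 (mV)
    and dy2 (K) across all zones.  Requires at least two zones with linearly
    independent (dW1, dW2); otherwise the protocol geometry is singular.
    """
    X = ss.design()
    if len(ss) < 2:
        raise SingularProtocolError("need at least two steady-state zones")
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] <= 1e-10 * max(sv[0], 1e-30):
        raise SingularProtocolError(
            "steady-state zones are proportional in (dW1, dW2): the protocol "
            "cannot separate the two inputs "
            f"(design rows {X.tolist()})"
        )
    dy1 = np.array([z.dy1 for z in ss.zones])
    dy2 = np.array([z.dy2 for z in ss.zones])
    XtXinv = np.linalg.inv(X.T @ X)
    se = {}
    out = []
    for name_pair, target in ((("K1", "K2"), dy1), (("K3", "K4"), dy2)):
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)
        resid = target - X @ beta
        dof = max(len(ss) - 2, 1)
        sigma2 = float(resid @ resid) / dof
        for name, var in zip(name_pair, np.diag(XtXinv)):
            se[name] = float(np.sqrt(sigma2 * var))
        out.append((beta, resid))
    (k12, r1), (k34, r2) = out
    return SensitivityResult(
        K1=float(k12[0]), K2=float(k12[1]), K3=float(k34[0]), K4=float(k34[1]),
        se=se, residuals_y1=r1, residuals_y2=r2,
    )


# ---------------------------------------------------------------------------
# 4. Dynamics fit
# ---------------------------------------------------------------------------

@dataclass
class OptimizerOptions:
    fatol: float = 1e-10
    xatol: float = 1e-6
    maxfev: int = 5000
    n_restarts: int = 3
    restart_scale: float = 0.05
    seed: int = RESTART_SEED


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _inv_softplus(x: float) -> float:
    if x < 1e-3:
        return -10.0
    return float(x + np.log(-np.expm1(-x)))


def _params_to_taus(p: np.ndarray) -> tuple[float, float, list[float]]:
    tau1, tau2 = np.exp(p[0]), np.exp(p[1])
    if tau1 < tau2:                      # slow pole first, by convention
        tau1, tau2 = tau2, tau1
    zeros = _softplus(p[2:6])
    zeros = [0.0 if z < 1e-3 else float(z) for z in zeros]
    return float(tau1), float(tau2), zeros


@dataclass
class _Trace:
    """Objective values at accepted simplex iterations (best vertex)."""
    values: list[float] = field(default_factory=list)


def _nm_fit(objective, x0: np.ndarray, opts: OptimizerOptions):
    """Nelder–Mead with seeded restart jitter; returns (x, f, trace, n_eval)."""
    n_eval = 0
    cache: dict[bytes, float] = {}

    def wrapped(x):
        nonlocal n_eval
        n_eval += 1
        f = objective(x)
        if not np.isfinite(f) or f < 0:
            raise FitConvergenceError(f"objective returned {f} at {x}")
        cache[np.asarray(x).tobytes()] = f
        return f

    trace = _Trace()

    def cb(xk):
        f = cache.get(np.asarray(xk).tobytes())
        if f is None:
            f = wrapped(xk)
        trace.values.append(f)

    rng = np.random.default_rng(opts.seed)
    best_x, best_f = None, np.inf
    start = np.asarray(x0, float)
    for attempt in range(opts.n_restarts + 1):
        res = optimize.minimize(
            wrapped, start, method="Nelder-Mead", callback=cb,
            options={"fatol": opts.fatol, "xatol": opts.xatol,
                     "maxfev": opts.maxfev, "adaptive": True},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
        if best_f < 1e-8:
            break
        start = best_x + rng.normal(0.0, opts.restart_scale, size=len(best_x))
    if best_x is None:
        raise FitConvergenceError("simplex search failed")
    return best_x, best_f, trace, n_eval


def fit_dynamics(
    rec: MeasurementRecord,
    gains: tuple[float, float, float, float],
    init_guess: tuple[float, ...] | None = None,
    opts: OptimizerOptions | None = None,
    mode: str = "joint",
    weights: tuple[float, float] = (0.2, 5e-3),
) -> tuple[SensorCalibration, float, float, _Trace, int]:
    """Fit the shared poles and the four zeros to both measured transients.

    With ``mode='joint'`` (default) the objective is the noise-normalized sum
    ``sigma_y1/0.2 mV + sigma_y2/5 mK``, coupling the channels through the
    shared poles; ``mode='y1'``/``mode='y2'`` fit a single channel.  Time
    constants are optimized as log(tau) (poles) and softplus(z) with an
    exact-zero snap below 1e-3 s (zeros).  Returns the fitted calibration,
    per-channel RMS errors (``sigma_y1`` mV, ``sigma_y2`` mK), the optimizer
    trace and the evaluation count.
    """
    if not rec.delta:
        raise ValueError("fit_dynamics needs a delta-form record")
    if rec.W1 is None:
        raise ValueError("calibration record must carry the known W1 channel")
    opts = opts or OptimizerOptions()
    K1, K2, K3, K4 = gains
    y1 = rec.y1.values
    y2 = rec.y2.values       # K
    n = len(rec)

    def build(tau1, tau2, zeros) -> SensorCalibration:
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # sign warnings during the search
            return SensorCalibration(
                K1=K1, K2=K2, K3=K3, K4=K4, tau1=tau1, tau2=tau2,
                tau1_star=zeros[0], tau2_star=zeros[1],
                tau3_star=zeros[2], tau4_star=zeros[3],
            )

    def sigmas(cal: SensorCalibration) -> tuple[float, float]:
        s1, s2 = simulate_outputs(cal, rec.W1, rec.W2, init="steady")
        sig1 = float(np.sqrt(np.mean((y1 - s1.values) ** 2)))
        sig2 = float(np.sqrt(np.mean((y2 - s2.values) ** 2)))
        return sig1, sig2

    w1, w2 = weights

    def objective(p):
        tau1, tau2, zeros = _params_to_taus(p)
        cal = build(tau1, tau2, zeros)
        sig1, sig2 = sigmas(cal)
        if mode == "y1":
            return sig1 / w1
        if mode == "y2":
            return sig2 / w2
        return sig1 / w1 + sig2 / w2

    if init_guess is None:
        init_guess = (50.0, 5.0, 10.0, 10.0, 10.0, 10.0)
    t1, t2 = init_guess[0], init_guess[1]
    zs = init_guess[2:6] if len(init_guess) >= 6 else (10.0,) * 4
    x0 = np.array(
        [np.log(t1), np.log(t2)] + [_inv_softplus(z) for z in zs]
    )
    x, _, trace, n_eval = _nm_fit(objective, x0, opts)
    tau1, tau2, zeros = _params_to_taus(x)
    cal = build(tau1, tau2, zeros)
    sig1, sig2 = sigmas(cal)
    return cal, sig1, sig2 * 1e3, trace, n_eval


def _pole_basis(taus: tuple[float, float], u: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Filter an input through 1/den and s/den for the shared pole pair.

    Any channel output is then ``K * base + K tau* * deriv``: for fixed poles
    the whole gain/zero set is linear in the data.
    """
    from scipy import signal as _sig

    tau1, tau2 = taus
    den = np.array([tau1 * tau2, tau1 + tau2, 1.0])
    cols = []
    for num in (np.array([1.0]), np.array([1.0, 0.0])):
        b, a, _ = _sig.cont2discrete((num, den), dt, method="zoh")
        b, a = np.atleast_1d(np.squeeze(b)), np.atleast_1d(np.squeeze(a))
        zi = _sig.lfilter_zi(b, a) * u[0]
        y, _ = _sig.lfilter(b, a, u, zi=zi)
        cols.append(y)
    return cols[0], cols[1]


def fit_dynamics_varpro(
    rec: MeasurementRecord,
    init_taus: tuple[float, float] = (50.0, 5.0),
    opts: OptimizerOptions | None = None,
    weights: tuple[float, float] = (0.2, 5e-3),
) -> tuple[SensorCalibration, float, float, _Trace, int]:
    """Fit all ten sensor parameters by variable projection.

    The simplex searches only the two shared poles (log scale); at each
    candidate pole pair the four gains and four zeros follow from two exact
    linear least-squares solves (one per output channel) on the full
    transient, because the numerator coefficients ``K_i`` and ``K_i tau_i*``
    enter the outputs linearly.  This uses every sample of the record for the
    gains as well, avoiding the residual-transient bias that finite steady
    zones impose on a steady-state-only estimate.

    Four nuisance regressors join the design per output: a constant and a
    linear ramp (window-mean baseline correction leaves small
    channel-inconsistent offsets, because the thermostat-power ripple is
    strongly autocorrelated and a finite baseline window misplaces the W2
    reference by a few mW), plus the two homogeneous solutions
    ``exp(-t/tau1)`` and ``exp(-t/tau2)``, which absorb the initial-state
    error a noisy first input sample would otherwise inject as a slow decay.
    """
    if not rec.delta:
        raise ValueError("fit_dynamics_varpro needs a delta-form record")
    if rec.W1 is None:
        raise ValueError("calibration record must carry the known W1 channel")
    opts = opts or OptimizerOptions()
    u1 = rec.W1.to("W").values
    u2 = rec.W2.to("W").values
    y1 = rec.y1.values
    y2 = rec.y2.values
    dt = rec.dt
    w1, w2 = weights

    n = len(y1)
    ramp = (np.arange(n) - (n - 1) / 2) / n

    def solve(logtaus):
        tau1, tau2 = np.exp(logtaus)
        if tau1 < tau2:
            tau1, tau2 = tau2, tau1
        base1, der1 = _pole_basis((tau1, tau2), u1, dt)
        base2, der2 = _pole_basis((tau1, tau2), u2, dt)
        tv = dt * np.arange(n)
        M = np.column_stack([
            base1, der1, base2, der2, np.ones(n), ramp,
            np.exp(-tv / tau1), np.exp(-tv / tau2),
        ])
        c_y1, *_ = np.linalg.lstsq(M, y1, rcond=None)
        c_y2, *_ = np.linalg.lstsq(M, y2, rcond=None)
        sig1 = float(np.sqrt(np.mean((y1 - M @ c_y1) ** 2)))
        sig2 = float(np.sqrt(np.mean((y2 - M @ c_y2) ** 2)))
        return (tau1, tau2), (c_y1, c_y2), (sig1, sig2)

    def objective(logtaus):
        _, _, (sig1, sig2) = solve(logtaus)
        return sig1 / w1 + sig2 / w2

    x0 = np.log(np.asarray(init_taus, float))
    x, _, trace, n_eval = _nm_fit(objective, x0, opts)
    (tau1, tau2), (c_y1, c_y2), (sig1, sig2) = solve(x)

    def unpack(c):
        (ka, ca, kb, cb) = c[:4]
        za = ca / ka if abs(ka) > 1e-12 else 0.0
        zb = cb / kb if abs(kb) > 1e-12 else 0.0
        return float(ka), float(kb), float(max(za, 0.0)), float(max(zb, 0.0))

    K1, K2, z1, z2 = unpack(c_y1)
    K3, K4, z3, z4 = unpack(c_y2)
    snap = lambda z: 0.0 if z < 1e-3 else z
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        cal = SensorCalibration(
            K1=K1, K2=K2, K3=K3, K4=K4, tau1=tau1, tau2=tau2,
            tau1_star=snap(z1), tau2_star=snap(z2),
            tau3_star=snap(z3), tau4_star=snap(z4),
        )
    return cal, sig1, sig2 * 1e3, trace, n_eval


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Fitted sensor calibration with its diagnostics.

    ``sigma_y1`` (mV) and ``sigma_y2`` (mK) are the per-channel RMS errors of
    the final simultaneous fit; ``sensitivities.se`` carries the least-squares
    standard errors of the gains (they describe the steady-state solve only,
    not run-to-run repeatability).
    """

    calibration: SensorCalibration
    sensitivities: SensitivityResult
    steady_states: SteadyStateSet
    sigma_y1: float          # mV
    sigma_y2: float          # mK
    n_eval: int
    trace: _Trace
    record: MeasurementRecord  # delta form

    def predict(self) -> tuple[TimeSeries, TimeSeries]:
        """Reconstructed (delta y1, delta y2) from the fitted model."""
        return simulate_outputs(self.calibration, self.record.W1,
                                self.record.W2, init="steady")

    def summary(self) -> str:
        c, se = self.calibration, self.sensitivities.se
        rows = [
            ("K1", c.K1, "mV/W", se.get("K1")), ("K2", c.K2, "mV/W", se.get("K2")),
            ("K3", c.K3, "K/W", se.get("K3")), ("K4", c.K4, "K/W", se.get("K4")),
            ("tau1", c.tau1, "s", None), ("tau2", c.tau2, "s", None),
            ("tau1*", c.tau1_star, "s", None), ("tau2*", c.tau2_star, "s", None),
            ("tau3*", c.tau3_star, "s", None), ("tau4*", c.tau4_star, "s", None),
        ]
        lines = [
            "Sensor calibration fit",
            "======================",
            f"  record length  : {len(self.record)} samples",
            f"  zones used     : {''.join(z.label for z in self.steady_states)}",
            "",
            "  parameter      value      (LS s.e.)",
            "  ---------  -----------  -----------",
        ]
        for name, val, unit, s in rows:
            sestr = f"+- {s:.2f}" if s is not None else ""
            lines.append(f"  {name:<9} {val:9.3f} {unit:<5} {sestr}")
        lines += [
            "",
            f"  sigma_y1 = {self.sigma_y1:.4f} mV   sigma_y2 = {self.sigma_y2:.3f} mK",
            f"  simplex evaluations: {self.n_eval}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured vs reconstructed transients (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
        p1, p2 = self.predict()
        t = self.record.y1.t
        ax[0].plot(t, self.record.y1.values, label="measured", lw=0.8)
        ax[0].plot(t, p1.values, label="model", lw=0.8)
        ax[0].set_ylabel("delta y1 / mV")
        ax[0].legend()
        ax[1].plot(t, self.record.y2.values * 1e3, lw=0.8)
        ax[1].plot(t, p2.values * 1e3, lw=0.8)
        ax[1].set_ylabel("delta y2 / mK")
        ax[1].set_xlabel("t / s")
        return ax


class SensorDynamicsModel:
    """Calibration model: estimate the sensor parameter set from one run.

    Parameters
    ----------
    record : MeasurementRecord
        A calibration run (raw or delta form) carrying the known W1 channel.
    schedule : ProtocolSchedule, optional
        The programmed protocol; defaults to the standard two-setpoint,
        one-pulse program, which also defines the steady zones a–e.
    """

    def __init__(self, record: MeasurementRecord, schedule: ProtocolSchedule | None = None):
        self.schedule = schedule or ProtocolSchedule.calibration_default()
        self.record = record if record.delta else auto_delta(record)

    def fit(
        self,
        method: str = "varpro",
        init_guess: tuple[float, ...] | None = None,
        opts: OptimizerOptions | None = None,
        mode: str = "joint",
        settle_multiplier: float = 1.2,
        tau_rough: float = 100.0,
        zone_method: str = "exp",
    ) -> CalibrationResult:
        """Calibrate the sensor.

        ``method='varpro'`` (default) refines gains and zeros jointly with
        the poles on the full transient (see :func:`fit_dynamics_varpro`);
        the steady-state solve still runs and is reported as a diagnostic.
        ``method='staged'`` keeps the gains fixed at the steady-state
        estimates and fits only the time constants (:func:`fit_dynamics`).
        """
        ss = extract_steady_states(
            self.record, self.schedule,
            settle_multiplier=settle_multiplier, tau_rough=tau_rough,
            method=zone_method,
        )
        sens = solve_sensitivities(ss)
        if method == "varpro":
            init_taus = (init_guess[0], init_guess[1]) if init_guess else (50.0, 5.0)
            cal, sig1, sig2, trace, n_eval = fit_dynamics_varpro(
                self.record, init_taus=init_taus, opts=opts,
            )
        elif method == "staged":
            cal, sig1, sig2, trace, n_eval = fit_dynamics(
                self.record, sens.gains, init_guess=init_guess, opts=opts, mode=mode,
            )
        else:
            raise ValueError("method must be 'varpro' or 'staged'")
        cal.label = str(self.record.meta.get("truth", {}).get("label", "")) or "fitted"
        return CalibrationResult(
            calibration=cal, sensitivities=sens, steady_states=ss,
            sigma_y1=sig1, sigma_y2=sig2, n_eval=n_eval, trace=trace,
            record=self.record,
        )
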