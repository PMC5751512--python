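"""Body heat-flux representation and recovery by inverse fitting.

The heat power a patch of skin pushes through the sensor during a contact
measurement is represented as a constant plus a sum of decaying exponentials::

    W1(t) = A0 + sum_i Ai exp(-(t - t_origin)/tau_i)

``A0`` is the steady-state flux through the 4 cm^2 contact area; in practice
two exponential terms suffice — a fast (~3 s) term produced by the thermal
discontinuity when the sensor leaves its base and touches the skin, and a
slow (~70 s) term tracking the body's adaptation to the contact.

Recovery inverts the sensor: candidate fluxes are pushed through the
calibrated two-pole/one-zero channel model together with the measured
thermostat power ``W2(t)``, and the amplitudes/time constants are chosen to
minimize the normalized RMS error (in %) between the measured and
reconstructed calorimetric signals.  Because the sensor model is linear in
the flux, amplitudes are separable: for given time constants they solve a
linear least-squares problem exactly (variable projection); only the time
constants require a simplex search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import (
    GridMismatchError,
    MeasurementRecord,
    SensorCalibration,
    TimeSeries,
    simulate_outputs,
)

MAX_TERMS = 4  # more exponentials are unidentifiable at the instrument's noise
MIN_WINDOW_S = 60.0


class FluxFitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# The flux model
# ---------------------------------------------------------------------------

@dataclass
class ExponentialFluxModel:
    """``W1(t) = A0 + sum Ai exp(-(t - t_origin)/tau_i)``, amplitudes in mW.

    ``terms`` is a list of ``(Ai mW, tau_i s)``; time constants are kept in
    strictly increasing order (canonical form).  Zero terms describe a pure
    Heaviside-type flux.  Amplitudes are unconstrained in sign: above the
    body surface temperature the contact term is negative.
    """

    A0: float
    terms: list[tuple[float, float]] = field(default_factory=list)
    t_origin: float = 0.0

    def __post_init__(self) -> None:
        taus = [tau for _, tau in self.terms]
        if any(tau <= 0 for tau in taus):
            raise ValueError(f"time constants must be positive, got {taus}")
        if len(set(taus)) != len(taus):
            raise ValueError("time constants must be distinct")
        self.terms = sorted(((float(a), float(tau)) for a, tau in self.terms),
                            key=lambda at: at[1])

    @property
    def taus(self) -> list[float]:
        return [tau for _, tau in self.terms]

    @property
    def amplitudes(self) -> list[float]:
        return [a for a, _ in self.terms]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the flux (mW) at absolute times ``t >= t_origin``."""
        trel = np.asarray(t, float) - self.t_origin
        out = np.full(trel.shape, float(self.A0))
        for a, tau in self.terms:
            out += a * np.exp(-trel / tau)
        return out

    def derivative(self, t: np.ndarray) -> np.ndarray:
        """Analytic dW1/dt (mW/s) at absolute times."""
        trel = np.asarray(t, float) - self.t_origin
        out = np.zeros(trel.shape)
        for a, tau in self.terms:
            out += -(a / tau) * np.exp(-trel / tau)
        return out


def evaluate_flux(
    m: ExponentialFluxModel,
    t: TimeSeries | np.ndarray,
    t_end: float | None = None,
) -> TimeSeries:
    """Sample the flux model on a grid, zero outside the application window.

    The window runs from ``m.t_origin`` to ``t_end`` (or the end of the grid);
    outside it the flux is 0 (delta form: the sensor sits on its base).
    """
    grid = t if isinstance(t, TimeSeries) else TimeSeries(np.asarray(t, float))
    tv = grid.t
    w = m(tv)
    w[tv < m.t_origin] = 0.0
    if t_end is not None:
        w[tv >= t_end] = 0.0
    return TimeSeries(w, dt=grid.dt, t0=grid.t0, units="mW")


def mean_power(m: ExponentialFluxModel, window: tuple[float, float]) -> float:
    """Window-averaged flux (mW): the estimator the exponential model refines.

    Closed form over ``[t_a, t_b]``::

        A0 + sum Ai tau_i (e^(-(t_a-t0)/tau_i) - e^(-(t_b-t0)/tau_i)) / (t_b - t_a)
    """
    t_a, t_b = window
    if not t_b > t_a:
        raise ValueError(f"empty averaging window {window}")
    if t_a < m.t_origin:
        raise ValueError("window starts before the flux origin")
    total = m.A0
    for a, tau in m.terms:
        ea = np.exp(-(t_a - m.t_origin) / tau)
        eb = np.exp(-(t_b - m.t_origin) / tau)
        total += a * tau * (ea - eb) / (t_b - t_a)
    return float(total)


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class HeatFluxResult:
    """Result of a body heat-flux fit.

    Attributes
    ----------
    model : ExponentialFluxModel
        Fitted flux.
    sigma_y1_pct : float
        Normalized reconstruction error of the calorimetric signal,
        ``100 sqrt(sum (y1_exp - y1_cal)^2 / sum y1_exp^2)`` in %.
    Wmean : float
        Window-mean flux over the application period (mW).
    n_eval : int
        Forward-model evaluations the optimizer used.
    fixed_taus : bool
        True when the time constants were prescribed, not fitted.
    """

    model: ExponentialFluxModel
    sigma_y1_pct: float
    Wmean: float
    n_eval: int
    fixed_taus: bool
    window: tuple[float, float] = (0.0, 0.0)
    y1_reconstructed: TimeSeries | None = None

    def __post_init__(self) -> None:
        if self.sigma_y1_pct < 0:
            raise ValueError("sigma_y1_pct must be >= 0")

    @property
    def A0(self) -> float:
        return self.model.A0

    def summary(self) -> str:
        lines = [
            "Body heat-flux fit",
            "==================",
            f"  terms          : {len(self.model.terms)}"
            + ("  (fixed time constants)" if self.fixed_taus else ""),
            f"  A0             : {self.model.A0:9.1f} mW   (steady-state flux)",
        ]
        for i, (a, tau) in enumerate(self.model.terms, start=1):
            lines.append(f"  A{i}, tau{i}       : {a:9.1f} mW, {tau:7.1f} s")
        lines += [
            f"  sigma_y1       : {self.sigma_y1_pct:9.2f} %  (normalized RMS)",
            f"  Wmean          : {self.Wmean:9.1f} mW  (window mean)",
            f"  evaluations    : {self.n_eval}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# The inverse model
# ---------------------------------------------------------------------------

class HeatFluxModel:
    """Inverse model: recover the body flux from a baseline-corrected record.

    Parameters
    ----------
    record : MeasurementRecord
        Body run in delta form (baselines of y1 and W2 removed).  The contact
        window is taken from the record's ``contact`` phase unless ``window``
        is given.
    calibration : SensorCalibration
        The sensor the record was measured with.
    n_terms : int, default 2
        Number of exponential terms; two suffice in practice.
    window : (float, float), optional
        Application window (start s, stop s) overriding the phase marker.

    Notes
    -----
    The forward model feeds the candidate flux and the *measured* W2 channel
    through the calibrated sensor; the reconstruction therefore inherits the
    thermostat's regulation transient exactly, and the fit only has to explain
    what the body added.
    """

    def __init__(
        self,
        record: MeasurementRecord,
        calibration: SensorCalibration,
        n_terms: int = 2,
        window: tuple[float, float] | None = None,
    ):
        if not record.delta:
            raise ValueError(
                "record must be baseline-corrected (delta form); "
                "apply minicalor.calibration.correct_baseline first"
            )
        if n_terms < 0 or n_terms > MAX_TERMS:
            raise ValueError(f"n_terms must be in [0, {MAX_TERMS}] (identifiability)")
        self.record = record
        self.cal = calibration
        self.n_terms = n_terms
        if window is None:
            i0, i1 = record.phase("contact")
            window = (record.y1.t0 + i0 * record.dt, record.y1.t0 + i1 * record.dt)
        if window[1] - window[0] < MIN_WINDOW_S:
            raise ValueError(
                f"application window shorter than {MIN_WINDOW_S:.0f} s: {window}"
            )
        self.window = window
        # y1 response to the measured thermostat power alone
        self._y_w2, _ = simulate_outputs(calibration, None, record.W2, init="steady")

    # -- forward pieces ------------------------------------------------------
    def _basis(self, taus: tuple[float, ...]) -> np.ndarray:
        """y1 responses (mV) to unit-amplitude flux components (1 mW each)."""
        grid = self.record.y1
        cols = []
        unit_step = ExponentialFluxModel(A0=1.0, t_origin=self.window[0])
        cols.append(evaluate_flux(unit_step, grid, t_end=self.window[1]))
        for tau in taus:
            term = ExponentialFluxModel(
                A0=0.0, terms=[(1.0, tau)], t_origin=self.window[0]
            )
            cols.append(evaluate_flux(term, grid, t_end=self.window[1]))
        out = np.empty((len(grid), len(cols)))
        for j, w1 in enumerate(cols):
            y, _ = simulate_outputs(self.cal, w1, None, init="steady")
            out[:, j] = y.values
        return out

    def _solve_amplitudes(self, taus: tuple[float, ...]) -> tuple[np.ndarray, float]:
        """Exact amplitude subproblem at fixed time constants."""
        M = self._basis(taus)
        target = self.record.y1.values - self._y_w2.values
        amps, *_ = np.linalg.lstsq(M, target, rcond=None)
        resid = target - M @ amps
        denom = float(np.sum(self.record.y1.values ** 2))
        if denom == 0:
            raise FluxFitError("y1 is identically zero; nothing to fit")
        sigma_pct = 100.0 * float(np.sqrt(np.sum(resid ** 2) / denom))
        return amps, sigma_pct

    def reconstruct(self, model: ExponentialFluxModel) -> TimeSeries:
        """Forward-simulate y1 (mV, delta) for a given flux model."""
        w1 = evaluate_flux(model, self.record.y1, t_end=self.window[1])
        y, _ = simulate_outputs(self.cal, w1, self.record.W2, init="steady")
        return y

    def sigma_pct(self, model: ExponentialFluxModel) -> float:
        """Normalized RMS error (%) of a candidate flux model."""
        resid = self.record.y1.values - self.reconstruct(model).values
        return 100.0 * float(
            np.sqrt(np.sum(resid ** 2) / np.sum(self.record.y1.values ** 2))
        )

    # -- fitting -------------------------------------------------------------
    def fit(
        self,
        fixed_taus: tuple[float, ...] | None = None,
        tau_init: tuple[float, ...] = (3.0, 70.0),
        maxfev: int = 2000,
    ) -> HeatFluxResult:
        """Fit the flux model.

        With ``fixed_taus`` (e.g. the canonical ``(3, 70)`` s) only the
        amplitudes are estimated — a single exact linear solve.  Otherwise a
        Nelder–Mead search over the log time constants wraps the linear
        amplitude solve (variable projection), started from ``tau_init``.
        """
        n_eval = 0

        if self.n_terms == 0 or fixed_taus is not None:
            taus = tuple(fixed_taus or ())[: self.n_terms] if fixed_taus else ()
            if fixed_taus is not None and len(taus) != self.n_terms:
                raise ValueError("fixed_taus length must match n_terms")
            amps, sigma = self._solve_amplitudes(taus)
            n_eval = 1
            fixed = True
        else:
            def objective(logtaus: np.ndarray) -> float:
                nonlocal n_eval
                n_eval += 1
                taus = tuple(np.sort(np.exp(logtaus)))
                if len(set(taus)) != len(taus):
                    return np.inf
                try:
                    _, sigma = self._solve_amplitudes(taus)
                except np.linalg.LinAlgError:
                    return np.inf
                return sigma

            x0 = np.log(np.asarray(tau_init[: self.n_terms], float))
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxfev": maxfev},
            )
            if not np.isfinite(res.fun):
                raise FluxFitError("time-constant search failed to converge")
            taus = tuple(np.sort(np.exp(res.x)))
            amps, sigma = self._solve_amplitudes(taus)
            fixed = False

        model = ExponentialFluxModel(
            A0=float(amps[0]),
            terms=[(float(a), float(tau)) for a, tau in zip(amps[1:], taus)],
            t_origin=self.window[0],
        )
        wmean = mean_power(model, self.window)
        return HeatFluxResult(
            model=model, sigma_y1_pct=sigma, Wmean=wmean, n_eval=n_eval,
            fixed_taus=fixed, window=self.window,
            y1_reconstructed=self.reconstruct(model),
        )


def fit_flux(
    record: MeasurementRecord,
    cal: SensorCalibration,
    n_terms: int = 2,
    fixed_taus: tuple[float, ...] | None = None,
    window: tuple[float, float] | None = None,
) -> HeatFluxResult:
    """Functional wrapper: fit the exponential body flux to one record."""
    return HeatFluxModel(record, cal, n_terms=n_terms, window=window).fit(
        fixed_taus=fixed_taus
    )
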