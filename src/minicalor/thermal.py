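"""Thermal resistance and conductivity from steady-flux/temperature series.

Across a series of body measurements at different thermostat temperatures the
steady-state flux ``A0`` falls on a straight line ``A0 = alpha + beta Tcal``.
The line's slope carries the physics: the heat path from the thermostat to the
body core behaves like a resistance chain, so

* ``R_T = 1/|beta|`` (W/K form) is the total thermostat-to-core resistance,
* ``R_body = R_T - R_sensor`` is the body's share, and
* ``lambda = L/(S R_body)`` is an order-of-magnitude tissue conductivity
  under a flat-wall assumption (slab of depth ``L`` and area ``S``).

The flat wall is knowingly crude — real tissue dissipation is dominated by
perfusion — but it places the result on the literature's 0.2–0.7 W/m/K scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_R_SENSOR = 12.0          # K/W, rounded per-sensor resistance
R_SENSOR_UNROUNDED = 5.0 / 0.420  # K/W, from the two-sensor contact experiment
DEFAULT_L = 0.01                 # m, assumed slab depth (hand half-width)
DEFAULT_S = 4e-4                 # m^2, sensor contact area (2 x 2 cm)


class SensorDominatesError(ValueError):
    """R_sensor >= R_T: no body resistance can be attributed."""


# ---------------------------------------------------------------------------
# Line fit
# ---------------------------------------------------------------------------

@dataclass
class ThermalLineFit:
    """OLS fit ``value = alpha + beta * Tcal`` for one flux coefficient."""

    coefficient: str            # "A0" | "A1" | "A2"
    alpha: float                # mW
    beta: float                 # mW/degC
    sigma: float                # mW, RMS of residuals
    max_dev: float              # mW, max |residual|
    r: float                    # Pearson correlation
    points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a fitting line needs at least 2 points")
        if not (abs(self.r) <= 1 + 1e-12):
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def predict(self, tcal: np.ndarray) -> np.ndarray:
        return self.alpha + self.beta * np.asarray(tcal, float)


def fit_line(points: list[tuple[float, float]], coefficient: str = "A0") -> ThermalLineFit:
    """Ordinary least squares of a flux coefficient against Tcal.

    ``sigma`` is the RMS residual (same form as the calibration's RMS error
    criterion); ``r`` is Pearson's correlation of the raw points.
    """
    pts = [(float(t), float(v)) for t, v in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    t = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.allclose(t, t[0]):
        raise ValueError("all Tcal values identical: slope undefined")
    res = stats.linregress(t, v)
    resid = v - (res.intercept + res.slope * t)
    return ThermalLineFit(
        coefficient=coefficient,
        alpha=float(res.intercept), beta=float(res.slope),
        sigma=float(np.sqrt(np.mean(resid ** 2))),
        max_dev=float(np.max(np.abs(resid))),
        r=float(res.rvalue) if len(pts) > 2 or not np.isnan(res.rvalue)
          else float(np.sign(res.slope)),
        points=pts,
    )


# ---------------------------------------------------------------------------
# Resistance chain
# ---------------------------------------------------------------------------

def total_resistance(beta_A0: float) -> float:
    """Total thermostat-to-core resistance (K/W) from the A0 slope (mW/K).

    The slope must be negative: warming the thermostat reduces the steady
    flux out of the body.
    """
    if beta_A0 >= 0:
        raise ValueError(
            f"A0 slope must be negative (flux falls as the thermostat warms), "
            f"got {beta_A0} mW/K"
        )
    return 1.0 / (abs(beta_A0) * 1e-3)


def body_resistance(R_T: float, R_sensor: float = DEFAULT_R_SENSOR) -> float:
    """Body share of the series resistance: ``R_T - R_sensor`` (K/W)."""
    if R_sensor < 0:
        raise ValueError("R_sensor must be >= 0")
    if R_sensor >= R_T:
        raise SensorDominatesError(
            f"R_sensor ({R_sensor} K/W) >= R_T ({R_T} K/W): the sensor "
            "dominates the path and no body resistance can be derived"
        )
    return R_T - R_sensor


def conductivity(R_body: float, L: float = DEFAULT_L, S: float = DEFAULT_S) -> float:
    """Flat-wall conductivity ``lambda = L / (S R_body)`` in W/m/K."""
    if min(R_body, L, S) <= 0:
        raise ValueError("R_body, L and S must all be positive")
    return L / (S * R_body)


def sensor_resistance_from_contact(
    dT_total: float, n_sensors_in_series: int, flux: float
) -> float:
    """Per-sensor resistance from the sensor-on-sensor contact experiment.

    Two sensors pressed face to face with a programmed temperature difference
    ``dT_total`` (K) across the stack pass a steady heat flow ``flux`` (W);
    the per-sensor share of the drop gives ``R = (dT_total/n)/flux`` (K/W).
    """
    if flux <= 0:
        raise ValueError("flux must be positive")
    if dT_total <= 0:
        raise ValueError("dT_total must be positive")
    if n_sensors_in_series < 1:
        raise ValueError("need at least one sensor in series")
    return (dT_total / n_sensors_in_series) / flux


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

@dataclass
class ThermalAnalysisResult:
    """Resistance chain derived from one coefficient-versus-temperature series."""

    line_fits: dict[str, ThermalLineFit]
    beta_A0: float        # mW/K (possibly rounded to printed precision)
    R_T: float            # K/W
    R_sensor: float       # K/W
    R_body: float         # K/W
    conductivity: float   # W/m/K
    L: float = DEFAULT_L
    S: float = DEFAULT_S

    def __post_init__(self) -> None:
        if not (self.R_T > self.R_sensor > 0):
            raise ValueError("requires R_T > R_sensor > 0")
        if self.conductivity <= 0:
            raise ValueError("conductivity must be positive")

    def summary(self) -> str:
        lines = [
            "Thermal resistance chain",
            "========================",
        ]
        for name, lf in self.line_fits.items():
            lines.append(
                f"  {name}: alpha = {lf.alpha:8.2f} mW, beta = {lf.beta:7.2f} "
                f"mW/degC, sigma = {lf.sigma:6.2f} mW, r = {lf.r:+.3f}"
            )
        lines += [
            "",
            f"  A0 slope       : {self.beta_A0:8.1f} mW/K",
            f"  R_T            : {self.R_T:8.1f} K/W   (1/|slope|)",
            f"  R_sensor       : {self.R_sensor:8.1f} K/W",
            f"  R_body         : {self.R_body:8.1f} K/W   (R_T - R_sensor)",
            f"  conductivity   : {self.conductivity:8.2f} W/m/K  "
            f"(flat wall, L = {self.L*100:.0f} cm, S = {self.S*1e4:.0f} cm^2)",
        ]
        return "\n".join(lines)


class ThermalSeriesModel:
    """Aggregate fitted flux coefficients across thermostat temperatures.

    Parameters
    ----------
    points : dict or list
        Either ``{"A0": [(Tcal, mW), ...], "A1": ..., "A2": ...}`` or a bare
        point list, taken to be the A0 series.  Only A0 enters the resistance
        chain; other coefficients get their fitting lines reported.
    """

    def __init__(self, points):
        if isinstance(points, dict):
            self.series = {k: list(v) for k, v in points.items()}
        else:
            self.series = {"A0": list(points)}
        if "A0" not in self.series:
            raise ValueError("an A0 series is required")

    def fit(
        self,
        R_sensor: float = DEFAULT_R_SENSOR,
        L: float = DEFAULT_L,
        S: float = DEFAULT_S,
        slope_decimals: int | None = 1,
    ) -> ThermalAnalysisResult:
        """Fit all lines and run the resistance chain off the A0 slope.

        ``slope_decimals`` rounds the A0 slope before inverting it, matching
        how the chain is quoted at the instrument's printed precision; pass
        ``None`` to keep full precision.
        """
        fits = {name: fit_line(pts, name) for name, pts in self.series.items()}
        beta = fits["A0"].beta
        if slope_decimals is not None:
            beta = round(beta, slope_decimals)
        R_T = total_resistance(beta)
        R_body = body_resistance(R_T, R_sensor)
        lam = conductivity(R_body, L, S)
        return ThermalAnalysisResult(
            line_fits=fits, beta_A0=beta, R_T=R_T, R_sensor=R_sensor,
            R_body=R_body, conductivity=lam, L=L, S=S,
        )
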