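"""Readers/writers and the pipeline orchestration.

One measurement record is stored as a CSV file (columns
``t,y1_mV,y2_C,W1_mW,W2_mW,Troom_C``, delta-form records carry a ``_delta``
suffix on the channel columns) plus a JSON sidecar of the same stem holding
phase markers, setpoints and provenance.  Sensor parameter sets live in flat
key/value YAML files; ``S1`` and ``S2`` ship with the package.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MeasurementRecord, SensorCalibration, TimeSeries

logger = logging.getLogger(__name__)

_COLUMNS = ("y1", "y2", "W1", "W2", "Troom")
_UNITS = {"y1": "mV", "y2": "C", "W1": "mW", "W2": "mW", "Troom": "C"}
_STORE_UNITS = {"y1": "mV", "y2": "degC", "W1": "mW", "W2": "mW", "Troom": "degC"}
_DELTA_UNITS = {"y1": "mV", "y2": "K", "W1": "mW", "W2": "mW", "Troom": "degC"}
_MANDATORY = ("y1", "y2", "W2")


class RecordFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Sensor parameter files
# ---------------------------------------------------------------------------

def read_sensor(path: str | Path) -> SensorCalibration:
    """Load a sensor parameter file (flat key/value YAML)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return SensorCalibration(**raw)
    except TypeError as exc:
        raise RecordFormatError(f"bad sensor file {path}: {exc}") from exc


def write_sensor(cal: SensorCalibration, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# Minisensor calibration parameters.\n")
        fh.write("# Gains: K1, K2 in mV/W; K3, K4 in K/W.  Time constants in s.\n")
        yaml.safe_dump(cal.as_dict(), fh, sort_keys=False)


def load_sensor(name: str) -> SensorCalibration:
    """Load a packaged sensor (``S1``/``S2``) or a sensor file path."""
    if name in ("S1", "S2"):
        ref = importlib.resources.files("minicalor.data") / f"{name}.yaml"
        with importlib.resources.as_file(ref) as path:
            return read_sensor(path)
    return read_sensor(name)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

def _colname(channel: str, delta: bool) -> str:
    base = f"{channel}_{_UNITS[channel]}"
    if delta and channel != "Troom":
        base += "_delta"
    return base


def write_record(rec: MeasurementRecord, path: str | Path) -> None:
    """Write a record to ``path`` (CSV) plus a JSON sidecar.

    Full float precision; fixed column order; missing channels left out.
    The sidecar stores phases, setpoints, the delta flag and any metadata
    (including ground-truth parameters of synthetic records).
    """
    if len(rec) == 0:
        raise ValueError("refusing to write an empty record")
    path = Path(path)
    cols: dict[str, np.ndarray] = {"t": rec.y1.t}
    channels = rec.channels()
    for name in _COLUMNS:
        if name in channels:
            cols[_colname(name, rec.delta)] = channels[name].values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "phases": [[lab, int(a), int(b)] for lab, a, b in rec.phases],
        "Tcal": rec.Tcal,
        "delta": rec.delta,
        "dt": rec.dt,
        "meta": rec.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=float))


def read_record(path: str | Path, dt_tol: float = 1e-6) -> MeasurementRecord:
    """Read a record CSV (+ optional sidecar) back into a MeasurementRecord.

    Validates the header, uniform sampling (tolerance ``dt_tol`` seconds) and
    the presence of the mandatory channels (y1, y2, W2).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "t" not in df.columns:
        raise RecordFormatError("record is missing the 't' column")
    t = df["t"].to_numpy(float)
    if len(t) < 2:
        raise RecordFormatError("record needs at least 2 samples")
    steps = np.diff(t)
    dt = steps[0]
    if np.any(np.abs(steps - dt) > dt_tol):
        raise RecordFormatError("non-uniform sampling: gaps or jitter in 't'")

    sidecar = {}
    sc_path = path.with_suffix(".json")
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
    delta = bool(sidecar.get("delta", False))

    found: dict[str, TimeSeries] = {}
    for channel in _COLUMNS:
        for d in (delta, not delta):
            col = _colname(channel, d)
            if col in df.columns:
                units = (_DELTA_UNITS if d else _STORE_UNITS)[channel]
                found[channel] = TimeSeries(
                    df[col].to_numpy(float), dt=dt, t0=t[0], units=units
                )
                delta = delta or d
                break
    known = {"t"} | {_colname(c, d) for c in _COLUMNS for d in (False, True)}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise RecordFormatError(f"unknown columns/units in record: {unknown}")
    missing = [c for c in _MANDATORY if c not in found]
    if missing:
        raise RecordFormatError(f"record is missing mandatory channel(s): {missing}")
    return MeasurementRecord(
        y1=found["y1"], y2=found["y2"], W2=found["W2"],
        W1=found.get("W1"), Troom=found.get("Troom"),
        phases=[tuple(p) for p in sidecar.get("phases", [])],
        Tcal=sidecar.get("Tcal"), delta=delta, meta=sidecar.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``sensor`` is a packaged label (S1/S2) or a parameter file path; thermal
    constants and the body-series temperatures have the instrument's standard
    defaults.  One ``seed`` feeds every stage through named spawns.
    """

    sensor: str = "S1"
    seed: int = 0
    noise: bool = True
    tcals: tuple[float, ...] = (24.0, 28.0, 32.0, 36.0)
    fixed_taus: tuple[float, float] = (3.0, 70.0)
    R_sensor: float = 12.0
    L: float = 0.01
    S: float = 4e-4
    out_dir: str | None = None
    skip: tuple[str, ...] = ()
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.R_sensor, self.L, self.S) <= 0:
            raise ValueError("thermal constants must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        for key in ("tcals", "fixed_taus", "skip"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic workflow and return one JSON-able report.

    Stages: ``synth`` (calibration + body runs), ``calibrate``, ``fitflux``,
    ``thermal``.  Any stage listed in ``config.skip`` is omitted (downstream
    stages then reuse ground truth where possible).  Stage failures are
    re-raised with the stage name attached.
    """
    from . import bodyflux, calibration, synthetic, thermal

    logging.basicConfig(level=config.log_level)
    report: dict = {"config": {
        "sensor": config.sensor, "seed": config.seed, "noise": config.noise,
        "tcals": list(config.tcals), "fixed_taus": list(config.fixed_taus),
        "R_sensor": config.R_sensor, "L": config.L, "S": config.S,
        "skip": list(config.skip),
    }}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    cal_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    body_seeds = seeds[1].spawn(len(config.tcals))
    noise = synthetic.NoiseSpec() if config.noise else synthetic.NoiseSpec.noiseless()

    def stage(name):
        return name not in config.skip

    try:
        current = "config"
        truth = load_sensor(config.sensor)
        current = "synth"
        cal_rec = synthetic.generate_calibration_run(truth, noise=noise, seed=cal_seed)
        body = synthetic.BodyModel(coupling=synthetic.CouplingRule())
        body_recs = {}
        for tcal, bs in zip(config.tcals, body_seeds):
            body_recs[tcal] = synthetic.generate_body_run(
                truth, body, tcal, noise=noise,
                seed=int(bs.generate_state(1)[0] % (2**31)),
            )
        report["synth"] = {
            "calibration_record": len(cal_rec),
            "body_records": {str(t): len(r) for t, r in body_recs.items()},
            "seed": config.seed,
        }
        if out_dir:
            write_record(cal_rec, out_dir / "calibration.csv")
            for t, r in body_recs.items():
                write_record(r, out_dir / f"body_{t:g}C.csv")

        current = "calibrate"
        if stage("calibrate"):
            result = calibration.SensorDynamicsModel(cal_rec).fit()
            fitted = result.calibration
            report["calibrate"] = {
                **fitted.as_dict(),
                "sigma_y1_mV": result.sigma_y1, "sigma_y2_mK": result.sigma_y2,
                "se": result.sensitivities.se, "n_eval": result.n_eval,
            }
            if out_dir:
                write_sensor(fitted, out_dir / "sensor_fitted.yaml")
        else:
            fitted = truth

        current = "fitflux"
        flux_rows = {}
        if stage("fitflux"):
            for tcal, rec in body_recs.items():
                drec = calibration.auto_delta(rec)
                res = bodyflux.HeatFluxModel(drec, fitted).fit(
                    fixed_taus=config.fixed_taus
                )
                flux_rows[tcal] = {
                    "A0": res.model.A0,
                    "terms": res.model.terms,
                    "sigma_y1_pct": res.sigma_y1_pct,
                    "Wmean": res.Wmean,
                }
            report["fitflux"] = {str(t): row for t, row in flux_rows.items()}

        current = "thermal"
        if stage("thermal") and flux_rows:
            series = {
                "A0": [(t, row["A0"]) for t, row in flux_rows.items()],
                "A1": [(t, row["terms"][0][0]) for t, row in flux_rows.items()],
                "A2": [(t, row["terms"][1][0]) for t, row in flux_rows.items()],
            }
            tres = thermal.ThermalSeriesModel(series).fit(
                R_sensor=config.R_sensor, L=config.L, S=config.S
            )
            report["thermal"] = {
                "lines": {
                    name: {"alpha": lf.alpha, "beta": lf.beta,
                           "sigma": lf.sigma, "max_dev": lf.max_dev, "r": lf.r}
                    for name, lf in tres.line_fits.items()
                },
                "beta_A0_mW_per_K": tres.beta_A0,
                "R_T": tres.R_T, "R_sensor": tres.R_sensor,
                "R_body": tres.R_body, "conductivity": tres.conductivity,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
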