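"""Configuration parsing, tidy CSV readers/writers, and run logging.

Configurations are JSON with a strict schema: unknown keys are rejected by
name, defaults are filled in, and the effective configuration (what actually
ran, seed included) can be re-emitted so any run is reproducible from its
own log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .params import Patient
from .simulate import OUTPUT_UNITS, DoseRegimen, Trajectory

log = logging.getLogger(__name__)

_TOP_LEVEL_KEYS = {
    "model", "patient", "regimen", "seed", "fit", "gsa", "nmpc", "cohort",
    "out", "log_level",
}
_FIT_KEYS = {"free", "bounds", "fixed", "population", "generations", "local_iters",
             "obs", "train_fraction"}
_GSA_KEYS = {"output", "n", "time_points", "p", "threshold", "bounds_factor", "horizon_days"}
_NMPC_KEYS = {"mode", "references", "weights", "interval_days", "window_days",
              "horizon_intervals", "u_min", "u_max", "du_max", "initial_dose", "n_restarts"}
_COHORT_KEYS = {"mode", "n_pd", "horizon_days"}


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    model: str = "6mp"
    patient: Patient = field(default_factory=Patient)
    regimen: DoseRegimen = field(default_factory=lambda: DoseRegimen.daily(75, 112))
    seed: int = 0
    fit: dict = field(default_factory=dict)
    gsa: dict = field(default_factory=dict)
    nmpc: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    out: str | None = None
    log_level: str = "INFO"

    def effective_dict(self) -> dict:
        return {
            "model": self.model,
            "patient": self.patient.to_dict(),
            "regimen": self.regimen.description or [[t, d] for t, d in self.regimen.events],
            "seed": self.seed,
            "fit": self.fit,
            "gsa": self.gsa,
            "nmpc": self.nmpc,
            "cohort": self.cohort,
            "out": self.out,
            "log_level": self.log_level,
        }


def _reject_unknown(data: dict, allowed: set, context: str) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in {context}")


def parse_config(path) -> RunConfig:
    """Parse and validate a JSON run configuration.

    Schema violations raise :class:`~sixmp.errors.ConfigError` naming the
    offending key; the effective configuration is echoed to the log.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("top-level configuration must be a JSON object")
    _reject_unknown(data, _TOP_LEVEL_KEYS, "configuration")
    for section, keys in (("fit", _FIT_KEYS), ("gsa", _GSA_KEYS),
                          ("nmpc", _NMPC_KEYS), ("cohort", _COHORT_KEYS)):
        if section in data:
            if not isinstance(data[section], dict):
                raise ConfigError(f"section {section!r} must be an object")
            _reject_unknown(data[section], keys, f"section {section!r}")

    patient_data = data.get("patient", {})
    if "id" not in patient_data and isinstance(patient_data, dict):
        patient_data = {**patient_data, "id": "config"}
    try:
        patient = Patient.from_dict(patient_data)
    except Exception as exc:
        raise ConfigError(f"invalid patient parameters: {exc}") from exc

    regimen_spec = data.get("regimen", "daily:75mg:112d")
    if isinstance(regimen_spec, str):
        regimen = DoseRegimen.parse(regimen_spec)
    else:
        regimen = DoseRegimen(tuple((float(t), float(d)) for t, d in regimen_spec))

    cfg = RunConfig(
        model=data.get("model", "6mp"),
        patient=patient,
        regimen=regimen,
        seed=int(data.get("seed", 0)),
        fit=data.get("fit", {}),
        gsa=data.get("gsa", {}),
        nmpc=data.get("nmpc", {}),
        cohort=data.get("cohort", {}),
        out=data.get("out"),
        log_level=str(data.get("log_level", "INFO")),
    )
    if cfg.model not in {"6mp", "leuko", "mcv", "all"}:
        raise ConfigError(f"unknown model {cfg.model!r} for key 'model'")
    log.info("effective config: %s", json.dumps(cfg.effective_dict(), sort_keys=True))
    return cfg


def emit_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.effective_dict(), indent=2, sort_keys=True) + "\n")


def write_timeseries(traj: Trajectory, path) -> None:
    """Write a trajectory as tidy CSV: time_days, variable, value, unit."""
    frame = traj.to_frame()
    frame["value"] = [repr(float(v)) for v in frame["value"]]
    frame.to_csv(path, index=False, lineterminator="\n")


def read_timeseries(path) -> Trajectory:
    """Read a tidy trajectory CSV back into a Trajectory."""
    frame = pd.read_csv(path)
    required = ["time_days", "variable", "value", "unit"]
    if list(frame.columns) != required:
        raise ConfigError(f"timeseries CSV must have columns {required}")
    values = {}
    times = None
    for var, group in frame.groupby("variable", sort=False):
        t = group["time_days"].to_numpy(dtype=float)
        if times is None:
            times = t
        elif t.shape != times.shape or not np.allclose(t, times):
            raise ConfigError("all variables must share the time grid")
        values[var] = group["value"].to_numpy(dtype=float)
    if times is None:
        times = np.array([])
    return Trajectory(times=times, values=values, metadata={"source": str(path)})
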