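"""Synthetic time-series datasets for the two simulation designs.

Two designs are emulated:

* **Motif grid** -- each of the four two-gene motifs (or a cooperative
  ``.H`` variant) is driven by the step signal S = {0, 1, 2, 0} switching
  at t = {0, 2, 6, 10}; both state variables are observed at 30 equally
  spaced time points (60 records), with additive N(0, 0.05^2) noise.
* **FF-subtype designs** -- the arabinose-, flagella- and galactose-like
  experiments: only the target z is observed, y stays hidden, and the
  record counts mirror the experimental series (ara: 30 ON + 30 OFF;
  flagella: 20 ON + 17 OFF; gal: 15 ON only).  Each step spans 10
  dimensionless time units with points equally spaced within the step.

Generating parameters default to rates 1, thresholds 0.5, Hill
coefficient 2.  Every simulation takes an explicit seed and is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import ConfigurationError, get_model, integrate

__all__ = [
    "TimeSeriesDataset",
    "simulate_motif_dataset",
    "simulate_ff_dataset",
    "FF_SYSTEMS",
    "MOTIF_FAMILY",
    "NOISE_SD",
]

#: Observation-noise standard deviation used by both designs.
NOISE_SD = 0.05
#: Models eligible for the four-motif simulation design.
MOTIF_FAMILY = ("SIM", "RC", "FF", "FB", "SIM.H", "RC.H", "FF.H", "FB.H")
#: FF-subtype designs: generating model and (step label, #points) layout.
FF_SYSTEMS = {
    "ara": ("FF.C1.AND", (("ON", 30), ("OFF", 30))),
    "flagella": ("FF.C1.OR.1", (("ON", 20), ("OFF", 17))),
    "gal": ("FF.I1.AND", (("ON", 15),)),
}
#: Control model fitted alongside the FF subtypes for each system.
FF_CONTROLS = {"ara": "CONTROL.ARA", "flagella": "CONTROL.FLA", "gal": "CONTROL.GAL"}


@dataclass
class TimeSeriesDataset:
    """Tidy observations: one row per (step, time, variable, value) record."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"step", "time", "variable", "value"}
        if not required <= set(self.data.columns):
            raise ValueError(f"dataset needs columns {sorted(required)}")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["variable"]))

    @property
    def step_labels(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["step"]))

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write records as CSV plus a JSON sidecar with design metadata."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        if sidecar:
            with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
                json.dump(self.meta, fh, indent=2, default=float)

    @classmethod
    def read_csv(cls, path) -> "TimeSeriesDataset":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = {}
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
        return cls(data=data, meta=meta)


def _observe(spec, params, step_label, times, rng, noise_sd, rows):
    step = spec.steps[step_label]
    sig = {name: step.signal(name) for name in spec.inputs}
    traj = integrate(spec, params, sig, times, initial_state=step.x0)
    if not traj.ok:
        raise RuntimeError(f"generating trajectory failed for {spec.name}")
    for var in spec.observed:
        clean = traj[var]
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.size) if noise_sd > 0 else clean
        for t, v in zip(times, noisy):
            rows.append((step_label, float(t), var, float(v)))


def simulate_motif_dataset(model: str, seed: int | None = None, *,
                           noise_sd: float = NOISE_SD, n_points: int = 30,
                           params: dict | None = None) -> TimeSeriesDataset:
    """Simulate the four-motif design from one generating motif.

    Both y and z are sampled at ``n_points`` equally spaced times over the
    signal window [0, 10] and observed with Gaussian noise.
    """
    spec = get_model(model)
    if spec.name not in MOTIF_FAMILY:
        raise ConfigurationError(
            f"{spec.name} is not part of the four-motif family {MOTIF_FAMILY}")
    params = dict(spec.true_params(), **(params or {}))
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, spec.steps["main"].duration, n_points)
    rows: list = []
    _observe(spec, params, "main", times, rng, noise_sd, rows)
    data = pd.DataFrame(rows, columns=["step", "time", "variable", "value"])
    meta = {"design": "motif_grid", "model": spec.name, "params": params,
            "noise_sd": noise_sd, "seed": seed, "n_points": n_points}
    return TimeSeriesDataset(data=data, meta=meta)


def simulate_ff_dataset(system: str, seed: int | None = None, *,
                        noise_sd: float = NOISE_SD, duration: float = 10.0,
                        params: dict | None = None) -> TimeSeriesDataset:
    """Simulate one FF-subtype design (``ara``, ``flagella`` or ``gal``).

    Only the target z is observed; the intermediate regulator y is
    hidden.  Steps are initialised from the generating model's canonical
    ON/OFF conditions.
    """
    try:
        model_name, layout = FF_SYSTEMS[system]
    except KeyError:
        raise ConfigurationError(
            f"unknown system {system!r}; available: {', '.join(FF_SYSTEMS)}") from None
    spec = get_model(model_name)
    params = dict(spec.true_params(), **(params or {}))
    rng = np.random.default_rng(seed)
    rows: list = []
    for step_label, n in layout:
        times = np.linspace(0.0, duration, n)
        _observe(spec, params, step_label, times, rng, noise_sd, rows)
    data = pd.DataFrame(rows, columns=["step", "time", "variable", "value"])
    meta = {"design": "ff_grid", "system": system, "model": spec.name,
            "params": params, "noise_sd": noise_sd, "seed": seed,
            "layout": [list(x) for x in layout], "duration": duration}
    return TimeSeriesDataset(data=data, meta=meta)
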