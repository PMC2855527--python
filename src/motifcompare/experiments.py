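"""End-to-end studies: simulate, fit all candidates, rank.

Two study grids are provided:

* :func:`run_motif_grid` -- data generated from each of the four motifs
  (optionally the cooperative ``.H`` family) and fitted by all four
  candidates, giving the 4 x 4 ranking grid;
* :func:`run_ff_grid` -- the artificial arabinose/flagella/galactose
  datasets fitted by the system control plus the three FF subtypes;
  :func:`run_flagella_extension` adds the two delay models on the
  flagella design.

Per-dataset and per-fit seeds are derived from the master seed by fixed
offsets, so a rerun with the same master seed is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .compare import ComparisonReport, rank_models
from .datasets import FF_CONTROLS, FF_SYSTEMS, simulate_ff_dataset, simulate_motif_dataset
from .model import ChainConfig, FULL_CONFIG, REDUCED_CONFIG, MotifModel
from .motifs import ConfigurationError, MODELS

__all__ = [
    "ExperimentConfig",
    "run_motif_grid",
    "run_ff_grid",
    "run_flagella_extension",
    "REDUCED_CONFIG",
    "FULL_CONFIG",
]

_SEED_MOD = 2**31


@dataclass
class ExperimentConfig:
    """Declarative description of one study run."""

    study: str = "motif_grid"
    generating: tuple[str, ...] = ()
    candidates: tuple[str, ...] = ()
    chains: ChainConfig = field(default_factory=lambda: REDUCED_CONFIG)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        for name in self.candidates:
            if name not in MODELS:
                raise ConfigurationError(f"unknown model {name!r} in config")
        ok_generating = set(MODELS) | set(FF_SYSTEMS)
        for name in self.generating:
            if name not in ok_generating:
                raise ConfigurationError(f"unknown generating model/system {name!r}")


def _data_seed(master: int, index: int) -> int:
    return (1_000 * master + 7 * index + 1) % _SEED_MOD


def _chain_seed(master: int, index: int, candidate_index: int) -> int:
    return (1_000 * master + 7 * index + 13 * candidate_index + 3) % _SEED_MOD


def _write(report: ComparisonReport, dataset, out_dir, tag):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset.to_csv(out_dir / f"{tag}_data.csv")
    report.to_csv(out_dir / f"{tag}_report.csv")
    report.to_json(out_dir / f"{tag}_report.json")


def _fit_all(dataset, candidates, cfg, master, index, out_dir, tag):
    fits = {}
    for k, cand in enumerate(candidates):
        chain_cfg = ChainConfig(**{**{f: getattr(cfg, f) for f in
                                      ("n_chains", "n_iterations", "burn_in",
                                       "thinning", "init_scale")},
                                   "seed": _chain_seed(master, index, k)})
        try:
            fits[cand] = MotifModel(dataset, cand).fit(chain_cfg)
        except Exception as err:  # a failed cell leaves a gap, the grid survives
            fits[cand] = None
            print(f"fit of {cand} failed: {err}")
    meta = {"title": f"data generated from {dataset.meta.get('model', tag)}",
            "dataset": dataset.meta, "master_seed": master,
            "chains": {f: getattr(cfg, f) for f in
                       ("n_chains", "n_iterations", "burn_in", "thinning")},
            "solver": {"dt": 0.02, "delay_dt": 0.01}}
    report = rank_models(fits, meta=meta)
    if out_dir:
        _write(report, dataset, out_dir, tag)
    return report


def run_motif_grid(seed: int = 0, *, generating=("SIM", "RC", "FF", "FB"),
                   candidates=None, config: ChainConfig = REDUCED_CONFIG,
                   cooperative: bool = False, out_dir=None) -> dict[str, ComparisonReport]:
    """Four-motif study: one report per generating model.

    With ``cooperative=True`` the grid runs on the ``.H`` variants
    instead (data and candidates with Hill production terms).
    """
    if cooperative:
        generating = tuple(g if g.endswith(".H") else g + ".H" for g in generating)
    candidates = tuple(candidates) if candidates is not None else tuple(generating)
    reports = {}
    for i, gen in enumerate(generating):
        data = simulate_motif_dataset(gen, seed=_data_seed(seed, i))
        reports[gen] = _fit_all(data, candidates, config, seed, i, out_dir,
                                tag=f"motif_{gen}")
    return reports


def run_ff_grid(seed: int = 0, *, systems=("ara", "flagella", "gal"),
                config: ChainConfig = REDUCED_CONFIG,
                out_dir=None) -> dict[str, ComparisonReport]:
    """FF-subtype study: each artificial dataset fitted by its control
    and the three FF subtypes."""
    reports = {}
    for i, system in enumerate(systems):
        data = simulate_ff_dataset(system, seed=_data_seed(seed, 100 + i))
        candidates = (FF_CONTROLS[system], "FF.C1.AND", "FF.C1.OR.1", "FF.I1.AND")
        reports[system] = _fit_all(data, candidates, config, seed, 100 + i,
                                   out_dir, tag=f"ff_{system}")
    return reports


def run_flagella_extension(seed: int = 0, *, config: ChainConfig = REDUCED_CONFIG,
                           out_dir=None) -> ComparisonReport:
    """Delay-model study on the flagella design (control, OR.1, OR.2, OR.3)."""
    data = simulate_ff_dataset("flagella", seed=_data_seed(seed, 200))
    candidates = ("CONTROL.FLA", "FF.C1.OR.1", "FF.C1.OR.2", "FF.C1.OR.3")
    return _fit_all(data, candidates, config, seed, 200, out_dir,
                    tag="flagella_extension")


def run_study(config: ExperimentConfig):
    """Dispatch a declarative :class:`ExperimentConfig`."""
    if config.study == "motif_grid":
        return run_motif_grid(config.seed, config=config.chains,
                              generating=config.generating or ("SIM", "RC", "FF", "FB"),
                              candidates=config.candidates or None,
                              out_dir=config.out_dir)
    if config.study == "ff_grid":
        return run_ff_grid(config.seed, config=config.chains,
                           systems=config.generating or ("ara", "flagella", "gal"),
                           out_dir=config.out_dir)
    if config.study == "flagella_extension":
        return run_flagella_extension(config.seed, config=config.chains,
                                      out_dir=config.out_dir)
    raise ConfigurationError(f"unknown study {config.study!r}")
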