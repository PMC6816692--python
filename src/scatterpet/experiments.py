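"""Experiment configuration, drivers, and serialization.

``ExperimentConfig`` validates a nested configuration (schema below) before
any computation; ``run_experiment`` ties phantom construction, system
building, simulation, and reconstruction together and writes a
self-describing output bundle (trace CSV, final images, summary JSON, and a
verbatim config echo).  The default pipeline contains no randomness, so
re-running a bundle from its echoed config reproduces it exactly.

Config schema (YAML/JSON)::

    scanner:  {n_detectors, radius_cm, scale}
    grid:     {nx, ny, voxel_cm}            # only for phantom.kind == flat
    energy:   {n_bins, min_pair_separation_deg}
    build:    {weight_mode, arc_samples_per_voxel}
    phantom:  {kind: chest|flat, resolution, scale, lam, mu}
    algorithm: {name: mlem_osl|mlga|2alg|4alg|mlaa|crosstalk|density_sweep,
                iterations, subsets, step_mode, step_constant, eta,
                reduce_data, gamma}
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import EnergyBinning
from .joint import (
    run_2algorithm,
    run_4algorithm,
    run_crosstalk_escape,
    run_mlaa,
)
from .metrics import ConvergenceSummary, density_sweep, nmse
from .phantoms import chest_phantom, flat_phantom, initial_guesses, \
    simulate_measurements
from .s2a import StepSizeSpec, run_s2a
from .systems import build_scatter_system, build_trues_system

__all__ = ["ExperimentConfig", "run_experiment", "PRESETS", "preset_config"]


@dataclass
class ScannerBlock:
    n_detectors: int = 64
    radius_cm: float = 40.0
    scale: float = 1.0


@dataclass
class GridBlock:
    nx: int = 9
    ny: int = 9
    voxel_cm: float = 5.0


@dataclass
class EnergyBlock:
    n_bins: int = 10
    min_pair_separation_deg: float = 45.0


@dataclass
class BuildBlock:
    weight_mode: str = "geometric"
    arc_samples_per_voxel: float = 8.0


@dataclass
class PhantomBlock:
    kind: str = "chest"
    resolution: int = 9
    scale: float = 1.0
    lam: float = 1.0      # flat phantom only
    mu: float = 0.1       # flat phantom only


@dataclass
class AlgorithmBlock:
    name: str = "mlga"
    iterations: int = 500
    subsets: int = 4
    step_mode: str = "mlem_like"
    step_constant: float = 0.5
    eta: float = 0.03
    reduce_data: bool = False
    gamma: float = 0.25


@dataclass
class ExperimentConfig:
    scanner: ScannerBlock = field(default_factory=ScannerBlock)
    grid: GridBlock = field(default_factory=GridBlock)
    energy: EnergyBlock = field(default_factory=EnergyBlock)
    build: BuildBlock = field(default_factory=BuildBlock)
    phantom: PhantomBlock = field(default_factory=PhantomBlock)
    algorithm: AlgorithmBlock = field(default_factory=AlgorithmBlock)

    def validate(self) -> "ExperimentConfig":
        if self.phantom.kind not in ("chest", "flat"):
            raise ValueError("phantom.kind must be 'chest' or 'flat'")
        if self.algorithm.name not in ("mlem_osl", "mlga", "2alg", "4alg",
                                       "mlaa", "crosstalk", "density_sweep"):
            raise ValueError(f"unknown algorithm {self.algorithm.name!r}")
        if self.algorithm.iterations < 1:
            raise ValueError("iterations must be positive")
        if self.scanner.n_detectors < 2 or self.scanner.scale <= 0:
            raise ValueError("invalid scanner block")
        if self.energy.n_bins < 1:
            raise ValueError("invalid energy block")
        if self.algorithm.step_mode not in ("mlem_like", "constant", "scaled"):
            raise ValueError("invalid step mode")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        blocks = {}
        for name, typ in (("scanner", ScannerBlock), ("grid", GridBlock),
                          ("energy", EnergyBlock), ("build", BuildBlock),
                          ("phantom", PhantomBlock),
                          ("algorithm", AlgorithmBlock)):
            sub = dict(d.get(name, {}))
            unknown = set(sub) - set(typ.__dataclass_fields__)
            if unknown:
                raise ValueError(f"unknown keys in {name}: {sorted(unknown)}")
            blocks[name] = typ(**sub)
        return cls(**blocks).validate()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


def _build_all(cfg: ExperimentConfig):
    if cfg.phantom.kind == "chest":
        ph = chest_phantom(resolution=cfg.phantom.resolution,
                           scale=cfg.phantom.scale,
                           n_detectors=cfg.scanner.n_detectors)
    else:
        ph = flat_phantom(cfg.grid.nx, lam_value=cfg.phantom.lam,
                          mu_value=cfg.phantom.mu,
                          extent_cm=cfg.grid.nx * cfg.grid.voxel_cm,
                          n_detectors=cfg.scanner.n_detectors,
                          ring_radius_cm=cfg.scanner.radius_cm)
    binning = EnergyBinning(cfg.energy.n_bins)
    scatter = build_scatter_system(
        ph.scanner, ph.grid, binning,
        weight_mode=cfg.build.weight_mode,
        min_pair_separation_deg=cfg.energy.min_pair_separation_deg,
        arc_samples_per_voxel=cfg.build.arc_samples_per_voxel)
    trues = build_trues_system(
        ph.scanner, ph.grid,
        min_pair_separation_deg=cfg.energy.min_pair_separation_deg)
    meas = simulate_measurements(ph, scatter, trues)
    return ph, scatter, trues, meas


def run_experiment(cfg: ExperimentConfig, outdir) -> dict:
    """Run the configured experiment and write the output bundle.

    Returns a summary dict (also written as ``summary.json``).
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    alg = cfg.algorithm

    if alg.name == "density_sweep":
        table = density_sweep(detector_counts=(2, 4, 8, 16, 32, 64),
                              voxel_counts=(2, 4, 8, 9, 16),
                              n_energy_bins=cfg.energy.n_bins)
        table.to_csv(outdir / "density_sweep.csv", index=False)
        summary = {"algorithm": alg.name, "rows": len(table)}
        _finalize(cfg, outdir, summary, t0)
        return summary

    ph, scatter, trues, meas = _build_all(cfg)
    lam0, rho0 = initial_guesses(ph)
    summary: dict = {"algorithm": alg.name, "phantom": ph.label,
                     "n_sors": scatter.n_sors, "n_lors": trues.n_lors,
                     "n_dropped_sors": scatter.n_dropped}

    if alg.name in ("mlem_osl", "mlga"):
        step = StepSizeSpec(mode=alg.step_mode, constant=alg.step_constant)
        rho, trace = run_s2a(scatter, ph.lam, meas.y, rho0,
                             algorithm=alg.name, step=step,
                             n_iterations=alg.iterations,
                             reduce_data=alg.reduce_data, rho_true=ph.rho)
        df = pd.DataFrame(trace)
        df.to_csv(outdir / "trace.csv", index=False)
        _save_image(outdir / "rho_final.csv", rho, ph.grid)
        series = df["nmse_rho"].to_numpy() if "nmse_rho" in df else []
        diverged = bool(df["diverged"].any()) if len(df) else False
        summary["convergence"] = asdict(ConvergenceSummary.from_nmse_series(
            series, final_ll=float(df["ll"].iloc[-1]) if "ll" in df else np.nan,
            diverged=diverged))
    elif alg.name in ("2alg", "4alg", "mlaa", "crosstalk"):
        if alg.name == "2alg":
            state, trace = run_2algorithm(
                scatter, trues, meas.y, meas.z, lam0, rho0,
                n_iterations=alg.iterations, n_subsets=alg.subsets,
                gamma=alg.gamma, lam_true=ph.lam, rho_true=ph.rho)
        elif alg.name == "4alg":
            state, trace = run_4algorithm(
                scatter, trues, meas.y, meas.z, lam0, rho0,
                n_iterations=alg.iterations, eta=alg.eta, gamma=alg.gamma,
                lam_true=ph.lam, rho_true=ph.rho)
        elif alg.name == "mlaa":
            state, trace, plateau = run_mlaa(
                trues, meas.z, lam0, rho0, n_iterations=alg.iterations,
                eta=alg.eta, lam_true=ph.lam, rho_true=ph.rho,
                scatter=scatter, y=meas.y)
            summary["plateau_iteration"] = plateau
        else:
            res = run_crosstalk_escape(
                scatter, trues, meas.y, meas.z, lam0, rho0,
                n_escape_iterations=alg.iterations, eta=alg.eta,
                gamma=alg.gamma, lam_true=ph.lam, rho_true=ph.rho)
            state, trace = res["escape_state"], res["escape_trace"]
            res["mlaa_trace"].to_dataframe().to_csv(
                outdir / "mlaa_trace.csv", index=False)
            summary["plateau"] = {k: (v if v is None else float(v))
                                  for k, v in res["plateau"].items()}
        trace.to_dataframe().to_csv(outdir / "trace.csv", index=False)
        _save_image(outdir / "rho_final.csv", state.rho, ph.grid)
        _save_image(outdir / "lambda_final.csv", state.lam, ph.grid)
        summary["final_nmse_rho"] = nmse(state.rho, ph.rho)
        summary["final_nmse_lambda"] = nmse(state.lam, ph.lam)
        summary["diverged"] = state.diverged

    _finalize(cfg, outdir, summary, t0)
    return summary


def _save_image(path, image, grid):
    np.savetxt(path, np.asarray(image).reshape(grid.ny, grid.nx),
               delimiter=",", fmt="%.12g")


def _finalize(cfg, outdir, summary, t0):
    summary["elapsed_s"] = round(time.time() - t0, 3)
    summary["version"] = __version__
    summary["python"] = platform.python_version()
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


PRESETS: dict[str, dict] = {
    # S2A scale sweep (NMSE-vs-iteration curves at three spatial scales)
    "fig6-rat-9x9-mlga": {
        "phantom": {"kind": "chest", "resolution": 9, "scale": 0.2},
        "algorithm": {"name": "mlga", "iterations": 500}},
    "fig6-human-9x9-mlga": {
        "phantom": {"kind": "chest", "resolution": 9, "scale": 1.0},
        "algorithm": {"name": "mlga", "iterations": 500}},
    "fig6-rat-9x9-mlem-osl": {
        "phantom": {"kind": "chest", "resolution": 9, "scale": 0.2},
        "algorithm": {"name": "mlem_osl", "iterations": 500}},
    "fig6-human-9x9-mlem-osl": {
        "phantom": {"kind": "chest", "resolution": 9, "scale": 1.0},
        "algorithm": {"name": "mlem_osl", "iterations": 500}},
    "fig7-reduced-rabbit-9x9": {
        "phantom": {"kind": "chest", "resolution": 9, "scale": 0.35},
        "algorithm": {"name": "mlem_osl", "iterations": 500,
                      "reduce_data": True}},
    # density tables harness
    "tables2-3-density": {
        "energy": {"n_bins": 4},
        "algorithm": {"name": "density_sweep", "iterations": 1}},
    # joint estimation
    "fig9-2alg-rat": {
        "phantom": {"kind": "chest", "resolution": 9, "scale": 0.2},
        "algorithm": {"name": "2alg", "iterations": 50}},
    "fig13-4alg-human": {
        "phantom": {"kind": "chest", "resolution": 9, "scale": 1.0},
        "algorithm": {"name": "4alg", "iterations": 500}},
    "fig14-crosstalk": {
        "phantom": {"kind": "chest", "resolution": 9, "scale": 1.0},
        "algorithm": {"name": "crosstalk", "iterations": 500}},
}


def preset_config(name: str) -> ExperimentConfig:
    """Named experiment presets covering the S2A scale sweep, reduced data,
    the density tables, the joint schedules, and the crosstalk study."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(PRESETS)}")
    return ExperimentConfig.from_dict(PRESETS[name])
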