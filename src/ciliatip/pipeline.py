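"""End-to-end pipeline drivers composing the analysis stages.

Each driver takes a :class:`~ciliatip.io.RunConfig`, runs the corresponding
chain deterministically for the configured seed, optionally persists
intermediates, and returns a schema-validated report dictionary.  Stage
failures propagate as :class:`PipelineStageError` naming the stage.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import __version__
from .errors import CiliaTipError
from .hydro import HydroParams
from .io import (
    RunConfig,
    SCHEMA_VERSION,
    read_trajectory_csv,
    write_report,
    write_trajectory_csv,
)
from .model import FreeBeatAnalysis, TrapAnalysis
from .synth import TrapSimParams, WaveformParams, generate_free_beating, generate_trapped_phase
from .trap import TrapParams

log = logging.getLogger("ciliatip")


class PipelineStageError(CiliaTipError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage '{stage}': {error}")
        self.stage = stage
        self.error = error


def _stage(name, fn, *args, **kwargs):
    log.info("stage %s: start", name)
    try:
        out = fn(*args, **kwargs)
    except CiliaTipError as exc:
        raise PipelineStageError(name, exc) from exc
    log.info("stage %s: done", name)
    return out


def _provenance(config: RunConfig) -> dict:
    return {
        "config_sha256": config.sha256(),
        "seed": int(config.seed),
        "package_version": __version__,
    }


def _load_free_trajectory(config: RunConfig):
    if config.trajectory_csv:
        return _stage("read-trajectory", read_trajectory_csv, config.trajectory_csv)
    params = WaveformParams(**config.waveform)
    log.info("simulating free beating: %s", params)
    return _stage("simulate", generate_free_beating, params, config.seed)


def run_free_pipeline(config: RunConfig) -> dict:
    """Free-beating chain: (load|simulate) → align → smooth → segment →
    metrics → sphere fit → force → flux → volume → report."""
    traj = _load_free_trajectory(config)
    hydro_params = HydroParams(**config.hydro) if config.hydro else HydroParams(
        eta_cp=traj.meta.get("viscosity_cp", 1.0)
    )
    analysis = FreeBeatAnalysis(traj, hydro_params=hydro_params)
    results = _stage("analyze-free", analysis.fit)
    report = {
        "schema_version": SCHEMA_VERSION,
        "mode": "analyze-free",
        "provenance": _provenance(config),
        **results.to_report(),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report_free.json")
        if config.save_intermediates:
            write_trajectory_csv(traj, out / "trajectory_raw.csv")
            aligned = results.smoothed.copy()
            aligned.phase = results.segmentation.labels
            write_trajectory_csv(aligned, out / "trajectory_centered_smoothed.csv")
            results.series.to_frame().to_csv(out / "force_flux.csv", index=False)
    return report


def run_trap_pipeline(config: RunConfig) -> dict:
    """Trapped-phase chain: (load|simulate) → smooth → amplitude/forces/
    peaks → report."""
    if config.trajectory_csv:
        traj = _stage("read-trajectory", read_trajectory_csv, config.trajectory_csv)
    else:
        params = TrapSimParams(**config.trap_sim)
        traj = _stage("simulate", generate_trapped_phase, params, config.seed)
    trap_params = None
    if config.trap:
        trap_params = TrapParams(
            k_xy_pn_nm=config.trap["k_xy_pn_nm"],
            k_z_pn_nm=config.trap["k_z_pn_nm"],
            trap_center_um=tuple(config.trap.get("center_um", (0.0, 0.0, 0.0))),
        )
    free_traj = None
    analysis = TrapAnalysis(traj, trap_params=trap_params, free_trajectory=free_traj)
    results = _stage("analyze-trap", analysis.fit)
    report = {
        "schema_version": SCHEMA_VERSION,
        "mode": "analyze-trap",
        "provenance": _provenance(config),
        **results.to_report(),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report_trap.json")
        if config.save_intermediates:
            write_trajectory_csv(traj, out / "trajectory_raw.csv")
            write_trajectory_csv(results.smoothed, out / "trajectory_smoothed.csv")
    return report
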