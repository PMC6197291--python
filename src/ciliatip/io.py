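"""File formats and run configuration.

Trajectory CSV dialect: UTF-8, comma-separated, mandatory header
``t_s,x_um,y_um,z_um`` (optional ``phase`` and ``quality`` columns),
``#``-prefixed metadata lines (``key=value``; ``meta`` holds JSON), values
written at full double precision so write→read is lossless.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import FormatError, ParameterError
from .trajectory import Trajectory

REQUIRED_COLUMNS = ("t_s", "x_um", "y_um", "z_um")


# --------------------------------------------------------------------------
# trajectory CSV
# --------------------------------------------------------------------------
def write_trajectory_csv(traj: Trajectory, path) -> None:
    path = Path(path)
    lines = ["# ciliatip trajectory v1"]
    if traj.sample_rate_hz is not None:
        lines.append(f"# sample_rate_hz={traj.sample_rate_hz!r}")
    if traj.rotation_deg is not None:
        lines.append(f"# rotation_deg={traj.rotation_deg!r}")
        lines.append(f"# flip_applied={int(bool(traj.flip_applied))}")
    if traj.meta:
        safe = {k: v for k, v in traj.meta.items() if _jsonable(v)}
        lines.append("# meta=" + json.dumps(safe, sort_keys=True))
    cols = list(REQUIRED_COLUMNS)
    if traj.phase is not None:
        cols.append("phase")
    if traj.quality is not None:
        cols.append("quality")
    lines.append(",".join(cols))
    for i in range(traj.n):
        row = [
            f"{traj.t[i]:.17g}",
            f"{traj.x[i]:.17g}",
            f"{traj.y[i]:.17g}",
            f"{traj.z[i]:.17g}",
        ]
        if traj.phase is not None:
            row.append(str(traj.phase[i]))
        if traj.quality is not None:
            row.append(str(int(traj.quality[i])))
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trajectory_csv(path) -> Trajectory:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta: dict = {}
    sample_rate = None
    rotation = None
    flip = None
    header: Optional[list] = None
    data_rows = []
    row_lines = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key == "sample_rate_hz":
                        sample_rate = float(val)
                    elif key == "rotation_deg":
                        rotation = float(val)
                    elif key == "flip_applied":
                        flip = bool(int(val))
                    elif key == "meta":
                        meta = json.loads(val)
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                missing = [c for c in REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise FormatError(
                        f"{path}: missing required column(s) {', '.join(missing)}"
                    )
                continue
            data_rows.append(line.split(","))
            row_lines.append(lineno)
    if header is None or not data_rows:
        raise FormatError(f"{path}: no data rows")

    idx = {c: header.index(c) for c in header}
    n = len(data_rows)
    arrays = {c: np.empty(n) for c in REQUIRED_COLUMNS}
    phase = [] if "phase" in idx else None
    quality = [] if "quality" in idx else None
    for k, (cells, lineno) in enumerate(zip(data_rows, row_lines)):
        if len(cells) != len(header):
            raise FormatError(f"{path}: line {lineno}: expected {len(header)} cells")
        for c in REQUIRED_COLUMNS:
            try:
                arrays[c][k] = float(cells[idx[c]])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric value "
                    f"{cells[idx[c]]!r} in column {c}"
                ) from None
        if phase is not None:
            phase.append(cells[idx["phase"]])
        if quality is not None:
            quality.append(bool(int(cells[idx["quality"]])))
    t = arrays["t_s"]
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise FormatError(
            f"{path}: line {row_lines[bad[0] + 1]}: time not strictly increasing"
        )
    if not all(np.all(np.isfinite(arrays[c])) for c in REQUIRED_COLUMNS):
        raise FormatError(f"{path}: non-finite coordinate values")
    return Trajectory(
        t=t,
        x=arrays["x_um"],
        y=arrays["y_um"],
        z=arrays["z_um"],
        sample_rate_hz=sample_rate,
        phase=np.asarray(phase) if phase else None,
        quality=np.asarray(quality, dtype=bool) if quality else None,
        rotation_deg=rotation,
        flip_applied=flip,
        meta=meta,
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------
MODES = ("simulate", "localize", "analyze-free", "analyze-trap", "flux-estimate")


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON serializable)."""

    mode: str
    seed: int = 0
    out_dir: Optional[str] = None
    save_intermediates: bool = False
    trajectory_csv: Optional[str] = None
    stack_tiff: Optional[str] = None
    calibration_json: Optional[str] = None
    waveform: dict = dataclasses.field(default_factory=dict)
    optics: dict = dataclasses.field(default_factory=dict)
    trap_sim: dict = dataclasses.field(default_factory=dict)
    hydro: dict = dataclasses.field(default_factory=dict)
    trap: dict = dataclasses.field(default_factory=dict)
    flux: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}")
        for attr in ("trajectory_csv", "stack_tiff", "calibration_json"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ParameterError(f"{attr} does not exist: {p}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


# --------------------------------------------------------------------------
# report schema
# --------------------------------------------------------------------------
SCHEMA_VERSION = "1"

#: key suffixes that declare units; bare keys must appear in the exemptions
UNIT_SUFFIXES = (
    "_hz", "_um", "_nm", "_pn", "_pN", "_s", "_cp", "_deg",
    "_um3_s", "_um3_cycle", "_pn_nm", "_samples",
)
UNITLESS_KEYS = {
    "n_cycles", "peaks_per_cycle", "flip_applied", "sphere_method",
    "freq_ratio", "schema_version", "mode", "seed", "config_sha256",
    "package_version",
}

FREE_REPORT_KEYS = {
    "freq_hz": float,
    "x_amplitude_um": float,
    "z_gap_um": float,
    "curvature_radius_um": float,
    "n_cycles": int,
    "L_eff_um": float,
    "L_rec_um": float,
    "maxF_effective_pN": float,
    "maxF_recovery_pN": float,
    "net_flux_um3_s": float,
    "net_flux_um3_cycle": float,
    "sphere_method": str,
}
TRAP_REPORT_KEYS = {
    "z_amp_nm": float,
    "maxF_z_pN": float,
    "maxF_x_pN": float,
    "freq_trapped_hz": float,
    "peaks_per_cycle": int,
}


def validate_report(report: dict) -> None:
    """Check report structure: version, provenance, units-suffixed keys."""
    if report.get("schema_version") != SCHEMA_VERSION:
        raise FormatError("report missing or wrong schema_version")
    mode = report.get("mode")
    if mode not in ("analyze-free", "analyze-trap"):
        raise FormatError(f"unknown report mode {mode!r}")
    prov = report.get("provenance")
    if not isinstance(prov, dict) or not {"config_sha256", "seed", "package_version"} <= set(prov):
        raise FormatError("report missing provenance block")
    required = FREE_REPORT_KEYS if mode == "analyze-free" else TRAP_REPORT_KEYS
    for key, typ in required.items():
        if key not in report:
            raise FormatError(f"report missing key {key}")
        if typ in (float, int) and not isinstance(report[key], (int, float)):
            raise FormatError(f"report key {key} must be numeric")
    for key, value in report.items():
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            continue
        if key in UNITLESS_KEYS:
            continue
        if not key.lower().endswith(tuple(s.lower() for s in UNIT_SUFFIXES)):
            raise FormatError(f"numeric report key {key!r} lacks a units suffix")


def write_report(report: dict, path) -> None:
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    report = json.loads(Path(path).read_text())
    validate_report(report)
    return report
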