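"""Time-stamped 3-D tip trajectories.

The :class:`Trajectory` is the package's central in-memory container: time in
seconds, coordinates in micrometres.  Both the synthetic generator and the
split-image tracker produce it, and all kinematic/hydrodynamic analyses
consume it.  Alignment metadata (in-plane rotation, flip) is attached by
:func:`ciliatip.kinematics.align_axes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError

#: canonical per-sample phase labels
PHASE_EFFECTIVE = "effective"
PHASE_RECOVERY = "recovery"
PHASE_PAUSE = "pause"


@dataclass
class Trajectory:
    """3-D bead/tip positions sampled at (near-)uniform rate.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing.
    x, y, z : ndarray
        Coordinates in micrometres.
    sample_rate_hz : float, optional
        Nominal acquisition rate; inferred from ``t`` when omitted.
    phase : ndarray of str, optional
        Per-sample stroke labels (``effective``/``recovery``/``pause``).
    quality : ndarray of bool, optional
        ``False`` marks interpolated (failed-localization) samples.
    rotation_deg, flip_applied
        Set by ``align_axes``; ``None`` for raw trajectories.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate_hz: Optional[float] = None
    phase: Optional[np.ndarray] = None
    quality: Optional[np.ndarray] = None
    rotation_deg: Optional[float] = None
    flip_applied: Optional[bool] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.t.size
        if not (self.x.size == self.y.size == self.z.size == n):
            raise ParameterError("t, x, y, z must have equal length")
        if n == 0:
            raise ParameterError("empty trajectory")
        if not np.all(np.isfinite(self.t)):
            raise ParameterError("non-finite sample times")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ParameterError("sample times must be strictly increasing")
        if self.phase is not None:
            self.phase = np.asarray(self.phase)
            if self.phase.size != n:
                raise ParameterError("phase labels must match trajectory length")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=bool)
            if self.quality.size != n:
                raise ParameterError("quality flags must match trajectory length")
        if self.sample_rate_hz is None and n > 1:
            self.sample_rate_hz = float(1.0 / np.median(np.diff(self.t)))

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of xyz positions in micrometres."""
        return np.column_stack([self.x, self.y, self.z])

    @property
    def is_aligned(self) -> bool:
        return self.rotation_deg is not None

    # -- transforms -------------------------------------------------------
    def copy(self) -> "Trajectory":
        return replace(
            self,
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            z=self.z.copy(),
            phase=None if self.phase is None else self.phase.copy(),
            quality=None if self.quality is None else self.quality.copy(),
            meta=dict(self.meta),
        )

    def with_positions(self, xyz: np.ndarray) -> "Trajectory":
        out = self.copy()
        out.x, out.y, out.z = xyz[:, 0].copy(), xyz[:, 1].copy(), xyz[:, 2].copy()
        return out

    def translated(self, offset) -> "Trajectory":
        """Rigidly translate by ``offset`` (3-vector, micrometres)."""
        off = np.asarray(offset, dtype=float)
        return self.with_positions(self.positions + off[None, :])

    def rotated_z(self, angle_deg: float) -> "Trajectory":
        """Rotate about the optical (z) axis by ``angle_deg``."""
        a = np.deg2rad(angle_deg)
        c, s = np.cos(a), np.sin(a)
        out = self.copy()
        out.x = c * self.x - s * self.y
        out.y = s * self.x + c * self.y
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_s": self.t, "x_um": self.x, "y_um": self.y, "z_um": self.z})
        if self.phase is not None:
            df["phase"] = self.phase
        if self.quality is not None:
            df["quality"] = self.quality.astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "Trajectory":
        phase = df["phase"].to_numpy() if "phase" in df.columns else None
        quality = df["quality"].to_numpy().astype(bool) if "quality" in df.columns else None
        return cls(
            t=df["t_s"].to_numpy(),
            x=df["x_um"].to_numpy(),
            y=df["y_um"].to_numpy(),
            z=df["z_um"].to_numpy(),
            phase=phase,
            quality=quality,
            **kwargs,
        )
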