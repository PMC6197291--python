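"""Split-beam image stacks: in-memory container and TIFF round trip.

A stack holds one frame per trajectory sample.  Each frame carries two images
of the same bead (the two split-beam channels); the half-difference of their
x-positions encodes the axial coordinate.  Stacks are written as multi-page
16-bit grayscale TIFF with a JSON sidecar holding the optics parameters,
sample times and the coordinate mapping.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .errors import FormatError


@dataclass
class ImageStack:
    """Multi-frame image stack plus acquisition metadata.

    ``origin_um`` maps pixel coordinates to physical coordinates:
    ``x_um = x_px * pixel_size_um + origin_um[0]`` (same for y).
    ``z_ref_um`` is the axial position at which the split half-difference
    equals its calibration intercept (the nominal focal plane).
    """

    frames: np.ndarray  # (n, h, w)
    times: np.ndarray  # (n,) seconds
    optics: "object"  # OpticsParams (kept loose to avoid circular import)
    origin_um: tuple = (0.0, 0.0)
    z_ref_um: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


def write_stack(stack: ImageStack, path) -> None:
    """Write a multi-page 16-bit TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    frames = np.clip(np.rint(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = {
        "optics": dataclasses.asdict(stack.optics),
        "times_s": stack.times.tolist(),
        "origin_um": list(stack.origin_um),
        "z_ref_um": stack.z_ref_um,
        "meta": {k: v for k, v in stack.meta.items() if _json_safe(v)},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_stack(path) -> ImageStack:
    """Read a TIFF stack written by :func:`write_stack`."""
    from .synth import OpticsParams  # deferred: synth imports this module

    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    return ImageStack(
        frames=np.asarray(frames, dtype=float),
        times=np.asarray(sidecar["times_s"], dtype=float),
        optics=OpticsParams(**sidecar["optics"]),
        origin_um=tuple(sidecar.get("origin_um", (0.0, 0.0))),
        z_ref_um=float(sidecar.get("z_ref_um", 0.0)),
        meta=sidecar.get("meta", {}),
    )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def render_spot(shape, center, sigma, flux, offset=0.0) -> np.ndarray:
    """Pixel-integrated 2-D Gaussian spot.

    Pixel ``(r, c)`` covers ``[c-0.5, c+0.5] x [r-0.5, r+0.5]`` so integer
    coordinates address pixel centres.  ``flux`` is the total photon count of
    the spot; the returned image holds expected photons per pixel.
    """
    from scipy.special import erf

    h, w = shape
    cx, cy = center
    s = np.sqrt(2.0) * sigma
    xs = np.arange(w)
    ys = np.arange(h)
    fx = 0.5 * (erf((xs + 0.5 - cx) / s) - erf((xs - 0.5 - cx) / s))
    fy = 0.5 * (erf((ys + 0.5 - cy) / s) - erf((ys - 0.5 - cy) / s))
    return offset + flux * np.outer(fy, fx)
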