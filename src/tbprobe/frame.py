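"""Retroauricular anatomical coordinate system and probe grid.

The frame originates at the most superior point of Henle's spine.  Two
points along the center of the zygomatic process set the x-axis (pointing
posteriorly across the retroauricular region); the y-axis is the axial
(transversal) image-plane normal, pointing superiorly; the z-axis points
laterally, away from the head.  Probe positions form a regular grid in
the frame's x/y-plane (default 8x8, 5 mm spacing, lower anterior corner
at x = 4 mm, y = -10 mm, covering 35 x 35 mm^2).
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RetroauricularFrame", "ProbeGrid", "build_frame", "make_grid",
           "load_landmarks"]

DEFAULT_GRID_N = 8
DEFAULT_GRID_SPACING_MM = 5.0
DEFAULT_GRID_CORNER_MM = (4.0, -10.0)


@dataclass
class RetroauricularFrame:
    origin: np.ndarray
    x_axis: np.ndarray  # posterior
    y_axis: np.ndarray  # superior (axial-plane normal)
    z_axis: np.ndarray  # lateral (away from the head on the probed side)
    side: str = "left"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        for name in ("x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be unit length")
            setattr(self, name, v)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")

    @property
    def rotation(self) -> np.ndarray:
        """Columns are the frame axes expressed in scanner coordinates."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (self.rotation.T @ (points - self.origin).T).T.reshape(points.shape)

    def to_physical(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return (self.origin + (self.rotation @ coords.T).T).reshape(coords.shape)


@dataclass
class ProbeGrid:
    nx: int
    ny: int
    spacing: float
    corner: tuple[float, float]
    points: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        cx, cy = self.corner
        # anterior->posterior (x fastest), then inferior->superior (y)
        pts = [(cx + i * self.spacing, cy + j * self.spacing)
               for j in range(self.ny) for i in range(self.nx)]
        self.points = np.asarray(pts, dtype=float)

    @property
    def extent(self) -> tuple[float, float]:
        return ((self.nx - 1) * self.spacing, (self.ny - 1) * self.spacing)


def _normalize(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"{what} has zero length")
    return v / n


def build_frame(henle, zyg_a, zyg_b, axial_normal=(0.0, 0.0, 1.0),
                side: str = "left", posterior_hint=None) -> RetroauricularFrame:
    """Construct the retroauricular frame from three landmarks.

    Parameters
    ----------
    henle
        Most superior point of Henle's spine (scanner mm); frame origin.
    zyg_a, zyg_b
        Two points along the center of the zygomatic process.  Their
        difference ``zyg_b - zyg_a``, projected onto the axial plane, sets
        the x-axis; pass the anterior point first so +x points posteriorly,
        or supply ``posterior_hint``.
    axial_normal
        Normal of the transversal (axial) image plane, pointing superiorly.
    side
        ``"left"`` or ``"right"`` ear; the z-axis is flipped as needed so
        it always points laterally, letting both sides share one grid.
    posterior_hint
        Optional scanner-space point known to lie posterior to Henle's
        spine (e.g. the ROI center); fixes the x-axis sign regardless of
        landmark order.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    henle = np.asarray(henle, dtype=float)
    y = _normalize(axial_normal, "axial_normal")
    d = np.asarray(zyg_b, dtype=float) - np.asarray(zyg_a, dtype=float)
    if np.linalg.norm(d) < 1e-12:
        raise ValueError("zygomatic landmarks coincide")
    x = d - (d @ y) * y
    if np.linalg.norm(x) < 1e-9 * np.linalg.norm(d):
        raise ValueError("zygomatic direction is parallel to the axial normal "
                         "(degenerate projection)")
    x = _normalize(x, "x_axis")
    if posterior_hint is not None:
        if (np.asarray(posterior_hint, dtype=float) - henle) @ x < 0:
            x = -x
    z = np.cross(x, y)
    if side == "right":
        z = -z  # mirror so +z stays lateral while +x stays posterior
    return RetroauricularFrame(origin=henle, x_axis=x, y_axis=y, z_axis=z, side=side)


def make_grid(frame: RetroauricularFrame, nx: int = DEFAULT_GRID_N,
              ny: int = DEFAULT_GRID_N, spacing: float = DEFAULT_GRID_SPACING_MM,
              corner: tuple[float, float] = DEFAULT_GRID_CORNER_MM) -> ProbeGrid:
    """Regular probe grid in the frame's x/y-plane (frame mm coordinates)."""
    del frame  # grid lives in frame coordinates; kept for call-site clarity
    return ProbeGrid(nx=int(nx), ny=int(ny), spacing=float(spacing),
                     corner=(float(corner[0]), float(corner[1])))


def load_landmarks(path: str | os.PathLike) -> dict:
    """Read landmarks from JSON or a 3-row CSV.

    JSON: either ``{"henle": [x,y,z], "zygoma_anterior": [...],
    "zygoma_posterior": [...], "side": "left", "axial_normal": [...]}``
    or a list of ``{"name":..., "x":..., "y":..., "z":...}`` records.
    CSV: rows named henle, zygoma_anterior, zygoma_posterior with columns
    name,x,y,z.
    """
    path = os.fspath(path)
    out: dict = {}
    if str(path).endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        if isinstance(payload, list):
            for rec in payload:
                out[rec["name"]] = np.array([rec["x"], rec["y"], rec["z"]], float)
        else:
            for key, val in payload.items():
                out[key] = (np.asarray(val, dtype=float)
                            if isinstance(val, (list, tuple)) else val)
    else:
        with open(path) as fh:
            for row in csv.DictReader(fh):
                out[row["name"]] = np.array(
                    [row["x"], row["y"], row["z"]], dtype=float)
    required = {"henle", "zygoma_anterior", "zygoma_posterior"}
    missing = required - out.keys()
    if missing:
        raise ValueError(f"landmark file is missing {sorted(missing)}")
    return out
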