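"""Surface-normal probing: trajectory projection, sampling, thickness and
cortical density.

Each grid point is cast medially (along the frame's -z axis) onto the
outer bone mesh.  From the entry triangle, a trajectory follows the
inward surface normal; radiodensity is sampled every 0.15 mm.  The
temporal bone thickness d_TB is the distance to the last mesh
intersection on the opposite surface, capped at 18 mm.  The external
cortical density is the mean HU over a 1.5 mm window starting at the
first sample of at least 1000 HU.

Ray-mesh intersection is a vectorized Moller-Trumbore test over all
triangles; meshes at this resolution are small enough that no broadphase
acceleration structure is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .frame import ProbeGrid, RetroauricularFrame
from .segmentation import BoneMesh
from .volume_io import CTVolume

__all__ = ["ProbeProfile", "project_probe", "sample_profile", "thickness",
           "cortical_density", "probe_point", "probe_grid"]

log = logging.getLogger(__name__)

DELTA_D_MM = 0.15
D_MAX_MM = 18.0
CORTICAL_ONSET_HU = 1000.0
CORTICAL_WINDOW_MM = 1.5

_EPS = 1e-9


@dataclass
class ProbeProfile:
    """One probe trajectory and its derived measurements."""

    grid_xy: tuple[float, float]
    status: str  # "ok", "no_intersection" or "no_cortex"
    entry_point: np.ndarray | None = None
    direction: np.ndarray | None = None
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    delta_d: float = DELTA_D_MM
    d_tb: float = float("nan")
    cortical_hu: float = float("nan")

    @property
    def depths(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.delta_d


def _moller_trumbore(triangles: np.ndarray, origin: np.ndarray,
                     direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distances t and triangle indices of all ray hits (t can be negative)."""
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    p = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, det, 1.0)
    s = origin - v0
    u = np.einsum("ij,ij->i", s, p) / inv
    q = np.cross(s, e1)
    v = (q @ direction) / inv
    t = np.einsum("ij,ij->i", e2, q) / inv
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol)
    return t[hit], np.nonzero(hit)[0]


def _ray_hits(mesh: BoneMesh, origin, direction):
    tris = mesh.vertices[mesh.triangles]
    return _moller_trumbore(tris, np.asarray(origin, float),
                            np.asarray(direction, float))


def project_probe(grid_point, mesh: BoneMesh, frame: RetroauricularFrame):
    """Cast a grid point medially onto the mesh.

    Returns ``(entry_point, direction)`` where ``direction`` is the inward
    unit normal of the first triangle hit, or ``None`` if the ray misses.
    """
    if len(mesh) == 0:
        raise ValueError("mesh is empty")
    gx, gy = float(grid_point[0]), float(grid_point[1])
    # start laterally outside the mesh, cast along -z (medially)
    z0 = float(np.max((mesh.vertices - frame.origin) @ frame.z_axis)) + 1.0
    origin = frame.to_physical(np.array([gx, gy, z0]))
    ray_dir = -frame.z_axis
    t, tri_idx = _ray_hits(mesh, origin, ray_dir)
    fwd = t > _EPS
    if not np.any(fwd):
        return None
    first = np.argmin(t[fwd])
    t_hit = t[fwd][first]
    tri = tri_idx[fwd][first]
    entry = origin + t_hit * ray_dir
    direction = -mesh.face_normals[tri]  # inward
    if direction @ ray_dir < 0:
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    return entry, direction


def thickness(mesh: BoneMesh, entry_point, direction,
              d_max: float = D_MAX_MM) -> float:
    """Distance from entry to the last mesh intersection along the inward
    normal, clamped to ``d_max``.

    Internal cavity surfaces crossed by the ray are ignored: the farthest
    intersection defines the opposite cortex.  If the ray never exits
    (open or sideways geometry) the thickness is reported at the cap with
    a warning, rather than discarding the probe.
    """
    t, _ = _ray_hits(mesh, entry_point, direction)
    t = t[t > 1e-6]
    if t.size == 0:
        log.warning("probe at %s found no opposite surface; thickness capped "
                    "at %.1f mm", np.round(entry_point, 2), d_max)
        return float(d_max)
    return float(min(t.max(), d_max))


def sample_profile(volume: CTVolume, entry_point, direction,
                   delta_d: float = DELTA_D_MM, d_max: float = D_MAX_MM,
                   interpolation: str = "linear") -> np.ndarray:
    """Radiodensity samples at ``entry + k * delta_d * direction``.

    Sampling stops at ``d_max`` or at the volume boundary, whichever comes
    first.  Values are interpolated (trilinear by default; ``"nearest"``
    reads the enclosing voxel).
    """
    entry_point = np.asarray(entry_point, dtype=float)
    if not volume.contains(entry_point):
        raise ValueError("trajectory entry point lies outside the volume")
    n = int(np.floor(d_max / delta_d + _EPS)) + 1
    depths = np.arange(n) * delta_d
    pts = entry_point[None, :] + depths[:, None] * np.asarray(direction, float)
    inside = volume.contains(pts)
    if not inside.all():
        n = int(np.argmin(inside))  # truncate at first exit
        pts = pts[:n]
    return volume.interp(pts, method=interpolation)


def cortical_density(samples, delta_d: float = DELTA_D_MM,
                     onset_hu: float = CORTICAL_ONSET_HU,
                     window_mm: float = CORTICAL_WINDOW_MM) -> float | None:
    """Mean HU over ``[onset, onset + window_mm]`` (ends inclusive), where
    onset is the depth of the first sample >= ``onset_hu``.

    Returns ``None`` when no sample reaches the onset threshold.  The mean
    is taken on raw HU; density conversion applies to the result.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty profile")
    above = np.nonzero(samples >= onset_hu)[0]
    if above.size == 0:
        return None
    start = int(above[0])
    span = int(np.floor(window_mm / delta_d + _EPS))
    return float(samples[start:start + span + 1].mean())


def probe_point(volume: CTVolume, mesh: BoneMesh, frame: RetroauricularFrame,
                grid_xy, *, delta_d: float = DELTA_D_MM,
                d_max: float = D_MAX_MM, onset_hu: float = CORTICAL_ONSET_HU,
                window_mm: float = CORTICAL_WINDOW_MM,
                interpolation: str = "linear") -> ProbeProfile:
    """Full per-probe evaluation: projection, thickness, profile, cortex."""
    gx, gy = float(grid_xy[0]), float(grid_xy[1])
    hit = project_probe((gx, gy), mesh, frame)
    if hit is None:
        return ProbeProfile(grid_xy=(gx, gy), status="no_intersection",
                            delta_d=delta_d)
    entry, direction = hit
    d_tb = thickness(mesh, entry, direction, d_max=d_max)
    samples = sample_profile(volume, entry, direction, delta_d=delta_d,
                             d_max=min(d_tb, d_max),
                             interpolation=interpolation)
    cort = cortical_density(samples, delta_d, onset_hu=onset_hu,
                            window_mm=window_mm)
    status = "ok" if cort is not None else "no_cortex"
    return ProbeProfile(grid_xy=(gx, gy), status=status, entry_point=entry,
                        direction=direction, samples=samples, delta_d=delta_d,
                        d_tb=d_tb,
                        cortical_hu=cort if cort is not None else float("nan"))


def probe_grid(volume: CTVolume, mesh: BoneMesh, frame: RetroauricularFrame,
               grid: ProbeGrid, **kwargs) -> list[ProbeProfile]:
    """Evaluate every grid position; misses are reported via status."""
    return [probe_point(volume, mesh, frame, xy, **kwargs) for xy in grid.points]
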