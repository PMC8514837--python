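"""Synthetic CT phantoms with analytic ground truth.

Two families make the whole pipeline testable without clinical data:

* **layered slabs** — stacks of uniform-HU layers (cortex over trabecular
  bone over cortex, etc.) embedded in air, optionally pneumatized with
  spherical air cells emulating mastoid cells, probed perpendicular to
  the outer surface;
* **the six-insert density calibration phantom** — cylinders of known
  hydroxyapatite density (0, 100, 200, 400, 600, 800 mg HA/cm^3) in a
  water background, imaged through a known linear HU response.

Conventions: air is -1000 HU, water 0 HU, mastoid air cells -800 HU
(aerated, mucosa-lined).  Noise is additive Gaussian on HU, seeded;
identical spec + seed yields a bitwise-identical volume.  Layer
boundaries snap to voxel boundaries and the ground truth records the
*realized* (snapped) geometry.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, hu_to_bmd
from .frame import RetroauricularFrame, build_frame
from .volume_io import CTVolume

__all__ = ["PhantomSpec", "SlabGroundTruth", "generate_slab",
           "generate_calibration", "INSERT_DENSITIES", "AIR_HU", "WATER_HU",
           "AIR_CELL_HU", "CLINICAL_SPACING_MM"]

AIR_HU = -1000.0
WATER_HU = 0.0
AIR_CELL_HU = -800.0

#: Voxel spacing of the clinical high-resolution protocol (mm).
CLINICAL_SPACING_MM = (0.156, 0.156, 0.2)

#: Hydroxyapatite densities of the calibration phantom inserts (mg HA/cm^3).
INSERT_DENSITIES = (0.0, 100.0, 200.0, 400.0, 600.0, 800.0)


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic volume."""

    kind: str  # "slab", "layered_slab" or "calibration"
    size_mm: tuple[float, float, float]
    spacing_mm: tuple[float, float, float] = CLINICAL_SPACING_MM
    layers: list[tuple[float, float]] = field(default_factory=list)
    lateral_margin_mm: float = 3.0
    air_cell_radius_mm: float = 1.0
    air_cell_fraction: float = 0.0
    insert_radius_mm: float = 4.0
    noise_sd_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("slab", "layered_slab", "calibration"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if any(s <= 0 for s in self.size_mm) or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("size and spacing must be positive")
        if any(t <= 0 for t, _ in self.layers):
            raise ValueError("layer thicknesses must be positive")
        if not (0 <= self.air_cell_fraction < 1):
            raise ValueError("air_cell_fraction must lie in [0, 1)")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(s / d))
                     for s, d in zip(self.size_mm, self.spacing_mm))

    @classmethod
    def from_dict(cls, payload: dict) -> "PhantomSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown phantom spec fields: {sorted(unknown)}")
        if "kind" not in payload:
            raise ValueError("phantom spec is missing required field 'kind'")
        if "size_mm" not in payload:
            raise ValueError("phantom spec is missing required field 'size_mm'")
        if payload["kind"] in ("slab", "layered_slab") and not payload.get("layers"):
            raise ValueError("phantom spec is missing required field 'layers'")
        kw = dict(payload)
        kw["size_mm"] = tuple(kw["size_mm"])
        if "spacing_mm" in kw:
            kw["spacing_mm"] = tuple(kw["spacing_mm"])
        if "layers" in kw:
            kw["layers"] = [tuple(l) for l in kw["layers"]]
        return cls(**kw)


@dataclass
class SlabGroundTruth:
    """Analytic truth for a generated slab, for perpendicular probes.

    Depth is measured medially from the outer (lateral) slab surface in
    mm; the analytic HU profile is piecewise constant over the realized
    layers.
    """

    layers: list[tuple[float, float]]  # realized (thickness_mm, hu), outer first
    total_thickness_mm: float
    surface_z_mm: float
    center_xy_mm: tuple[float, float]
    lateral_halfwidth_mm: tuple[float, float]
    frame: RetroauricularFrame

    @property
    def landmarks(self) -> dict:
        """Scanner-space landmark set reproducing :attr:`frame` via
        :func:`tbprobe.frame.build_frame` (synthetic stand-ins for
        Henle's spine and the zygomatic-process points)."""
        cx, cy = self.center_xy_mm
        o = np.array([cx, cy, self.surface_z_mm])
        return {
            "henle": o,
            "zygoma_anterior": o + np.array([-12.0, 0.0, 0.0]),
            "zygoma_posterior": o + np.array([-4.0, 0.0, 0.0]),
            "axial_normal": np.array([0.0, 1.0, 0.0]),
            "side": "left",
        }

    def profile_hu(self, depths) -> np.ndarray:
        """Analytic HU at medial depths (mm) below the outer surface."""
        depths = np.asarray(depths, dtype=float)
        out = np.full(depths.shape, AIR_HU)
        top = 0.0
        for t, hu in self.layers:
            sel = (depths >= top - 1e-12) & (depths < top + t - 1e-12)
            out[sel] = hu
            top += t
        return out

    # Analytic counterparts of the pipeline measurements, computed by
    # plain loops on the piecewise-constant profile.
    def expected_thickness(self, d_max: float = 18.0) -> float:
        return min(self.total_thickness_mm, d_max)

    def _samples(self, delta_d: float, d_max: float) -> np.ndarray:
        d_tb = self.expected_thickness(d_max)
        n = int(np.floor(d_tb / delta_d + 1e-9)) + 1
        return self.profile_hu(np.arange(n) * delta_d)

    def expected_cortical_hu(self, delta_d: float = 0.15,
                             onset_hu: float = 1000.0,
                             window_mm: float = 1.5,
                             d_max: float = 18.0) -> float | None:
        samples = self._samples(delta_d, d_max)
        start = None
        for i, v in enumerate(samples):
            if v >= onset_hu:
                start = i
                break
        if start is None:
            return None
        span = int(np.floor(window_mm / delta_d + 1e-9))
        window = samples[start:start + span + 1]
        return float(np.mean(window))

    def expected_sisi(self, d_min: float, delta_d: float = 0.15,
                      dense_hu: float = 1000.0, d_max: float = 18.0) -> float:
        if self.expected_thickness(d_max) <= d_min:
            return 0.0
        samples = self._samples(delta_d, d_max)
        n = n_dense = 0
        for i, v in enumerate(samples):
            if i * delta_d <= d_min + 1e-9:
                n += 1
                if v >= dense_hu:
                    n_dense += 1
        return 100.0 * n_dense / n

    def expected_codi(self, model: CalibrationModel, delta_d: float = 0.15,
                      d_max: float = 18.0) -> float:
        total = 0.0
        for v in self._samples(delta_d, d_max):
            total += hu_to_bmd(model, float(v)) / 1000.0 * delta_d
        return total

    def to_dict(self) -> dict:
        return {
            "layers_mm_hu": [list(l) for l in self.layers],
            "total_thickness_mm": self.total_thickness_mm,
            "surface_z_mm": self.surface_z_mm,
            "center_xy_mm": list(self.center_xy_mm),
            "lateral_halfwidth_mm": list(self.lateral_halfwidth_mm),
            "landmarks": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                          for k, v in self.landmarks.items()},
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def generate_slab(spec: PhantomSpec) -> tuple[CTVolume, SlabGroundTruth]:
    """Layered bone slab in air, outer surface facing +z (lateral).

    Layers are listed outer (lateral) to inner (medial).  Layers below
    1000 HU are treated as trabecular and receive spherical air cells
    when ``air_cell_fraction`` > 0, carved until the sub-1000-HU volume
    fraction reaches the target.
    """
    if spec.kind not in ("slab", "layered_slab"):
        raise ValueError(f"generate_slab needs a slab spec, got {spec.kind!r}")
    if not spec.layers:
        raise ValueError("slab spec has no layers")
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing_mm
    rng = np.random.default_rng(spec.seed)

    n_layer = [max(1, int(round(t / sz))) for t, _ in spec.layers]
    n_bone = sum(n_layer)
    if n_bone + 2 > nz:
        raise ValueError("layers thicker than the volume allows (need >= 1 "
                         "voxel of air margin on both z sides)")
    realized = [(n * sz, hu) for n, (_, hu) in zip(n_layer, spec.layers)]
    total = sum(t for t, _ in realized)

    data = np.full((nx, ny, nz), AIR_HU, dtype=np.float32)
    mx = min(int(round(spec.lateral_margin_mm / sx)), (nx - 2) // 2)
    my = min(int(round(spec.lateral_margin_mm / sy)), (ny - 2) // 2)
    x0, x1 = mx, nx - mx
    y0, y1 = my, ny - my

    n_top = (nz - n_bone) // 2
    k_hi = nz - 1 - n_top          # outermost (lateral) bone voxel plane
    k = k_hi
    layer_slices = []
    for n_vox, (_, hu) in zip(n_layer, spec.layers):
        sl = slice(k - n_vox + 1, k + 1)
        data[x0:x1, y0:y1, sl] = hu
        layer_slices.append(sl)
        k -= n_vox

    if spec.air_cell_fraction > 0:
        r_vox = np.asarray(spec.air_cell_radius_mm) / np.array([sx, sy, sz])
        for sl, (_, hu) in zip(layer_slices, spec.layers):
            if hu >= 1000.0:
                continue
            _carve_air_cells(data, rng, (x0, x1), (y0, y1), sl, r_vox,
                             spec.air_cell_fraction)

    if spec.noise_sd_hu > 0:
        data += rng.normal(0.0, spec.noise_sd_hu, size=data.shape).astype(np.float32)

    volume = CTVolume(data, np.array([sx, sy, sz]))
    surface_z = (k_hi + 0.5) * sz
    cx, cy = (nx - 1) * sx / 2.0, (ny - 1) * sy / 2.0
    gt = SlabGroundTruth(
        layers=realized,
        total_thickness_mm=total,
        surface_z_mm=surface_z,
        center_xy_mm=(cx, cy),
        lateral_halfwidth_mm=((x1 - x0) * sx / 2.0, (y1 - y0) * sy / 2.0),
        frame=None,  # type: ignore[arg-type]
    )
    lm = gt.landmarks
    gt.frame = build_frame(lm["henle"], lm["zygoma_anterior"],
                           lm["zygoma_posterior"], lm["axial_normal"],
                           side=lm["side"])
    return volume, gt


def _carve_air_cells(data, rng, xr, yr, z_slice, r_vox, fraction,
                     max_iter: int = 20000) -> None:
    """Carve -800 HU spheres into a layer until the sub-1000-HU fraction
    inside the layer reaches ``fraction``."""
    x0, x1 = xr
    y0, y1 = yr
    region = data[x0:x1, y0:y1, z_slice]
    n_total = region.size
    ii, jj, kk = np.meshgrid(np.arange(region.shape[0]),
                             np.arange(region.shape[1]),
                             np.arange(region.shape[2]), indexing="ij")
    carved = np.zeros(region.shape, dtype=bool)
    for _ in range(max_iter):
        if carved.sum() / n_total >= fraction:
            break
        c = rng.uniform([0, 0, 0], region.shape)
        d2 = (((ii - c[0]) / r_vox[0]) ** 2 + ((jj - c[1]) / r_vox[1]) ** 2
              + ((kk - c[2]) / r_vox[2]) ** 2)
        carved |= d2 <= 1.0
    region[carved] = AIR_CELL_HU
    data[x0:x1, y0:y1, z_slice] = region


def generate_calibration(spec: PhantomSpec, slope: float = 1.32,
                         intercept: float = 0.0
                         ) -> tuple[CTVolume, pd.DataFrame]:
    """Six-insert density phantom in water with linear HU response.

    Returns the volume and the measured insert table — one row per
    insert with its known density and the mean HU observed over the
    insert voxels — ready for :func:`tbprobe.calibration.fit_calibration`.
    """
    if spec.kind != "calibration":
        raise ValueError(f"generate_calibration needs kind='calibration', "
                         f"got {spec.kind!r}")
    if slope <= 0:
        raise ValueError("slope must be positive")
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing_mm
    rng = np.random.default_rng(spec.seed)

    data = np.full((nx, ny, nz), WATER_HU, dtype=np.float32)
    xs = (np.arange(nx) + 0.5) * sx
    ys = (np.arange(ny) + 0.5) * sy
    # 3 x 2 insert lattice centered in-plane
    cx = np.array([1, 3, 5]) / 6.0 * nx * sx
    cy = np.array([1, 2]) / 3.0 * ny * sy
    centers = [(a, b) for b in cy for a in cx]
    r = spec.insert_radius_mm
    masks = []
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    for (a, b), dens in zip(centers, INSERT_DENSITIES):
        m2d = (X - a) ** 2 + (Y - b) ** 2 <= r * r
        mask = np.repeat(m2d[:, :, None], nz, axis=2)
        data[mask] = slope * dens + intercept
        masks.append(mask)
    if spec.noise_sd_hu > 0:
        data += rng.normal(0.0, spec.noise_sd_hu, size=data.shape).astype(np.float32)

    rows = [{"density_mg_ha_cm3": dens, "mean_hu": float(data[mask].mean()),
             "n_voxels": int(mask.sum())}
            for dens, mask in zip(INSERT_DENSITIES, masks)]
    table = pd.DataFrame(rows)
    volume = CTVolume(data, np.array([sx, sy, sz]))
    return volume, table
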