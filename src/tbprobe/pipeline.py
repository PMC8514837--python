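"""End-to-end orchestration: segment -> frame -> probe -> indices -> table."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import indices, probing, segmentation
from .calibration import CalibrationModel, hu_to_bmd
from .frame import (DEFAULT_GRID_CORNER_MM, DEFAULT_GRID_N,
                    DEFAULT_GRID_SPACING_MM, ProbeGrid, RetroauricularFrame,
                    make_grid)
from .volume_io import CTVolume

__all__ = ["RunConfig", "run_probe_grid", "profiles_to_table"]


@dataclass
class RunConfig:
    """Numeric parameters of a probing run; defaults are the clinical
    protocol values."""

    threshold_hu: float = segmentation.DEFAULT_THRESHOLD_HU
    min_island_voxels: int = segmentation.DEFAULT_MIN_ISLAND_VOXELS
    smoothing_mm: float = segmentation.DEFAULT_SMOOTHING_MM
    grid_nx: int = DEFAULT_GRID_N
    grid_ny: int = DEFAULT_GRID_N
    grid_spacing_mm: float = DEFAULT_GRID_SPACING_MM
    grid_corner_mm: tuple[float, float] = DEFAULT_GRID_CORNER_MM
    delta_d_mm: float = probing.DELTA_D_MM
    d_max_mm: float = probing.D_MAX_MM
    onset_hu: float = probing.CORTICAL_ONSET_HU
    window_mm: float = probing.CORTICAL_WINDOW_MM
    d_min_mm: tuple[float, ...] = indices.DEFAULT_D_MIN_MM
    interpolation: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("smoothing_mm",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("grid_nx", "grid_ny", "grid_spacing_mm", "delta_d_mm",
                     "d_max_mm", "window_mm", "min_island_voxels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(d <= 0 for d in self.d_min_mm):
            raise ValueError("d_min values must be positive")
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError("interpolation must be 'linear' or 'nearest'")

    def to_dict(self) -> dict:
        return asdict(self)


def _dmin_col(d_min: float) -> str:
    return "sisi_" + f"{d_min:g}".replace(".", "p") + "mm"


def profiles_to_table(profiles, model: CalibrationModel,
                      d_min_mm=indices.DEFAULT_D_MIN_MM,
                      subject: str = "subject") -> pd.DataFrame:
    """Per-probe records: thickness, cortical density, SISI and CODI.

    Probes that missed the mesh keep their row with empty measurement
    fields (NaN) and a status flag.
    """
    rows = []
    for p in profiles:
        row = {
            "subject": subject,
            "grid_x_mm": p.grid_xy[0],
            "grid_y_mm": p.grid_xy[1],
            "status": p.status,
            "d_tb_mm": np.nan,
            "cortical_hu": np.nan,
            "cortical_bmd_mg_ha_cm3": np.nan,
            "codi_mg_ha_mm2": np.nan,
        }
        for d in d_min_mm:
            row[_dmin_col(d)] = np.nan
        if p.status != "no_intersection":
            row["d_tb_mm"] = p.d_tb
            if np.isfinite(p.cortical_hu):
                row["cortical_hu"] = p.cortical_hu
                row["cortical_bmd_mg_ha_cm3"] = hu_to_bmd(model, p.cortical_hu)
            for d in d_min_mm:
                row[_dmin_col(d)] = indices.sisi(p, d)
            row["codi_mg_ha_mm2"] = indices.codi(p, model)
        rows.append(row)
    return pd.DataFrame(rows)


def run_probe_grid(volume: CTVolume, frame: RetroauricularFrame,
                   model: CalibrationModel, config: RunConfig | None = None,
                   subject: str = "subject",
                   mesh: segmentation.BoneMesh | None = None,
                   grid: ProbeGrid | None = None) -> pd.DataFrame:
    """Run the full pipeline on one volume and return the probe table.

    A pre-built mesh or grid may be injected (e.g. for staged CLI runs);
    otherwise segmentation and grid construction use the config values.
    """
    config = config or RunConfig()
    if mesh is None:
        label = segmentation.label_bone(volume, config.threshold_hu)
        label = segmentation.remove_islands(label, config.min_island_voxels)
        mesh = segmentation.build_mesh(label, config.smoothing_mm)
    if grid is None:
        grid = make_grid(frame, config.grid_nx, config.grid_ny,
                         config.grid_spacing_mm, config.grid_corner_mm)
    profiles = probing.probe_grid(
        volume, mesh, frame, grid,
        delta_d=config.delta_d_mm, d_max=config.d_max_mm,
        onset_hu=config.onset_hu, window_mm=config.window_mm,
        interpolation=config.interpolation)
    return profiles_to_table(profiles, model, config.d_min_mm, subject=subject)
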