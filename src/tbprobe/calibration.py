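"""Hounsfield-unit to bone-mineral-density calibration.

Quantitative CT expresses bone mineral density (BMD) as hydroxyapatite
concentration in mg HA/cm^3, obtained by scanning a phantom with inserts
of known density and fitting the linear relation ``HU = slope * BMD +
intercept``.  Conversion clamps negative HU to zero first, so calibrated
densities are never negative.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CalibrationModel", "fit_calibration", "hu_to_bmd",
           "default_calibration", "read_insert_table"]

log = logging.getLogger(__name__)

#: Published scaling factor between HU and mg HA/cm^3 for the clinical
#: high-resolution temporal-bone protocol; used when no phantom is supplied.
DEFAULT_SLOPE = 1.32


@dataclass
class CalibrationModel:
    """Linear HU <-> BMD map: ``hu = slope * bmd + intercept``."""

    slope: float
    intercept: float = 0.0
    insert_table: list[tuple[float, float]] = field(default_factory=list)
    residuals_hu: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")

    def bmd_to_hu(self, bmd):
        return self.slope * np.asarray(bmd, dtype=float) + self.intercept

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "slope_hu_per_mg_ha_cm3": self.slope,
            "intercept_hu": self.intercept,
            "insert_table": [list(p) for p in self.insert_table],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "CalibrationModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            slope=payload["slope_hu_per_mg_ha_cm3"],
            intercept=payload.get("intercept_hu", 0.0),
            insert_table=[tuple(p) for p in payload.get("insert_table", [])],
        )


def fit_calibration(insert_table) -> CalibrationModel:
    """Ordinary least-squares fit of ``HU = slope * density + intercept``.

    Parameters
    ----------
    insert_table
        Iterable of ``(density_mg_ha_cm3, mean_hu)`` pairs, at least two
        distinct non-negative densities.
    """
    pairs = [(float(d), float(h)) for d, h in insert_table]
    if len(pairs) < 2:
        raise ValueError("calibration needs at least two insert measurements")
    dens = np.array([p[0] for p in pairs])
    hu = np.array([p[1] for p in pairs])
    if np.any(dens < 0):
        raise ValueError("insert densities must be non-negative")
    if np.ptp(dens) == 0:
        raise ValueError("degenerate calibration: all insert densities identical")
    res = stats.linregress(dens, hu)
    model = CalibrationModel(slope=float(res.slope), intercept=float(res.intercept),
                             insert_table=pairs)
    model.residuals_hu = hu - model.bmd_to_hu(dens)
    return model


def hu_to_bmd(model: CalibrationModel, hu):
    """Convert radiodensity (HU) to BMD (mg HA/cm^3).

    Negative HU are clamped to 0 before the linear map and any density
    still negative after the intercept shift is floored at 0, so the
    result is a non-decreasing, non-negative function of HU.  Vectorized.
    """
    hu_arr = np.maximum(np.asarray(hu, dtype=float), 0.0)
    bmd = (hu_arr - model.intercept) / model.slope
    bmd = np.maximum(bmd, 0.0)
    return bmd if np.asarray(hu).ndim else float(bmd)


def default_calibration() -> CalibrationModel:
    """Fallback model (slope 1.32, intercept 0) for uncalibrated scans."""
    log.warning(
        "no calibration phantom supplied: using default slope %.2f HU per mg HA/cm^3, "
        "intercept 0; densities are protocol-approximate", DEFAULT_SLOPE,
    )
    return CalibrationModel(slope=DEFAULT_SLOPE, intercept=0.0)


def read_insert_table(path: str | os.PathLike) -> list[tuple[float, float]]:
    """Read a two-column CSV ``(density_mg_ha_cm3, mean_hu)``."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        d = df[cols["density_mg_ha_cm3"]]
        h = df[cols["mean_hu"]]
    except KeyError as exc:
        raise ValueError(
            "calibration CSV needs columns 'density_mg_ha_cm3' and 'mean_hu'"
        ) from exc
    return list(zip(d.astype(float), h.astype(float)))
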