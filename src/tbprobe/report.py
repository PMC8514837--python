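"""Cohort aggregation over the probe grid and heat-map rendering.

Per-subject probe tables are averaged cell by cell; cells where no
subject produced a valid measurement stay missing (never zero-filled)
and are hatched in the rendered maps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

__all__ = ["GridSummary", "aggregate", "render_heatmap"]


@dataclass
class GridSummary:
    """Per-grid-cell mean/SD/count of one probe measure across subjects."""

    measure: str
    grid_x: np.ndarray          # sorted unique x coordinates (mm)
    grid_y: np.ndarray          # sorted unique y coordinates (mm)
    mean: np.ndarray            # (ny, nx); NaN where no valid probe
    sd: np.ndarray              # (ny, nx); ddof=1, NaN for n < 2
    count: np.ndarray           # (ny, nx) int

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for j, y in enumerate(self.grid_y):
            for i, x in enumerate(self.grid_x):
                recs.append({"grid_x_mm": x, "grid_y_mm": y,
                             "mean": self.mean[j, i], "sd": self.sd[j, i],
                             "n": int(self.count[j, i])})
        return pd.DataFrame(recs)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="")


def _grid_key(table: pd.DataFrame) -> np.ndarray:
    return np.unique(table[["grid_x_mm", "grid_y_mm"]].to_numpy(float), axis=0)


def aggregate(tables: Sequence[pd.DataFrame], measure: str) -> GridSummary:
    """Cell-wise mean/SD/count of ``measure`` over subjects.

    All tables must share the same grid geometry; rows whose measure is
    missing (NaN) are ignored in that cell's statistics.
    """
    if not tables:
        raise ValueError("no tables to aggregate")
    key = _grid_key(tables[0])
    for t in tables[1:]:
        if not np.array_equal(_grid_key(t), key):
            raise ValueError("probe tables have mismatched grid geometry")
    if measure not in tables[0].columns:
        raise ValueError(f"measure {measure!r} not found in probe tables")

    gx = np.unique(key[:, 0])
    gy = np.unique(key[:, 1])
    nx, ny = len(gx), len(gy)
    mean = np.full((ny, nx), np.nan)
    sd = np.full((ny, nx), np.nan)
    count = np.zeros((ny, nx), dtype=int)

    pooled = pd.concat(tables, ignore_index=True)
    grouped = pooled.groupby(["grid_x_mm", "grid_y_mm"])[measure]
    stats = grouped.agg(["mean", "std", "count"])
    xi = {x: i for i, x in enumerate(gx)}
    yi = {y: j for j, y in enumerate(gy)}
    for (x, y), row in stats.iterrows():
        i, j = xi[float(x)], yi[float(y)]
        n = int(row["count"])
        count[j, i] = n
        if n >= 1:
            mean[j, i] = row["mean"]
        if n >= 2:
            sd[j, i] = row["std"]
    return GridSummary(measure=measure, grid_x=gx, grid_y=gy,
                       mean=mean, sd=sd, count=count)


def render_heatmap(summary: GridSummary, path: str | os.PathLike,
                   title: str | None = None, units: str = "",
                   cmap: str = "viridis"):
    """Render the per-cell means as a raster heat map (PNG or SVG).

    Axes are frame coordinates (x posterior and y superior from Henle's
    spine, mm) with ticks at the probe positions; missing cells are
    hatched grey.  Returns the matplotlib Figure (also saved to ``path``).
    """
    if summary.mean.size == 0:
        raise ValueError("empty grid summary")
    gx, gy = summary.grid_x, summary.grid_y
    dx = gx[1] - gx[0] if len(gx) > 1 else 1.0
    dy = gy[1] - gy[0] if len(gy) > 1 else 1.0
    extent = (gx[0] - dx / 2, gx[-1] + dx / 2, gy[0] - dy / 2, gy[-1] + dy / 2)

    fig = Figure(figsize=(6.0, 5.0))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    masked = np.ma.masked_invalid(summary.mean)
    im = ax.imshow(masked, origin="lower", extent=extent, cmap=cmap,
                   aspect="equal", interpolation="nearest")
    missing = np.ma.masked_where(~masked.mask, np.ones_like(summary.mean))
    if masked.mask.any():
        xe = np.concatenate([gx - dx / 2, [gx[-1] + dx / 2]])
        ye = np.concatenate([gy - dy / 2, [gy[-1] + dy / 2]])
        ax.pcolor(xe, ye, missing, hatch="//", alpha=0.0,
                  edgecolor="0.5", linewidth=0.0)
    ax.set_xticks(gx)
    ax.set_yticks(gy)
    ax.set_xlabel("x, posterior from Henle's spine (mm)")
    ax.set_ylabel("y, superior from Henle's spine (mm)")
    label = summary.measure if not units else f"{summary.measure} ({units})"
    fig.colorbar(im, ax=ax, label=label)
    if title:
        ax.set_title(title)
    fig.savefig(str(path), dpi=150, bbox_inches="tight")
    return fig
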