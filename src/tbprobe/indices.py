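"""Preoperative screw-placement indices.

Two radiographic scores summarize a probe trajectory for surgical
planning:

* **SISI** (Screw Implantation Safety Index, %): for a screw-length
  threshold ``d_min``, the percentage of trajectory samples within
  ``d_min`` whose radiodensity is at least 1000 HU.  Probes with bone
  thickness ``d_TB <= d_min`` score 0 (the screw would breach into soft
  tissue).

* **CODI** (Column Density Index, mg HA/mm^2): the line integral of
  calibrated bone mineral density over the full bone thickness,
  ``sum_i rho(i) * delta_d`` — a column mass per unit area, high where a
  thick and/or dense bone column is available for implant coupling.

Calibrated densities arrive in mg HA/cm^3 and are divided by 1000
(mg HA/mm^3) before multiplying by the sampling step in mm.
"""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationModel, hu_to_bmd
from .probing import ProbeProfile

__all__ = ["sisi", "codi", "DENSE_HU", "DEFAULT_D_MIN_MM"]

DENSE_HU = 1000.0
DEFAULT_D_MIN_MM = (4.0, 5.0)

_EPS = 1e-9


def sisi(profile: ProbeProfile, d_min: float, dense_hu: float = DENSE_HU) -> float:
    """Screw Implantation Safety Index in percent.

    ``0`` when ``d_TB <= d_min``; otherwise ``100 * N_S / N`` where the
    counts run over samples at depth <= ``d_min`` and N_S counts samples
    with HU >= ``dense_hu`` (threshold inclusive).
    """
    if profile.status != "ok" and profile.status != "no_cortex":
        raise ValueError(f"cannot score a probe with status {profile.status!r}")
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if profile.d_tb <= d_min:
        return 0.0
    k_max = int(np.floor(d_min / profile.delta_d + _EPS))
    window = np.asarray(profile.samples, dtype=float)[: k_max + 1]
    n = window.size
    n_dense = int(np.count_nonzero(window >= dense_hu))
    return 100.0 * n_dense / n


def codi(profile: ProbeProfile, model: CalibrationModel,
         depth_limit: float | None = None) -> float:
    """Column Density Index in mg HA/mm^2.

    Sums calibrated density over the sampled trajectory, which spans the
    full bone thickness d_TB (capped at the sampling limit).  An optional
    ``depth_limit`` (mm) restricts the summation, e.g. to a screw length.
    """
    if profile.status != "ok" and profile.status != "no_cortex":
        raise ValueError(f"cannot score a probe with status {profile.status!r}")
    samples = np.asarray(profile.samples, dtype=float)
    if depth_limit is not None:
        k_max = int(np.floor(depth_limit / profile.delta_d + _EPS))
        samples = samples[: k_max + 1]
    bmd_mm3 = hu_to_bmd(model, samples) / 1000.0  # mg HA/cm^3 -> mg HA/mm^3
    return float(np.sum(bmd_mm3) * profile.delta_d)
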