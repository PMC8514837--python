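# tbprobe

Quantitative retroauricular temporal-bone morphometry from CT, for
preoperative planning of screw and implant placement in otological and
robotic ear surgery (fiducial screws, bone-anchored hearing aids, bone
conduction implants).

Given a calibrated CT volume and three anatomical landmarks — the most
superior point of Henle's spine and two points along the center of the
zygomatic process — `tbprobe`:

1. segments bone (threshold 620 HU, 26-connected islands under 300 voxels
   removed), extracts the outer surface with marching cubes, and smooths
   it at a 4 mm spatial scale;
2. builds an anatomical coordinate frame (origin at Henle's spine, x
   posterior along the zygomatic direction, y superior, z lateral) and an
   8×8 probe grid with 5 mm spacing covering 35 × 35 mm², lower anterior
   corner at (x, y) = (4, −10) mm;
3. casts each grid point medially onto the bone surface and samples
   radiodensity every Δd = 0.15 mm along the inward surface normal;
4. derives, per probe:
   - the temporal-bone thickness `d_TB` — distance from the entry point
     to the last surface intersection, capped at 18 mm;
   - the external cortical density — mean HU over a 1.5 mm window
     starting at the first sample ≥ 1000 HU, convertible to bone mineral
     density (mg HA/cm³) through a phantom-fitted linear calibration
     (HU = 1.32 · BMD for the reference protocol);
   - the **Screw Implantation Safety Index**
     `SISI = 100 · N_S / N` if `d_TB > d_min`, else 0, where `N` counts
     samples within the screw length `d_min` (default 4 and 5 mm) and
     `N_S` those ≥ 1000 HU;
   - the **Column Density Index** `CODI = Σ_i ρ(i) · Δd` (mg HA/mm²),
     the calibrated density integrated over the full bone thickness;
5. aggregates probe tables across subjects into per-grid-cell
   mean/SD/count and renders heat maps.

A synthetic phantom module generates layered cortical/trabecular bone
slabs (optionally pneumatized with air cells), and the six-insert
density calibration phantom (0, 100, 200, 400, 600, 800 mg HA/cm³), with
analytic ground truth — so the whole pipeline is testable without
clinical data.

## Worked example

Probe a synthetic three-layer slab (2 mm cortex at 1500 HU, 6 mm
trabecular bone at 300 HU, 2 mm cortex) with a 3×3 grid:

```python
from tbprobe import (PhantomSpec, generate_slab, CalibrationModel,
                     RunConfig, run_probe_grid)

spec = PhantomSpec(kind="layered_slab", size_mm=(30, 30, 16),
                   spacing_mm=(0.3, 0.3, 0.2),
                   layers=[(2.0, 1500.0), (6.0, 300.0), (2.0, 1500.0)])
volume, truth = generate_slab(spec)
model = CalibrationModel(slope=1.32, intercept=0.0)
config = RunConfig(grid_nx=3, grid_ny=3, grid_spacing_mm=5.0,
                   grid_corner_mm=(-5.0, -5.0))
table = run_probe_grid(volume, truth.frame, model, config)
print(table[["grid_x_mm", "grid_y_mm", "d_tb_mm", "cortical_hu",
             "sisi_4mm", "sisi_5mm", "codi_mg_ha_mm2"]]
      .round(2).to_string(index=False))
```

```
 grid_x_mm  grid_y_mm  d_tb_mm  cortical_hu  sisi_4mm  sisi_5mm  codi_mg_ha_mm2
      -5.0       -5.0     10.0       1500.0     48.15     38.24            5.82
       0.0       -5.0     10.0       1500.0     48.15     38.24            5.82
       ...
       5.0        5.0     10.0       1500.0     48.15     38.24            5.82
```

Every probe recovers the 10 mm slab thickness and the 1500 HU cortex.
`sisi_4mm` ≈ 48 %: of the 27 samples within the 4 mm screw length, only
those in the 2 mm cortical layer reach 1000 HU (the analytic value on
the ideal profile is 51.9 %; the difference is the interpolated sample
at the air–bone boundary). `codi_mg_ha_mm2` ≈ 5.8 is the column mass of
the full 10 mm bone column; converting 1500 HU at slope 1.32 gives
1136 mg HA/cm³ of cortical bone mineral density.

The same run is available from the shell:

```bash
tbprobe simulate --spec slab_spec.json --out phantom/
tbprobe probe --volume phantom/phantom.nii --landmarks phantom/landmarks.json \
              --calibration default --out run/
tbprobe report --probes run/probes.csv --measure d_tb_mm --out cohort/
```

`probe` writes the per-probe CSV, per-measure summary CSVs, heat maps
and a run manifest; `calibrate` fits the HU→BMD line from an insert
table CSV; `segment` exports the bone mask (NIfTI) and mesh (PLY).

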