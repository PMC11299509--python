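# osteolcn

Quantitative morphometry of the osteocyte lacuno-canalicular network
(LCN) in cortical bone, built for studies of myeloma bone disease and
other conditions that remodel the peri-lacunar matrix. The package
covers the three measurement modalities such studies combine:

* **3D lacunar morphometry** from high-resolution micro-CT stacks:
  cortex segmentation, enclosed-pore extraction by hole filling, volume
  band classification (noise < 25 um^3 <= lacuna < 2000 um^3 <= canal),
  and per-sample metrics — lacunar density (mm^-3), proportion (% of
  cortical bone), mean volume (um^3) and mean Wadell sphericity
  psi = pi^(1/3) (6V)^(2/3) / A.
* **2D LCN quantification** on silver-stained histology fields: network
  area fraction, skeleton-based tracing of unbranched canaliculi
  (geodesic length in um), and the orientation statistic — the fraction
  of canaliculi whose major axis lies within +/-20 degrees of the
  perpendicular to the lamellae.
* **qPCR relative expression** for a peri-lacunar remodeling gene panel
  by the 2^-ddCt method against *Gapdh*, with unpaired two-tailed
  Student's t-tests on dCt.

Because raw scans for such studies are rarely deposited, the package
ships synthetic-data generators with exact ground truth (3D cortical
slabs, 2D stained fields, Ct tables) and named presets that encode the
published effect sizes of two myeloma models, so every stage is
validated by parameter recovery.

## Worked example

```python
from osteolcn import (
    Volume3DSpec, generate_volume, analyze_volume,
    Field2DSpec, generate_field2d, analyze_field,
    qpcr_preset, generate_ct_table, delta_delta_ct,
)

# 3D: synthesize a cortical slab and run the lacunar pipeline
vol, truth = generate_volume(Volume3DSpec(seed=1))
res = analyze_volume(vol)
print(res.metrics.as_dict())

# 2D: one silver-stain field
fld, _ = generate_field2d(Field2DSpec(seed=3))
fa = analyze_field(fld)
print(f"area {fa.area_fraction_pct:.2f}%  mean length {fa.mean_length_um:.1f} um  "
      f"aligned {fa.aligned_fraction:.2f}")

# qPCR: noiseless preset table
table = generate_ct_table(qpcr_preset())
print(delta_delta_ct(table)["fold_change"].round(2))
```

This prints (numbers from the seeds above):

```
{'n_lacunae': 32, 'cortical_bone_volume_mm3': 0.000823..., 'density_per_mm3': 38865.9,
 'proportion_pct': 0.776, 'mean_volume_um3': 199.5, 'mean_sphericity': 0.943}
area 5.95%  mean length 16.0 um  aligned 0.38
gene
Gapdh    1.00
Dmp1     0.49
MMP13    4.90
Ctsk     3.20
Acp5     7.70
MMP2     1.74
Sost     1.00
```

The 3D metrics recover the generator's conditions (33 lacunae placed at
4 x 10^4 / mm^3 with mean volume ~205 um^3 for this seed; one lacuna is
lost to the detection chain). The fold-change column reproduces the
preset panel exactly because the table is noiseless.

A whole synthetic study — paired cohorts for a named preset through all
three stages plus group statistics — is one call (or
`osteolcn all --preset u266_vs_nsg --out runs/demo` on the shell):

```python
from osteolcn import RunConfig, run_pipeline
result = run_pipeline(RunConfig(preset="u266_vs_nsg", seed=0, n_pairs=10,
                                output_dir="runs/demo"))
print(result.comparison_table()[["metric", "percent_change", "p", "stars"]])
```

The CLI exposes the same stages individually (`osteolcn generate`,
`lacunae3d`, `lcn2d`, `qpcr`, `compare`, `all`); every run writes CSV
outputs and a JSON manifest with parameter values and file hashes, and
reruns with the same seed are byte-identical.

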