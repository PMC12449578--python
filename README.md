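# corticon

Deconvolution-based morphometry of the vertebral cortical shell on
high-resolution quantitative CT (HR-QCT), with a digital phantom forge for
end-to-end validation.

## The problem

The cortical shell of a vertebral body is 200–600 μm thin — far below the
effective resolution of clinical CT. Measured directly on the image, the
shell appears 3–4× thicker than it is (partial-volume blur), and small
treatment-induced changes at its endosteal and periosteal surfaces are
invisible to naive thresholding. `corticon` implements the model-based
workflow used to quantify such changes in osteoanabolic-treatment trials:

- **Phantom forge** (`corticon.phantoms`): elliptic-cylindrical vertebral
  phantoms with a thin shell of tissue mineral density 1100 mgCaHA/cc over a
  trabecular interior, imaged through scanner-specific Gaussian PSFs
  (σ = 0.39 / 0.61 / 0.55 mm for the Siemens B70s / Philips D / GE BONE
  kernels), HR-QCT voxel grids (0.2 × 0.2 × 0.3 mm, 1.0–1.25 mm slice
  averaging) and additive noise, including longitudinal pairs with known
  surface apposition.
- **Calibration** (`corticon.calibration`): linear raw-unit → mgCaHA/cc
  mapping from calibration-rod measurements.
- **Segmentation** (`corticon.segmentation`): centroid-ray ridge detection
  of the blurred shell, half-maximum boundary placement, and VOI
  decomposition (vertical cortex, endplates, 2 mm subcortex, peeled
  spongiosa).
- **Radial profiles** (`corticon.profiles`): pooled 200 μm nested layers of
  mean BMD across the shell, and ridge-centered zone summaries
  (periosteal +0.2…+0.6 mm, central ±0.2 mm, endosteal −0.6…−0.2 mm,
  ~2 mm subcortical band).
- **ICON deconvolution** (`corticon.icon`): the core forward model. With
  `Φ` the standard normal CDF, the radial profile of a cortex of width *w*
  centered at *c* under Gaussian blur σ is

  ```
  y(x) = S + (P − S)·Φ((e − x)/σ) + (T − S)·[Φ((p − x)/σ) − Φ((e − x)/σ)]
  ```

  with endosteal/periosteal edges `e = c − w/2`, `p = c + w/2`, spongiosa
  plateau `P`, soft-tissue level `S`, and fixed mineralization
  `T = 1100 mgCaHA/cc`. Fitting this edge-spread + line-spread model to the
  measured profile recovers the deconvolved cortical thickness dcCt.Th = *w*
  even when the apparent thickness is several times larger, because blur
  conserves mineral mass. Longitudinal apposition is fitted as extra matrix
  slabs (50% mineralized by default) flush to the baseline cortex.
- **Thickness metrics** (`corticon.thickness`): Maximum-Sphere local
  thickness Ct.Th and density-weighted wCt.Th (labels × BMD/1100).
- **Cancellous metrics** (`corticon.cancellous`): BV/TV and TMD at the
  250 mg/cc threshold, compartment BMD/BMC.
- **Cohort statistics** (`corticon.stats`): baseline/follow-up changes,
  arm summaries, one-way ANOVA and Student's t-tests at p < .05.

## Worked example

```python
import corticon as ct

spec = ct.PhantomSpec(cortical_width_true=359.0, trabecular_bmd=105.0)
apposition = ct.AppositionTruth(endosteal_matrix=136.0, periosteal_matrix=58.0,
                                mineralization_fraction=0.5)
imaging = ct.ImagingSpec.preset("GE_BONE", noise_sd=25.0)

baseline, followup, truth = ct.make_longitudinal_pair(
    spec, apposition, imaging, seed=7, supersampling=2
)
paired, objects = ct.analyze_pair(baseline, followup, imaging.psf_sigma_inplane)

print(f"apparent Ct.Th      : {paired['ctth_um'][0]:7.0f} um")
print(f"weighted wCt.Th     : {paired['wctth_um'][0]:7.0f} um")
print(f"deconvolved dcCt.Th : {paired['dcctth_um'][0]:7.0f} -> {paired['dcctth_um'][1]:.0f} um")
app = objects["apposition"]
print(f"apposition (e/p)    : {app.endosteal_width*1e3:7.0f} / {app.periosteal_width*1e3:.0f} um")
```

prints

```
apparent Ct.Th      :    1221 um
weighted wCt.Th     :     304 um
deconvolved dcCt.Th :     361 -> 553 um
apposition (e/p)    :     140 / 52 um
```

The phantom's true cortex is 359 μm with 136/58 μm of endosteal/periosteal
matrix added at follow-up. The segmentation-based Ct.Th reads ~1.2 mm (the
partial-volume inflation), the density-weighted wCt.Th roughly restores the
scale, and the ICON fit recovers both the baseline width and the sub-voxel
apposition — the total change of ~190 μm is well below the 200–300 μm voxel
size.

A command-line interface wraps phantom generation and cohort analysis:

```sh
corticon phantom --config cohort.yaml --seed 1 --out cohort/
corticon run --cohort cohort/ --out results/
```

producing `table1.csv` / `table2.csv` (cortical and cancellous arm
summaries), `fig4_zones.csv` (zone-wise changes), per-subject fit JSON and
test tables.

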