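# enfaceoct

En face OCT imaging of subretinal fluid (SRF).

In neovascular age-related macular degeneration, fluid leaking from
choroidal neovascularization pools between the photoreceptors and the
retinal pigment epithelium (RPE). On a cross-sectional SDOCT B-scan the
fluid is obvious but its *lateral extent* is not: judging change across
visits means paging through two stacks of B-scans. This package turns a
dense SDOCT raster volume into a single frontal-plane (en face) image of
the layer where the fluid lives, and measures the dark fluid regions so
their area can be tracked across visits.

The pipeline, for a volume `I(z, x, b)` (axial depth × A-scan × B-scan):

1. **RPE segmentation.** Per A-scan, smooth with a moving average and
   find the two greatest local intensity maxima (nerve fiber layer and
   RPE, separation ≥ 20 px); the posterior peak is the initial RPE depth
   `z₀(x)`. Median-filter `z₀` across A-scans, refine each depth to the
   brightest *raw* pixel within ±10 px of the estimate, and
   median-filter once more, giving the RPE topography `z_RPE(x, b)`.
2. **Slab projection.** Convert the slab from micrometres to pixels
   (39 µm offset → 10 px, 30 µm thickness → 8 px at 3.9 µm/px) and
   average raw intensity over the half-open axial interval
   `[z_RPE − 18, z_RPE − 10)` — the depth of the photoreceptor
   inner-segment ellipsoid, one outer-segment length above the RPE. Row
   `b` of the en face image is B-scan `b`'s slab means. Because the slab
   rides on the per-B-scan RPE, axial eye motion between B-scans cancels
   exactly.
3. **SRF quantification.** Median-denoise the en face image, threshold
   it (exact Otsu by default), label connected dark components
   (8-connectivity, ≥ 25 px), convert pixel counts to mm² with the scan
   calibration, and compare total areas between visits.
4. **Thickness.** The anterior member of the detected peak pair gives
   the inner retinal surface; ILM→RPE distance yields a thickness map
   and the central subfield thickness (CST, mean over the central
   1 mm ETDRS disc).

No clinical data is needed: `enfaceoct.synthetic_data` generates layered
retina phantoms (domed RPE, elliptical SRF pockets, vessel shadows,
per-B-scan axial displacement, multiplicative gamma speckle) with exact
ground truth, so every stage is testable end to end.

## Worked example

```python
import numpy as np
import enfaceoct as eo

params = eo.PhantomParams(seed=7)           # 256 x 768 x 145, speckle k=4
volume, truth = eo.make_phantom(params)

surface = eo.segment_volume(volume)
rms = np.sqrt(np.mean((surface.z_rpe - truth.true_rpe) ** 2.0))
print(f"RMS surface error: {rms:.2f} px ({rms * volume.axial_res_um:.2f} um)")

image = eo.build_enface(volume, surface)    # 39 um offset, 30 um slab
mask, cutoff = eo.threshold_dark(image)
regions = eo.label_regions(mask, min_area_px=25, connectivity=8,
                           threshold_used=cutoff,
                           lateral_res_um=volume.lateral_res_um,
                           bscan_spacing_um=volume.bscan_spacing_um)
print(f"threshold: {cutoff:.1f}   regions: {len(regions.regions)}")
print(f"SRF area: {regions.total_area_mm2:.3f} mm^2 "
      f"(truth {truth.srf_total_area_mm2:.3f} mm^2)")

tmap = eo.thickness_map(eo.detect_ilm(volume), surface, volume.axial_res_um,
                        lateral_res_um=volume.lateral_res_um,
                        bscan_spacing_um=volume.bscan_spacing_um,
                        fovea_center=volume.default_fovea())
print(f"CST: {tmap.cst_um:.1f} um")
```

Output:

```
RMS surface error: 0.77 px (3.02 um)
threshold: 34.8   regions: 1
SRF area: 0.996 mm^2 (truth 0.997 mm^2)
CST: 445.8 um
```

The detected surface is within a pixel of truth despite heavy speckle;
the simulated ~1 mm² fluid pocket is recovered to 0.1%; the CST reflects
the pocket-elevated retina (a flat 92-px retina alone would read
~359 µm).

## Command line

```sh
enface simulate --seed 17 --out vol.tiff --truth gt.json
enface segment  --volume vol.tiff --out surface.tsv
enface project  --volume vol.tiff --surface surface.tsv \
                --offset-um 39 --thickness-um 30 --out enface.png
enface quantify --volume vol.tiff --summary-out visit1.json
enface compare  --summary-a visit1.json --summary-b visit2.json
enface thickness --volume vol.tiff
enface run      --volume vol.tiff --outdir out/   # full pipeline
```

Parameters can also come from a flat JSON config (`--config`); unknown
keys are rejected, and every summary echoes the effective configuration.

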