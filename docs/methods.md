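# Methods

## Setting and model

A spectral-domain OCT raster volume is a stack of B-scans, each a
`z × x` image of axial reflectance profiles (A-scans). The package's
coordinate convention is `(z, x, b)` with `z = 0` the most anterior row
(vitreous); "anterior to the RPE" always means smaller `z`. Default
calibration follows a dense macular raster: 145 B-scans × 768 A-scans
over a 15° × 15° field at 3.9 µm/px axial sampling. The paper-style
lateral extent is angular; it is mapped to micrometres with the
emmetropic-eye convention of 288 µm/degree, giving 5.625 µm per A-scan
step and ≈29.79 µm between B-scans. The µm/degree constant is a
configurable convention, not a measurement.

Subretinal fluid (SRF) is hyporeflective and collects between the
photoreceptor outer segments and the RPE. Averaging a thin slab at the
inner-segment-ellipsoid (ISe) depth — posterior edge 39 µm anterior to
the RPE, 30 µm thick — therefore renders SRF as dark regions on the en
face projection, and anchoring the slab to the per-B-scan RPE makes the
projection invariant to axial eye motion between B-scans.

## RPE segmentation

Four stages per B-scan, all deterministic:

1. *Initial detection.* Each A-scan is smoothed with a centred moving
   average (`ma_window_px = 7`, edge windows truncated). The two
   greatest-intensity local maxima with axial separation
   ≥ `min_peak_separation_px = 20` (≈78 µm) are selected greedily:
   the global highest local maximum, then the highest compatible one.
   A local maximum must strictly exceed its neighbours; plateaus of
   equal samples count once, at their first (anterior) index. The
   *posterior* member of the pair is the initial RPE depth regardless of
   relative brightness — the RPE is identified positionally. A plain
   "two highest samples" rule would pick two adjacent pixels of one
   band, hence the local-maximum + separation reading. A-scans without
   two qualifying peaks are filled by linear interpolation from the
   nearest valid A-scans (ends take the nearest valid value); only a
   B-scan with no valid A-scan at all fails, carrying its index.
2. *Median smoothing* across A-scans, `median_window_ascans = 15`.
3. *Refinement*: the brightest pixel of the **raw** A-scan within
   ±`refine_radius_px = 10` of the estimate (half-width reading of
   "within 10 pixels"). Refinement exists to undo smoothing bias, hence
   raw intensities. Ties go to the candidate nearest the estimate, then
   to the smaller depth — deterministic and unbiased toward the prior.
4. *Second median smoothing*, `median_window2_ascans = 15` (equal
   windows by default; both exposed).

The source method names the moving-average and median filters but not
their lengths; the defaults were chosen once so that smoothing spans are
small against a 768-A-scan B-scan (15 A-scans ≈ 84 µm) and are all
configurable.

**Median edge handling.** Running medians complete their edge windows by
replicating the first/last value (scipy's `nearest` mode) rather than
truncating. A truncated edge window's centre is not its midpoint, which
biases the median on sloped surfaces at B-scan edges by up to a pixel;
replication preserves monotone depth traces exactly. Output values are
always members of the input multiset restricted to the (clipped) window.

**Resolvability.** A window-`w` median cannot represent surface features
narrower than `(w+1)/2` A-scans. Consequently the pipeline reproduces a
noiseless phantom surface exactly if and only if the quantized true
surface is a fixed point of the median smoothing — true for planar,
gently domed, and SRF-elevated topographies, but violated at isolated
pixels wherever quantization of a smooth dome produces a run narrower
than 8 columns (e.g. near the saddle of two domes). The exactness tests
assert this precondition explicitly.

## En face projection

Distances convert to pixels by rounding half away from zero:
39 µm → 10 px, 30 µm → 8 px at 3.9 µm/px. The slab spans the half-open
interval `[z_RPE − offset_px − thickness_px, z_RPE − offset_px)`; the
stated 39 µm distance is read as the slab's *posterior edge* (an
`alignment="center"` option exists), which places the slab over the ISe
band. Each en face pixel is the arithmetic mean of the raw intensities
in the clipped interval; intervals partially outside the volume are
clipped (peripheral tilted retina should not kill the image), fully
outside is an error naming the A-scan. Means use raw intensities —
smoothing exists only for peak finding.

## SRF quantification

The delineation rule is this package's design (the imaging method it
implements proposes measuring dark-region area but gives no rule):

- The en face image is denoised with a 3×3 median filter before
  thresholding (`smooth_px = 3`; 1 disables). Speckle leaves the raw
  background with a coefficient of variation ≈ 0.2 and a heavy lower
  tail; a global threshold computed on the raw image lands far above the
  fluid level and sweeps in vessel shadows and background tail
  (observed: Dice ≈ 0.45 vs ≈ 0.999 with the prefilter).
- Default cutoff is **exact Otsu**: between-class variance maximized
  exhaustively over every distinct-value split (cumulative-sum
  implementation), ties to the smallest cutoff. Histogram-binned Otsu
  implementations disagree with direct enumeration on flat-objective
  images, which matters for reproducibility on float images.
  `fraction-of-median` and `fixed` cutoffs are provided.
- Dark components are labelled at 8-connectivity; components below
  `min_area_px = 25` (≈ 4·10⁻³ mm²) are dropped and zeroed in the label
  map; labels are renumbered in raster order of first pixel.
- Area = pixel count × lateral_res × B-scan spacing (rectangular pixel
  footprint, no curvature correction). Visit comparison reports
  absolute and percent change (negative = reduction); a percent change
  from a zero baseline is flagged undefined rather than infinite.

## Thickness and CST

The anterior member of the detected peak pair marks the inner retinal
surface; it is median-smoothed with the same two windows but not
argmax-refined (the inner surface is an edge, not a brightest pixel; on
band phantoms it sits a constant few pixels below the true ILM, which
cancels in thickness *differences*). Thickness is the axial ILM→RPE
distance × axial resolution; crossing surfaces are an error listing
offending coordinates. CST is the mean thickness over pixels whose
centre lies within 500 µm of the fovea (1 mm ETDRS central disc),
defaulting to the volume's geometric centre when no fovea is recorded.

## Synthetic phantoms

`make_phantom` builds a layered retina, top down: vitreous (5), NFL
(8 px, 120), inner retina (45 px, 60), ONL (25 px, 25), ISe (4 px, 110),
outer segments (9 px, 25), RPE complex, choroid (40) — reflectances on
an 8-bit-like scale, chosen so the RPE is the global maximum and the ISe
the second bright outer band. The RPE is a 7-px complex: shoulders at
140 around a central row at 160 that is strictly the brightest voxel of
every column. A single constant-reflectance band would leave "the" RPE
depth ill-defined under argmax refinement (ties); a 1-px band would not
survive speckle. The ISe band sits centred within the projected slab
(2 px dark margin each side) so a ±1 px surface error exchanges only
dark rows; with the band flush against the slab edge, surface noise
couples band intensity directly into the projection.

Pathologies and nuisances: Gaussian RPE elevations (domes); elliptical
SRF pockets (default ≈1 mm², fluid height 24 px at reflectance 2)
resting *on* the RPE and elevating every band above the fluid, so CST
rises with pocket height while the RPE itself stays put; vessel shadows
(columns ×0.7 below the NFL); optional bright scar patches (+60 on the
dark slab rows flanking the ISe); per-B-scan integer axial shifts; and
multiplicative unit-mean gamma speckle (`k = 4` default, variance
`1/k`), drawn from numpy's PCG64 so volumes are bit-reproducible per
seed. With speckle off, every A-scan is piecewise constant per band and
ground truth (surfaces, SRF footprint, areas, shifts) equals the
construction.

What the phantom does **not** emulate: wave-optics speckle correlation
(real speckle is spatially correlated; independent voxel noise is
harsher at fixed variance), curved retinal geometry, transverse eye
motion, intraretinal cysts, RPE atrophy, and graded fluid boundaries
(pockets have constant height, hence knife-edge footprints). Passing
tests therefore demonstrate the algorithmic properties — exact
anchoring, motion invariance, robustness to heavy uncorrelated
multiplicative noise, area recovery on crisp pockets — not clinical
segmentation accuracy on real eyes.

## Problem sizes and runtime choices

Tests and the acceptance script use the full default geometry
(256 × 768 × 145 ≈ 28.5 M voxels); a full simulate→measure pipeline
takes a few seconds on one CPU. Seed sweeps use 40 seeds for surface
robustness, 20 for en face agreement and SRF recovery, 10 for the
two-visit direction check. Small unit phantoms (200 × 120 × 24) cover
construction and invariance properties.

## Known limitations

- Vessel shadows and overlying pathology dim the slab and can mimic
  SRF; the min-area filter and denoised global threshold suppress the
  default narrow shadows, but there is no shadow/fluid discrimination.
- Surface features narrower than half the median window are flattened
  (see resolvability above).
- No longitudinal registration: visits are compared by total area, not
  pixelwise.
- Bruch's membrane, choroid, and intraretinal layers are out of scope;
  eyes without a posterior bright band (RPE atrophy) will mis-anchor.
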