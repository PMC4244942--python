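"""Synthetic SDOCT volume phantoms with exact ground truth.

The generator emulates the acquisition geometry of a dense macular
raster — by default 145 B-scans of 768 A-scans at 3.9 μm axial sampling
over a 15° × 15° area — and the retinal features the en face method must
handle:

* a layered retina (bright NFL band, dark outer nuclear layer, bright
  inner-segment-ellipsoid band, brightest RPE band, dark outer-segment
  zone between them, choroid below, vitreous above);
* smooth RPE topography: a base plane plus Gaussian elevations (domes);
* elliptical subretinal-fluid pockets of near-zero reflectance inserted
  between the photoreceptors and the RPE, elevating every band anterior
  to the fluid while the RPE itself stays put;
* vessel shadows (columns attenuated below the NFL);
* optional bright "fibrotic scar" patches in the slab zone;
* per-B-scan integer axial displacement (eye motion between B-scans);
* multiplicative unit-mean gamma speckle.

With speckle off every A-scan is piecewise constant per band, and the
RPE is modelled as a 7-pixel reflective complex whose central row is
strictly the brightest voxel of the column, so the true surface is
unambiguous and exactly recoverable.  Ground truth (surfaces, SRF
footprint, areas, shifts) is recorded at construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .volume_io import (
    OCTVolume,
    DEFAULT_AXIAL_RES_UM,
    DEFAULT_LATERAL_RES_UM,
    DEFAULT_BSCAN_SPACING_UM,
)

__all__ = [
    "Band", "BandModel", "GaussianElevation", "SRFPocket", "VesselShadow",
    "ScarPatch", "PhantomParams", "GroundTruth",
    "make_phantom", "apply_speckle", "apply_axial_shifts",
    "write_ground_truth", "read_ground_truth",
]


@dataclass(frozen=True)
class Band:
    thickness_px: int
    reflectance: float


@dataclass(frozen=True)
class BandModel:
    """Layer stack of the phantom retina, top (vitreous) to bottom (choroid).

    Reflectances are on an 8-bit-like scale.  The RPE is a reflective
    complex ``rpe_halfwidth_px`` pixels to each side of a central row at
    ``rpe_peak`` (strictly the brightest reflectance in the model), with
    the flanking rows at ``rpe_shoulder``; the true RPE surface is the
    central row.
    """

    vitreous: float = 5.0
    nfl: Band = field(default_factory=lambda: Band(8, 120.0))
    inner_retina: Band = field(default_factory=lambda: Band(45, 60.0))
    onl: Band = field(default_factory=lambda: Band(25, 25.0))
    ise: Band = field(default_factory=lambda: Band(4, 110.0))
    outer_segments: Band = field(default_factory=lambda: Band(9, 25.0))
    rpe_peak: float = 160.0
    rpe_shoulder: float = 140.0
    rpe_halfwidth_px: int = 3
    choroid: float = 40.0
    fluid: float = 2.0

    def __post_init__(self) -> None:
        others = [self.vitreous, self.nfl.reflectance,
                  self.inner_retina.reflectance, self.onl.reflectance,
                  self.ise.reflectance, self.outer_segments.reflectance,
                  self.rpe_shoulder, self.choroid, self.fluid]
        if not all(self.rpe_peak > v for v in others):
            raise ValueError("RPE peak reflectance must be strictly greatest")

    @property
    def retina_above_rpe_px(self) -> int:
        """Axial span from the ILM to the top of the RPE complex."""
        return (self.nfl.thickness_px + self.inner_retina.thickness_px
                + self.onl.thickness_px + self.ise.thickness_px
                + self.outer_segments.thickness_px)


@dataclass(frozen=True)
class GaussianElevation:
    """Anterior Gaussian dome of the RPE surface (e.g. a PED)."""

    center: Tuple[float, float]       # (x, b)
    amplitude_px: float               # anterior displacement at the apex
    sigma: Tuple[float, float]        # (sigma_x, sigma_b) in pixels


@dataclass(frozen=True)
class SRFPocket:
    """Elliptical pocket of subretinal fluid resting on the RPE."""

    center: Tuple[float, float]       # (x, b)
    semi_axes: Tuple[float, float]    # (a_x, a_b) in pixels
    height_px: int                    # fluid column height

    def scaled(self, footprint: float = 1.0, height: float = 1.0) -> "SRFPocket":
        return SRFPocket(self.center,
                         (self.semi_axes[0] * footprint,
                          self.semi_axes[1] * footprint),
                         max(1, int(round(self.height_px * height))))


@dataclass(frozen=True)
class VesselShadow:
    x_center: int
    width_px: int
    attenuation: float = 0.7          # multiplicative factor below the NFL


@dataclass(frozen=True)
class ScarPatch:
    """Hyperreflective patch in the slab zone (hypopigmented fibrotic scar)."""

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]
    delta_reflectance: float = 60.0


def _default_elevations() -> List[GaussianElevation]:
    return [GaussianElevation(center=(300.0, 60.0), amplitude_px=12.0,
                              sigma=(90.0, 18.0))]


def _default_pockets() -> List[SRFPocket]:
    # ~1 mm^2 footprint at the default lateral calibration, under the fovea
    return [SRFPocket(center=(384.0, 72.0), semi_axes=(95.0, 20.0), height_px=24)]


def _default_vessels() -> List[VesselShadow]:
    return [VesselShadow(x_center=x, width_px=5, attenuation=0.7)
            for x in (96, 224, 352, 480, 608, 704)]


@dataclass(frozen=True)
class PhantomParams:
    """Everything that defines a phantom volume; deterministic given ``seed``."""

    dims: Tuple[int, int, int] = (256, 768, 145)      # (n_z, n_ascans, n_bscans)
    axial_res_um: float = DEFAULT_AXIAL_RES_UM
    lateral_res_um: float = DEFAULT_LATERAL_RES_UM
    bscan_spacing_um: float = DEFAULT_BSCAN_SPACING_UM
    bands: BandModel = field(default_factory=BandModel)
    rpe_base_depth_px: int = 170
    elevations: Tuple[GaussianElevation, ...] = field(
        default_factory=lambda: tuple(_default_elevations()))
    srf_pockets: Tuple[SRFPocket, ...] = field(
        default_factory=lambda: tuple(_default_pockets()))
    vessel_shadows: Tuple[VesselShadow, ...] = field(
        default_factory=lambda: tuple(_default_vessels()))
    scar_patches: Tuple[ScarPatch, ...] = ()
    bscan_axial_shifts: Optional[Tuple[int, ...]] = None
    speckle: str = "gamma"            # "off" | "gamma"
    speckle_shape_k: float = 4.0
    seed: int = 0

    def with_(self, **kw) -> "PhantomParams":
        for key in ("elevations", "srf_pockets", "vessel_shadows",
                    "scar_patches", "bscan_axial_shifts"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        return replace(self, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """Construction truth of a phantom, all indexed (b, x)."""

    true_rpe: np.ndarray              # int, central RPE row
    true_ilm: np.ndarray              # int, first NFL row
    srf_footprint_mask: np.ndarray    # bool
    srf_total_area_mm2: float
    bscan_axial_shifts: np.ndarray    # int per b
    lateral_res_um: float
    bscan_spacing_um: float


def _ellipse_mask(shape_xb: Tuple[int, int], center, semi_axes) -> np.ndarray:
    """Discrete ellipse footprint over an (x, b) grid, by pixel centre."""
    n_x, n_b = shape_xb
    cx, cb = center
    ax, ab = semi_axes
    xx = (np.arange(n_x)[:, None] - cx) / ax
    bb = (np.arange(n_b)[None, :] - cb) / ab
    return xx ** 2 + bb ** 2 <= 1.0


def make_phantom(params: Optional[PhantomParams] = None
                 ) -> Tuple[OCTVolume, GroundTruth]:
    """Build a layered-retina phantom volume and its ground truth."""
    params = params or PhantomParams()
    n_z, n_x, n_b = params.dims
    bands = params.bands
    hw = bands.rpe_halfwidth_px

    shifts = (np.zeros(n_b, dtype=int) if params.bscan_axial_shifts is None
              else np.asarray(params.bscan_axial_shifts, dtype=int))
    if shifts.shape != (n_b,):
        raise ValueError(f"bscan_axial_shifts must have length {n_b}")

    # RPE central-row depth per (x, b): base plane + domes + per-B-scan shift
    r = np.full((n_x, n_b), float(params.rpe_base_depth_px))
    for el in params.elevations:
        cx, cb = el.center
        sx, sb = el.sigma
        g = np.exp(-((np.arange(n_x)[:, None] - cx) ** 2 / (2 * sx ** 2)
                     + (np.arange(n_b)[None, :] - cb) ** 2 / (2 * sb ** 2)))
        r -= el.amplitude_px * g
    r = np.round(r).astype(int) + shifts[None, :]

    # fluid height per (x, b)
    h = np.zeros((n_x, n_b), dtype=int)
    srf_mask_xb = np.zeros((n_x, n_b), dtype=bool)
    for p in params.srf_pockets:
        m = _ellipse_mask((n_x, n_b), p.center, p.semi_axes)
        h = np.where(m, np.maximum(h, p.height_px), h)
        srf_mask_xb |= m

    ilm = r - hw - h - bands.retina_above_rpe_px
    if ilm.min() < 0 or (r + hw + 1).max() > n_z:
        raise ValueError(
            "phantom structures fall outside the axial range: "
            f"ilm min {ilm.min()}, rpe complex max {(r + hw).max()}, n_z {n_z}"
        )

    # fill the stack top-down; boundaries are (x, b) maps of z indices
    zg = np.arange(n_z)[:, None, None]
    vol = np.full((n_z, n_x, n_b), bands.vitreous, dtype=np.float32)

    def paint(top, bot, refl):
        np.copyto(vol, np.float32(refl),
                  where=(zg >= top[None]) & (zg < bot[None]))

    cursor = ilm
    for band in (bands.nfl, bands.inner_retina, bands.onl, bands.ise,
                 bands.outer_segments):
        nxt = cursor + band.thickness_px
        paint(cursor, nxt, band.reflectance)
        cursor = nxt
    # fluid sits on the RPE complex: [r - hw - h, r - hw)
    paint(r - hw - h, r - hw, bands.fluid)
    paint(r - hw, r + hw + 1, bands.rpe_shoulder)
    paint(r, r + 1, bands.rpe_peak)
    paint(r + hw + 1, np.full_like(r, n_z), bands.choroid)

    # bright scar patches: raise the dark rows flanking the ISe band
    # (inside the projected slab) without rivalling the ISe or RPE peaks
    for scar in params.scar_patches:
        m = _ellipse_mask((n_x, n_b), scar.center, scar.semi_axes)
        ise_bot = cursor - bands.outer_segments.thickness_px
        ise_top = ise_bot - bands.ise.thickness_px
        zone = (((zg >= (ise_top - 2)[None]) & (zg < ise_top[None])
                 | (zg >= ise_bot[None]) & (zg < (ise_bot + 2)[None]))
                & m[None])
        vol[zone] += np.float32(scar.delta_reflectance)

    # vessel shadows: attenuate everything below the NFL in chosen columns
    nfl_bot = ilm + bands.nfl.thickness_px
    for v in params.vessel_shadows:
        x0 = max(0, v.x_center - v.width_px // 2)
        x1 = min(n_x, x0 + v.width_px)
        sub = vol[:, x0:x1, :]
        sub *= np.where(zg >= nfl_bot[None, x0:x1, :], v.attenuation, 1.0
                        ).astype(np.float32)

    volume = OCTVolume(
        intensity=vol,
        axial_res_um=params.axial_res_um,
        lateral_res_um=params.lateral_res_um,
        bscan_spacing_um=params.bscan_spacing_um,
        fovea_center=(n_x // 2, n_b // 2),
    )
    if params.speckle == "gamma":
        volume = apply_speckle(volume, params.speckle_shape_k, params.seed)
    elif params.speckle != "off":
        raise ValueError(f"unknown speckle model {params.speckle!r}")

    px_area = params.lateral_res_um * params.bscan_spacing_um * 1e-6
    truth = GroundTruth(
        true_rpe=r.T.copy(),
        true_ilm=ilm.T.copy(),
        srf_footprint_mask=srf_mask_xb.T.copy(),
        srf_total_area_mm2=float(srf_mask_xb.sum()) * px_area,
        bscan_axial_shifts=shifts.copy(),
        lateral_res_um=params.lateral_res_um,
        bscan_spacing_um=params.bscan_spacing_um,
    )
    return volume, truth


def apply_speckle(volume: OCTVolume, shape_k: float, seed: int) -> OCTVolume:
    """Multiply every voxel by an independent unit-mean gamma draw.

    ``shape_k`` controls the noise level: the multiplicative field has
    variance ``1/shape_k``, so the expected value of every voxel is
    unchanged and large ``shape_k`` approaches the noise-free volume.
    Uses numpy's PCG64 generator, so the field is reproducible across
    platforms for a fixed seed.
    """
    if shape_k <= 0:
        raise ValueError(f"speckle shape k must be > 0, got {shape_k}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_gamma(shape_k, size=volume.intensity.shape,
                               dtype=np.float32)
    noise /= np.float32(shape_k)
    noise *= volume.intensity.astype(np.float32, copy=False)
    return volume.with_intensity(noise)


def apply_axial_shifts(volume: OCTVolume, shifts: Sequence[int]) -> OCTVolume:
    """Axially translate each B-scan of an existing volume (noise and all).

    A positive shift moves a B-scan's content toward larger ``z``
    (posteriorly); vacated rows are filled with the B-scan's edge row.
    Useful for axial-motion experiments on an identical speckle field.
    """
    shifts = np.asarray(shifts, dtype=int)
    if shifts.shape != (volume.n_bscans,):
        raise ValueError(f"need one shift per B-scan ({volume.n_bscans})")
    out = np.empty_like(volume.intensity)
    for b, s in enumerate(shifts):
        src = volume.intensity[:, :, b]
        if s == 0:
            out[:, :, b] = src
        elif s > 0:
            out[s:, :, b] = src[:-s]
            out[:s, :, b] = src[0]
        else:
            out[:s, :, b] = src[-s:]
            out[s:, :, b] = src[-1]
    return volume.with_intensity(out)


# ---------------------------------------------------------------------------
# Ground-truth serialization (JSON + TSV mask)
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write ground truth as JSON (surfaces, area, shifts) + TSV mask."""
    path = Path(path)
    payload = {
        "true_rpe": gt.true_rpe.astype(int).tolist(),
        "true_ilm": gt.true_ilm.astype(int).tolist(),
        "srf_total_area_mm2": gt.srf_total_area_mm2,
        "bscan_axial_shifts": gt.bscan_axial_shifts.astype(int).tolist(),
        "lateral_res_um": gt.lateral_res_um,
        "bscan_spacing_um": gt.bscan_spacing_um,
    }
    path.write_text(json.dumps(payload))
    mask_path = path.with_suffix(".mask.tsv")
    np.savetxt(mask_path, gt.srf_footprint_mask.astype(int), fmt="%d",
               delimiter="\t")


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    payload = json.loads(path.read_text())
    mask = np.loadtxt(path.with_suffix(".mask.tsv"), dtype=int,
                      delimiter="\t", ndmin=2).astype(bool)
    return GroundTruth(
        true_rpe=np.asarray(payload["true_rpe"], dtype=int),
        true_ilm=np.asarray(payload["true_ilm"], dtype=int),
        srf_footprint_mask=mask,
        srf_total_area_mm2=float(payload["srf_total_area_mm2"]),
        bscan_axial_shifts=np.asarray(payload["bscan_axial_shifts"], dtype=int),
        lateral_res_um=float(payload["lateral_res_um"]),
        bscan_spacing_um=float(payload["bscan_spacing_um"]),
    )
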