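"""En face slab projection anterior to the RPE surface.

A thin layer — by default ~30 μm thick with its posterior edge 39 μm
anterior to the RPE, i.e. at the depth of the photoreceptor inner segment
ellipsoid (one outer-segment length above the RPE) — is extracted from
every A-scan following the detected RPE topography, and the mean
intensity of the layer forms one row of the en face image per B-scan.
Subretinal fluid, being hyporeflective, appears as dark regions.

Because the slab is positioned relative to the per-B-scan RPE surface,
axial displacement of the retina between B-scans cancels out of the
projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .volume_io import OCTVolume, EnFaceImage
from .rpe_segmentation import RPESurface

__all__ = ["SlabSpec", "SlabError", "microns_to_pixels",
           "extract_slab_means", "build_enface"]


class SlabError(ValueError):
    """The slab interval is invalid or falls outside the volume."""


def microns_to_pixels(distance_um: float, axial_res_um: float) -> int:
    """Convert an axial physical distance to a pixel count.

    Rounds half away from zero, so 39 μm at 3.9 μm/px gives exactly 10 px
    and 30 μm gives 8 px.
    """
    if axial_res_um <= 0:
        raise ValueError(f"axial_res_um must be positive, got {axial_res_um}")
    if distance_um < 0:
        raise ValueError(f"distance_um must be >= 0, got {distance_um}")
    return int(np.floor(distance_um / axial_res_um + 0.5))


@dataclass(frozen=True)
class SlabSpec:
    """Anterior offset and thickness of the projected layer.

    ``offset_um`` is the distance from the RPE to the slab's *posterior*
    edge (``alignment="posterior-edge"``, the default), so the slab spans
    the half-open axial interval ``[z_rpe − offset_px − thickness_px,
    z_rpe − offset_px)``.  With ``alignment="center"`` the slab is instead
    centred ``offset_um`` anterior to the RPE.  Pixel values are derived
    by :func:`microns_to_pixels` for the given axial resolution.
    """

    offset_um: float = 39.0
    thickness_um: float = 30.0
    axial_res_um: float = 3.9
    alignment: str = "posterior-edge"

    def __post_init__(self) -> None:
        if self.offset_um < 0:
            raise SlabError(f"offset_um must be >= 0, got {self.offset_um}")
        if self.thickness_um <= 0:
            raise SlabError(f"thickness_um must be > 0, got {self.thickness_um}")
        if self.alignment not in ("posterior-edge", "center"):
            raise SlabError(f"unknown alignment {self.alignment!r}")
        if self.thickness_px < 1:
            raise SlabError(
                f"thickness {self.thickness_um} um is below one pixel at "
                f"{self.axial_res_um} um/px"
            )

    @property
    def offset_px(self) -> int:
        return microns_to_pixels(self.offset_um, self.axial_res_um)

    @property
    def thickness_px(self) -> int:
        return microns_to_pixels(self.thickness_um, self.axial_res_um)

    def top_offset_px(self) -> int:
        """Offset from the RPE to the slab's most anterior row (inclusive)."""
        if self.alignment == "posterior-edge":
            return self.offset_px + self.thickness_px
        return self.offset_px + self.thickness_px // 2 + self.thickness_px % 2


def extract_slab_means(bscan: np.ndarray, rpe_depths: np.ndarray,
                       slab: SlabSpec) -> np.ndarray:
    """Mean raw intensity of the slab above the RPE, per A-scan.

    The per-column interval is clipped at the B-scan boundaries; a column
    whose interval vanishes entirely raises :class:`SlabError` naming the
    A-scan index.
    """
    bscan = np.asarray(bscan, dtype=float)
    nz, nx = bscan.shape
    rpe = np.round(np.asarray(rpe_depths)).astype(int)
    if rpe.shape != (nx,):
        raise SlabError(f"rpe_depths shape {rpe.shape} != ({nx},)")
    if rpe.min() < 0 or rpe.max() >= nz:
        raise SlabError("rpe_depths out of B-scan bounds")
    top = rpe - slab.top_offset_px()                 # most anterior row
    offs = np.arange(slab.thickness_px)[:, None]     # (t, 1)
    z = top[None, :] + offs                          # (t, x)
    inside = (z >= 0) & (z < nz)
    counts = inside.sum(axis=0)
    if (counts == 0).any():
        x_bad = int(np.flatnonzero(counts == 0)[0])
        raise SlabError(
            f"slab entirely outside the B-scan at A-scan x={x_bad} "
            f"(rpe={rpe[x_bad]}, interval top {top[x_bad]})"
        )
    vals = np.where(inside, bscan[np.clip(z, 0, nz - 1), np.arange(nx)[None, :]], 0.0)
    return vals.sum(axis=0) / counts


def build_enface(volume: OCTVolume, surface: RPESurface,
                 slab: Optional[SlabSpec] = None) -> EnFaceImage:
    """Assemble the en face image: row ``b`` is B-scan ``b``'s slab means."""
    if slab is None:
        slab = SlabSpec(axial_res_um=volume.axial_res_um)
    if surface.stage != "final":
        raise ValueError(f"surface stage must be 'final', got {surface.stage!r}")
    if surface.z_rpe.shape != (volume.n_bscans, volume.n_ascans):
        raise ValueError(
            f"surface shape {surface.z_rpe.shape} does not match volume "
            f"({volume.n_bscans}, {volume.n_ascans})"
        )
    rows = np.empty((volume.n_bscans, volume.n_ascans))
    for b in range(volume.n_bscans):
        try:
            rows[b] = extract_slab_means(volume.bscan(b), surface.z_rpe[b], slab)
        except SlabError as exc:
            raise SlabError(f"B-scan b={b}: {exc}") from None
    return EnFaceImage(pixels=rows, lateral_res_um=volume.lateral_res_um,
                       bscan_spacing_um=volume.bscan_spacing_um, slab=slab)
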