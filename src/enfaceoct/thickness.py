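"""Total retinal thickness maps and central subfield thickness (CST).

Commercial OCT instruments report retinal thickness between the inner
limiting membrane (ILM) and the RPE; this module reproduces that
computation from the same two-peak A-scan detection used for the RPE:
the *anterior* member of the detected peak pair marks the inner retinal
surface, and thickness is the axial ILM→RPE distance in micrometres.

The central subfield is the standard ETDRS central disc: 1 mm diameter
(500 μm radius) centred on the fovea; CST is the mean thickness over
map pixels whose centre lies within that disc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .volume_io import OCTVolume
from .rpe_segmentation import (
    SegmentationParams,
    RPESurface,
    BScanSegmentationError,
    _detect_peaks_bscan,
    _fill_invalid,
    median_smooth_depths,
)

__all__ = ["ThicknessMap", "CENTRAL_SUBFIELD_RADIUS_UM",
           "detect_ilm", "thickness_map", "central_subfield"]

CENTRAL_SUBFIELD_RADIUS_UM = 500.0


@dataclass(frozen=True)
class ThicknessMap:
    """ILM-to-RPE thickness per (b, x), in micrometres, with calibration."""

    thickness_um: np.ndarray                 # (n_bscans, n_ascans)
    lateral_res_um: float
    bscan_spacing_um: float
    fovea_center: Tuple[int, int]            # (x, b)

    def __post_init__(self) -> None:
        t = np.asarray(self.thickness_um, dtype=float)
        if t.ndim != 2:
            raise ValueError("thickness_um must be 2-D (b, x)")
        if t.min() < 0:
            raise ValueError("thickness must be non-negative everywhere")
        object.__setattr__(self, "thickness_um", t)

    @property
    def cst_um(self) -> float:
        return central_subfield(self, self.fovea_center)


def detect_ilm(volume: OCTVolume, params: SegmentationParams | None = None
               ) -> np.ndarray:
    """Anterior-peak (inner retinal surface) depths per (b, x).

    Uses the same smoothed two-peak detection as the RPE path and applies
    the same two median-smoothing passes; there is no windowed-maximum
    refinement because the inner surface is an intensity *edge*, not the
    brightest pixel of its neighbourhood.
    """
    params = params or SegmentationParams()
    n_b = volume.n_bscans
    z_ilm = np.empty((n_b, volume.n_ascans), dtype=int)
    for b in range(n_b):
        z_ant, _, valid = _detect_peaks_bscan(volume.bscan(b), params)
        if not valid.any():
            raise BScanSegmentationError(b)
        depths = _fill_invalid(z_ant, valid)
        depths = median_smooth_depths(depths, params.median_window_ascans)
        z_ilm[b] = median_smooth_depths(depths, params.median_window2_ascans)
    return z_ilm


def thickness_map(ilm: np.ndarray, rpe: RPESurface, axial_res_um: float,
                  *, lateral_res_um: float, bscan_spacing_um: float,
                  fovea_center: Optional[Tuple[int, int]] = None
                  ) -> ThicknessMap:
    """Axial ILM→RPE distance in μm; errors if the surfaces cross."""
    ilm = np.asarray(ilm)
    z_rpe = np.asarray(rpe.z_rpe)
    if ilm.shape != z_rpe.shape:
        raise ValueError(f"surface shapes differ: {ilm.shape} vs {z_rpe.shape}")
    if axial_res_um <= 0:
        raise ValueError("axial_res_um must be positive")
    crossing = np.argwhere(ilm > z_rpe)
    if crossing.size:
        coords = [(int(b), int(x)) for b, x in crossing[:10]]
        raise ValueError(
            f"ILM lies posterior to the RPE at {crossing.shape[0]} pixels, "
            f"first offenders (b, x): {coords}"
        )
    if fovea_center is None:
        fovea_center = (ilm.shape[1] // 2, ilm.shape[0] // 2)
    return ThicknessMap(
        thickness_um=(z_rpe - ilm).astype(float) * axial_res_um,
        lateral_res_um=lateral_res_um,
        bscan_spacing_um=bscan_spacing_um,
        fovea_center=tuple(fovea_center),
    )


def central_subfield(tmap: ThicknessMap, center: Optional[Tuple[int, int]] = None,
                     radius_um: float = CENTRAL_SUBFIELD_RADIUS_UM) -> float:
    """Mean thickness over pixels within ``radius_um`` of the fovea centre.

    Membership is by pixel-centre physical distance.  Raises when the disc
    misses the map entirely.
    """
    if center is None:
        center = tmap.fovea_center
    cx, cb = center
    n_b, n_x = tmap.thickness_um.shape
    dx = (np.arange(n_x) - cx) * tmap.lateral_res_um
    db = (np.arange(n_b) - cb) * tmap.bscan_spacing_um
    dist2 = db[:, None] ** 2 + dx[None, :] ** 2
    inside = dist2 <= radius_um ** 2
    if not inside.any():
        raise ValueError(
            f"central subfield disc at (x={cx}, b={cb}) does not intersect "
            f"the {n_b}×{n_x} map"
        )
    return float(tmap.thickness_um[inside].mean())
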