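"""Reading and writing OCT volumes, en face images, and surface tables.

Coordinate convention used throughout the package: a volume is indexed
``(z, x, b)`` where ``z`` is axial depth in pixels (``z = 0`` is the most
anterior row, vitreous side, increasing toward the choroid), ``x`` is the
A-scan index within a B-scan, and ``b`` is the B-scan index.  "Anterior to
the RPE" therefore always means *smaller* ``z``.  All indices are 0-based
and depth intervals are half-open.

Volumes travel as multi-page TIFF (one page per B-scan, each page a
``z × x`` image) or as little-endian raw binary with a JSON sidecar
declaring shape and dtype (``z`` fastest-varying).  En face images are
written as 8- or 16-bit grayscale PNG/TIFF with a JSON sidecar recording
the slab and calibration so the image is self-describing.  Surfaces are
plain TSV with columns ``(b, x, z_rpe)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

__all__ = [
    "DEFAULT_AXIAL_RES_UM",
    "DEFAULT_LATERAL_RES_UM",
    "DEFAULT_BSCAN_SPACING_UM",
    "VolumeFormatError",
    "CalibrationError",
    "OCTVolume",
    "EnFaceImage",
    "read_volume",
    "write_volume",
    "write_enface",
    "read_enface",
    "write_surface",
    "read_surface",
]

# Default acquisition calibration: 3.9 um axial sampling; a 15-degree by
# 15-degree raster of 768 A-scans x 145 B-scans, with the lateral extent
# mapped at the emmetropic-eye convention of 288 um per degree.  The
# um/degree constant is a configurable convention, not a measurement.
UM_PER_DEGREE = 288.0
SCAN_ANGLE_DEG = 15.0
DEFAULT_N_ASCANS = 768
DEFAULT_N_BSCANS = 145
DEFAULT_AXIAL_RES_UM = 3.9
DEFAULT_LATERAL_RES_UM = SCAN_ANGLE_DEG * UM_PER_DEGREE / DEFAULT_N_ASCANS
DEFAULT_BSCAN_SPACING_UM = SCAN_ANGLE_DEG * UM_PER_DEGREE / DEFAULT_N_BSCANS


class VolumeFormatError(ValueError):
    """A file's structure does not match its declared or required layout."""


class CalibrationError(ValueError):
    """A physical calibration value is missing or non-positive."""


def _check_calibration(name: str, value: float) -> float:
    if not np.isfinite(value) or value <= 0:
        raise CalibrationError(f"{name} must be positive and finite, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class OCTVolume:
    """A 3-D OCT intensity volume with physical calibration.

    Parameters
    ----------
    intensity
        Non-negative array indexed ``(z, x, b)``.
    axial_res_um, lateral_res_um, bscan_spacing_um
        Physical pixel pitch in micrometres along ``z``, ``x`` and ``b``.
    fovea_center
        Optional ``(x, b)`` location of the fovea; defaults to the
        geometric centre when absent.
    """

    intensity: np.ndarray
    axial_res_um: float = DEFAULT_AXIAL_RES_UM
    lateral_res_um: float = DEFAULT_LATERAL_RES_UM
    bscan_spacing_um: float = DEFAULT_BSCAN_SPACING_UM
    fovea_center: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity)
        if arr.ndim != 3:
            raise VolumeFormatError(
                f"intensity must be 3-D (z, x, b), got ndim={arr.ndim}"
            )
        if any(s < 1 for s in arr.shape):
            raise VolumeFormatError(f"all dimensions must be >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)) or arr.min() < 0:
            raise VolumeFormatError("intensities must be finite and non-negative")
        object.__setattr__(self, "intensity", arr)
        _check_calibration("axial_res_um", self.axial_res_um)
        _check_calibration("lateral_res_um", self.lateral_res_um)
        _check_calibration("bscan_spacing_um", self.bscan_spacing_um)

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_bscans(self) -> int:
        return self.intensity.shape[2]

    def bscan(self, b: int) -> np.ndarray:
        """The ``z × x`` image of B-scan ``b``."""
        return self.intensity[:, :, b]

    def default_fovea(self) -> Tuple[int, int]:
        if self.fovea_center is not None:
            return self.fovea_center
        return (self.n_ascans // 2, self.n_bscans // 2)

    def with_intensity(self, intensity: np.ndarray) -> "OCTVolume":
        return replace(self, intensity=intensity)


@dataclass(frozen=True)
class EnFaceImage:
    """Mean-intensity en face projection: rows are B-scans, columns A-scans."""

    pixels: np.ndarray
    lateral_res_um: float
    bscan_spacing_um: float
    slab: "object" = None  # SlabSpec; kept loose to avoid an import cycle

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2:
            raise VolumeFormatError(f"en face image must be 2-D, got ndim={arr.ndim}")
        if arr.size == 0:
            raise VolumeFormatError("en face image must be non-empty")
        if not np.all(np.isfinite(arr)) or arr.min() < 0:
            raise VolumeFormatError("en face pixels must be finite and non-negative")
        object.__setattr__(self, "pixels", arr)
        _check_calibration("lateral_res_um", self.lateral_res_um)
        _check_calibration("bscan_spacing_um", self.bscan_spacing_um)

    @property
    def pixel_area_mm2(self) -> float:
        return self.lateral_res_um * self.bscan_spacing_um * 1e-6


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_volume(path, *, axial_res_um: Optional[float] = None,
                lateral_res_um: Optional[float] = None,
                bscan_spacing_um: Optional[float] = None,
                fovea_center: Optional[Tuple[int, int]] = None) -> OCTVolume:
    """Read an OCT volume from multi-page TIFF or raw binary + JSON sidecar.

    TIFF pages are B-scans in acquisition order, each a ``z × x`` image.
    Raw binaries require a sidecar ``<file>.json`` declaring ``shape``
    (``[n_z, n_x, n_b]``) and ``dtype``; data are little-endian with ``z``
    fastest-varying.  Calibration keyword arguments override any sidecar
    values; whatever remains unset falls back to the package defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) != 1:
                raise VolumeFormatError(
                    f"B-scan pages disagree in shape: {sorted(shapes)}"
                )
            pages = tf.asarray()  # (b, z, x)
        if pages.ndim == 2:
            pages = pages[None]
        intensity = np.moveaxis(pages, 0, 2)  # -> (z, x, b)
    else:
        if not sidecar.exists():
            raise VolumeFormatError(
                f"raw volume {path} needs a JSON sidecar {sidecar.name} "
                "declaring shape and dtype"
            )
        try:
            shape = tuple(int(s) for s in meta["shape"])
            dtype = np.dtype(meta["dtype"]).newbyteorder("<")
        except KeyError as exc:
            raise VolumeFormatError(f"sidecar missing required field {exc}") from exc
        raw = np.fromfile(path, dtype=dtype)
        expected = int(np.prod(shape))
        if raw.size != expected:
            raise VolumeFormatError(
                f"file holds {raw.size} samples but sidecar shape {shape} "
                f"implies {expected}"
            )
        # z fastest-varying: stored order is (b, x, z) slowest-to-fastest.
        intensity = raw.reshape(shape[::-1]).transpose(2, 1, 0)

    def pick(arg, key, default):
        if arg is not None:
            return arg
        if key in meta:
            return meta[key]
        return default

    fov = fovea_center if fovea_center is not None else meta.get("fovea_center")
    return OCTVolume(
        intensity=intensity,
        axial_res_um=pick(axial_res_um, "axial_res_um", DEFAULT_AXIAL_RES_UM),
        lateral_res_um=pick(lateral_res_um, "lateral_res_um", DEFAULT_LATERAL_RES_UM),
        bscan_spacing_um=pick(bscan_spacing_um, "bscan_spacing_um",
                              DEFAULT_BSCAN_SPACING_UM),
        fovea_center=tuple(fov) if fov is not None else None,
    )


def write_volume(volume: OCTVolume, path) -> None:
    """Write a volume as multi-page TIFF (pages = B-scans) plus JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise VolumeFormatError("write_volume writes multi-page TIFF (.tif/.tiff)")
    pages = np.moveaxis(volume.intensity, 2, 0)  # (b, z, x)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "axial_res_um": volume.axial_res_um,
        "lateral_res_um": volume.lateral_res_um,
        "bscan_spacing_um": volume.bscan_spacing_um,
    }
    if volume.fovea_center is not None:
        meta["fovea_center"] = list(volume.fovea_center)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# En face images
# ---------------------------------------------------------------------------

def write_enface(image: EnFaceImage, path, *, scale: str = "linear-min-max",
                 fixed_range: Optional[Tuple[float, float]] = None,
                 bit_depth: int = 8) -> None:
    """Write an en face image as grayscale PNG/TIFF with a JSON sidecar.

    ``scale`` is the display-normalization policy: ``linear-min-max``
    stretches the image's own range to the full bit range; ``fixed-range``
    maps the given ``(lo, hi)`` interval instead (values clipped).
    """
    path = Path(path)
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    arr = image.pixels
    if scale == "linear-min-max":
        lo, hi = float(arr.min()), float(arr.max())
    elif scale == "fixed-range":
        if fixed_range is None:
            raise ValueError("fixed-range scaling requires fixed_range=(lo, hi)")
        lo, hi = map(float, fixed_range)
        if hi <= lo:
            raise ValueError(f"fixed_range must satisfy lo < hi, got {fixed_range}")
    else:
        raise ValueError(f"unknown scale policy {scale!r}")

    top = 2 ** bit_depth - 1
    if hi > lo:
        scaled = (np.clip(arr, lo, hi) - lo) / (hi - lo) * top
    else:  # constant image under min-max: uniform output raster
        scaled = np.zeros_like(arr)
    out = np.round(scaled).astype(np.uint8 if bit_depth == 8 else np.uint16)
    iio.imwrite(path, out)

    slab = image.slab
    sidecar = {
        "scale": scale,
        "range": [lo, hi],
        "bit_depth": bit_depth,
        "lateral_res_um": image.lateral_res_um,
        "bscan_spacing_um": image.bscan_spacing_um,
        "slab": None if slab is None else {
            "offset_um": slab.offset_um,
            "thickness_um": slab.thickness_um,
            "offset_px": slab.offset_px,
            "thickness_px": slab.thickness_px,
            "alignment": slab.alignment,
        },
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_enface(path) -> Tuple[np.ndarray, dict]:
    """Read back an en face raster and its sidecar, undoing the scaling."""
    path = Path(path)
    raw = np.asarray(iio.imread(path), dtype=float)
    meta = json.loads(_sidecar_path(path).read_text())
    lo, hi = meta["range"]
    top = 2 ** meta["bit_depth"] - 1
    pixels = raw / top * (hi - lo) + lo if hi > lo else np.full(raw.shape, lo)
    return pixels, meta


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------

def write_surface(surface, path) -> None:
    """Write a segmented surface as TSV with columns ``b, x, z_rpe``."""
    z = np.asarray(surface.z_rpe)
    n_b, n_x = z.shape
    bb, xx = np.meshgrid(np.arange(n_b), np.arange(n_x), indexing="ij")
    df = pd.DataFrame({
        "b": bb.ravel(),
        "x": xx.ravel(),
        "z_rpe": z.ravel(),
    })
    df.to_csv(path, sep="\t", index=False)


def read_surface(path, *, n_depth: Optional[int] = None):
    """Read a surface TSV back into an :class:`RPESurface`.

    The table must cover every ``(b, x)`` cell of the implied grid exactly
    once; depths must be non-negative (and ``< n_depth`` when given).
    """
    from .rpe_segmentation import RPESurface  # local import: avoid cycle

    df = pd.read_csv(path, sep="\t")
    required = {"b", "x", "z_rpe"}
    if not required.issubset(df.columns):
        raise VolumeFormatError(
            f"surface TSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df[["b", "x", "z_rpe"]].isna().any().any():
        raise VolumeFormatError("surface TSV contains malformed/missing values")
    if (df["z_rpe"] < 0).any():
        bad = df.loc[df["z_rpe"] < 0].iloc[0]
        raise VolumeFormatError(
            f"negative depth {bad.z_rpe} at (b={int(bad.b)}, x={int(bad.x)})"
        )
    n_b = int(df["b"].max()) + 1
    n_x = int(df["x"].max()) + 1
    z = np.full((n_b, n_x), -1, dtype=float)
    z[df["b"].to_numpy(int), df["x"].to_numpy(int)] = df["z_rpe"].to_numpy()
    missing = np.argwhere(z < 0)
    if missing.size:
        b0, x0 = missing[0]
        raise VolumeFormatError(f"surface TSV missing cell (b={b0}, x={x0})")
    if n_depth is not None and z.max() >= n_depth:
        bad = np.argwhere(z >= n_depth)[0]
        raise VolumeFormatError(
            f"depth {z[tuple(bad)]} at (b={bad[0]}, x={bad[1]}) exceeds "
            f"volume depth {n_depth}"
        )
    zi = z.astype(int) if np.allclose(z, np.round(z)) else z
    return RPESurface(z_rpe=zi, stage="final")
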