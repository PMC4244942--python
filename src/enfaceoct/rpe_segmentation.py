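"""Automatic RPE surface detection in SDOCT volumes.

The retinal pigment epithelium (RPE) is the hyperreflective outer band of
the retina and serves as the depth anchor for en face slab extraction.
It is located per B-scan in four stages:

1. **Initial detection** — each A-scan is smoothed with a centred moving
   average and the two greatest-intensity *local maxima* (subject to a
   minimum axial separation) are found; these correspond to the nerve
   fiber layer and the RPE.  The posterior (larger ``z``) peak is the
   initial RPE depth.  A-scans without two qualifying peaks are filled by
   interpolation from their nearest valid neighbours.
2. **Median smoothing** — the depth trace across A-scans is smoothed with
   a running median, yielding a robust per-B-scan estimate.
3. **Refinement** — the RPE is re-located as the maximum-intensity pixel
   of the *raw* A-scan within ``refine_radius_px`` (default 10) pixels of
   the estimate, undoing the axial bias introduced by smoothing.
4. **Final median smoothing** of the refined depths.

Because detection is independent per B-scan and anchored to image
content, constant axial displacement of a B-scan (eye motion between
B-scans) shifts its detected surface by exactly that amount, so
downstream RPE-relative slab extraction is invariant to axial motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from typing import Tuple

import numpy as np

from .volume_io import OCTVolume

__all__ = [
    "SegmentationParams",
    "RPESurface",
    "InsufficientPeaksError",
    "BScanSegmentationError",
    "smooth_ascan",
    "detect_two_peaks",
    "initial_rpe_bscan",
    "median_smooth_depths",
    "refine_rpe_bscan",
    "segment_volume",
]

logger = logging.getLogger(__name__)


class InsufficientPeaksError(ValueError):
    """Fewer than two qualifying local maxima were found in an A-scan."""

    def __init__(self, found: int):
        self.found = found
        super().__init__(f"insufficient peaks: found {found}, need 2")


class BScanSegmentationError(RuntimeError):
    """No A-scan of a B-scan yielded a two-peak detection."""

    def __init__(self, b: int):
        self.b = b
        super().__init__(f"segmentation failed for entire B-scan b={b}")


def _check_odd_window(window: int, name: str = "window") -> None:
    if window < 1 or window % 2 == 0:
        raise ValueError(f"{name} must be odd and >= 1, got {window}")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the RPE detection pipeline.

    ``refine_radius_px`` is a half-width: the refinement search spans
    ``estimate ± refine_radius_px``.  Window lengths are in pixels
    (moving average, axial) or A-scans (median filters, lateral) and must
    be odd so windows are centred.
    """

    ma_window_px: int = 7
    median_window_ascans: int = 15
    median_window2_ascans: int = 15
    refine_radius_px: int = 10
    min_peak_separation_px: int = 20

    def __post_init__(self) -> None:
        _check_odd_window(self.ma_window_px, "ma_window_px")
        _check_odd_window(self.median_window_ascans, "median_window_ascans")
        _check_odd_window(self.median_window2_ascans, "median_window2_ascans")
        if self.refine_radius_px < 0:
            raise ValueError("refine_radius_px must be >= 0")
        if self.min_peak_separation_px < 1:
            raise ValueError("min_peak_separation_px must be >= 1")


@dataclass(frozen=True)
class RPESurface:
    """Per-(B-scan, A-scan) axial depth of the RPE.

    ``z_rpe`` has shape ``(n_bscans, n_ascans)``; ``stage`` records which
    pipeline stage produced it (``initial``, ``smoothed``, ``refined`` or
    ``final``).
    """

    z_rpe: np.ndarray
    stage: str = "final"
    params: SegmentationParams | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z_rpe)
        if z.ndim != 2:
            raise ValueError(f"z_rpe must be 2-D (b, x), got ndim={z.ndim}")
        if z.min() < 0:
            raise ValueError("z_rpe depths must be non-negative")
        if self.stage not in ("initial", "smoothed", "refined", "final"):
            raise ValueError(f"unknown stage {self.stage!r}")
        object.__setattr__(self, "z_rpe", z)

    @property
    def n_bscans(self) -> int:
        return self.z_rpe.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.z_rpe.shape[1]


# ---------------------------------------------------------------------------
# Stage 1: A-scan smoothing and two-peak detection
# ---------------------------------------------------------------------------

def smooth_ascan(profile: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge windows truncated to the valid range."""
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1:
        raise ValueError("profile must be 1-D")
    _check_odd_window(window)
    if window > profile.shape[0]:
        raise ValueError(
            f"window {window} exceeds profile length {profile.shape[0]}"
        )
    return _smooth_columns(profile[:, None], window)[:, 0]


def _smooth_columns(bscan: np.ndarray, window: int) -> np.ndarray:
    """Moving average of every column of a (z, x) array, truncated edges."""
    n = bscan.shape[0]
    half = window // 2
    # cumulative-sum windowed mean with per-row valid counts
    csum = np.zeros((n + 1,) + bscan.shape[1:])
    np.cumsum(bscan, axis=0, out=csum[1:])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    sums = csum[hi] - csum[lo]
    counts = (hi - lo).astype(float)
    return sums / counts.reshape((-1,) + (1,) * (bscan.ndim - 1))


def _local_maxima_mask(columns: np.ndarray) -> np.ndarray:
    """Plateau-aware strict local maxima of each column of a (z, x) array.

    A sample is a local maximum when it strictly exceeds its immediate
    neighbours; a plateau of equal samples strictly above both flanks is
    marked at its first (most anterior) index.  Endpoints are never maxima.
    """
    nz = columns.shape[0]
    mask = np.zeros(columns.shape, dtype=bool)
    if nz < 3:
        return mask
    d = np.sign(np.diff(columns, axis=0))  # (nz-1, x)
    rows = np.broadcast_to(np.arange(nz - 1).reshape((-1,) + (1,) * (d.ndim - 1)),
                           d.shape)
    # index of the next nonzero diff at-or-after each position (nz-1 if none)
    nz_idx = np.where(d != 0, rows, nz - 1)
    nxt = np.minimum.accumulate(nz_idx[::-1], axis=0)[::-1]
    next_sign = np.take_along_axis(d, np.minimum(nxt, nz - 2), axis=0)
    has_next = nxt <= nz - 2
    # value position i (1 <= i <= nz-2) starts a peak/plateau iff the step
    # into it rises (d[i-1] > 0) and the next nonzero step from i on falls
    mask[1:-1] = (d[:-1] > 0) & (next_sign[1:] < 0) & has_next[1:]
    return mask


def _top_two_peaks_columns(columns: np.ndarray, min_sep: int
                           ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per column: the two highest local maxima at least ``min_sep`` apart.

    Selection is greedy by height: the globally highest local maximum is
    taken first, then the highest remaining maximum at axial distance
    >= ``min_sep`` from it.  Returns ``(z_anterior, z_posterior, valid)``;
    where ``valid`` is False the other outputs are undefined.
    """
    nz = columns.shape[0]
    peaks = _local_maxima_mask(columns)
    vals = np.where(peaks, columns, -np.inf)
    z1 = np.argmax(vals, axis=0)
    v1 = np.take_along_axis(vals, z1[None], axis=0)[0]
    zgrid = np.arange(nz).reshape((-1,) + (1,) * (columns.ndim - 1))
    far = np.abs(zgrid - z1[None]) >= min_sep
    vals2 = np.where(far, vals, -np.inf)
    z2 = np.argmax(vals2, axis=0)
    v2 = np.take_along_axis(vals2, z2[None], axis=0)[0]
    valid = np.isfinite(v1) & np.isfinite(v2)
    z_ant = np.minimum(z1, z2)
    z_post = np.maximum(z1, z2)
    return z_ant, z_post, valid


def detect_two_peaks(profile: np.ndarray, min_sep: int) -> Tuple[int, int]:
    """Locate the NFL and RPE peaks of a smoothed A-scan.

    Returns the depth indices ``(z_anterior, z_posterior)`` of the two
    greatest-intensity local maxima whose axial separation is at least
    ``min_sep`` pixels.  Raises :class:`InsufficientPeaksError` when fewer
    than two qualifying maxima exist.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.shape[0] < 3:
        raise ValueError("profile must be 1-D with length >= 3")
    cols = profile[:, None]
    z_ant, z_post, valid = _top_two_peaks_columns(cols, min_sep)
    if not valid[0]:
        found = int(_local_maxima_mask(cols)[:, 0].sum())
        raise InsufficientPeaksError(found)
    return int(z_ant[0]), int(z_post[0])


def _detect_peaks_bscan(bscan: np.ndarray, params: SegmentationParams
                        ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed two-peak detection for every A-scan of a (z, x) B-scan."""
    sm = _smooth_columns(np.asarray(bscan, dtype=float), params.ma_window_px)
    return _top_two_peaks_columns(sm, params.min_peak_separation_px)


def _fill_invalid(depths: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Interpolate failed A-scans from nearest valid neighbours (ends: nearest)."""
    out = depths.astype(float)
    if valid.all():
        return out
    x = np.arange(depths.shape[0])
    out[~valid] = np.interp(x[~valid], x[valid], depths[valid].astype(float))
    return np.round(out).astype(depths.dtype)


def initial_rpe_bscan(bscan: np.ndarray, params: SegmentationParams | None = None
                      ) -> np.ndarray:
    """Initial per-A-scan RPE depths of one B-scan (posterior smoothed peak)."""
    params = params or SegmentationParams()
    _, z_post, valid = _detect_peaks_bscan(bscan, params)
    if not valid.any():
        raise BScanSegmentationError(-1)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.debug("initial RPE: interpolated %d/%d A-scans", n_bad, valid.size)
    return _fill_invalid(z_post, valid)


# ---------------------------------------------------------------------------
# Stage 2/4: median smoothing of depth traces
# ---------------------------------------------------------------------------

def median_smooth_depths(depths: np.ndarray, window: int) -> np.ndarray:
    """Running median across A-scans with replicated (nearest) edge values.

    Edge windows are completed by replicating the first/last depth, so
    windows are always odd and the median exact; this preserves monotone
    depth traces at the B-scan edges, where a truncated window would bias
    the output toward the interior.  Every output value is a member of
    the input multiset restricted to its (clipped) window.
    """
    depths = np.asarray(depths)
    _check_odd_window(window)
    if depths.ndim != 1 or depths.size == 0:
        raise ValueError("depths must be a non-empty 1-D vector")
    if window == 1:
        return depths.copy()
    half = window // 2
    padded = np.concatenate([np.repeat(depths[:1], half), depths,
                             np.repeat(depths[-1:], half)])
    win = np.lib.stride_tricks.sliding_window_view(padded, window)
    return np.sort(win, axis=1)[:, half]


# ---------------------------------------------------------------------------
# Stage 3: windowed maximum-intensity refinement
# ---------------------------------------------------------------------------

def refine_rpe_bscan(bscan: np.ndarray, estimate: np.ndarray, radius: int
                     ) -> np.ndarray:
    """Snap each depth to the brightest raw pixel within ``± radius`` of it.

    Ties are broken toward the smaller ``|z − estimate|``, then toward the
    smaller ``z``; the result therefore never leaves the search window.
    """
    bscan = np.asarray(bscan, dtype=float)
    estimate = np.asarray(estimate)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    nz, nx = bscan.shape
    est = np.round(estimate).astype(int)
    if est.min() < 0 or est.max() >= nz:
        raise ValueError("estimate out of B-scan depth bounds")
    offs = np.arange(-radius, radius + 1)[:, None]            # (w, 1)
    z = est[None, :] + offs                                    # (w, x)
    inside = (z >= 0) & (z < nz)
    vals = np.where(inside,
                    bscan[np.clip(z, 0, nz - 1), np.arange(nx)[None, :]],
                    -np.inf)
    vmax = vals.max(axis=0)
    # lexicographic tie-break: smaller |offset|, then negative offset first
    key = 2 * np.abs(offs) + (offs > 0)
    key = np.where(vals == vmax[None, :], key, np.iinfo(np.int64).max)
    best = np.argmin(key, axis=0)
    return (est + (best - radius)).astype(int)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def segment_volume(volume: OCTVolume, params: SegmentationParams | None = None
                   ) -> RPESurface:
    """Detect the RPE surface across an entire volume.

    Runs initial detection → median smoothing → windowed refinement →
    second median smoothing independently on each B-scan.  Deterministic
    for fixed input and parameters.
    """
    params = params or SegmentationParams()
    n_b = volume.n_bscans
    z_rpe = np.empty((n_b, volume.n_ascans), dtype=int)
    for b in range(n_b):
        bscan = volume.bscan(b)
        try:
            initial = initial_rpe_bscan(bscan, params)
        except BScanSegmentationError:
            raise BScanSegmentationError(b) from None
        smoothed = median_smooth_depths(initial, params.median_window_ascans)
        refined = refine_rpe_bscan(bscan, smoothed, params.refine_radius_px)
        z_rpe[b] = median_smooth_depths(refined, params.median_window2_ascans)
    return RPESurface(z_rpe=z_rpe, stage="final", params=params)
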