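"""Independent brute-force reference implementations used by the tests.

Everything here is written as plainly as possible — explicit loops,
no vectorization — so it shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def moving_average_oracle(profile, window):
    """Per-index mean over the centred window truncated to the array."""
    n = len(profile)
    half = window // 2
    out = np.empty(n, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = sum(profile[lo:hi]) / (hi - lo)
    return out


def running_median_oracle(depths, window):
    """Per-index median over the centred window, edges completed by
    replicating the first/last value."""
    n = len(depths)
    half = window // 2
    out = np.empty(n, dtype=np.asarray(depths).dtype)
    for i in range(n):
        w = []
        for j in range(i - half, i + half + 1):
            w.append(depths[min(max(j, 0), n - 1)])
        w.sort()
        out[i] = w[half]
    return out


def local_maxima_oracle(profile):
    """Indices of strict local maxima; plateaus marked at their first index."""
    n = len(profile)
    peaks = []
    i = 1
    while i < n - 1:
        if profile[i] > profile[i - 1]:
            j = i
            while j + 1 < n and profile[j + 1] == profile[i]:
                j += 1
            if j < n - 1 and profile[j + 1] < profile[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return peaks


def top_two_peaks_oracle(profile, min_sep):
    """Greedy highest peak, then highest at distance >= min_sep; None if <2."""
    peaks = local_maxima_oracle(profile)
    if not peaks:
        return None
    z1 = max(peaks, key=lambda z: (profile[z], -z))
    candidates = [z for z in peaks if abs(z - z1) >= min_sep]
    if not candidates:
        return None
    z2 = max(candidates, key=lambda z: (profile[z], -z))
    return (min(z1, z2), max(z1, z2))


def windowed_argmax_oracle(bscan, estimate, radius):
    """Brightest pixel within ±radius of the estimate, tie-broken toward the
    estimate then toward smaller depth."""
    nz, nx = bscan.shape
    out = np.empty(nx, dtype=int)
    for x in range(nx):
        e = int(estimate[x])
        best = None
        for z in range(max(0, e - radius), min(nz, e + radius + 1)):
            key = (-bscan[z, x], abs(z - e), z)
            if best is None or key < best[0]:
                best = (key, z)
        out[x] = best[1]
    return out


def otsu_oracle(values):
    """Exhaustive between-class-variance maximization; smallest tied cutoff.

    Returns the cutoff c such that the dark class is ``values < c``.
    """
    flat = np.asarray(values, dtype=float).ravel()
    uniq = np.sort(np.unique(flat))
    best, best_c = -1.0, None
    for c in uniq[1:]:
        lo = flat[flat < c]
        hi = flat[flat >= c]
        w0 = lo.size / flat.size
        w1 = hi.size / flat.size
        bc = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if bc > best:
            best, best_c = bc, c
    return best_c


def flood_fill_label_oracle(mask, connectivity):
    """Connected components by BFS flood fill; labels in raster order.

    Returns an int label map (0 = background).
    """
    mask = np.asarray(mask, dtype=bool)
    n_r, n_c = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    lab = np.zeros(mask.shape, dtype=int)
    nxt = 1
    for r in range(n_r):
        for c in range(n_c):
            if mask[r, c] and lab[r, c] == 0:
                stack = [(r, c)]
                lab[r, c] = nxt
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < n_r and 0 <= c2 < n_c
                                and mask[r2, c2] and lab[r2, c2] == 0):
                            lab[r2, c2] = nxt
                            stack.append((r2, c2))
                nxt += 1
    return lab


def ellipse_mask_oracle(n_x, n_b, center, semi_axes):
    """Pixel-centre ellipse membership by direct loop."""
    cx, cb = center
    ax, ab = semi_axes
    out = np.zeros((n_x, n_b), dtype=bool)
    for x in range(n_x):
        for b in range(n_b):
            if ((x - cx) / ax) ** 2 + ((b - cb) / ab) ** 2 <= 1.0:
                out[x, b] = True
    return out


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * np.logical_and(a, b).sum() / denom
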