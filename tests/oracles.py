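"""Independent brute-force oracles used by the test suite.

Each function reimplements a measured quantity by a different route from
the library (flood fill instead of union-find labelling, an exhaustive
angle sweep instead of rotating calipers, direct python sums instead of
vectorised moments) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected components by explicit BFS flood fill.

    Labels are assigned in raster-scan order of each component's first
    pixel, starting at 1.
    """
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    elif connectivity == 4:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    else:
        raise ValueError(connectivity)
    h, w = mask.shape
    out = np.zeros((h, w), dtype=np.int32)
    label = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or out[r0, c0]:
                continue
            label += 1
            stack = [(r0, c0)]
            out[r0, c0] = label
            while stack:
                r, c = stack.pop()
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not out[rr, cc]:
                        out[rr, cc] = label
                        stack.append((rr, cc))
    return out


def _sweep_widths(pts: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    dirs = np.column_stack([np.cos(angles_rad), np.sin(angles_rad)])
    proj = pts @ dirs.T  # (n_points, n_angles)
    return proj.max(axis=0) - proj.min(axis=0)


def caliper_sweep(points: np.ndarray, step_deg: float = 0.01) -> tuple[float, float]:
    """(max, min) projection width of a point set by exhaustive sweep.

    Sweeps directions 0..180 degrees in ``step_deg`` steps and measures
    the extent of the projections onto each direction; the maximum over
    directions is the maximum caliper (Feret) diameter and the minimum is
    the minimum caliper (MinFeret) width.  The width function of a
    polygon has a *linear* kink at each minimum (it is a maximum of
    sinusoids), so the coarse sweep brackets the minimising direction and
    a local fine sweep (1e-5 degrees) pins the minimum itself; maxima are
    smooth, so the coarse sweep already resolves the Feret diameter.
    """
    pts = np.asarray(points, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    widths = _sweep_widths(pts, angles)
    w_max = float(widths.max())
    w_min = float(widths.min())
    # refine every near-minimal valley, not just the argmin: a kinked
    # minimum in a neighbouring valley can undercut the coarse winner
    for k in np.nonzero(widths < w_min + 2e-3)[0]:
        lo, hi = angles[k] - np.deg2rad(step_deg), angles[k] + np.deg2rad(step_deg)
        fine = np.linspace(lo, hi, int(2 * step_deg / 1e-5) + 1)
        w_min = min(w_min, float(_sweep_widths(pts, fine).min()))
    return w_max, w_min


def chain_length(boundary: np.ndarray) -> float:
    """Closed-chain length by an explicit step-by-step walk."""
    pts = [tuple(map(float, p)) for p in boundary]
    total = 0.0
    for i, p in enumerate(pts):
        q = pts[(i + 1) % len(pts)]
        total += math.hypot(q[0] - p[0], q[1] - p[1])
    return total


def moment_stats(values) -> tuple[float, float]:
    """Skewness and excess kurtosis by direct python sums."""
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    m2 = sum((v - mean) ** 2 for v in vals) / n
    m3 = sum((v - mean) ** 3 for v in vals) / n
    m4 = sum((v - mean) ** 4 for v in vals) / n
    return m3 / m2**1.5, m4 / m2**2 - 3.0


def ols_fit(x, y) -> tuple[float, float]:
    """Closed-form simple OLS slope and intercept."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    slope = sxy / sxx
    return slope, my - slope * mx


def intermeans_iteration(hist: np.ndarray) -> float:
    """IsoData threshold by literal repeated class-mean averaging."""
    levels = list(range(256))
    total = sum(hist)
    t = sum(l * h for l, h in zip(levels, hist)) / total
    for _ in range(1000):
        low_w = sum(h for l, h in zip(levels, hist) if l <= t)
        high_w = total - low_w
        if low_w == 0 or high_w == 0:
            break
        m1 = sum(l * h for l, h in zip(levels, hist) if l <= t) / low_w
        m2 = sum(l * h for l, h in zip(levels, hist) if l > t) / high_w
        t_new = (m1 + m2) / 2
        if t_new == t:
            break
        t = t_new
    return t
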