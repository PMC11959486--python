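"""Independent brute-force reference implementations used only by tests.

Every function here recomputes an operation from its definition with
explicit loops (or a naive enumeration), deliberately avoiding the code
paths and library calls the production implementations use.
"""

from collections import deque

import numpy as np
import scipy.stats


def brute_mip(channel_3d):
    z, ny, nx = channel_3d.shape
    out = np.empty((ny, nx))
    for y in range(ny):
        for x in range(nx):
            m = channel_3d[0, y, x]
            for k in range(1, z):
                if channel_3d[k, y, x] > m:
                    m = channel_3d[k, y, x]
            out[y, x] = m
    return out


def brute_otsu(values, nbins=256):
    """Exhaustive search over all candidate split points for the maximum
    between-class variance on an nbins histogram of the input range."""
    arr = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(arr, bins=nbins, range=(arr.min(), arr.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = hist.sum()
    best_var, best_idx = -1.0, 0
    for split in range(nbins - 1):  # class 1 = bins 0..split, class 2 = rest
        w0 = hist[: split + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: split + 1] * centers[: split + 1]).sum() / w0
        mu1 = (hist[split + 1 :] * centers[split + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:  # strict: keeps the lowest qualifying threshold
            best_var, best_idx = var, split
    return centers[best_idx]


def brute_moments(slice_2d, nbins=256):
    """Tsai's moment-preserving threshold, re-derived via np.roots."""
    arr = np.asarray(slice_2d, dtype=float).ravel()
    hist, edges = np.histogram(arr, bins=nbins, range=(arr.min(), arr.max()))
    p = hist / hist.sum()
    i = np.arange(nbins, dtype=float)
    m1, m2, m3 = (i * p).sum(), (i**2 * p).sum(), (i**3 * p).sum()
    cd = m2 - m1 * m1
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    roots = np.roots([1.0, c1, c0])
    z0, z1 = np.sort(roots.real)
    p0 = (z1 - m1) / (z1 - z0)
    cdf = np.cumsum(p)
    idx = int(np.argmax(cdf >= p0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers[idx]


def brute_bernsen(slice_2d, radius, contrast, global_otsu):
    """Per-pixel local min/max over the radius-r disk by direct loops."""
    f = np.asarray(slice_2d, dtype=float)
    ny, nx = f.shape
    out = np.zeros((ny, nx), dtype=bool)
    r2 = radius * radius
    for y in range(ny):
        for x in range(nx):
            lo, hi = np.inf, -np.inf
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    if dy * dy + dx * dx > r2:
                        continue
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < ny and 0 <= xx < nx:
                        v = f[yy, xx]
                        lo = min(lo, v)
                        hi = max(hi, v)
            mid = 0.5 * (lo + hi)
            if hi - lo >= contrast:
                out[y, x] = f[y, x] > mid
            else:
                out[y, x] = mid > global_otsu
    return out


def brute_rolling_ball(slice_2d, radius):
    """Sliding-paraboloid background by naive sup-over-translates.

    For every apex position the highest paraboloid of curvature
    1/radius fitting under the surface is found by scanning all pixels;
    the background is the upper envelope of those paraboloids.
    """
    f = np.asarray(slice_2d, dtype=float)
    ny, nx = f.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    apex = np.empty((ny, nx))
    for y0 in range(ny):
        for x0 in range(nx):
            d2 = (ys - y0) ** 2 + (xs - x0) ** 2
            apex[y0, x0] = np.min(f + d2 / (2.0 * radius))
    bg = np.full((ny, nx), -np.inf)
    for y0 in range(ny):
        for x0 in range(nx):
            d2 = (ys - y0) ** 2 + (xs - x0) ** 2
            bg = np.maximum(bg, apex[y0, x0] - d2 / (2.0 * radius))
    bg = np.minimum(bg, f)
    return f - bg


def _ball_offsets(radius):
    offs = []
    for dz in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                if dz * dz + dy * dy + dx * dx <= radius * radius:
                    offs.append((dz, dy, dx))
    return offs


def brute_dilate(mask, radius):
    """Binary dilation by a ball; out-of-bounds voxels are background."""
    m = np.asarray(mask, dtype=bool)
    nz, ny, nx = m.shape
    out = np.zeros_like(m)
    for (z, y, x) in np.argwhere(m):
        for dz, dy, dx in _ball_offsets(radius):
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                out[zz, yy, xx] = True
    return out


def brute_erode(mask, radius):
    m = np.asarray(mask, dtype=bool)
    nz, ny, nx = m.shape
    out = np.zeros_like(m)
    for (z, y, x) in np.argwhere(m):
        ok = True
        for dz, dy, dx in _ball_offsets(radius):
            zz, yy, xx = z + dz, y + dy, x + dx
            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx) or not m[zz, yy, xx]:
                ok = False
                break
        out[z, y, x] = ok
    return out


def brute_shell(mask, radius):
    """dilate(open(M)) AND NOT erode(open(M)) by voxel loops."""
    opened = brute_dilate(brute_erode(mask, radius), radius)
    return brute_dilate(opened, radius) & ~brute_erode(opened, radius)


def flood_fill_label(mask, connectivity=26):
    """Connected-component labelling by breadth-first flood fill."""
    m = np.asarray(mask, dtype=bool)
    if connectivity == 26:
        neigh = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    nz, ny, nx = m.shape
    labels = np.zeros(m.shape, dtype=int)
    current = 0
    for start in map(tuple, np.argwhere(m)):
        if labels[start]:
            continue
        current += 1
        q = deque([start])
        labels[start] = current
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in neigh:
                zz, yy, xx = z + dz, y + dy, x + dx
                if (
                    0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                    and m[zz, yy, xx] and not labels[zz, yy, xx]
                ):
                    labels[zz, yy, xx] = current
                    q.append((zz, yy, xx))
    return labels, current


def welch_ttest(control, treatment, tails="two"):
    """Welch's t statistic and p-value from the textbook formulas."""
    c = np.asarray(control, dtype=float)
    t = np.asarray(treatment, dtype=float)
    nc, nt = len(c), len(t)
    vc, vt = c.var(ddof=1), t.var(ddof=1)
    se2 = vc / nc + vt / nt
    tstat = (t.mean() - c.mean()) / np.sqrt(se2)
    df = se2**2 / ((vc / nc) ** 2 / (nc - 1) + (vt / nt) ** 2 / (nt - 1))
    if tails == "two":
        p = 2.0 * scipy.stats.t.sf(abs(tstat), df)
    else:  # one-tailed, treatment > control
        p = scipy.stats.t.sf(tstat, df)
    return tstat, p


def otsu_split_variance(values, threshold, nbins=256):
    """Between-class variance achieved by a given threshold on the
    standard nbins histogram (for checking near-optimality)."""
    arr = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(arr, bins=nbins, range=(arr.min(), arr.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    split = int(np.clip(np.searchsorted(centers, threshold, side="right") - 1, 0, nbins - 2))
    n = hist.sum()
    w0 = hist[: split + 1].sum()
    w1 = n - w0
    if w0 == 0 or w1 == 0:
        return -np.inf
    mu0 = (hist[: split + 1] * centers[: split + 1]).sum() / w0
    mu1 = (hist[split + 1 :] * centers[split + 1 :]).sum() / w1
    return w0 * w1 * (mu0 - mu1) ** 2
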