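"""Independent brute-force oracles used only to check the implementation."""

import numpy as np


def membrane_profile_1d(width_nm, thickness_nm, psf_sigma_nm,
                        half_extent_nm=600.0, step_nm=0.25):
    """Dense 1-D cross-section of a straight membrane tube.

    Two boxes of the membrane thickness centred at +-width/2, convolved
    numerically with a Gaussian PSF.  Returns (positions_nm, profile).
    """
    x = np.arange(-half_extent_nm, half_extent_nm + step_nm, step_nm)
    density = ((np.abs(x - width_nm / 2.0) <= thickness_nm / 2.0)
               | (np.abs(x + width_nm / 2.0) <= thickness_nm / 2.0)
               ).astype(float)
    k = np.arange(-6 * psf_sigma_nm, 6 * psf_sigma_nm + step_nm, step_nm)
    kernel = np.exp(-k ** 2 / (2.0 * psf_sigma_nm ** 2))
    kernel /= kernel.sum()
    profile = np.convolve(density, kernel, mode="same")
    return x, profile


def profile_peaks(x, y, min_frac=0.05, prominence_frac=0.1):
    """Grid local maxima of a dense profile above a fraction of its max.

    Maxima separated by a valley shallower than ``prominence_frac`` of the
    dynamic range count as one merged peak (reported at the global argmax).
    """
    inner = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]) \
        & (y[1:-1] > min_frac * y.max())
    px = x[1:-1][inner]
    if len(px) >= 2:
        i0 = np.searchsorted(x, px[0])
        i1 = np.searchsorted(x, px[-1])
        valley = y[i0:i1 + 1].min()
        dip = min(y[i0], y[i1]) - valley
        if dip < prominence_frac * np.ptp(y):
            return x[[np.argmax(y)]]
    return px


def bernsen_reference(img, radius_px, contrast,
                      low_contrast_foreground=False):
    """Per-pixel Bernsen rule evaluated literally over clipped disks."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    out = np.zeros((h, w), dtype=bool)
    global_half = (img.min() + img.max()) / 2.0
    for r in range(h):
        for c in range(w):
            vals = []
            for dr in range(-radius_px, radius_px + 1):
                for dc in range(-radius_px, radius_px + 1):
                    if dr * dr + dc * dc > radius_px * radius_px:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        vals.append(img[rr, cc])
            lo, hi = min(vals), max(vals)
            mid = (lo + hi) / 2.0
            if hi - lo >= contrast:
                out[r, c] = img[r, c] > mid
            else:
                fg = mid > global_half
                out[r, c] = (not fg) if low_contrast_foreground else fg
    return out


def ellipse_moments_reference(mask):
    """Moment ellipse by explicit pixel sums (major_px, minor_px, angle)."""
    rr, cc = np.nonzero(np.asarray(mask, dtype=bool))
    n = rr.size
    xbar, ybar = cc.mean(), rr.mean()
    mu20 = ((cc - xbar) ** 2).sum() / n
    mu02 = ((rr - ybar) ** 2).sum() / n
    mu11 = ((cc - xbar) * (rr - ybar)).sum() / n
    tr = mu20 + mu02
    det = np.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11 ** 2)
    lam1, lam2 = (tr + det) / 2.0, (tr - det) / 2.0
    major = 4.0 * np.sqrt(max(lam1, 0.0))
    minor = 4.0 * np.sqrt(max(lam2, 0.0))
    if minor > 0:
        s = np.sqrt(n / (np.pi * major * minor / 4.0))
        major, minor = major * s, minor * s
    angle = -np.degrees(0.5 * np.arctan2(2.0 * mu11, mu20 - mu02))
    if angle >= 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0
    return major, minor, angle


def grid_fit_single_gaussian(x, y):
    """Coarse grid + polish least-squares single Gaussian (returns FWHM)."""
    base = np.percentile(y, 10)
    best = None
    for mu in np.linspace(x[0], x[-1], 61):
        for sigma in np.linspace(10.0, (x[-1] - x[0]) / 2.0, 60):
            g = np.exp(-(x - mu) ** 2 / (2 * sigma ** 2))
            amp = max(np.sum((y - base) * g) / np.sum(g * g), 0.0)
            sse = np.sum((y - base - amp * g) ** 2)
            if best is None or sse < best[0]:
                best = (sse, mu, sigma, amp)
    _, mu, sigma, amp = best
    # local polish on a fine grid around the coarse optimum
    for mu2 in np.linspace(mu - 10, mu + 10, 41):
        for sigma2 in np.linspace(max(sigma - 5, 1.0), sigma + 5, 41):
            g = np.exp(-(x - mu2) ** 2 / (2 * sigma2 ** 2))
            amp2 = max(np.sum((y - base) * g) / np.sum(g * g), 0.0)
            sse = np.sum((y - base - amp2 * g) ** 2)
            if sse < best[0]:
                best = (sse, mu2, sigma2, amp2)
    return 2.0 * np.sqrt(2.0 * np.log(2.0)) * best[2]


def grid_fit_double_gaussian(x, y):
    """Coarse grid + polish double Gaussian; returns |mu2 - mu1|."""
    base = np.percentile(y, 10)
    yy = y - base
    sigmas = np.linspace(15.0, 80.0, 14)
    mus = np.linspace(x[0], x[-1], 81)
    best = None
    for s in sigmas:
        for i, m1 in enumerate(mus):
            g1 = np.exp(-(x - m1) ** 2 / (2 * s ** 2))
            for m2 in mus[i + 2:]:
                g2 = np.exp(-(x - m2) ** 2 / (2 * s ** 2))
                # least squares amplitudes for the two fixed kernels
                a11, a12 = np.dot(g1, g1), np.dot(g1, g2)
                a22 = np.dot(g2, g2)
                b1, b2 = np.dot(g1, yy), np.dot(g2, yy)
                det = a11 * a22 - a12 * a12
                if det <= 0:
                    continue
                c1 = (b1 * a22 - b2 * a12) / det
                c2 = (b2 * a11 - b1 * a12) / det
                if c1 < 0 or c2 < 0:
                    continue
                sse = np.sum((yy - c1 * g1 - c2 * g2) ** 2)
                if best is None or sse < best[0]:
                    best = (sse, m1, m2, s)
    # polish around the coarse optimum on fine local grids
    _, m1c, m2c, sc = best
    step = mus[1] - mus[0]
    for s in np.linspace(max(sc - 6, 5.0), sc + 6, 13):
        for m1 in np.linspace(m1c - step, m1c + step, 17):
            g1 = np.exp(-(x - m1) ** 2 / (2 * s ** 2))
            for m2 in np.linspace(m2c - step, m2c + step, 17):
                g2 = np.exp(-(x - m2) ** 2 / (2 * s ** 2))
                a11, a12 = np.dot(g1, g1), np.dot(g1, g2)
                a22 = np.dot(g2, g2)
                b1, b2 = np.dot(g1, yy), np.dot(g2, yy)
                det = a11 * a22 - a12 * a12
                if det <= 0:
                    continue
                c1 = (b1 * a22 - b2 * a12) / det
                c2 = (b2 * a11 - b1 * a12) / det
                if c1 < 0 or c2 < 0:
                    continue
                sse = np.sum((yy - c1 * g1 - c2 * g2) ** 2)
                if sse < best[0]:
                    best = (sse, m1, m2, s)
    return abs(best[2] - best[1])


def mixture_valley(background_frac=0.7, scale=20.0, mu=200.0, sigma=25.0):
    """Argmin of the analytic Exp+Normal mixture density on (0, mu)."""
    x = np.linspace(1e-6, mu, 200001)
    dens = (background_frac / scale * np.exp(-x / scale)
            + (1 - background_frac) / (sigma * np.sqrt(2 * np.pi))
            * np.exp(-(x - mu) ** 2 / (2 * sigma ** 2)))
    return float(x[np.argmin(dens)])
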