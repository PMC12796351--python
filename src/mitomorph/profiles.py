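"""Perpendicular line profiles and the Gaussian-fit width decision tree.

With a membrane label, the cross-section of a tubule shows the two membrane
ridges; the distance between them is the width.  Profiles (0.75 um long,
averaged over 5 parallel pixel lines) are drawn perpendicular to the object
axis at three anchors: the centre and two near-end points.  The number of
detected peaks decides the model:

* 1 peak  - single Gaussian + baseline; width = FWHM (membranes unresolved,
  an overestimate of the true width, but the best available estimate).
* 2 peaks - double Gaussian + baseline; width = centre-to-centre distance.
* 3-4 peaks - two objects side by side; adjacent peak distances give the
  widths and the record is excluded from non-width parameters.
* >4 peaks, a failed fit or R^2 below threshold - the object is rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

#: Length cutoff (um) between the L/6 and the 350-nm anchor rules.
LONG_OBJECT_UM = 2.1

#: Profile length (um) and lateral averaging width (pixel lines).
PROFILE_LENGTH_UM = 0.75
PROFILE_N_LINES = 5

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class LineProfile:
    positions_nm: np.ndarray     # sample positions, centred on the axis
    intensity: np.ndarray
    anchor: str                  # center | end1 | end2
    object_id: int = -1
    truncated: bool = False


@dataclass
class PeakFit:
    model: str                   # single | double | multi | rejected
    n_peaks: int
    width_nm: float = float("nan")
    width_source: str = ""       # fwhm | peak_distance
    params: dict = field(default_factory=dict)
    r2: float = float("nan")
    status: str = "ok"           # ok | rejected
    anchor: str = ""

    @property
    def accepted(self) -> bool:
        return self.status == "ok"


def profile_positions(length_um: float) -> dict[str, float]:
    """Anchor offsets along the major axis (um from the object's end).

    Short objects (L < 2.1 um) use L/6 and 5L/6; longer ones 350 nm and
    L - 350 nm.  The centre anchor is always L/2.
    """
    if length_um <= 0:
        raise ValueError("length must be positive")
    if length_um < LONG_OBJECT_UM:
        e1, e2 = length_um / 6.0, 5.0 * length_um / 6.0
    else:
        e1, e2 = 0.35, length_um - 0.35
    return {"end1": e1, "center": length_um / 2.0, "end2": e2}


def extract_profile(img, obj, offset_um: float, anchor: str = "center",
                    length_um: float = PROFILE_LENGTH_UM,
                    n_lines: int = PROFILE_N_LINES,
                    object_length_um: float | None = None) -> LineProfile:
    """Sample one perpendicular profile by bilinear interpolation.

    The anchor sits ``offset_um`` from the object's end along the major
    axis; sampling runs perpendicular to the positioning angle at 1-px
    steps, averaged over ``n_lines`` parallel lines spaced 1 px along the
    axis.  A footprint that leaves the image flags the profile truncated
    (outside samples read as 0).
    """
    data = np.asarray(getattr(img, "data", img), dtype=np.float64)
    px = obj.pixel_size_nm
    px_um = px * 1e-3
    if object_length_um is None:
        object_length_um = obj.major_um
    a = math.radians(obj.angle_deg)
    u = np.array([-math.sin(a), math.cos(a)])   # (dy, dx) along axis
    v = np.array([math.cos(a), math.sin(a)])    # perpendicular
    cy = obj.centroid_um[1] / px_um - 0.5       # pixel-centre coordinates
    cx = obj.centroid_um[0] / px_um - 0.5
    along = (offset_um - object_length_um / 2.0) / px_um
    ay = cy + along * u[0]
    ax = cx + along * u[1]
    half = length_um / 2.0 / px_um
    n = int(round(2 * half)) + 1
    s = np.linspace(-half, half, n)
    offsets = np.arange(n_lines) - (n_lines - 1) / 2.0
    rows = ay + np.add.outer(offsets * u[0], s * v[0])
    cols = ax + np.add.outer(offsets * u[1], s * v[1])
    truncated = bool((rows < 0).any() or (cols < 0).any()
                     or (rows > data.shape[0] - 1).any()
                     or (cols > data.shape[1] - 1).any())
    samples = ndimage.map_coordinates(data, [rows.ravel(), cols.ravel()],
                                      order=1, mode="constant", cval=0.0)
    intensity = samples.reshape(n_lines, n).mean(axis=0)
    return LineProfile(positions_nm=s * px, intensity=intensity,
                       anchor=anchor, object_id=getattr(obj, "label", -1),
                       truncated=truncated)


def _merge_shallow_peaks(y: np.ndarray, peaks, min_dip: float):
    """Merge adjacent maxima whose separating valley is shallower than
    ``min_dip`` (keeps the higher of the pair).

    Twin ridges blurred below the resolution limit leave two near-equal
    maxima with a negligible dip; a plain prominence filter keeps both
    because equal-height peaks reference the signal ends, not each other.
    """
    peaks = list(peaks)
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        for i in range(len(peaks) - 1):
            a, b = peaks[i], peaks[i + 1]
            valley = y[a:b + 1].min()
            if min(y[a], y[b]) - valley < min_dip:
                peaks.pop(i if y[a] < y[b] else i + 1)
                changed = True
                break
    return np.asarray(peaks, dtype=int)


def _peak_positions(profile: LineProfile, prominence_frac: float = 0.1,
                    min_separation: int = 2):
    y = np.asarray(profile.intensity, dtype=float)
    rng = np.ptp(y)
    if rng == 0:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(y, prominence=prominence_frac * rng,
                                 distance=min_separation)
    return _merge_shallow_peaks(y, peaks, prominence_frac * rng)


def count_peaks(profile: LineProfile, prominence_frac: float = 0.1,
                min_separation: int = 2) -> int:
    """Number of local maxima above baseline.

    Peaks must rise by at least ``prominence_frac`` of the profile's
    dynamic range, be at least ``min_separation`` samples apart, and be
    separated from their neighbours by a valley at least that deep; a flat
    profile has none.
    """
    y = np.asarray(profile.intensity, dtype=float)
    if y.size == 0:
        raise ValueError("empty profile")
    return int(_peak_positions(profile, prominence_frac,
                               min_separation).size)


def _gauss1(x, a, mu, sigma, c):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2)) + c


def _gauss2(x, a1, mu1, s1, a2, mu2, s2, c):
    return (a1 * np.exp(-((x - mu1) ** 2) / (2.0 * s1 ** 2))
            + a2 * np.exp(-((x - mu2) ** 2) / (2.0 * s2 ** 2)) + c)


def _gauss2_shared(x, a1, mu1, a2, mu2, s, c):
    return _gauss2(x, a1, mu1, s, a2, mu2, s, c)


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_width(profile: LineProfile, n_peaks: int | None = None,
              r2_threshold: float = 0.80,
              shared_sigma: bool = False,
              max_peaks: int = 4) -> PeakFit:
    """Fit the profile per the peak-count decision tree and extract a width.

    Initialization comes from the detected peak positions and heights.  A
    fit whose R^2 falls below ``r2_threshold``, a non-convergent optimizer,
    or more than ``max_peaks`` detected peaks all reject the profile.
    """
    x = np.asarray(profile.positions_nm, dtype=float)
    y = np.asarray(profile.intensity, dtype=float)
    peaks = _peak_positions(profile)
    if n_peaks is None:
        n_peaks = int(peaks.size)
    if n_peaks == 0 or n_peaks > max_peaks:
        return PeakFit(model="rejected", n_peaks=n_peaks, status="rejected",
                       anchor=profile.anchor)
    base = float(np.percentile(y, 10))
    amp = float(y.max() - base)
    if n_peaks == 1:
        mu0 = float(x[peaks[0]]) if peaks.size else float(x[np.argmax(y)])
        p0 = [amp, mu0, 60.0, base]
        bounds = ([0.0, x[0], 1.0, -np.inf],
                  [np.inf, x[-1], x[-1] - x[0], np.inf])
        try:
            popt, _ = optimize.curve_fit(_gauss1, x, y, p0=p0,
                                         bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            return PeakFit(model="single", n_peaks=1, status="rejected",
                           anchor=profile.anchor)
        r2 = _r_squared(y, _gauss1(x, *popt))
        fit = PeakFit(model="single", n_peaks=1,
                      width_nm=FWHM_PER_SIGMA * popt[2],
                      width_source="fwhm",
                      params={"amplitudes": [popt[0]], "centers": [popt[1]],
                              "sigmas": [popt[2]], "baseline": popt[3]},
                      r2=r2, anchor=profile.anchor)
        if r2 < r2_threshold:
            fit.status = "rejected"
        return fit
    if n_peaks == 2:
        if peaks.size >= 2:
            order = np.argsort(y[peaks])[::-1]
            mu1, mu2 = sorted(float(x[p]) for p in peaks[order[:2]])
            a1 = float(y[peaks[order[0]]] - base)
            a2 = float(y[peaks[order[1]]] - base)
        else:
            mu1, mu2 = float(x[0]) / 2, float(x[-1]) / 2
            a1 = a2 = amp
        lo_s, hi_s = 1.0, (x[-1] - x[0]) / 2.0
        try:
            if shared_sigma:
                p0 = [a1, mu1, a2, mu2, 40.0, base]
                bounds = ([0.0, x[0], 0.0, x[0], lo_s, -np.inf],
                          [np.inf, x[-1], np.inf, x[-1], hi_s, np.inf])
                popt, _ = optimize.curve_fit(_gauss2_shared, x, y, p0=p0,
                                             bounds=bounds, maxfev=20000)
                a1, mu1, a2, mu2, s, c = popt
                s1 = s2 = s
            else:
                p0 = [a1, mu1, 40.0, a2, mu2, 40.0, base]
                bounds = ([0.0, x[0], lo_s, 0.0, x[0], lo_s, -np.inf],
                          [np.inf, x[-1], hi_s, np.inf, x[-1], hi_s,
                           np.inf])
                popt, _ = optimize.curve_fit(_gauss2, x, y, p0=p0,
                                             bounds=bounds, maxfev=20000)
                a1, mu1, s1, a2, mu2, s2, c = popt
        except (RuntimeError, ValueError):
            return PeakFit(model="double", n_peaks=2, status="rejected",
                           anchor=profile.anchor)
        yhat = _gauss2(x, a1, mu1, s1, a2, mu2, s2, c)
        r2 = _r_squared(y, yhat)
        fit = PeakFit(model="double", n_peaks=2,
                      width_nm=abs(mu2 - mu1), width_source="peak_distance",
                      params={"amplitudes": [a1, a2],
                              "centers": sorted([mu1, mu2]),
                              "sigmas": [s1, s2], "baseline": c},
                      r2=r2, anchor=profile.anchor)
        if r2 < r2_threshold:
            fit.status = "rejected"
        return fit
    # 3-4 peaks: likely two membranes of two side-by-side objects
    centers = np.sort(x[peaks])
    gaps = np.diff(centers)
    return PeakFit(model="multi", n_peaks=n_peaks,
                   width_nm=float(np.mean(gaps)),
                   width_source="peak_distance",
                   params={"centers": centers.tolist(),
                           "gaps_nm": gaps.tolist()},
                   r2=float("nan"), status="ok", anchor=profile.anchor)


def object_width(fits: dict[str, PeakFit]) -> dict:
    """Combine the three anchor fits into centre and outer widths.

    W_m is the centre-anchor width; W_o the mean of accepted end widths.
    A rejected centre fit fails the object's width QC.
    """
    center = fits.get("center")
    ends = [fits[k] for k in ("end1", "end2") if k in fits]
    w_m = center.width_nm if center is not None and center.accepted \
        else float("nan")
    accepted_ends = [f.width_nm for f in ends if f.accepted]
    w_o = float(np.mean(accepted_ends)) if accepted_ends else float("nan")
    ratio = w_o / w_m if np.isfinite(w_m) and np.isfinite(w_o) and w_m > 0 \
        else float("nan")
    side_by_side = any(f.model == "multi" for f in fits.values())
    return {"width_center_nm": w_m, "width_outer_nm": w_o,
            "width_ratio": ratio,
            "qc_ok": bool(np.isfinite(w_m)),
            "side_by_side": side_by_side}


def measure_object_width(img, obj, length_um: float | None = None,
                         r2_threshold: float = 0.80,
                         shared_sigma: bool = False) -> dict:
    """Run the full per-object width measurement (three anchors)."""
    if length_um is None:
        length_um = obj.major_um
    fits = {}
    for anchor, off in profile_positions(length_um).items():
        prof = extract_profile(img, obj, off, anchor=anchor,
                               object_length_um=length_um)
        fits[anchor] = fit_width(prof, r2_threshold=r2_threshold,
                                 shared_sigma=shared_sigma)
    out = object_width(fits)
    out["fits"] = fits
    return out
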