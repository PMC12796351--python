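"""Per-image automated +/- calling of functional channels.

For a channel such as TMRE (membrane potential) or MitoSOX (superoxide),
each object's mean intensity over its pixel set is computed.  The per-image
histogram of those means is modelled as exponential-decay background plus a
Gaussian signal component,

    f(x) = a exp(-b x) + A exp(-(x - mu)^2 / (2 sigma^2)),

and the local minimum of the fitted f between the two modes is the calling
threshold t*: objects whose mean exceeds t* are positive.  Thresholds are
fitted image by image because absolute intensities vary with acquisition
settings and labelling efficiency.  When the fit fails or f is unimodal the
caller falls back to Otsu's threshold on the means and flags it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from skimage.filters import threshold_otsu


class InsufficientDataError(ValueError):
    """Raised when too few objects exist to fit a per-image threshold."""


@dataclass
class ThresholdModel:
    t_star: float
    status: str                      # ok | fallback
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    counts: np.ndarray = field(default_factory=lambda: np.array([]))
    a: float = float("nan")          # exponential amplitude
    b: float = float("nan")          # exponential rate
    amp: float = float("nan")        # Gaussian amplitude
    mu: float = float("nan")
    sigma: float = float("nan")
    r2: float = float("nan")
    intercept: float = float("nan")  # where the two components cross
    fallback: bool = False

    @property
    def bin_width(self) -> float:
        if self.bin_edges.size < 2:
            return float("nan")
        return float(self.bin_edges[1] - self.bin_edges[0])


def object_mean_signal(objects, channel) -> pd.Series:
    """Mean channel intensity over each object's pixel set."""
    data = np.asarray(getattr(channel, "data", channel), dtype=np.float64)
    means = {}
    for obj in objects:
        patch = data[obj.slices] if hasattr(obj, "slices") else None
        if patch is None or patch.shape != obj.mask.shape:
            raise ValueError("channel not aligned with objects")
        means[obj.label] = float(patch[obj.mask].mean())
    return pd.Series(means, name="mean_intensity")


def _model(x, a, b, amp, mu, sigma):
    return a * np.exp(-b * x) + amp * np.exp(-((x - mu) ** 2)
                                             / (2.0 * sigma ** 2))


def _histogram(means: np.ndarray, floor_bins: int = 12):
    q75, q25 = np.percentile(means, [75, 25])
    iqr = q75 - q25
    if iqr > 0:
        width = 2.0 * iqr / len(means) ** (1.0 / 3.0)  # Freedman-Diaconis
        n_bins = max(int(np.ceil(np.ptp(means) / width)), floor_bins)
    else:
        n_bins = floor_bins
    return np.histogram(means, bins=n_bins)


def fit_threshold(means, min_objects: int = 30,
                  floor_bins: int = 12) -> ThresholdModel:
    """Fit the exp + Gaussian histogram model and locate the valley t*.

    t* is the numeric argmin of the fitted f on (0, mu).  The crossing point
    of the two components is recorded alongside for comparison.  Degenerate
    or unimodal fits fall back to Otsu's threshold with ``fallback=True``.
    """
    means = np.asarray(means, dtype=float)
    means = means[np.isfinite(means)]
    if means.size < min_objects:
        raise InsufficientDataError(
            f"need >= {min_objects} objects, got {means.size}")
    if np.ptp(means) == 0:
        return ThresholdModel(t_star=float(means[0]), status="fallback",
                              fallback=True)
    counts, edges = _histogram(means, floor_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0

    # initialization: decay rate from the lower-quartile slope, Gaussian
    # moments from the upper half of the distribution
    upper = means[means > np.median(means)]
    mu0 = float(np.mean(upper))
    sigma0 = float(np.std(upper)) or np.ptp(means) / 10.0
    low = counts[: max(len(counts) // 4, 2)]
    a0 = float(max(counts[0], 1.0))
    with np.errstate(divide="ignore"):
        pos = low > 0
        if pos.sum() >= 2:
            slope = np.polyfit(centers[: len(low)][pos], np.log(low[pos]), 1)
            b0 = float(max(-slope[0], 1e-6))
        else:
            b0 = 1.0 / max(np.median(means), 1e-6)
    amp0 = float(max(counts[np.argmin(np.abs(centers - mu0))], 1.0))
    try:
        popt, _ = optimize.curve_fit(
            _model, centers, counts, p0=[a0, b0, amp0, mu0, sigma0],
            bounds=([0.0, 1e-9, 0.0, centers[0], 1e-9],
                    [np.inf, np.inf, np.inf, centers[-1] * 2.0, np.inf]),
            maxfev=20000)
        ok = True
    except (RuntimeError, ValueError):
        ok = False
    if ok:
        a, b, amp, mu, sigma = popt
        yhat = _model(centers, *popt)
        ss_tot = np.sum((counts - counts.mean()) ** 2)
        r2 = 1.0 - np.sum((counts - yhat) ** 2) / ss_tot if ss_tot else 0.0
        grid = np.linspace(1e-9, mu, 4096)
        f = _model(grid, *popt)
        k = int(np.argmin(f))
        interior = 0 < k < len(grid) - 1
        if interior:
            t_star = float(grid[k])
            cross = grid[np.argmin(np.abs(
                a * np.exp(-b * grid)
                - amp * np.exp(-((grid - mu) ** 2) / (2 * sigma ** 2))))]
            return ThresholdModel(t_star=t_star, status="ok",
                                  bin_edges=edges, counts=counts,
                                  a=a, b=b, amp=amp, mu=mu, sigma=sigma,
                                  r2=r2, intercept=float(cross))
    # unimodal fitted f or failed optimization
    t_star = float(threshold_otsu(means))
    return ThresholdModel(t_star=t_star, status="fallback",
                          bin_edges=edges, counts=counts, fallback=True)


def call_objects(means, model: ThresholdModel,
                 image_id: str = "image0") -> pd.DataFrame:
    """Per-object +/- calls against the image's threshold."""
    if model.status not in ("ok", "fallback"):
        raise ValueError(f"unusable threshold model: {model.status}")
    means = pd.Series(means)
    calls = np.where(means.to_numpy() > model.t_star, "+", "-")
    return pd.DataFrame({
        "id": means.index,
        "mean_intensity": means.to_numpy(),
        "call": calls,
        "image_id": image_id,
        "t_star": model.t_star,
    })


def positive_fraction_pct(n_positive: int, n_negative: int) -> float:
    """Positive percentage from per-category counts."""
    total = n_positive + n_negative
    if total <= 0:
        raise ValueError("no objects")
    return 100.0 * n_positive / total


def colocalization_call(objects, marker_channel, records=None,
                        min_objects: int = 30, image_id: str = "image0",
                        **fit_kwargs):
    """Call a second organelle channel (e.g. lysosome) with the same model.

    Returns ``(calls, model, mds_positive_ratio)``; the ratio is the
    fraction of MDSs called positive (marker-overlapping) when a
    morphometry table with an ``object_class`` column is supplied.
    """
    means = object_mean_signal(objects, marker_channel)
    if np.ptp(means.to_numpy()) == 0:
        model = ThresholdModel(t_star=float(means.iloc[0]),
                               status="fallback", fallback=True)
    else:
        model = fit_threshold(means, min_objects=min_objects, **fit_kwargs)
    calls = call_objects(means, model, image_id=image_id)
    ratio = float("nan")
    if records is not None:
        merged = calls.merge(records[["id", "object_class"]], on="id")
        mds = merged[merged["object_class"] == "MDS"]
        if len(mds):
            ratio = float((mds["call"] == "+").mean())
    return calls, model, ratio
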