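"""Binarization of the structural (OMM) channel.

Two variants feed the morphometry: a global threshold (fixed value or the
triangle rule on the intensity histogram) and local Bernsen thresholding,
which handles uneven labelling across a field.  Both are followed by a
configurable sequence of morphological refinements and, when a soma mask is
available, exclusion of everything inside it so that only neurite
mitochondria remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_triangle

#: 3x3 cross (4-connected) structuring element used by all refinement steps.
CROSS = ndimage.generate_binary_structure(2, 1)


def triangle_threshold(data: np.ndarray) -> float:
    """Triangle-rule threshold with a histogram matched to the dynamic
    range (roughly unit-width bins, so near-integer count data does not
    leave empty bins next to the background peak)."""
    nbins = int(np.clip(np.ptp(data), 16, 256)) + 1
    return float(threshold_triangle(data, nbins=nbins))


def remove_small(mask: np.ndarray, n_px: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``n_px`` pixels."""
    data = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(data,
                              structure=ndimage.generate_binary_structure(
                                  2, 2))
    if n == 0:
        return data.copy()
    sizes = ndimage.sum_labels(data, labels, index=np.arange(1, n + 1))
    keep = np.concatenate(([False], np.asarray(sizes) >= n_px))
    return keep[labels]


class DegenerateHistogramError(ValueError):
    """Raised when an automatic threshold is requested on a constant image."""


@dataclass
class BinaryMask:
    """A boolean raster plus the provenance that reconstructs it."""

    data: np.ndarray
    pixel_size_nm: float
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.data.shape


def _as_array(img) -> np.ndarray:
    data = getattr(img, "data", img)
    return np.asarray(data, dtype=np.float64)


def binarize_global(img, threshold="auto",
                    pixel_size_nm: float = 25.0) -> BinaryMask:
    """Global threshold: ``img > threshold``.

    ``threshold='auto'`` derives the value with the triangle rule on the
    intensity histogram; a constant image has no histogram geometry and
    raises :class:`DegenerateHistogramError`.
    """
    data = _as_array(img)
    if data.size == 0:
        raise ValueError("empty image")
    if threshold == "auto":
        if np.ptp(data) == 0:
            raise DegenerateHistogramError(
                "constant image: triangle threshold undefined")
        threshold = triangle_threshold(data)
    return BinaryMask(data > threshold, pixel_size_nm,
                      {"method": "global", "threshold": float(threshold)})


def binarize_bernsen(img, radius_px: int = 9, contrast: float = 15.0,
                     pixel_size_nm: float = 25.0,
                     low_contrast_foreground: bool = False,
                     presmooth_sigma_px: float = 0.0) -> BinaryMask:
    """Local Bernsen threshold over a disk neighbourhood.

    Per pixel, the local min and max over a disk of ``radius_px`` are taken.
    Where the local range (max - min) reaches ``contrast``, the pixel is
    foreground if it exceeds the local midgray (min+max)/2.  Low-contrast
    neighbourhoods are assigned as a block: foreground if the local midgray
    exceeds the global half-range (midpoint of the image min/max), which for
    dark-background fluorescence sends them to background.  Set
    ``low_contrast_foreground`` to invert that tie rule.

    The min/max filters use clamped (edge-replicating) boundaries, which is
    exactly the min/max over the disk neighbourhood clipped to the image.
    ``presmooth_sigma_px`` optionally Gaussian-smooths the image first, the
    usual preparation when the input is raw rather than deconvolved (local
    min/max are otherwise dominated by shot noise).
    """
    data = _as_array(img)
    if presmooth_sigma_px > 0:
        data = ndimage.gaussian_filter(data, presmooth_sigma_px)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * radius_px + 1 > min(data.shape):
        raise ValueError("Bernsen radius larger than the image")
    yy, xx = np.mgrid[-radius_px:radius_px + 1, -radius_px:radius_px + 1]
    disk = yy ** 2 + xx ** 2 <= radius_px ** 2
    lo = ndimage.minimum_filter(data, footprint=disk, mode="nearest")
    hi = ndimage.maximum_filter(data, footprint=disk, mode="nearest")
    mid = (lo + hi) / 2.0
    local_range = hi - lo
    global_half = (data.min() + data.max()) / 2.0
    confident = local_range >= contrast
    low_val = mid > global_half
    if low_contrast_foreground:
        low_val = ~low_val
    out = np.where(confident, data > mid, low_val)
    return BinaryMask(out.astype(bool), pixel_size_nm,
                      {"method": "bernsen", "radius_px": int(radius_px),
                       "contrast": float(contrast),
                       "presmooth_sigma_px": float(presmooth_sigma_px)})


def refine_mask(mask: BinaryMask, steps) -> BinaryMask:
    """Apply an ordered sequence of morphological refinements.

    Steps: ``erode``, ``dilate``, ``open``, ``close``, ``fill_holes``,
    ``("remove_small", n_px)`` (drop 8-connected components below n_px
    pixels).  All use the 3x3 cross element.  An empty list is the identity.
    """
    out = mask.data.copy()
    applied = []
    for step in steps:
        if isinstance(step, (tuple, list)):
            name, arg = step
        else:
            name, arg = step, None
        if name == "erode":
            out = ndimage.binary_erosion(out, structure=CROSS)
        elif name == "dilate":
            out = ndimage.binary_dilation(out, structure=CROSS)
        elif name == "open":
            out = ndimage.binary_opening(out, structure=CROSS)
        elif name == "close":
            out = ndimage.binary_closing(out, structure=CROSS)
        elif name == "fill_holes":
            out = ndimage.binary_fill_holes(out, structure=CROSS)
        elif name == "remove_small":
            if arg is None:
                raise ValueError("remove_small needs a pixel count")
            out = remove_small(out, int(arg))
        else:
            raise ValueError(f"unknown refinement step {name!r}")
        applied.append((name, arg))
    prov = dict(mask.provenance)
    prov["refine"] = applied
    return BinaryMask(out, mask.pixel_size_nm, prov)


def apply_region_exclusion(mask: BinaryMask, exclusion) -> BinaryMask:
    """Remove everything inside an exclusion region (e.g. the soma)."""
    excl = getattr(exclusion, "data", exclusion)
    excl = np.asarray(excl, dtype=bool)
    if excl.shape != mask.data.shape:
        raise ValueError(
            f"shape mismatch {mask.data.shape} vs {excl.shape}")
    prov = dict(mask.provenance)
    prov["excluded_px"] = int((mask.data & excl).sum())
    return BinaryMask(mask.data & ~excl, mask.pixel_size_nm, prov)
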