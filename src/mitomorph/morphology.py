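"""Per-object morphometry: labelling, ellipse parameters, skeleton length,
length selection and size/shape classification.

Each 8-connected component of the binary mask becomes one object carrying
the particle-analysis parameters: area A, the moment-fit ellipse (major axis
L_ell, minor axis W_ell, orientation), and the skeleton length L_skel.  The
reported length L is the ellipse major axis for small objects
(A < 0.2 um^2, where a skeleton under-covers the rounded caps) and the
longer of the two measurements otherwise.  Objects with A below
A_th = 0.086 um^2 are classified as mitochondria-derived structures (MDS);
MDSs with aspect ratio W/L >= 0.5 are vesicles, below that sticks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops
from skimage.morphology import skeletonize

#: Area threshold (um^2) separating mitochondria from MDSs.
A_TH_UM2 = 0.086

#: Area (um^2) below which the ellipse length is always preferred.
SMALL_AREA_UM2 = 0.2

#: Aspect-ratio threshold separating vesicles (>= 0.5) from sticks.
AR_VESICLE = 0.5

EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass
class LabeledObject:
    """One connected component with its primary morphometry."""

    label: int
    slices: tuple                 # bounding-box slices into the full image
    mask: np.ndarray              # boolean patch within the bounding box
    pixel_size_nm: float
    centroid_um: tuple[float, float]   # (x, y)
    area_um2: float
    major_um: float               # L_ell
    minor_um: float               # W_ell
    angle_deg: float              # CCW from +x, y up; in [-90, 90)
    skeleton_length_um: float

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (row, col) pixel indices in the full image."""
        rr, cc = np.nonzero(self.mask)
        return np.column_stack((rr + self.slices[0].start,
                                cc + self.slices[1].start))

    def pixel_values(self, img: np.ndarray) -> np.ndarray:
        patch = img[self.slices]
        return patch[self.mask]


def ellipse_from_moments(mask: np.ndarray) -> tuple[float, float, float]:
    """Moment-fit ellipse (major_px, minor_px, angle_deg) of a pixel set.

    Axes come from the normalized second central moments and are then scaled
    so the ellipse area equals the pixel count (the particle-analysis
    convention).  The angle is the major-axis orientation, CCW from +x with
    y pointing up, mapped to [-90, 90).  Degenerate (single-row/column)
    regions keep the unscaled moment axes.
    """
    rr, cc = np.nonzero(mask)
    n = rr.size
    if n == 0:
        raise ValueError("empty component")
    ybar, xbar = rr.mean(), cc.mean()
    mu20 = np.mean((cc - xbar) ** 2)
    mu02 = np.mean((rr - ybar) ** 2)
    mu11 = np.mean((cc - xbar) * (rr - ybar))
    common = math.hypot(mu20 - mu02, 2.0 * mu11)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    major = 4.0 * math.sqrt(max(lam1, 0.0))
    minor = 4.0 * math.sqrt(max(lam2, 0.0))
    if minor > 0:
        scale = math.sqrt(n / (math.pi * major * minor / 4.0))
        major *= scale
        minor *= scale
    theta_arr = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    angle = -math.degrees(theta_arr)
    if angle >= 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0
    return major, minor, angle


def skeleton_length_from_mask(mask: np.ndarray,
                              pixel_size_nm: float) -> float:
    """Total skeleton branch length of one component, in um.

    The mask is thinned to a 1-px skeleton and the lengths of all
    8-neighbour steps are summed (1 px for orthogonal, sqrt(2) px for
    diagonal), each step counted once.  A diagonal step whose two pixels
    share an orthogonal skeleton neighbour is skipped, so corners are not
    double counted.  A single-pixel skeleton has length zero.
    """
    data = np.asarray(mask, dtype=bool)
    # a component that is already single-pixel wide (no 2x2 solid block)
    # is its own skeleton; thinning algorithms would clip its corners
    has_block = (data[:-1, :-1] & data[1:, :-1]
                 & data[:-1, 1:] & data[1:, 1:]).any()
    skel = skeletonize(data) if has_block else data
    rr, cc = np.nonzero(skel)
    if rr.size <= 1:
        return 0.0
    pixset = set(zip(rr.tolist(), cc.tolist()))
    total = 0.0
    for y, x in pixset:
        for dy, dx in ((0, 1), (1, 0)):
            if (y + dy, x + dx) in pixset:
                total += 1.0
        for dy, dx in ((1, 1), (1, -1)):
            if (y + dy, x + dx) in pixset:
                # skip if an orthogonal two-step path exists via a shared
                # neighbour; the two unit edges already cover it
                if ((y, x + dx) in pixset or (y + dy, x) in pixset):
                    continue
                total += math.sqrt(2.0)
    return total * pixel_size_nm * 1e-3


def label_objects(mask, img=None, pixel_size_nm: float | None = None,
                  background_dilate_px: int = 3):
    """Split a binary mask into 8-connected objects with their morphometry.

    Returns ``(objects, intensity)`` where ``intensity`` is the source image
    with everything outside the dilated mask zeroed (the copy used for line
    profiles), or ``None`` when no image is given.  An empty mask yields an
    empty list.
    """
    data = np.asarray(getattr(mask, "data", mask), dtype=bool)
    if pixel_size_nm is None:
        pixel_size_nm = getattr(mask, "pixel_size_nm", 25.0)
    px_um = pixel_size_nm * 1e-3
    labels, n = ndimage.label(data, structure=EIGHT)
    intensity = None
    if img is not None:
        arr = np.asarray(getattr(img, "data", img), dtype=np.float64)
        if arr.shape != data.shape:
            raise ValueError("mask and image shapes differ")
        halo = ndimage.binary_dilation(data, structure=EIGHT,
                                       iterations=background_dilate_px)
        intensity = arr * halo
    objects = []
    for prop in regionprops(labels):
        patch = prop.image
        major, minor, angle = ellipse_from_moments(patch)
        cy, cx = prop.centroid
        objects.append(LabeledObject(
            label=prop.label,
            slices=tuple(prop.slice),
            mask=patch,
            pixel_size_nm=pixel_size_nm,
            centroid_um=((cx + 0.5) * px_um, (cy + 0.5) * px_um),
            area_um2=prop.area * px_um ** 2,
            major_um=major * px_um,
            minor_um=minor * px_um,
            angle_deg=angle,
            skeleton_length_um=skeleton_length_from_mask(patch,
                                                         pixel_size_nm),
        ))
    return objects, intensity


def skeleton_length(obj: LabeledObject) -> float:
    """Skeleton length (um) of one labelled object."""
    return skeleton_length_from_mask(obj.mask, obj.pixel_size_nm)


def select_length(area_um2: float, l_ell_um: float, l_skel_um: float) -> float:
    """The reported object length (um).

    Small objects (A < 0.2 um^2) always use the ellipse major axis; larger
    ones take the longer of ellipse and skeleton length.  The boundary
    A = 0.2 um^2 belongs to the large branch.
    """
    if min(area_um2, l_ell_um, l_skel_um) < 0:
        raise ValueError("negative morphometry input")
    if area_um2 < SMALL_AREA_UM2:
        return l_ell_um
    return max(l_ell_um, l_skel_um)


def classify_mds(area_um2: float, a_th_um2: float = A_TH_UM2) -> str:
    """'MDS' for areas strictly below the threshold, else 'mitochondrion'."""
    if area_um2 < 0:
        raise ValueError("negative area")
    return "MDS" if area_um2 < a_th_um2 else "mitochondrion"


def classify_shape(aspect_ratio: float,
                   ar_threshold: float = AR_VESICLE) -> str:
    """'vesicle' for AR in [0.5, 1], 'stick' below; AR = W/L must be <= 1."""
    if not 0.0 < aspect_ratio <= 1.0:
        raise ValueError(
            f"aspect ratio must be in (0, 1], got {aspect_ratio}")
    return "vesicle" if aspect_ratio >= ar_threshold else "stick"


def rect_equivalent_area_um2(length_um: float, width_um: float) -> float:
    """Area of the rectangle with the object's length and width."""
    return length_um * width_um


def build_morph_records(objects, widths=None, a_th_um2: float = A_TH_UM2,
                        ar_threshold: float = AR_VESICLE) -> pd.DataFrame:
    """Assemble the per-object morphometry table.

    ``widths`` optionally maps object label -> (W_m_nm, W_o_nm, qc_ok) from
    the profile fits; when a centre width is available it feeds the aspect
    ratio, otherwise the ellipse minor axis stands in (recorded in
    ``ar_width_source``).
    """
    rows = []
    widths = widths or {}
    for obj in objects:
        length = select_length(obj.area_um2, obj.major_um,
                               obj.skeleton_length_um)
        w_m, w_o, qc_ok = widths.get(obj.label, (np.nan, np.nan, False))
        if np.isfinite(w_m):
            width_nm = w_m
            source = "fit_center"
        else:
            width_nm = obj.minor_um * 1e3
            source = "ellipse_minor"
        ar = min(width_nm * 1e-3 / length, 1.0) if length > 0 else np.nan
        klass = classify_mds(obj.area_um2, a_th_um2)
        shape = ""
        if klass == "MDS" and np.isfinite(ar) and ar > 0:
            shape = classify_shape(ar, ar_threshold)
        rows.append({
            "id": obj.label,
            "centroid_x_um": obj.centroid_um[0],
            "centroid_y_um": obj.centroid_um[1],
            "area_um2": obj.area_um2,
            "ellipse_major_um": obj.major_um,
            "ellipse_minor_um": obj.minor_um,
            "angle_deg": obj.angle_deg,
            "skeleton_length_um": obj.skeleton_length_um,
            "length_um": length,
            "width_center_nm": w_m,
            "width_outer_nm": w_o,
            "width_ratio": w_o / w_m if np.isfinite(w_m) and w_m > 0
            else np.nan,
            "width_nm": width_nm,
            "ar_width_source": source,
            "aspect_ratio": ar,
            "object_class": klass,
            "shape": shape,
            "qc_pass": bool(qc_ok) or not widths,
        })
    columns = ["id", "centroid_x_um", "centroid_y_um", "area_um2",
               "ellipse_major_um", "ellipse_minor_um", "angle_deg",
               "skeleton_length_um", "length_um", "width_center_nm",
               "width_outer_nm", "width_ratio", "width_nm",
               "ar_width_source", "aspect_ratio", "object_class", "shape",
               "qc_pass"]
    return pd.DataFrame(rows, columns=columns)


def assign_region_flags(records: pd.DataFrame, objects,
                        region_masks: dict) -> pd.DataFrame:
    """Add per-object Boolean compartment flags (``in_<region>``).

    Each object's centre position is tested against the corresponding
    binary region image (dendrite, axon, transfected-cell mask, ...).
    """
    out = records.copy()
    by_label = {obj.label: obj for obj in objects}
    for name, mask in region_masks.items():
        data = np.asarray(getattr(mask, "data", mask), dtype=bool)
        flags = []
        for oid in out["id"]:
            obj = by_label[oid]
            px_um = obj.pixel_size_nm * 1e-3
            r = int(obj.centroid_um[1] / px_um - 0.5)
            c = int(obj.centroid_um[0] / px_um - 0.5)
            r = min(max(r, 0), data.shape[0] - 1)
            c = min(max(c, 0), data.shape[1] - 1)
            flags.append(bool(data[r, c]))
        out[f"in_{name}"] = flags
    return out


def summarize_population(records: pd.DataFrame,
                         area_bin_um2: float = 0.01,
                         ar_bin: float = 0.1,
                         width_bin_nm: float = 10.0) -> dict:
    """Cohort-level summary of a morphometry table.

    Returns per-class area histograms (bin width 0.01 um^2), the MDS aspect
    ratio histogram (bin width 0.1), width mode (exact multiset mode, plus
    the width-histogram peak), medians, the fractions of mitochondria in
    the 100-200 nm band and beyond 300 nm, the fraction of mitochondria
    longer than 10 um, and the MDS/mitochondria count ratio.  An empty
    table yields an empty dict.
    """
    if records.empty:
        return {}
    out: dict = {}
    mito = records[records["object_class"] == "mitochondrion"]
    mds = records[records["object_class"] == "MDS"]
    out["n_mitochondria"] = int(len(mito))
    out["n_mds"] = int(len(mds))
    out["mds_mito_ratio"] = (len(mds) / len(mito)) if len(mito) else np.nan

    def _hist(values, bin_width):
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            return np.array([]), np.array([])
        hi = math.ceil(values.max() / bin_width + 1) * bin_width
        edges = np.arange(0.0, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(values, bins=edges)
        return counts, edges

    for name, sub in (("mitochondrion", mito), ("MDS", mds)):
        counts, edges = _hist(sub["area_um2"], area_bin_um2)
        out[f"area_hist_{name}"] = (counts, edges)
        if counts.size:
            k = int(np.argmax(counts))
            out[f"area_mode_{name}_um2"] = float(
                (edges[k] + edges[k + 1]) / 2)
            out[f"area_median_{name}_um2"] = float(
                np.median(sub["area_um2"]))
    counts, edges = _hist(mds["aspect_ratio"], ar_bin)
    out["ar_hist_mds"] = (counts, edges)

    widths = records["width_nm"].to_numpy(dtype=float)
    widths = widths[np.isfinite(widths)]
    if widths.size:
        vals, cnts = np.unique(widths, return_counts=True)
        out["width_mode_nm"] = float(vals[np.argmax(cnts)])
        counts, edges = _hist(widths, width_bin_nm)
        k = int(np.argmax(counts))
        out["width_hist_mode_nm"] = float((edges[k] + edges[k + 1]) / 2)
        out["width_median_nm"] = float(np.median(widths))
        out["frac_width_100_200"] = float(
            np.mean((widths >= 100.0) & (widths <= 200.0)))
        out["frac_width_below_100"] = float(np.mean(widths < 100.0))
        out["frac_width_above_300"] = float(np.mean(widths > 300.0))
    lengths = mito["length_um"].to_numpy(dtype=float)
    if lengths.size:
        out["frac_length_above_10um"] = float(np.mean(lengths > 10.0))
    return out


def plot_histograms(summary: dict, outdir) -> list:
    """Save the population histograms (area per class, MDS aspect ratio)
    as PNG; returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    panels = [(k, "area (um^2)") for k in ("area_hist_mitochondrion",
                                           "area_hist_MDS")]
    panels.append(("ar_hist_mds", "aspect ratio W/L"))
    for key, xlabel in panels:
        if key not in summary:
            continue
        counts, edges = summary[key]
        if not len(counts):
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
               color="0.3")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("count")
        ax.set_title(key)
        fig.tight_layout()
        path = outdir / f"{key}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
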