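"""Spatial statistics: process length and number density, radial turnover,
protrusion classification and contact-site linear density.

The neurite process map is built from the faint membrane-label background
outside the soma: intensities are capped, thresholded with the triangle
rule, cleaned morphologically (remove <20 px, dilate x20, erode x15), and
the largest connected component is skeletonized; its branch lengths sum to
the total process length, the denominator of per-compartment number
densities.  Pulse-chase turnover uses the ratiometric refreshment
R = S_new / (S_old + S_new) per object, aggregated over concentric rings of
30 um around the soma.  Protrusions are tip or side by the quarters rule on
their axial position along the parent tubule, and marker-positive when
their footprint mean exceeds background by k standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .morphology import skeleton_length_from_mask
from .segment import CROSS, remove_small, triangle_threshold

#: Default ring thickness (um) for the radial turnover analysis.
RING_WIDTH_UM = 30.0

EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass
class ProcessMap:
    mask: np.ndarray
    skeleton: np.ndarray
    total_length_um: float
    pixel_size_nm: float
    provenance: dict = field(default_factory=dict)


@dataclass
class ProtrusionRecord:
    parent_id: int
    axial_fraction: float
    position_class: str                  # tip | side
    marker_calls: dict = field(default_factory=dict)
    neck_width_nm: float = float("nan")
    background_mean: float = float("nan")


def build_process_map(img, soma_mask=None, pixel_size_nm: float = 25.0,
                      cap_percentile: float = 98.0, min_size: int = 20,
                      n_dilate: int = 20, n_erode: int = 15) -> ProcessMap:
    """Binary map and total length of the neurite processes.

    Sequence: zero the soma, cap intensities at the ``cap_percentile``
    value, triangle-threshold, remove objects below ``min_size`` px, dilate
    ``n_dilate`` times, erode ``n_erode`` times, keep the largest connected
    component, skeletonize and sum branch lengths.  An image with nothing
    left after filtering yields a zero-length map.
    """
    data = np.asarray(getattr(img, "data", img), dtype=np.float64).copy()
    if soma_mask is not None:
        soma = np.asarray(getattr(soma_mask, "data", soma_mask), dtype=bool)
        data[soma] = 0.0
    if np.ptp(data) == 0:
        empty = np.zeros(data.shape, dtype=bool)
        return ProcessMap(empty, empty, 0.0, pixel_size_nm,
                          {"note": "flat image"})
    cap = np.percentile(data, cap_percentile)
    data = np.minimum(data, cap)
    thr = triangle_threshold(data)
    mask = data > thr
    mask = remove_small(mask, min_size)
    if mask.any():
        mask = ndimage.binary_dilation(mask, structure=CROSS,
                                       iterations=n_dilate)
        mask = ndimage.binary_erosion(mask, structure=CROSS,
                                      iterations=n_erode)
    if not mask.any():
        empty = np.zeros(data.shape, dtype=bool)
        return ProcessMap(empty, empty, 0.0, pixel_size_nm,
                          {"threshold": thr, "note": "empty after filtering"})
    labels, n = ndimage.label(mask, structure=EIGHT)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    skel = skeletonize(mask)
    length = skeleton_length_from_mask(mask, pixel_size_nm)
    return ProcessMap(mask, skel, length, pixel_size_nm,
                      {"threshold": thr, "cap": float(cap),
                       "min_size": min_size, "n_dilate": n_dilate,
                       "n_erode": n_erode})


def number_density(count: int, process_map) -> float:
    """Objects per um of process length; undefined for zero length."""
    length = getattr(process_map, "total_length_um", process_map)
    if length <= 0:
        raise ValueError("process length is zero; density undefined")
    return count / length


def turnover_ratio(obj, ch_old, ch_new) -> float:
    """Refreshment ratio R = S_new / (S_old + S_new) over the object pixels.

    R = 1 means fully refreshed label, 0 none; 0/0 is undefined (NaN).
    """
    old = np.asarray(getattr(ch_old, "data", ch_old), dtype=np.float64)
    new = np.asarray(getattr(ch_new, "data", ch_new), dtype=np.float64)
    if old.shape != new.shape:
        raise ValueError("turnover channels misaligned")
    s_old = float(obj.pixel_values(old).sum())
    s_new = float(obj.pixel_values(new).sum())
    total = s_old + s_new
    if total == 0:
        return float("nan")
    return s_new / total


def soma_distance_um(objects, soma_mask, pixel_size_nm: float) -> np.ndarray:
    """Euclidean distance (um) from each centroid to the soma boundary.

    Centroids inside the soma get distance -1 (excluded downstream).
    """
    soma = np.asarray(getattr(soma_mask, "data", soma_mask), dtype=bool)
    if not soma.any():
        raise ValueError("empty soma mask")
    px_um = pixel_size_nm * 1e-3
    edt = ndimage.distance_transform_edt(~soma) * px_um
    out = np.empty(len(objects))
    for i, obj in enumerate(objects):
        r = int(round(obj.centroid_um[1] / px_um - 0.5))
        c = int(round(obj.centroid_um[0] / px_um - 0.5))
        r = min(max(r, 0), soma.shape[0] - 1)
        c = min(max(c, 0), soma.shape[1] - 1)
        out[i] = -1.0 if soma[r, c] else edt[r, c]
    return out


def radial_rings(objects, soma_mask, values, classes=None,
                 pixel_size_nm: float | None = None,
                 ring_width_um: float = RING_WIDTH_UM,
                 normalize_to_ring0: bool = False) -> pd.DataFrame:
    """Aggregate a per-object quantity over concentric rings around the soma.

    Ring k covers distances [k*w, (k+1)*w) from the soma boundary; objects
    whose centroid lies inside the soma are excluded.  Aggregation is
    object-averaged, separately per class when ``classes`` is given (e.g.
    mitochondrion vs MDS).  ``normalize_to_ring0`` divides by the ring-0
    mean (proximal normalization for single-label intensities).
    """
    if pixel_size_nm is None:
        pixel_size_nm = objects[0].pixel_size_nm
    values = np.asarray(values, dtype=float)
    d = soma_distance_um(objects, soma_mask, pixel_size_nm)
    ring = np.where(d < 0, -1, np.floor(d / ring_width_um)).astype(int)
    classes = np.asarray(classes) if classes is not None \
        else np.array(["all"] * len(objects))
    keep = (ring >= 0) & np.isfinite(values)
    df = pd.DataFrame({"ring": ring[keep], "value": values[keep],
                       "object_class": classes[keep],
                       "distance_um": d[keep]})
    rows = []
    for (k, cls), grp in df.groupby(["ring", "object_class"]):
        rows.append({
            "ring": int(k),
            "inner_um": k * ring_width_um,
            "outer_um": (k + 1) * ring_width_um,
            "object_class": cls,
            "mean": float(grp["value"].mean()),
            "sd": float(grp["value"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "n": int(len(grp)),
        })
    out = pd.DataFrame(rows, columns=["ring", "inner_um", "outer_um",
                                      "object_class", "mean", "sd", "n"])
    out = out.sort_values(["object_class", "ring"]).reset_index(drop=True)
    if normalize_to_ring0 and len(out):
        for cls, grp in out.groupby("object_class"):
            ring0 = grp[grp["ring"] == grp["ring"].min()]
            ref = float(ring0["mean"].iloc[0])
            if ref != 0:
                sel = out["object_class"] == cls
                out.loc[sel, "mean"] = out.loc[sel, "mean"] / ref
                out.loc[sel, "sd"] = out.loc[sel, "sd"] / ref
    return out


def classify_protrusion(parent, anchor_um, parent_length_um=None,
                        marker_channels=None, background=(0.0, 0.0),
                        k_sigma: float = 2.0,
                        footprint_radius_px: int = 3) -> ProtrusionRecord:
    """Tip/side call and marker calls for one protrusion.

    The anchor is projected onto the parent's major axis; axial fraction in
    [0, 0.25] or [0.75, 1] (the extremity quarters, boundaries inclusive to
    the tip) makes it a tip, otherwise a side protrusion.  For each marker
    channel, the mean over a small disk at the anchor is compared with
    background mean + ``k_sigma`` background SDs.
    """
    if parent_length_um is None:
        parent_length_um = parent.major_um
    a = math.radians(parent.angle_deg)
    u = np.array([-math.sin(a), math.cos(a)])       # (dy, dx)
    dy = anchor_um[1] - parent.centroid_um[1]
    dx = anchor_um[0] - parent.centroid_um[0]
    axial = dy * u[0] + dx * u[1]
    frac = float(np.clip(axial / parent_length_um + 0.5, 0.0, 1.0))
    position = "tip" if (frac <= 0.25 or frac >= 0.75) else "side"
    calls = {}
    bg_mean, bg_sd = background
    if marker_channels:
        px_um = parent.pixel_size_nm * 1e-3
        for name, channel in marker_channels.items():
            data = np.asarray(getattr(channel, "data", channel),
                              dtype=np.float64)
            r = int(round(anchor_um[1] / px_um - 0.5))
            c = int(round(anchor_um[0] / px_um - 0.5))
            r0 = max(r - footprint_radius_px, 0)
            r1 = min(r + footprint_radius_px + 1, data.shape[0])
            c0 = max(c - footprint_radius_px, 0)
            c1 = min(c + footprint_radius_px + 1, data.shape[1])
            yy, xx = np.mgrid[r0:r1, c0:c1]
            disk = (yy - r) ** 2 + (xx - c) ** 2 <= footprint_radius_px ** 2
            mean = float(data[r0:r1, c0:c1][disk].mean())
            calls[name] = "+" if mean > bg_mean + k_sigma * bg_sd else "-"
    return ProtrusionRecord(parent_id=getattr(parent, "label", -1),
                            axial_fraction=frac, position_class=position,
                            marker_calls=calls, background_mean=bg_mean)


def filament_background(channel, structure_mask, process_mask=None,
                        dilate_px: int = 5) -> tuple[float, float]:
    """Mean and SD of a channel inside the filaments, outside structures."""
    data = np.asarray(getattr(channel, "data", channel), dtype=np.float64)
    struct = np.asarray(getattr(structure_mask, "data", structure_mask),
                        dtype=bool)
    region = ~ndimage.binary_dilation(struct, structure=EIGHT,
                                      iterations=dilate_px)
    if process_mask is not None:
        region &= np.asarray(getattr(process_mask, "data", process_mask),
                             dtype=bool)
    vals = data[region]
    if vals.size == 0:
        raise ValueError("no background pixels available")
    return float(vals.mean()), float(vals.std())


def contact_site_density(total_length_um: float, mito_mask, puncta_mask,
                         pixel_size_nm: float,
                         distance_nm: float = 0.0) -> tuple[float, int]:
    """Contacting puncta per um of total mitochondrial length.

    A punctum contacts a mitochondrion when it overlaps the mask or its
    boundary-to-boundary gap is at most ``distance_nm``; pixel adjacency
    (a gap below one pixel diagonal) always counts as touching.  Returns
    ``(density_per_um, n_contacts)``.
    """
    if total_length_um <= 0:
        raise ValueError("zero mitochondrial length; density undefined")
    mito = np.asarray(getattr(mito_mask, "data", mito_mask), dtype=bool)
    puncta = np.asarray(getattr(puncta_mask, "data", puncta_mask),
                        dtype=bool)
    if mito.shape != puncta.shape:
        raise ValueError("mask shapes differ")
    labels, n = ndimage.label(puncta, structure=EIGHT)
    if n == 0:
        return 0.0, 0
    if not mito.any():
        return 0.0, 0
    gap_nm = ndimage.distance_transform_edt(~mito) * pixel_size_nm
    reach = max(distance_nm, math.sqrt(2.0) * pixel_size_nm)
    min_gap = ndimage.minimum(gap_nm, labels, index=np.arange(1, n + 1))
    contacts = int(np.sum(np.asarray(min_gap) <= reach))
    return contacts / total_length_um, contacts
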