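"""Synthetic STED-like neurite fields with planted ground truth.

Real inputs to the morphometry are 2-D STED images (20-30 nm pixels) of
neurons whose outer mitochondrial membrane (OMM) carries the fluorescent
label.  Because the label sits on the membrane, tubular mitochondria appear
as hollow capsules: a bright ridge along the outline and a dim interior.
This module renders that appearance for capsules (stadium shapes) of known
length, width and orientation, places them along simulated neurite paths
radiating from a soma disk, and attaches optional functional channels
(bimodal per-object intensity), a two-label turnover pair with a planted
radial gradient, membrane protrusions and marker puncta.  Every planted
parameter is returned in a ground-truth table so downstream estimators can
be scored against it.

Rendering model: the membrane is a ring of configurable thickness centred on
the nominal half-width, drawn on a supersampled grid, box-averaged down to
the pixel grid and convolved with an isotropic Gaussian PSF (sigma in nm).
Noise is Poisson on the photon counts followed by additive Gaussian read
noise.  For a fixed config (which includes the seed) the output is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


class CapacityError(RuntimeError):
    """Raised when objects cannot be placed without overlap."""


class GeometryError(ValueError):
    """Raised when an object does not fit into its target patch."""


@dataclass(frozen=True)
class ObjectSpec:
    """Geometry of one membrane-labelled object (capsule outline)."""

    center_um: tuple[float, float]  # (x, y), y increasing down rows
    angle_deg: float                # CCW from +x with y up (image convention)
    length_um: float                # tip-to-tip length at the membrane centre
    width_nm: float                 # diameter at the membrane centre
    shape: str = "stick"            # vesicle | stick
    kind: str = "mitochondrion"     # mitochondrion | MDS


@dataclass
class SimConfig:
    image_size_px: tuple[int, int] = (1024, 1024)
    pixel_size_nm: float = 25.0
    psf_sigma_nm: float = 25.0
    n_mitochondria: int = 30
    n_mds: int = 20
    width_range_nm: tuple[float, float] = (120.0, 250.0)
    width_mean_nm: float = 160.0        # peaked cohort, truncated normal
    width_sigma_nm: float = 35.0
    length_range_um: tuple[float, float] = (0.9, 3.0)
    mds_area_max_um2: float = 0.086
    vesicle_fraction: float = 0.6
    membrane_thickness_nm: float = 40.0
    peak_intensity: float = 150.0
    background: float = 5.0
    poisson_noise: bool = True
    gaussian_read_sigma: float = 3.0
    functional_positive_fraction: float = 0.7
    functional_positive_mean: float = 200.0
    functional_positive_sigma: float = 25.0
    functional_negative_scale: float = 20.0
    turnover_ratio_at_soma: float = 0.8
    turnover_slope_per_um: float = 0.005
    n_protrusions: int = 0
    protrusion_tip_fraction: float = 0.5
    protrusion_neck_width_nm: float = 80.0
    soma_radius_um: float = 2.0
    n_neurites: int = 6
    neurite_halfwidth_um: float = 0.5
    neurite_intensity: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vesicle_fraction", "functional_positive_fraction",
                     "protrusion_tip_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 10.0 <= self.pixel_size_nm <= 50.0:
            raise ValueError("pixel_size_nm must lie in [10, 50] nm")
        lo, hi = self.width_range_nm
        if not (60.0 <= lo <= hi <= 600.0):
            raise ValueError("width_range_nm must lie within [60, 600] nm")


@dataclass
class SimulatedField:
    """One rendered field plus its ground truth."""

    structural: np.ndarray
    channels: dict[str, np.ndarray]
    soma_mask: np.ndarray
    truth: pd.DataFrame
    truth_protrusions: pd.DataFrame
    cfg: SimConfig
    path_length_um: float = 0.0


# ---------------------------------------------------------------------------
# geometry helpers

def capsule_area_um2(length_um: float, width_nm: float) -> float:
    """Analytic footprint area of a capsule bounded at the membrane centre."""
    w = width_nm * 1e-3
    body = max(length_um - w, 0.0) * w
    return body + math.pi * (w / 2.0) ** 2


def _axis_vectors(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors (dy, dx) along and across the axis in array coordinates.

    Angles follow the image convention (CCW from +x with y pointing up), so
    the row component is negated.
    """
    a = math.radians(angle_deg)
    u = np.array([-math.sin(a), math.cos(a)])
    v = np.array([math.cos(a), math.sin(a)])
    return u, v


def _capsule_distance_nm(yy_nm, xx_nm, cy_nm, cx_nm, angle_deg,
                         length_nm, width_nm):
    """Distance from grid points to the capsule's medial segment (nm)."""
    half = max(length_nm - width_nm, 0.0) / 2.0
    u, _ = _axis_vectors(angle_deg)
    ry = yy_nm - cy_nm
    rx = xx_nm - cx_nm
    t = np.clip(ry * u[0] + rx * u[1], -half, half)
    return np.hypot(ry - t * u[0], rx - t * u[1])


def render_membrane_object(spec: ObjectSpec, cfg: SimConfig,
                           patch_shape_px: tuple[int, int] | None = None,
                           supersample: int = 4) -> np.ndarray:
    """Render one hollow-membrane capsule, peak-normalised, noise free.

    The membrane ring (thickness ``cfg.membrane_thickness_nm`` centred on the
    nominal half-width) is drawn at ``supersample``-fold resolution, block
    averaged onto the pixel grid and blurred with the Gaussian PSF.  The
    object is centred in the returned patch.

    Raises
    ------
    GeometryError
        If the object (plus PSF margin) does not fit in the patch.
    """
    px = cfg.pixel_size_nm
    length_nm = spec.length_um * 1e3
    extent_nm = length_nm + cfg.membrane_thickness_nm + 8.0 * cfg.psf_sigma_nm
    need = int(math.ceil(extent_nm / px)) + 2
    if patch_shape_px is None:
        patch_shape_px = (need, need)
    h, w = patch_shape_px
    if need > min(h, w):
        raise GeometryError(
            f"object extent {extent_nm:.0f} nm exceeds patch "
            f"{min(h, w) * px:.0f} nm")

    ss = int(supersample)
    sub = px / ss
    ys = (np.arange(h * ss) + 0.5) * sub
    xs = (np.arange(w * ss) + 0.5) * sub
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    cy = h * px / 2.0
    cx = w * px / 2.0
    d = _capsule_distance_nm(yy, xx, cy, cx, spec.angle_deg,
                             length_nm, spec.width_nm)
    ring = (np.abs(d - spec.width_nm / 2.0)
            <= cfg.membrane_thickness_nm / 2.0).astype(np.float64)
    img = ring.reshape(h, ss, w, ss).mean(axis=(1, 3))
    img = ndimage.gaussian_filter(img, sigma=cfg.psf_sigma_nm / px)
    peak = img.max()
    if peak > 0:
        img /= peak
    return img


def capsule_footprint(spec: ObjectSpec, shape_px: tuple[int, int],
                      pixel_size_nm: float,
                      extra_nm: float = 0.0) -> np.ndarray:
    """Boolean filled footprint of a capsule on the full image grid.

    The boundary sits at the membrane centre plus ``extra_nm``.
    """
    h, w = shape_px
    px = pixel_size_nm
    cx_nm = spec.center_um[0] * 1e3
    cy_nm = spec.center_um[1] * 1e3
    r = spec.width_nm / 2.0 + extra_nm
    length_nm = spec.length_um * 1e3
    # bounding window to keep the distance evaluation local
    half_extent = length_nm / 2.0 + r + 2 * px
    r0 = max(int((cy_nm - half_extent) / px) - 1, 0)
    r1 = min(int((cy_nm + half_extent) / px) + 2, h)
    c0 = max(int((cx_nm - half_extent) / px) - 1, 0)
    c1 = min(int((cx_nm + half_extent) / px) + 2, w)
    out = np.zeros((h, w), dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    ys = (np.arange(r0, r1) + 0.5) * px
    xs = (np.arange(c0, c1) + 0.5) * px
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    d = _capsule_distance_nm(yy, xx, cy_nm, cx_nm, spec.angle_deg,
                             length_nm, spec.width_nm)
    out[r0:r1, c0:c1] = d <= r
    return out


# ---------------------------------------------------------------------------
# field generation

def _make_paths(cfg: SimConfig, rng: np.random.Generator):
    """Piecewise-linear neurite paths radiating from the soma disk (um)."""
    h, w = cfg.image_size_px
    px_um = cfg.pixel_size_nm * 1e-3
    cx, cy = w * px_um / 2.0, h * px_um / 2.0
    xmax, ymax = w * px_um, h * px_um
    paths = []
    for i in range(cfg.n_neurites):
        phi = 2.0 * math.pi * (i + rng.uniform(0.0, 0.6)) / cfg.n_neurites
        x = cx + cfg.soma_radius_um * math.cos(phi)
        y = cy + cfg.soma_radius_um * math.sin(phi)
        pts = [(x, y)]
        ang = phi
        for _ in range(64):
            ang += rng.normal(0.0, math.radians(12.0))
            x += 1.5 * math.cos(ang)
            y += 1.5 * math.sin(ang)
            if not (0.3 < x < xmax - 0.3 and 0.3 < y < ymax - 0.3):
                break
            pts.append((x, y))
        if len(pts) >= 2:
            paths.append(np.asarray(pts))
    if not paths:
        raise CapacityError("field too small to grow any neurite path")
    return paths


def _path_point(paths, rng: np.random.Generator):
    """Random point on a random path: position (um) and tangent angle (deg)."""
    path = paths[rng.integers(len(paths))]
    seg = rng.integers(len(path) - 1)
    t = rng.uniform()
    p0, p1 = path[seg], path[seg + 1]
    p = p0 + t * (p1 - p0)
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    angle = math.degrees(math.atan2(-dy, dx))  # image convention, y down
    return p, angle


def _sample_mds_geometry(cfg: SimConfig, rng: np.random.Generator):
    """Width/length/shape for one sub-threshold structure (area < A_max)."""
    for _ in range(200):
        if rng.uniform() < cfg.vesicle_fraction:
            shape = "vesicle"
            w = rng.uniform(90.0, 250.0)
            length = w * rng.uniform(1.0, 1.3) * 1e-3
        else:
            shape = "stick"
            w = rng.uniform(80.0, 120.0)
            length = w * rng.uniform(2.6, 4.0) * 1e-3
        if capsule_area_um2(length, w) < 0.8 * cfg.mds_area_max_um2:
            return w, length, shape
    raise CapacityError("could not sample sub-threshold geometry")


def _paint_neurites(canvas: np.ndarray, paths, cfg: SimConfig) -> None:
    """Add faint membrane-label background along the neurite ribbons."""
    px_um = cfg.pixel_size_nm * 1e-3
    h, w = canvas.shape
    ribbon = np.zeros((h, w), dtype=bool)
    for path in paths:
        for p0, p1 in zip(path[:-1], path[1:]):
            n = max(int(np.hypot(*(p1 - p0)) / px_um) * 2, 2)
            ts = np.linspace(0.0, 1.0, n)
            xs = (p0[0] + ts * (p1[0] - p0[0])) / px_um
            ys = (p0[1] + ts * (p1[1] - p0[1])) / px_um
            rr = np.clip(ys.astype(int), 0, h - 1)
            cc = np.clip(xs.astype(int), 0, w - 1)
            ribbon[rr, cc] = True
    halfwidth_px = max(int(cfg.neurite_halfwidth_um / px_um), 1)
    ribbon = ndimage.binary_dilation(ribbon, iterations=halfwidth_px)
    canvas += cfg.neurite_intensity * ndimage.gaussian_filter(
        ribbon.astype(np.float64), sigma=2.0)


def generate_field(cfg: SimConfig) -> SimulatedField:
    """Render one field: structural + functional channels and ground truth.

    Objects are placed along neurite paths outside the soma disk, with
    rejection sampling against an occupancy mask (at most 1000 attempts per
    object; protrusions are the only allowed overlaps).  Functional levels
    follow the two-component model the +/- caller assumes: positives are
    Gaussian around a high mean, negatives exponential-tail background.
    Turnover channels satisfy new/(old+new) = planted ratio before noise.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size_px
    px = cfg.pixel_size_nm
    px_um = px * 1e-3
    structural = np.full((h, w), float(cfg.background))
    soma_center = np.array([w * px_um / 2.0, h * px_um / 2.0])

    paths = _make_paths(cfg, rng)
    path_length = float(sum(
        np.hypot(*np.diff(p, axis=0).T).sum() for p in paths))
    _paint_neurites(structural, paths, cfg)

    # soma disk: mask plus moderate structural signal
    yy, xx = np.meshgrid((np.arange(h) + 0.5) * px_um,
                         (np.arange(w) + 0.5) * px_um, indexing="ij")
    d_soma_grid = np.hypot(yy - soma_center[1], xx - soma_center[0])
    soma_mask = d_soma_grid <= cfg.soma_radius_um
    # intensity is painted inset from the mask so that PSF-scale spill
    # never leaks outside the region the exclusion step removes
    structural[d_soma_grid <= cfg.soma_radius_um - 0.15] += \
        0.3 * cfg.peak_intensity

    occupancy = np.zeros((h, w), dtype=bool)
    rows = []
    specs: list[ObjectSpec] = []
    plan = (["mitochondrion"] * cfg.n_mitochondria + ["MDS"] * cfg.n_mds)
    for oid, kind in enumerate(plan):
        if kind == "mitochondrion":
            lo, hi = cfg.width_range_nm
            for _ in range(200):
                width = rng.normal(cfg.width_mean_nm, cfg.width_sigma_nm)
                if lo <= width <= hi:
                    break
            else:
                width = cfg.width_mean_nm
            length = rng.uniform(*cfg.length_range_um)
            shape = ""
        else:
            width, length, shape = _sample_mds_geometry(cfg, rng)
        placed = False
        for _ in range(1000):
            p, tangent = _path_point(paths, rng)
            _, v = _axis_vectors(tangent)
            off = rng.normal(0.0, 0.3)
            center = (p[0] + off * v[1], p[1] + off * v[0])
            angle = tangent + rng.normal(0.0, 10.0)
            if kind == "MDS" and shape == "vesicle":
                angle = rng.uniform(-90.0, 90.0)
            spec = ObjectSpec(center, angle, length, width, shape or "stick",
                              kind)
            d_soma = np.hypot(center[0] - soma_center[0],
                              center[1] - soma_center[1])
            if d_soma < cfg.soma_radius_um + length / 2.0 + 0.3:
                continue
            margin = length / 2.0 + width * 1e-3
            if not (margin < center[0] < w * px_um - margin
                    and margin < center[1] < h * px_um - margin):
                continue
            # clearance covers the PSF skirt so neighbours stay separable
            foot = capsule_footprint(
                spec, (h, w), px,
                extra_nm=cfg.membrane_thickness_nm / 2.0 + 4 * px)
            if (foot & occupancy).any():
                continue
            occupancy |= foot
            specs.append(spec)
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place object {oid} after 1000 attempts")
        d_soma = np.hypot(spec.center_um[0] - soma_center[0],
                          spec.center_um[1] - soma_center[1])
        rows.append({
            "id": oid,
            "object_class": kind,
            "shape": shape,
            "center_x_um": spec.center_um[0],
            "center_y_um": spec.center_um[1],
            "angle_deg": spec.angle_deg,
            "true_length_um": spec.length_um,
            "true_width_nm": spec.width_nm,
            "true_area_um2": capsule_area_um2(spec.length_um, spec.width_nm),
            "radial_distance_um": max(d_soma - cfg.soma_radius_um, 0.0),
        })
    truth = pd.DataFrame(
        rows, columns=["id", "object_class", "shape", "center_x_um",
                       "center_y_um", "angle_deg", "true_length_um",
                       "true_width_nm", "true_area_um2",
                       "radial_distance_um"])

    # structural rendering
    for spec in specs:
        patch = render_membrane_object(spec, cfg)
        ph, pw = patch.shape
        r0 = int(round(spec.center_um[1] / px_um)) - ph // 2
        c0 = int(round(spec.center_um[0] / px_um)) - pw // 2
        rs, cs = slice(max(r0, 0), min(r0 + ph, h)), \
            slice(max(c0, 0), min(c0 + pw, w))
        prs = slice(rs.start - r0, rs.stop - r0)
        pcs = slice(cs.start - c0, cs.stop - c0)
        structural[rs, cs] += cfg.peak_intensity * patch[prs, pcs]

    # functional channel: planted bimodal per-object mean level
    n_obj = len(specs)
    positive = rng.uniform(size=n_obj) < cfg.functional_positive_fraction
    levels = np.where(
        positive,
        rng.normal(cfg.functional_positive_mean,
                   cfg.functional_positive_sigma, n_obj),
        rng.exponential(cfg.functional_negative_scale, n_obj))
    levels = np.clip(levels, 0.0, None)
    functional = np.full((h, w), float(cfg.background))
    footprints = [capsule_footprint(s, (h, w), px,
                                    extra_nm=cfg.membrane_thickness_nm / 2.0)
                  for s in specs]
    for foot, lev in zip(footprints, levels):
        functional[foot] += lev
    truth["functional_state"] = np.where(positive, "+", "-")
    truth["functional_level"] = levels

    # turnover pair: new/(old+new) follows the planted radial gradient
    ratios = np.clip(
        cfg.turnover_ratio_at_soma
        - cfg.turnover_slope_per_um * truth["radial_distance_um"].to_numpy(),
        0.02, 0.98)
    ch_old = np.full((h, w), float(cfg.background))
    ch_new = np.full((h, w), float(cfg.background))
    for foot, r in zip(footprints, ratios):
        ch_new[foot] += r * cfg.peak_intensity
        ch_old[foot] += (1.0 - r) * cfg.peak_intensity
    truth["true_turnover_ratio"] = ratios

    # protrusions on mitochondria
    truth["protrusion"] = "none"
    prot_rows = []
    mito_ids = [i for i, s in enumerate(specs) if s.kind == "mitochondrion"]
    margin_nm = cfg.membrane_thickness_nm / 2.0 + 4 * px
    for pid in range(cfg.n_protrusions):
        if not mito_ids:
            break
        pspec = None
        for _ in range(100):
            parent = int(rng.choice(mito_ids))
            spec = specs[parent]
            is_tip = rng.uniform() < cfg.protrusion_tip_fraction
            if is_tip:
                f = rng.uniform(0.02, 0.22) if rng.uniform() < 0.5 \
                    else rng.uniform(0.78, 0.98)
            else:
                f = rng.uniform(0.28, 0.72)
            u, v = _axis_vectors(spec.angle_deg)
            side = 1.0 if rng.uniform() < 0.5 else -1.0
            r_out = (spec.width_nm + cfg.membrane_thickness_nm) / 2.0 * 1e-3
            ax = (f - 0.5) * spec.length_um
            anchor = (spec.center_um[0] + ax * u[1] + side * r_out * v[1],
                      spec.center_um[1] + ax * u[0] + side * r_out * v[0])
            plen = 0.25
            pangle = math.degrees(math.atan2(-side * v[0], side * v[1]))
            pcen = (anchor[0] + side * v[1] * plen / 2.0,
                    anchor[1] + side * v[0] * plen / 2.0)
            cand = ObjectSpec(pcen, pangle, plen,
                              cfg.protrusion_neck_width_nm, "stick",
                              "protrusion")
            # a protrusion may overlap only its parent, never a neighbour
            cand_foot = capsule_footprint(cand, (h, w), px,
                                          extra_nm=margin_nm)
            parent_foot = capsule_footprint(spec, (h, w), px,
                                            extra_nm=margin_nm)
            if not (cand_foot & occupancy & ~parent_foot).any():
                pspec = cand
                occupancy |= cand_foot
                break
        if pspec is None:
            continue
        patch = render_membrane_object(pspec, cfg)
        ph, pw = patch.shape
        r0 = int(round(pcen[1] / px_um)) - ph // 2
        c0 = int(round(pcen[0] / px_um)) - pw // 2
        rs = slice(max(r0, 0), min(r0 + ph, h))
        cs = slice(max(c0, 0), min(c0 + pw, w))
        if rs.stop <= rs.start or cs.stop <= cs.start:
            continue
        structural[rs, cs] += cfg.peak_intensity * patch[
            slice(rs.start - r0, rs.stop - r0),
            slice(cs.start - c0, cs.stop - c0)]
        truth.loc[parent, "protrusion"] = "tip" if is_tip else "side"
        prot_rows.append({
            "protrusion_id": pid,
            "parent_id": parent,
            "axial_fraction": f,
            "placement": "tip" if is_tip else "side",
            "anchor_x_um": anchor[0],
            "anchor_y_um": anchor[1],
        })
    truth_protrusions = pd.DataFrame(
        prot_rows, columns=["protrusion_id", "parent_id", "axial_fraction",
                            "placement", "anchor_x_um", "anchor_y_um"])

    channels = {"functional": functional, "old": ch_old, "new": ch_new}
    if cfg.poisson_noise:
        structural = rng.poisson(structural).astype(np.float64)
        for name in ("functional", "old", "new"):
            channels[name] = rng.poisson(channels[name]).astype(np.float64)
    if cfg.gaussian_read_sigma > 0:
        structural = structural + rng.normal(
            0.0, cfg.gaussian_read_sigma, structural.shape)
        for name in ("functional", "old", "new"):
            channels[name] = channels[name] + rng.normal(
                0.0, cfg.gaussian_read_sigma, channels[name].shape)
        structural = np.clip(structural, 0.0, None)
        for name in channels:
            channels[name] = np.clip(channels[name], 0.0, None)

    return SimulatedField(structural=structural, channels=channels,
                          soma_mask=soma_mask, truth=truth,
                          truth_protrusions=truth_protrusions, cfg=cfg,
                          path_length_um=path_length)


def generate_puncta(field: SimulatedField, n_puncta: int,
                    fraction_contacting: float, radius_nm: float = 100.0,
                    seed: int = 0,
                    target_class: str | None = None):
    """Plant marker puncta, a set fraction of them touching planted objects.

    Returns ``(mask, table)`` where ``table`` records per punctum whether it
    was planted in contact and with which object.  Non-contacting puncta are
    kept at least 500 nm away from every object footprint.
    """
    rng = np.random.default_rng(seed)
    cfg = field.cfg
    h, w = cfg.image_size_px
    px = cfg.pixel_size_nm
    px_um = px * 1e-3
    truth = field.truth
    if target_class is not None:
        truth = truth[truth["object_class"] == target_class]
    occupancy = np.zeros((h, w), dtype=bool)
    for _, row in field.truth.iterrows():
        spec = ObjectSpec((row.center_x_um, row.center_y_um), row.angle_deg,
                          row.true_length_um, row.true_width_nm)
        occupancy |= capsule_footprint(
            spec, (h, w), px, extra_nm=cfg.membrane_thickness_nm / 2.0)
    clearance = ndimage.distance_transform_edt(~occupancy) * px_um
    mask = np.zeros((h, w), dtype=bool)
    r_px = max(radius_nm / px, 1.0)
    rows = []
    n_contact = int(round(n_puncta * fraction_contacting))
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for pid in range(n_puncta):
        contact = pid < n_contact
        for _ in range(1000):
            if contact:
                row = truth.iloc[int(rng.integers(len(truth)))]
                u, v = _axis_vectors(row.angle_deg)
                f = rng.uniform(-0.4, 0.4) * row.true_length_um
                side = 1.0 if rng.uniform() < 0.5 else -1.0
                rad = row.true_width_nm / 2.0 * 1e-3
                cx = row.center_x_um + f * u[1] + side * rad * v[1]
                cy = row.center_y_um + f * u[0] + side * rad * v[0]
                target = int(row.id)
            else:
                cx = rng.uniform(0.5, w * px_um - 0.5)
                cy = rng.uniform(0.5, h * px_um - 0.5)
                target = -1
            rc, cc = int(cy / px_um), int(cx / px_um)
            if not (0 <= rc < h and 0 <= cc < w):
                continue
            if not contact and clearance[rc, cc] < 0.5 + radius_nm * 1e-3:
                continue
            disk = (yy - rc) ** 2 + (xx - cc) ** 2 <= r_px ** 2
            if (disk & mask).any():
                continue
            mask |= disk
            rows.append({"punctum_id": pid, "contacting": contact,
                         "target_id": target,
                         "center_x_um": cx, "center_y_um": cy})
            break
        else:
            raise CapacityError(f"could not place punctum {pid}")
    table = pd.DataFrame(rows, columns=["punctum_id", "contacting",
                                        "target_id", "center_x_um",
                                        "center_y_um"])
    return mask, table
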