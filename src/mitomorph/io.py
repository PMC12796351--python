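"""Formats, run configuration and pipeline orchestration.

Images travel as multi-page TIFF (one page per channel, 16-bit), the soma
mask as single-page 8-bit TIFF, tables as CSV and the run manifest as JSON.
The physical pixel size always comes from the configuration: microscopy
TIFF metadata dialects are too unreliable to be authoritative, so a
mismatch with file metadata only warns.  ``run_pipeline`` chains
segmentation, morphometry, width fitting, functional calling and the
spatial statistics, skipping stages whose channels are missing, and logs a
reason code for every dropped object.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import functional, morphology, profiles, segment, spatial

log = logging.getLogger("mitomorph")


@dataclass
class ChannelImage:
    """One 2-D intensity raster with its physical pixel size."""

    data: np.ndarray
    pixel_size_nm: float
    role: str = ""


@dataclass
class RunConfig:
    pixel_size_nm: float = 25.0
    threshold_method: str = "global"        # global | bernsen
    global_threshold: float | str = "auto"
    bernsen_radius_px: int = 9
    bernsen_contrast: float = 15.0
    refine_steps: tuple = (("fill_holes", None), ("erode", None),
                           ("erode", None), ("remove_small", 8))
    a_th_um2: float = morphology.A_TH_UM2
    ar_threshold: float = morphology.AR_VESICLE
    r2_threshold: float = 0.80
    shared_sigma: bool = False
    ring_width_um: float = spatial.RING_WIDTH_UM
    min_objects_for_calls: int = 30
    background_dilate_px: int = 3
    seed: int = 0
    output_dir: str | None = None

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["refine_steps"] = [list(s) if isinstance(s, (tuple, list)) else s
                             for s in self.refine_steps]
        return d


def read_image_bundle(paths: dict[str, str | Path],
                      pixel_size_nm: float) -> dict[str, ChannelImage]:
    """Read TIFF channels keyed by role.

    ``paths`` maps role names (``structural`` required; ``soma``,
    ``functional``, ``old``, ``new``, ``marker`` ... optional) either to a
    file each, or several roles to pages of one multi-page TIFF via
    ``(path, page)`` tuples.  All rasters must share one shape; integer
    data is promoted to float64 counts; the soma role is coerced boolean.
    """
    if "structural" not in paths:
        raise ValueError("role 'structural' is required")
    out: dict[str, ChannelImage] = {}
    shape = None
    for role, src in paths.items():
        if isinstance(src, tuple):
            path, page = src
            arr = tifffile.imread(path, key=int(page))
        else:
            arr = tifffile.imread(src)
        arr = np.asarray(arr)
        if arr.ndim == 3 and arr.shape[0] == 1:
            arr = arr[0]
        if arr.ndim != 2:
            raise ValueError(f"role {role!r}: expected a 2-D page, "
                             f"got shape {arr.shape}")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"role {role!r}: shape {arr.shape} does not "
                             f"match {shape}")
        if role in ("soma", "dendrite", "axon", "transfected"):
            data = arr.astype(bool)
        else:
            data = arr.astype(np.float64)
        out[role] = ChannelImage(data=data, pixel_size_nm=pixel_size_nm,
                                 role=role)
    return out


def write_field(field_obj, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated field: TIFF stack, soma mask, truth CSV, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pages = [field_obj.structural] + list(field_obj.channels.values())
    names = ["structural"] + list(field_obj.channels.keys())
    stack = np.stack([np.clip(np.round(p), 0, 65535).astype(np.uint16)
                      for p in pages])
    paths = {}
    paths["channels"] = outdir / "channels.tif"
    tifffile.imwrite(paths["channels"], stack, photometric="minisblack",
                     metadata={"axes": "CYX", "channels": names,
                               "pixel_size_nm": field_obj.cfg.pixel_size_nm,
                               "seed": field_obj.cfg.seed})
    paths["soma"] = outdir / "soma.tif"
    tifffile.imwrite(paths["soma"],
                     (field_obj.soma_mask.astype(np.uint8) * 255))
    paths["truth"] = outdir / "ground_truth.csv"
    field_obj.truth.to_csv(paths["truth"], index=False)
    if len(field_obj.truth_protrusions):
        paths["truth_protrusions"] = outdir / "ground_truth_protrusions.csv"
        field_obj.truth_protrusions.to_csv(paths["truth_protrusions"],
                                           index=False)
    paths["config"] = outdir / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(field_obj.cfg), fh)
    return paths


def segment_structural(channel: ChannelImage, cfg: RunConfig,
                       soma: ChannelImage | None = None):
    """Run the configured binarization + refinement (+ soma exclusion)."""
    if cfg.threshold_method == "bernsen":
        mask = segment.binarize_bernsen(channel.data,
                                        radius_px=cfg.bernsen_radius_px,
                                        contrast=cfg.bernsen_contrast,
                                        pixel_size_nm=cfg.pixel_size_nm)
    else:
        mask = segment.binarize_global(channel.data,
                                       threshold=cfg.global_threshold,
                                       pixel_size_nm=cfg.pixel_size_nm)
    mask = segment.refine_mask(mask, cfg.refine_steps)
    if soma is not None:
        mask = segment.apply_region_exclusion(mask, soma.data)
    return mask


def run_pipeline(channels: dict[str, ChannelImage],
                 cfg: RunConfig) -> dict:
    """Execute segmentation -> morphometry -> widths -> calls -> spatial.

    Returns a bundle with the morphometry table, call tables, ring stats,
    population summary and the run manifest.  Stages whose channels are
    missing are skipped with a warning recorded in the bundle.
    """
    warnings: list[str] = []
    dropped: list[dict] = []
    structural = channels["structural"]
    soma = channels.get("soma")
    mask = segment_structural(structural, cfg, soma)
    objects, intensity = morphology.label_objects(
        mask, structural.data, pixel_size_nm=cfg.pixel_size_nm,
        background_dilate_px=cfg.background_dilate_px)

    widths = {}
    for obj in objects:
        length = morphology.select_length(obj.area_um2, obj.major_um,
                                          obj.skeleton_length_um)
        try:
            res = profiles.measure_object_width(
                intensity, obj, length_um=length,
                r2_threshold=cfg.r2_threshold,
                shared_sigma=cfg.shared_sigma)
        except ValueError as exc:
            dropped.append({"id": obj.label, "reason": f"profile: {exc}"})
            continue
        if not res["qc_ok"]:
            dropped.append({"id": obj.label, "reason": "center_fit_rejected"})
        widths[obj.label] = (res["width_center_nm"], res["width_outer_nm"],
                             res["qc_ok"])
    records = morphology.build_morph_records(
        objects, widths, a_th_um2=cfg.a_th_um2,
        ar_threshold=cfg.ar_threshold)
    regions = {role: ch.data for role, ch in channels.items()
               if role in ("dendrite", "axon", "transfected")}
    if regions:
        records = morphology.assign_region_flags(records, objects, regions)
    summary = morphology.summarize_population(records)

    calls = {}
    models = {}
    for role in ("functional", "marker"):
        if role not in channels:
            warnings.append(f"channel {role!r} missing: calls skipped")
            continue
        means = functional.object_mean_signal(objects, channels[role].data)
        try:
            model = functional.fit_threshold(
                means, min_objects=cfg.min_objects_for_calls)
        except functional.InsufficientDataError as exc:
            warnings.append(f"{role}: {exc}")
            continue
        calls[role] = functional.call_objects(means, model)
        models[role] = model

    turnover = None
    rings = None
    if "old" in channels and "new" in channels:
        ratios = np.array([
            spatial.turnover_ratio(o, channels["old"].data,
                                   channels["new"].data) for o in objects])
        turnover = pd.DataFrame({"id": [o.label for o in objects],
                                 "turnover_ratio": ratios})
        if soma is not None and np.any(soma.data):
            rings = spatial.radial_rings(
                objects, soma.data, ratios,
                classes=records["object_class"].to_numpy(),
                pixel_size_nm=cfg.pixel_size_nm,
                ring_width_um=cfg.ring_width_um)
    else:
        warnings.append("turnover channels missing: stage skipped")

    process_map = None
    densities = None
    if soma is not None:
        process_map = spatial.build_process_map(
            structural.data, soma.data, pixel_size_nm=cfg.pixel_size_nm)
        if process_map.total_length_um > 0:
            densities = {
                cls: spatial.number_density(int(n), process_map)
                for cls, n in
                records["object_class"].value_counts().items()}
    else:
        warnings.append("soma mask missing: process density skipped")

    for w in warnings:
        log.warning(w)
    return {
        "mask": mask,
        "objects": objects,
        "records": records,
        "summary": summary,
        "calls": calls,
        "threshold_models": models,
        "turnover": turnover,
        "rings": rings,
        "process_map": process_map,
        "densities": densities,
        "dropped": dropped,
        "warnings": warnings,
        "manifest": cfg.manifest(),
    }


def write_bundle(bundle: dict, outdir: str | Path) -> None:
    """Persist the pipeline outputs as CSV/JSON (stable column order)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["records"].to_csv(outdir / "morphometry.csv", index=False)
    for role, table in bundle["calls"].items():
        table.to_csv(outdir / f"calls_{role}.csv", index=False)
    if bundle["turnover"] is not None:
        bundle["turnover"].to_csv(outdir / "turnover.csv", index=False)
    if bundle["rings"] is not None:
        bundle["rings"].to_csv(outdir / "ring_stats.csv", index=False)
    side = {
        "manifest": bundle["manifest"],
        "warnings": bundle["warnings"],
        "dropped": bundle["dropped"],
        "densities": bundle["densities"],
        "process_length_um":
            bundle["process_map"].total_length_um
            if bundle["process_map"] is not None else None,
    }
    with open(outdir / "run.json", "w") as fh:
        json.dump(side, fh, indent=2, default=str)
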