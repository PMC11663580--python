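"""Batch orchestration across a multiplexed image series.

One configuration drives the whole run: images are ordered by the capture
time parsed from their filenames, the plate layout is detected on the
first image and reused, every image is segmented against the color hull,
per-unit areas are extracted, and relative growth rates are fitted per
unit with group summaries.  Per-image processing is independent, so
results are identical regardless of processing order.
"""

from __future__ import annotations

import glob as _glob
import logging
import re
import time as _time
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import growth, layout as layout_mod, segmentation
from .colorspace import LabImage, srgb_to_lab
from .config import RunConfig
from .growth import AreaRecord, FitCriteria, RgrFit
from .layout import Circle, PlateLayout

logger = logging.getLogger("hullseg")

__all__ = ["RunResult", "run_series", "evaluate_masks", "parse_time", "sort_images"]


@dataclass
class RunResult:
    areas: pd.DataFrame
    fits: pd.DataFrame
    groups: pd.DataFrame
    layout: PlateLayout | None
    skipped: list = field(default_factory=list)
    out_dir: Path | None = None


def parse_time(
    name: str, time_regex: str, time_format: str
) -> datetime | None:
    m = re.search(time_regex, name)
    if not m:
        return None
    return datetime.strptime(m.group("ts"), time_format)


def sort_images(
    paths: list[Path], time_regex: str, time_format: str
) -> list[tuple[Path, float]]:
    """Order images by parsed capture time (ties lexicographic); returns
    (path, days since first image) pairs."""
    stamped = []
    for p in paths:
        ts = parse_time(p.name, time_regex, time_format)
        if ts is None:
            raise ValueError(f"cannot parse a timestamp from {p.name!r}")
        stamped.append((p, ts))
    stamped.sort(key=lambda x: (x[1], x[0].name))
    t0 = stamped[0][1]
    return [(p, (ts - t0).total_seconds() / 86400.0) for p, ts in stamped]


def _resolve_images(images: str) -> list[Path]:
    p = Path(images)
    if p.is_dir():
        found = sorted(
            q for q in p.iterdir()
            if q.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff")
            and not q.name.startswith("mask_")
        )
    else:
        found = sorted(Path(q) for q in _glob.glob(images))
    return found


def _layout_from_config(config: RunConfig, first_image: np.ndarray) -> PlateLayout | None:
    lc = config.layout
    if lc.fixed:
        circles, groups, order = [], [], []
        for entry in lc.fixed:
            unit, row, col, radius = entry[:4]
            group = int(entry[4]) if len(entry) > 4 else 1
            circles.append(Circle(center=(float(row), float(col)), radius=float(radius)))
            groups.append(group)
            order.append(int(unit))
        units = [
            layout_mod.LayoutUnit(
                unit_index=order[i],
                center=circles[i].center,
                radius=circles[i].radius,
                group_index=groups[i],
            )
            for i in range(len(circles))
        ]
        units.sort(key=lambda u: u.unit_index)
        return PlateLayout(units=units, grouping_cut=lc.cut_distance, ordering=lc.ordering)
    if lc.expected_n and lc.expected_n > 0:
        gray = np.asarray(Image.fromarray(first_image).convert("L"))
        circles = layout_mod.detect_circles(
            gray, lc.r_min, lc.r_max, lc.expected_n
        )
        groups = layout_mod.cluster_centers(circles, lc.cut_distance)
        return layout_mod.index_layout(
            circles, groups, ordering=lc.ordering, cut_distance=lc.cut_distance
        )
    return None  # whole frame treated as one unit


def _apply_background(lab: LabImage, cuboid) -> LabImage:
    if not cuboid:
        return lab
    lo = np.asarray(cuboid[0], dtype=float)
    hi = np.asarray(cuboid[1], dtype=float)
    inside = np.all((lab.lab >= lo) & (lab.lab <= hi), axis=-1)
    return LabImage(lab=lab.lab, valid=lab.valid & ~inside)


def run_series(config: RunConfig, criteria: FitCriteria | None = None) -> RunResult:
    """Execute the full pipeline for a configured image series.

    Deterministic given the configuration and inputs.  Unreadable images
    are skipped with a logged warning and recorded in the result; a layout
    detection failure aborts the run.
    """
    paths = _resolve_images(config.images)
    if not paths:
        raise FileNotFoundError(f"no images match {config.images!r}")
    ordered = sort_images(paths, config.time_regex, config.time_format)

    spec = config.hull_spec()
    mesh = spec.build()
    params = segmentation.SegmentationParams(
        fill_area=config.fill_area, remove_area=config.remove_area
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    plate: PlateLayout | None = None
    unit_groups: dict[int, int] = {}
    records: list[AreaRecord] = []
    skipped: list[str] = []
    for i, (path, t_days) in enumerate(ordered):
        t_start = _time.perf_counter()
        try:
            rgb = np.asarray(Image.open(path).convert("RGB"))
        except OSError as exc:
            logger.warning("skipping unreadable image %s: %s", path, exc)
            skipped.append(str(path))
            continue
        if plate is None and i == len(skipped):  # first readable image
            plate = _layout_from_config(config, rgb)
            if plate is not None:
                unit_groups = {u.unit_index: u.group_index for u in plate.units}
        lab = _apply_background(srgb_to_lab(rgb), config.background_cuboid)
        mask = segmentation.segment(lab, spec, mesh)
        mask = segmentation.postprocess(mask, params)
        if plate is not None:
            labels = layout_mod.roi_mask(
                plate, mask.shape, dilation=config.layout.dilation
            )
        else:
            labels = np.ones(mask.shape, dtype=np.int32)
        records.extend(
            growth.area_per_unit(
                mask, labels, time=t_days, scale=config.scale,
                groups=unit_groups or None,
            )
        )
        if config.debug:
            _write_debug(out_dir, path, rgb, mask, config)
        logger.info(
            "%s: %.0f ms", path.name, 1e3 * (_time.perf_counter() - t_start)
        )

    fits = _fit_all(records, criteria)
    areas_df = growth.areas_table(records)
    fits_df = growth.fits_table(fits)
    groups_df = growth.group_summary(fits, plate)

    areas_df.to_csv(out_dir / "areas.csv", index=False)
    fits_df.to_csv(out_dir / "fits.csv", index=False)
    groups_df.to_csv(out_dir / "groups.csv", index=False)
    return RunResult(
        areas=areas_df, fits=fits_df, groups=groups_df, layout=plate,
        skipped=skipped, out_dir=out_dir,
    )


def _fit_all(records: list[AreaRecord], criteria: FitCriteria | None) -> list[RgrFit]:
    by_unit: dict[int, list[AreaRecord]] = {}
    for r in records:
        by_unit.setdefault(r.unit_index, []).append(r)
    fits = [
        growth.fit_rgr(sorted(series, key=lambda r: r.time))
        for _, series in sorted(by_unit.items())
    ]
    return growth.flag_outliers(fits, criteria)


def _write_debug(
    out_dir: Path, path: Path, rgb: np.ndarray, mask: np.ndarray, config: RunConfig
) -> None:
    dbg = out_dir / "debug"
    dbg.mkdir(exist_ok=True)
    Image.fromarray((mask * 255).astype(np.uint8)).save(
        dbg / f"{path.stem}_mask.png"
    )
    ov = segmentation.overlay(rgb, mask, color=tuple(config.overlay_color))
    Image.fromarray(ov).save(dbg / f"{path.stem}_overlay.png")


def evaluate_masks(pred_dir: str | Path, ref_dir: str | Path) -> pd.DataFrame:
    """Per-image Dice between matching mask files in two directories.

    Returns a tidy table with one row per matched filename plus a
    trailing summary row (mean ± SD over successful pairs).  Unmatched
    files and dimension mismatches are recorded, not fatal.
    """
    pred_dir, ref_dir = Path(pred_dir), Path(ref_dir)
    preds = {p.name: p for p in sorted(pred_dir.iterdir()) if p.is_file()}
    refs = {p.name: p for p in sorted(ref_dir.iterdir()) if p.is_file()}
    rows = []
    for name in sorted(set(preds) | set(refs)):
        if name not in preds or name not in refs:
            rows.append({"image": name, "dice": np.nan, "status": "unmatched"})
            continue
        a = np.asarray(Image.open(preds[name]).convert("L")) > 0
        b = np.asarray(Image.open(refs[name]).convert("L")) > 0
        if a.shape != b.shape:
            rows.append(
                {"image": name, "dice": np.nan, "status": "dimension mismatch"}
            )
            continue
        rows.append(
            {"image": name, "dice": segmentation.dice(a, b), "status": "ok"}
        )
    df = pd.DataFrame(rows, columns=["image", "dice", "status"])
    ok = df[df.status == "ok"].dice
    summary = {
        "image": "__summary__",
        "dice": float(ok.mean()) if len(ok) else np.nan,
        "status": f"mean±SD over {len(ok)}: "
        f"{ok.mean():.3f} ± {ok.std(ddof=1) if len(ok) > 1 else 0.0:.3f}"
        if len(ok)
        else "no pairs",
    }
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
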