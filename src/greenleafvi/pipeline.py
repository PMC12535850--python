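"""Batch pipeline: white-balance, segment, and measure a directory of images.

Each input image runs through the enabled stages in order; intermediate
images are written with their stage suffixes ("_whitebalanced",
"_segmented") as lossless PNG, and one tidy row per detected object is
appended to results.csv.  Images are processed in lexicographic filename
order; a failed image is logged and skipped rather than aborting the batch.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from greenleafvi.image_io import (
    Roi,
    SEGMENTED_SUFFIX,
    WHITEBALANCED_SUFFIX,
    read_rgb_image,
    write_rgb_image,
)
from greenleafvi.indices import INDEX_COLUMNS, compute_indices
from greenleafvi.measure import measure_objects
from greenleafvi.segmentation import HsvBounds, segment
from greenleafvi.white_balance import (
    AUTO_MAX_CHANNEL_SPREAD,
    AUTO_MIN_AREA,
    AUTO_MIN_INTENSITY,
    ReferenceNotFoundError,
    apply_white_balance,
    locate_white_reference,
)

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")

STAT_COLUMNS = tuple(
    f"{stat}_{ch}" for ch in ("R", "G", "B") for stat in ("min", "max", "median", "mean")
)

RESULT_COLUMNS = ("image", "object", "area") + STAT_COLUMNS + INDEX_COLUMNS + ("undefined",)


@dataclass(frozen=True)
class PipelineConfig:
    input_dir: Path
    output_dir: Path
    white_balance: bool = True
    white_balance_mode: str = "auto"  # "auto" | "manual"
    white_balance_roi: Roi | None = None
    auto_min_intensity: int = AUTO_MIN_INTENSITY
    auto_max_channel_spread: int = AUTO_MAX_CHANNEL_SPREAD
    auto_min_area: int = AUTO_MIN_AREA
    segmentation: bool = True
    hsv_bounds: HsvBounds = field(default_factory=HsvBounds)
    connectivity: int = 8
    csv_name: str = "results.csv"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.white_balance_mode not in ("auto", "manual"):
            raise ValueError(f"white_balance_mode must be auto|manual, got {self.white_balance_mode!r}")
        if self.white_balance_mode == "manual" and self.white_balance and self.white_balance_roi is None:
            raise ValueError("manual white balance requires a roi")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        wb = d.get("white_balance", {}) or {}
        seg = d.get("segmentation", {}) or {}
        auto = wb.get("auto", {}) or {}
        hsv = seg.get("hsv", {}) or {}
        roi = wb.get("roi")
        return cls(
            input_dir=Path(d["input_dir"]),
            output_dir=Path(d["output_dir"]),
            white_balance=bool(wb.get("enabled", True)),
            white_balance_mode=wb.get("mode", "auto"),
            white_balance_roi=Roi(*roi) if roi else None,
            auto_min_intensity=int(auto.get("min_intensity", AUTO_MIN_INTENSITY)),
            auto_max_channel_spread=int(auto.get("max_channel_spread", AUTO_MAX_CHANNEL_SPREAD)),
            auto_min_area=int(auto.get("min_area", AUTO_MIN_AREA)),
            segmentation=bool(seg.get("enabled", True)),
            hsv_bounds=HsvBounds(
                h_min=int(hsv.get("h_min", 0)),
                h_max=int(hsv.get("h_max", 255)),
                s_min=int(hsv.get("s_min", 0)),
                s_max=int(hsv.get("s_max", 255)),
                v_min=int(hsv.get("v_min", 0)),
                v_max=int(hsv.get("v_max", 255)),
                min_area=int(seg.get("min_area", 0)),
            ),
            connectivity=int(seg.get("connectivity", 8)),
            csv_name=d.get("csv_name", "results.csv"),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _measure_image(name: str, image, labels, exclude_roi) -> list[dict]:
    rows = []
    for st in measure_objects(image, labels, exclude_roi=exclude_roi):
        idx = compute_indices(st.mean_r, st.mean_g, st.mean_b)
        undefined = sorted(k for k, ok in idx.flags.items() if not ok)
        row = {"image": name, "object": st.object_id, "area": st.area}
        for ch_lower, ch_upper in (("r", "R"), ("g", "G"), ("b", "B")):
            for stat in ("min", "max", "median", "mean"):
                row[f"{stat}_{ch_upper}"] = getattr(st, f"{stat}_{ch_lower}")
        row.update(idx.as_columns())
        row["undefined"] = ";".join(undefined)
        rows.append(row)
    return rows


def process_image(path: Path, config: PipelineConfig) -> list[dict]:
    """Run one image through the enabled stages; return its result rows."""
    image = read_rgb_image(path)
    ref_roi: Roi | None = None

    if config.white_balance:
        try:
            ref_roi = locate_white_reference(
                image,
                roi=config.white_balance_roi if config.white_balance_mode == "manual" else None,
                min_intensity=config.auto_min_intensity,
                max_channel_spread=config.auto_max_channel_spread,
                min_area=config.auto_min_area,
            )
        except ReferenceNotFoundError:
            logger.warning("%s: no white reference found; skipping white balance", path.name)
        else:
            result = apply_white_balance(image, ref_roi)
            image = result.balanced_image
            write_rgb_image(image, path, WHITEBALANCED_SUFFIX, output_dir=config.output_dir)

    if config.segmentation:
        segmented, labels = segment(image, config.hsv_bounds, connectivity=config.connectivity)
        write_rgb_image(segmented, path, SEGMENTED_SUFFIX, output_dir=config.output_dir)
    else:
        # fallback: a single all-foreground object (reference excluded at measurement)
        labels = np.ones(image.shape[:2], dtype=np.int32)

    rows = _measure_image(path.name, image, labels, ref_roi)
    if not rows:
        logger.info("%s: no objects detected", path.name)
    return rows


def run_batch(config: PipelineConfig) -> pd.DataFrame:
    """Process every image in ``config.input_dir``; write and return results.

    Returns the tidy results table (one row per image-object pair) that is
    also written to ``output_dir/csv_name``.
    """
    input_dir = Path(config.input_dir)
    paths = sorted(
        p for p in input_dir.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
        and not any(p.stem.endswith(s) for s in (WHITEBALANCED_SUFFIX, SEGMENTED_SUFFIX))
    )
    if not paths:
        raise ValueError(f"no readable images found in {input_dir}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_rows: list[dict] = []
    for path in paths:
        logger.info("processing %s", path.name)
        try:
            all_rows.extend(process_image(path, config))
        except Exception:
            logger.exception("%s: processing failed; skipping", path.name)
    return write_results(all_rows, out_dir / config.csv_name)


def write_results(rows: list[dict], path: str | os.PathLike) -> pd.DataFrame:
    """Write result rows as tidy CSV (fixed column order, NaN as "NA")."""
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False, na_rep="NA")
    return df


def regression_report(results: pd.DataFrame, chl: pd.DataFrame) -> pd.DataFrame:
    """Per-index validation fits of chlorophyll content on each CVI.

    ``results`` is a pipeline results table; ``chl`` must carry ``sample_id``
    (the image filename stem) and ``chl_mg_per_cm2``.  CVIs are averaged per
    image when several objects are present; the Woebbecke index is fitted on
    the reciprocal model y ~ -1/x, all others with y ~ x.
    """
    from greenleafvi.regression import fit_linear, fit_reciprocal

    res = results.copy()
    res["sample_id"] = [Path(n).stem for n in res["image"]]
    per_image = res.groupby("sample_id", as_index=False)[list(INDEX_COLUMNS)].mean()
    merged = per_image.merge(chl[["sample_id", "chl_mg_per_cm2"]], on="sample_id")

    rows = []
    for col in INDEX_COLUMNS:
        x = merged[col].to_numpy(dtype=float)
        y = merged["chl_mg_per_cm2"].to_numpy(dtype=float)
        if col == "Woebbecke":
            ok = (x != 0) & ~pd.isna(x)
            fit_fn, model = fit_reciprocal, "reciprocal"
            x, y = x[ok], y[ok]
        else:
            fit_fn, model = fit_linear, "linear"
        try:
            fit = fit_fn(x, y)
            rows.append({
                "index": col, "model": model, "slope": fit.slope,
                "intercept": fit.intercept, "r_squared": fit.r_squared,
                "p_value": fit.p_value, "n": fit.n,
            })
        except ValueError as exc:
            logger.warning("%s: fit failed (%s)", col, exc)
            rows.append({
                "index": col, "model": model, "slope": math.nan,
                "intercept": math.nan, "r_squared": math.nan,
                "p_value": math.nan, "n": 0,
            })
    return pd.DataFrame(rows)
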