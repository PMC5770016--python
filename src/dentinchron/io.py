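"""Readers and writers for measurement tables, summary tables and TIFF images.

CSV dialect is fixed: comma separator, '.' decimal, UTF-8, one header
row. Stored values are full precision; only emitted summary tables are
rounded to 2 decimals.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .model import (
    DayEstimate,
    GLGRecord,
    GLGSummary,
    ImageWithScale,
    PredictionPair,
    SchemaError,
    SpacingMeasurement,
    ValidationError,
)

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["specimen_id", "glg_label", "position_um", "spacing_um"]
METADATA_COLUMNS = [
    "specimen_id",
    "glg_label",
    "thickness_um",
    "sex",
    "tooth_position",
    "whale_length_cm",
    "preparation",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_metadata_table(path: Union[str, Path]) -> list[GLGRecord]:
    """Read a GLG metadata CSV into validated records.

    Optional columns (sex, tooth_position, whale_length_cm, preparation)
    may be absent or empty; (specimen_id, glg_label) must be unique.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["specimen_id", "glg_label", "thickness_um"], path)
    records: list[GLGRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based file line, after the header
        try:
            rec = GLGRecord(
                specimen_id=str(row["specimen_id"]),
                glg_label=str(row["glg_label"]),
                thickness_um=float(row["thickness_um"]),
                sex=str(row["sex"]) if "sex" in df.columns and pd.notna(row.get("sex")) else "unknown",
                tooth_position=int(row["tooth_position"])
                if "tooth_position" in df.columns and pd.notna(row.get("tooth_position"))
                else 1,
                whale_length_cm=float(row["whale_length_cm"])
                if "whale_length_cm" in df.columns and pd.notna(row.get("whale_length_cm"))
                else None,
                preparation=str(row["preparation"])
                if "preparation" in df.columns and pd.notna(row.get("preparation"))
                else "demineralized",
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {rowno}: {exc}") from exc
        if rec.key in seen:
            raise ValidationError(
                f"{path} row {rowno}: duplicate GLG {rec.key[0]}-{rec.key[1]}"
            )
        seen.add(rec.key)
        records.append(rec)
    return records


def read_measurement_table(
    path: Union[str, Path],
    metadata: Union[str, Path, Sequence[GLGRecord], None] = None,
) -> tuple[list[GLGRecord], list[SpacingMeasurement]]:
    """Read spacing measurements, optionally joined with GLG metadata.

    Returns ``(records, measurements)`` with measurements grouped in
    file order by (specimen_id, glg_label). When ``metadata`` (a path or
    a record list) is supplied, each measurement's position is checked
    against the referenced GLG's thickness and the records are returned;
    without it the record list is empty.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, MEASUREMENT_COLUMNS, path)

    if metadata is None:
        records: list[GLGRecord] = []
    elif isinstance(metadata, (str, Path)):
        records = read_metadata_table(metadata)
    else:
        records = list(metadata)
    thickness = {r.key: r.thickness_um for r in records}

    measurements: list[SpacingMeasurement] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2
        key = (str(row["specimen_id"]), str(row["glg_label"]))
        try:
            m = SpacingMeasurement(
                glg_ref=key,
                position_um=float(row["position_um"]),
                spacing_um=float(row["spacing_um"]),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {rowno}: {exc}") from exc
        if key in thickness and m.position_um > thickness[key] + 1e-9:
            raise ValidationError(
                f"{path} row {rowno}: position {m.position_um:.2f} μm exceeds "
                f"thickness {thickness[key]:.2f} μm of GLG {key[0]}-{key[1]}"
            )
        measurements.append(m)
    # stable grouping by GLG, preserving within-GLG file order
    order = {k: j for j, k in enumerate(dict.fromkeys(m.glg_ref for m in measurements))}
    measurements.sort(key=lambda m: order[m.glg_ref])
    return records, measurements


def write_measurement_table(
    measurements: Iterable[SpacingMeasurement], path: Union[str, Path]
) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "specimen_id": m.glg_ref[0],
                "glg_label": m.glg_ref[1],
                "position_um": m.position_um,
                "spacing_um": m.spacing_um,
            }
            for m in measurements
        ],
        columns=MEASUREMENT_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def write_metadata_table(records: Iterable[GLGRecord], path: Union[str, Path]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "glg_label": r.glg_label,
                "thickness_um": r.thickness_um,
                "sex": r.sex,
                "tooth_position": r.tooth_position,
                "whale_length_cm": r.whale_length_cm,
                "preparation": r.preparation,
            }
            for r in records
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def write_summary_table(
    records: Sequence[GLGRecord],
    summaries: Sequence[GLGSummary],
    estimates: Sequence[DayEstimate],
    predictions: Sequence[PredictionPair],
    path: Union[str, Path],
) -> Path:
    """Write a per-GLG summary CSV with a final unweighted "Average" row.

    All four lists must be aligned by GLG; numeric cells are rounded to
    2 decimals on write (values stay full precision in memory).
    """
    path = Path(path)
    if len(records) == 0:
        raise ValidationError("cannot write a summary table with no GLGs")
    if not (len(records) == len(summaries) == len(estimates) == len(predictions)):
        keys = [f"{r.specimen_id}-{r.glg_label}" for r in records]
        raise ValidationError(
            "misaligned inputs: "
            f"{len(records)} records vs {len(summaries)} summaries, "
            f"{len(estimates)} estimates, {len(predictions)} predictions "
            f"(records: {', '.join(keys)})"
        )
    rows = []
    for r, s, e, p in zip(records, summaries, estimates, predictions):
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "glg_label": r.glg_label,
                "thickness_um": r.thickness_um,
                "mean_um": s.mean_um,
                "three_se_um": s.three_se_um,
                "sum_um": s.sum_um,
                "n": s.n,
                "pred_1glg_um": p.pred_1glg_um,
                "pred_2glg_um": p.pred_2glg_um,
                "days": e.days,
                "err_minus": e.err_minus,
                "err_plus": e.err_plus,
            }
        )
    df = pd.DataFrame(rows)
    avg = df.select_dtypes(include=[np.number]).mean(axis=0)
    avg_row = {"specimen_id": "Average", "glg_label": ""} | avg.to_dict()
    out = pd.concat([df, pd.DataFrame([avg_row])], ignore_index=True)
    out = out.round(2)
    out.to_csv(path, index=False)
    return path


def read_summary_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a summary table (including its Average row)."""
    return pd.read_csv(Path(path), comment="#")


def load_image(path: Union[str, Path], um_per_px: float) -> ImageWithScale:
    """Load a grayscale TIFF (single plane, or multi-page as a z-stack)."""
    path = Path(path)
    if not (um_per_px > 0):
        raise ValidationError(f"um_per_px must be > 0, got {um_per_px!r}")
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < arr.shape[-2]:
        raise ValidationError(
            f"{path}: multi-channel (color) images are not supported; "
            "convert to single-channel grayscale first"
        )
    if arr.ndim not in (2, 3):
        raise ValidationError(f"{path}: expected a 2-D image or 3-D stack, got ndim={arr.ndim}")
    return ImageWithScale(pixels=arr, um_per_px=float(um_per_px))


def save_image(image: ImageWithScale, path: Union[str, Path]) -> Path:
    """Write an image (or z-stack, one page per plane) as float32 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image.pixels, dtype=np.float32))
    return path
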