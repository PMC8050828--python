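"""TIFF and tabular I/O for the pipeline.

Frames travel as multi-page 16-bit unsigned TIFF (one page per channel,
channel 0 = lipid marker, channel 1 = construct label); records and
summaries travel as UTF-8 CSV with a header row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .quantify import PartitionRecord
from .synthetic import ImageFrame

__all__ = ["save_frame", "load_frame", "records_to_frame", "write_records", "read_records"]

RECORD_COLUMNS = [
    "vesicle_id",
    "frame",
    "population_label",
    "radius_px",
    "I_Lo",
    "I_Ld",
    "f_p_Lo",
    "separation_score",
    "flags",
]


def save_frame(frame: ImageFrame, path: str | Path) -> None:
    """Write a frame as a multi-page uint16 TIFF (values clipped/rounded)."""
    data = np.clip(np.rint(frame.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def load_frame(path: str | Path, pixel_size_um: float = 0.2) -> ImageFrame:
    """Read a two-channel TIFF as an :class:`ImageFrame` (float counts)."""
    data = tifffile.imread(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        raise ValidationError(f"{path}: single-channel image; two channels required")
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected (channels, H, W), got {data.shape}")
    if data.shape[0] > data.shape[-1]:  # channels-last layout
        data = np.moveaxis(data, -1, 0)
    return ImageFrame(data.astype(float), pixel_size_um=pixel_size_um)


def records_to_frame(
    records: Sequence[PartitionRecord], frame_ids: Sequence[int] | None = None
) -> pd.DataFrame:
    """Convert partition records to the interchange DataFrame."""
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "vesicle_id": r.vesicle_id,
                "frame": frame_ids[i] if frame_ids is not None else 0,
                "population_label": r.population_label,
                "radius_px": r.radius,
                "I_Lo": r.I_Lo,
                "I_Ld": r.I_Ld,
                "f_p_Lo": r.f_p_Lo,
                "separation_score": r.separation_score,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records_df: pd.DataFrame, path: str | Path) -> None:
    records_df.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("population_label", "flags"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    missing = set(RECORD_COLUMNS) - {"flags"} - set(df.columns)
    if missing:
        raise ValidationError(f"records file {path} missing columns {sorted(missing)}")
    return df
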