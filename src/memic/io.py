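"""Reading and writing the pipeline's on-disk formats.

Images travel as single-plane grayscale TIFFs (16-bit by default, matching
stitched microscope exports), cell tables as CSV with a YAML metadata
sidecar, and simulator/segmentation configuration as flat YAML files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .cytometry import CellTable, ChamberMeta, ChannelImage, SegmentationParams
from .profiling import OpeningSpec
from .simulate import ChamberSpec, ReporterSpec

__all__ = [
    "read_channel_image",
    "write_channel_image",
    "write_label_map",
    "read_label_map",
    "write_cell_table",
    "read_cell_table",
    "load_segmentation_params",
    "load_chamber_config",
]


def read_channel_image(
    path: str | Path,
    pixel_size: float = 1.0,
    channel: str | None = None,
    bit_depth: int = 16,
) -> ChannelImage:
    """Load a single-plane grayscale TIFF as a :class:`ChannelImage`.

    The channel name defaults to the file stem.
    """
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane grayscale TIFF, got shape {pixels.shape}")
    return ChannelImage(
        pixels=pixels,
        pixel_size=pixel_size,
        channel=channel or path.stem,
        bit_depth=bit_depth,
    )


def _int_dtype(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8) if bit_depth <= 8 else np.dtype(np.uint16)


def write_channel_image(image: ChannelImage, path: str | Path) -> Path:
    """Write a channel as a grayscale TIFF at its native bit depth."""
    path = Path(path)
    dtype = _int_dtype(image.bit_depth)
    px = np.asarray(image.pixels)
    if not np.issubdtype(px.dtype, np.integer):
        px = np.clip(np.round(px), 0, 2**image.bit_depth - 1)
    tifffile.imwrite(path, px.astype(dtype), photometric="minisblack")
    return path


def write_label_map(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label map as a 16-bit TIFF (max 65535 labels)."""
    if labels.max() > 65535:
        raise ValueError("label map exceeds 16-bit range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16), photometric="minisblack")
    return Path(path)


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def _meta_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.yaml")


def write_cell_table(table: CellTable, csv_path: str | Path) -> Path:
    """Write a cell table as CSV plus a YAML metadata sidecar.

    CSV columns follow the measurement convention: 0-based pixel centroids
    converted to µm, areas in µm², raw mean intensities per channel.
    """
    csv_path = Path(csv_path)
    table.df.to_csv(csv_path, index=False)
    meta = {
        "chamber_id": table.meta.chamber_id,
        "condition": table.meta.condition,
        "pixel_size_um": table.meta.pixel_size,
    }
    if table.meta.opening is not None:
        meta["opening"] = {
            "edge_axis": table.meta.opening.edge_axis,
            "edge_offset_um": table.meta.opening.edge_offset,
        }
    _meta_path(csv_path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return csv_path


def read_cell_table(csv_path: str | Path) -> CellTable:
    """Read a cell table CSV (and its metadata sidecar, if present)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = ChamberMeta()
    mp = _meta_path(csv_path)
    if mp.exists():
        raw = yaml.safe_load(mp.read_text()) or {}
        opening = None
        if "opening" in raw:
            opening = OpeningSpec(
                edge_axis=raw["opening"]["edge_axis"],
                edge_offset=float(raw["opening"]["edge_offset_um"]),
            )
        meta = ChamberMeta(
            chamber_id=raw.get("chamber_id", "chamber"),
            condition=raw.get("condition", ""),
            pixel_size=float(raw.get("pixel_size_um", 1.0)),
            opening=opening,
        )
    return CellTable(df=df, meta=meta)


def load_segmentation_params(path: str | Path) -> SegmentationParams:
    """Load :class:`SegmentationParams` from a flat YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(SegmentationParams)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown segmentation parameters: {sorted(unknown)}")
    return SegmentationParams(**raw)


def load_chamber_config(path: str | Path) -> tuple[ChamberSpec, ReporterSpec]:
    """Load simulator configuration from YAML.

    Top-level keys are :class:`ChamberSpec` fields; an optional ``reporter``
    block holds :class:`ReporterSpec` fields.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    rep_raw = raw.pop("reporter", {}) or {}
    chamber_fields = {f.name for f in dataclasses.fields(ChamberSpec)}
    unknown = set(raw) - chamber_fields
    if unknown:
        raise ValueError(f"unknown chamber parameters: {sorted(unknown)}")
    return ChamberSpec(**raw), ReporterSpec(**rep_raw)
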