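"""Single-cell detection, segmentation and measurement on stitched chamber images.

Implements a flow-cytometry-like quantification of fluorescence microscopy
images ("image cytometry"): nuclei are detected on a uniform nuclear stain
(e.g. Hoechst), touching nuclei are split by a distance-transform watershed,
each nucleus is optionally expanded into a cell territory, and per-cell
position, area and per-channel mean intensities are tabulated.

All spatial parameters are in micrometres and converted to pixels internally
using the image's pixel size. Intensities are reported on the raw
(unnormalized) scale; normalization is an explicit downstream step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops_table
from skimage.morphology import h_maxima
from skimage.segmentation import expand_labels, relabel_sequential, watershed

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .profiling import OpeningSpec

__all__ = [
    "ChannelImage",
    "SegmentationParams",
    "ChamberMeta",
    "CellTable",
    "detect_nuclei",
    "segment_cells",
    "measure_cells",
]


@dataclass(frozen=True)
class ChannelImage:
    """One fluorescence channel: a 2D intensity grid plus physical calibration.

    Parameters
    ----------
    pixels : 2D array of non-negative intensities (any integer or float dtype).
    pixel_size : physical size of one pixel in µm/px.
    channel : channel name (e.g. ``"hoechst"``, ``"gfp"``).
    bit_depth : acquisition bit depth; pixel values must lie in
        ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    pixel_size: float
    channel: str
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if px.size and (px.min() < 0 or px.max() > 2**self.bit_depth - 1):
            raise ValueError(
                f"pixel values outside [0, {2**self.bit_depth - 1}] "
                f"for {self.bit_depth}-bit channel {self.channel!r}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field in µm."""
        h, w = self.pixels.shape
        return w * self.pixel_size, h * self.pixel_size


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for nucleus detection and cell-territory assignment.

    smoothing_sigma : Gaussian pre-smoothing of the nuclear channel, µm.
    threshold_method : ``"otsu"`` (parameter-free) or ``"fixed"``.
    fixed_threshold : threshold in raw intensity units when method is fixed.
    min_nucleus_area, max_nucleus_area : area filter bounds, µm².
    split_touching : split merged blobs by watershed on the distance transform.
    h_minima_depth : depth (µm) below which distance-transform maxima are
        merged into a single watershed seed; larger values split less.
    cell_expansion_radius : how far (µm) each nucleus is grown into a cell
        territory, contested pixels going to the nearest nucleus; 0 keeps
        the nucleus as the cell region.
    """

    smoothing_sigma: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_nucleus_area: float = 10.0
    max_nucleus_area: float = 500.0
    split_touching: bool = True
    h_minima_depth: float = 1.0
    cell_expansion_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if not 0 < self.min_nucleus_area < self.max_nucleus_area:
            raise ValueError("require 0 < min_nucleus_area < max_nucleus_area")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required for threshold_method='fixed'")
        if self.h_minima_depth < 0 or self.cell_expansion_radius < 0:
            raise ValueError("h_minima_depth and cell_expansion_radius must be >= 0")


@dataclass(frozen=True)
class ChamberMeta:
    """Chamber-level metadata shared by every cell record of a table."""

    chamber_id: str = "chamber"
    condition: str = ""
    pixel_size: float = 1.0
    opening: "OpeningSpec | None" = None


@dataclass
class CellTable:
    """Per-cell measurements plus chamber metadata.

    ``df`` columns: ``cell_id``, ``x_um``, ``y_um``, ``area_um2``, one
    ``<channel>_mean`` per measured channel; the profiling layer appends
    ``distance_um`` and ``outside_chamber``. Coordinates are 0-based pixel
    centroids converted to µm.
    """

    df: pd.DataFrame
    meta: ChamberMeta = field(default_factory=ChamberMeta)

    def __post_init__(self) -> None:
        if len(self.df) and self.df["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def channels(self) -> list[str]:
        return [c[:-5] for c in self.df.columns if c.endswith("_mean")]

    def with_df(self, df: pd.DataFrame) -> "CellTable":
        return dataclasses.replace(self, df=df)


def _threshold(smoothed: np.ndarray, params: SegmentationParams) -> float | None:
    if params.threshold_method == "fixed":
        return float(params.fixed_threshold)
    if smoothed.max() == smoothed.min():
        return None  # flat image: nothing to detect
    return float(threshold_otsu(smoothed))


def _area_filter(labels: np.ndarray, min_px: float, max_px: float) -> np.ndarray:
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    bad = (counts < min_px) | (counts > max_px)
    bad[0] = False
    if bad.any():
        labels = np.where(bad[labels], 0, labels)
    return relabel_sequential(labels)[0]


def detect_nuclei(nuclear: ChannelImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Detect nuclei on the uniform nuclear stain; return an integer label map.

    The channel is Gaussian-smoothed, thresholded (Otsu by default),
    area-filtered, and — when ``split_touching`` — merged blobs are divided by
    a marker-based watershed on the Euclidean distance transform, with seeds
    taken as h-maxima of the distance map (shallow maxima within
    ``h_minima_depth`` of a deeper one are merged). Background is label 0.
    A blank image yields an all-zero map, not an error.
    """
    params = params or SegmentationParams()
    img = np.asarray(nuclear.pixels, dtype=np.float64)
    ps = nuclear.pixel_size
    sigma_px = params.smoothing_sigma / ps
    smoothed = gaussian(img, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else img

    thr = _threshold(smoothed, params)
    if thr is None:
        return np.zeros(img.shape, dtype=np.int32)
    mask = smoothed > thr
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)

    if params.split_touching:
        dist = ndi.distance_transform_edt(mask)
        h_px = max(params.h_minima_depth / ps, np.finfo(float).eps)
        seeds = sk_label(h_maxima(dist, h_px))
        if seeds.max() > 0:
            labels = watershed(-dist, markers=seeds, mask=mask)
        else:  # degenerate: no maxima deeper than h
            labels = sk_label(mask)
    else:
        labels = sk_label(mask)

    min_px = params.min_nucleus_area / ps**2
    max_px = params.max_nucleus_area / ps**2
    return _area_filter(labels.astype(np.int32), min_px, max_px)


def segment_cells(
    nuclei: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Grow each nucleus into a cell territory by Voronoi-constrained expansion.

    Every nucleus label is dilated outward by up to ``cell_expansion_radius``
    (µm); pixels contested by several nuclei are assigned to the nearest one.
    Nucleus pixels keep their label; labels are never merged or dropped.
    ``cell_expansion_radius == 0`` returns the input unchanged.
    """
    params = params or SegmentationParams()
    if params.cell_expansion_radius == 0:
        return nuclei
    dist_px = params.cell_expansion_radius / pixel_size
    return expand_labels(nuclei, distance=dist_px)


def measure_cells(
    cell_labels: np.ndarray,
    channels: Sequence[ChannelImage],
    meta: ChamberMeta | None = None,
) -> CellTable:
    """Measure position, area and per-channel mean intensity for every label.

    Centroids are 0-based pixel centroids × pixel size (µm); areas are pixel
    counts × pixel size² (µm²); intensities are means of raw pixel values
    within each labeled region. Rows are ordered by ascending label.
    """
    if not channels:
        raise ValueError("at least one channel required")
    ps = channels[0].pixel_size
    for ch in channels:
        if ch.pixels.shape != cell_labels.shape:
            raise ValueError(
                f"channel {ch.channel!r} shape {ch.pixels.shape} does not match "
                f"label map shape {cell_labels.shape}"
            )
        if ch.pixel_size != ps:
            raise ValueError("all channels must share one pixel size")
    meta = meta or ChamberMeta(pixel_size=ps)

    mean_cols = [f"{ch.channel}_mean" for ch in channels]
    if cell_labels.max() == 0:
        df = pd.DataFrame(columns=["cell_id", "x_um", "y_um", "area_um2", *mean_cols])
        return CellTable(df=df, meta=meta)

    stack = np.stack([np.asarray(ch.pixels, dtype=np.float64) for ch in channels], axis=-1)
    props = regionprops_table(
        cell_labels,
        intensity_image=stack,
        properties=("label", "centroid", "area", "intensity_mean"),
    )
    df = pd.DataFrame(
        {
            "cell_id": props["label"],
            "x_um": props["centroid-1"] * ps,
            "y_um": props["centroid-0"] * ps,
            "area_um2": props["area"] * ps**2,
        }
    )
    for i, col in enumerate(mean_cols):
        key = f"intensity_mean-{i}" if f"intensity_mean-{i}" in props else "intensity_mean"
        df[col] = props[key]
    df = df.sort_values("cell_id", ignore_index=True)
    return CellTable(df=df, meta=meta)
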