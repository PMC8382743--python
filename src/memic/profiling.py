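"""Distance-resolved summaries of per-cell measurements.

Converts cell tables into spatial profiles along the axis perpendicular to
the chamber opening: distance assignment relative to the opening edge,
per-cell channel normalization, moving-median ± interquartile-range profiles,
binned positive fractions, and the half-maximal-signal position used as the
summary statistic for gradient position.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cytometry import CellTable

__all__ = [
    "OpeningSpec",
    "SpatialProfile",
    "BinnedFractionProfile",
    "FlatProfileError",
    "assign_distance",
    "normalize_channel",
    "moving_profile",
    "binned_fraction",
    "half_max_position",
]


class FlatProfileError(ValueError):
    """Half-max position is undefined for a flat profile (no gradient)."""


@dataclass(frozen=True)
class OpeningSpec:
    """Location of the opening edge (top-coverslip edge) in image coordinates.

    ``edge_axis`` names the image border the opening sits on; ``edge_offset``
    is its coordinate in µm (x for left/right edges, y for top/bottom).
    Distance increases from the edge into the chamber.
    """

    edge_axis: str = "left"
    edge_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.edge_axis not in ("left", "right", "top", "bottom"):
            raise ValueError("edge_axis must be left, right, top or bottom")


@dataclass(frozen=True)
class SpatialProfile:
    """Moving median ± IQR along distance from the opening.

    Windows with fewer than ``min_cells`` cells are kept on the grid but
    flagged absent (NaN median/quartiles). ``centers`` is strictly increasing
    and covers [0, max distance].
    """

    centers: np.ndarray  # window centers, µm
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    counts: np.ndarray
    window_width: float
    step: float
    min_cells: int

    @property
    def populated(self) -> np.ndarray:
        return self.counts >= self.min_cells

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_um": self.centers,
                "median": self.median,
                "q25": self.q25,
                "q75": self.q75,
                "n": self.counts,
            }
        )


@dataclass(frozen=True)
class BinnedFractionProfile:
    """Fraction of marker-positive cells per distance bin, per replicate.

    Bins are contiguous, half-open ``[lo, hi)`` and anchored at 0.
    ``fractions[r, b]`` is replicate r's positive fraction in bin b (NaN if
    the replicate has no cells there); ``counts`` holds the per-bin cell
    numbers.
    """

    bin_edges: np.ndarray  # (n_bins + 1,), µm
    fractions: np.ndarray  # (n_replicates, n_bins)
    counts: np.ndarray  # (n_replicates, n_bins)
    threshold: float

    @property
    def n_replicates(self) -> int:
        return self.fractions.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def assign_distance(table: CellTable, opening: OpeningSpec | None = None) -> CellTable:
    """Assign each cell its perpendicular distance from the opening edge.

    Distance increases into the chamber and is >= 0; cells on the reservoir
    side of the edge get distance 0 and ``outside_chamber=True``. Adds
    ``distance_um`` and ``outside_chamber`` columns and records the opening
    in the table metadata.
    """
    opening = opening or table.meta.opening
    if opening is None:
        raise ValueError("an OpeningSpec is required to assign distances")
    df = table.df.copy()
    coord = df["x_um"] if opening.edge_axis in ("left", "right") else df["y_um"]
    if opening.edge_axis in ("left", "top"):
        raw = coord - opening.edge_offset
    else:
        raw = opening.edge_offset - coord
    df["distance_um"] = np.maximum(raw, 0.0)
    df["outside_chamber"] = raw < 0
    meta = dataclasses.replace(table.meta, opening=opening)
    return CellTable(df=df, meta=meta)


def normalize_channel(
    table: CellTable,
    numerator: str,
    denominator: str,
    eps: float = 0.0,
) -> tuple[CellTable, int]:
    """Append a per-cell ratio column ``<numerator>_over_<denominator>``.

    Cells whose denominator intensity is <= ``eps`` are excluded from the
    returned table; the second return value counts them. An all-zero
    denominator channel is an error.
    """
    num_col, den_col = f"{numerator}_mean", f"{denominator}_mean"
    for col in (num_col, den_col):
        if col not in table.df.columns:
            raise KeyError(f"channel column {col!r} not in table")
    den = table.df[den_col].to_numpy(dtype=float)
    if len(den) and not (den > eps).any():
        raise ValueError(f"denominator channel {denominator!r} is zero for every cell")
    keep = den > eps
    df = table.df.loc[keep].copy()
    df[f"{numerator}_over_{denominator}"] = (
        df[num_col].to_numpy(dtype=float) / df[den_col].to_numpy(dtype=float)
    )
    return table.with_df(df.reset_index(drop=True)), int((~keep).sum())


def _require_distance(table: CellTable) -> pd.DataFrame:
    if "distance_um" not in table.df.columns:
        raise ValueError("distances not assigned; call assign_distance first")
    df = table.df
    if "outside_chamber" in df.columns:
        df = df.loc[~df["outside_chamber"]]
    return df


def moving_profile(
    table: CellTable,
    value: str,
    window_width: float = 100.0,
    step: float = 25.0,
    min_cells: int = 20,
) -> SpatialProfile:
    """Moving median and interquartile bounds of ``value`` versus distance.

    For each window center c on a 0-anchored grid of spacing ``step`` covering
    [0, max distance], takes the median / 25th / 75th percentile of the value
    over cells with distance in ``[c − w/2, c + w/2)``. Windows with fewer
    than ``min_cells`` cells are flagged absent (NaN). Cells flagged
    outside-chamber are excluded.
    """
    if window_width <= 0 or step <= 0:
        raise ValueError("window_width and step must be positive")
    df = _require_distance(table)
    if value not in df.columns:
        raise KeyError(f"value column {value!r} not in table")
    d = df["distance_um"].to_numpy(dtype=float)
    v = df[value].to_numpy(dtype=float)
    if len(d) == 0:
        z = np.array([])
        return SpatialProfile(z, z, z, z, z.astype(int), window_width, step, min_cells)

    order = np.argsort(d, kind="stable")
    d, v = d[order], v[order]
    n_win = int(np.floor(d.max() / step)) + 1
    centers = np.arange(n_win) * step
    lo = np.searchsorted(d, centers - window_width / 2, side="left")
    hi = np.searchsorted(d, centers + window_width / 2, side="left")
    counts = hi - lo
    med = np.full(n_win, np.nan)
    q25 = np.full(n_win, np.nan)
    q75 = np.full(n_win, np.nan)
    for i in range(n_win):
        if counts[i] >= min_cells and counts[i] > 0:
            q25[i], med[i], q75[i] = np.percentile(v[lo[i] : hi[i]], [25, 50, 75])
    return SpatialProfile(centers, med, q25, q75, counts, window_width, step, min_cells)


def binned_fraction(
    tables: Sequence[CellTable],
    marker: str,
    threshold: float,
    bin_width: float = 250.0,
) -> BinnedFractionProfile:
    """Per-replicate fraction of marker-positive cells in contiguous bins.

    A cell is positive when its marker value is strictly above ``threshold``.
    Bins are half-open ``[lo, lo + bin_width)`` anchored at 0 and extend to
    the maximum distance over all replicates; a replicate with no cells in a
    bin contributes NaN there.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not tables:
        raise ValueError("at least one replicate table required")
    dfs = [_require_distance(t) for t in tables]
    max_d = max((df["distance_um"].max() for df in dfs if len(df)), default=0.0)
    n_bins = max(int(np.floor(max_d / bin_width)) + 1, 1)
    edges = np.arange(n_bins + 1) * bin_width
    fractions = np.full((len(tables), n_bins), np.nan)
    counts = np.zeros((len(tables), n_bins), dtype=int)
    for r, df in enumerate(dfs):
        if not len(df):
            continue
        d = df["distance_um"].to_numpy(dtype=float)
        pos = df[marker].to_numpy(dtype=float) > threshold
        idx = np.minimum((d / bin_width).astype(int), n_bins - 1)
        n_in = np.bincount(idx, minlength=n_bins)
        n_pos = np.bincount(idx, weights=pos.astype(float), minlength=n_bins)
        counts[r] = n_in
        with np.errstate(invalid="ignore"):
            fractions[r] = np.where(n_in > 0, n_pos / np.maximum(n_in, 1), np.nan)
    return BinnedFractionProfile(edges, fractions, counts, threshold)


def half_max_position(
    profile: SpatialProfile | tuple[np.ndarray, np.ndarray],
) -> float:
    """Distance at which the median profile first reaches half-maximal signal.

    The threshold is ``min + 0.5 (max − min)`` over the populated windows
    (the profile's own minimum serves as baseline, which tolerates nonzero
    background fluorescence). Returns the smallest distance where the profile
    crosses the threshold, linearly interpolated between adjacent populated
    window centers. A flat profile (max == min) raises
    :class:`FlatProfileError` — the no-gradient condition.
    """
    if isinstance(profile, SpatialProfile):
        mask = profile.populated & np.isfinite(profile.median)
        x, v = profile.centers[mask], profile.median[mask]
    else:
        x, v = (np.asarray(a, dtype=float) for a in profile)
        keep = np.isfinite(v)
        x, v = x[keep], v[keep]
    if len(x) < 3:
        raise ValueError("half-max position needs at least 3 populated windows")
    vmin, vmax = v.min(), v.max()
    if vmax <= vmin:
        raise FlatProfileError("flat profile: half-max position undefined")
    t = vmin + 0.5 * (vmax - vmin)
    for i in range(len(x)):
        if v[i] == t:
            return float(x[i])
        if i + 1 < len(x) and (v[i] - t) * (v[i + 1] - t) < 0:
            return float(x[i] + (t - v[i]) / (v[i + 1] - v[i]) * (x[i + 1] - x[i]))
    raise FlatProfileError("profile never crosses half-max")  # pragma: no cover
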