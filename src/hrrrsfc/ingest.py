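"""Reading and repairing hourly gridded series.

Three concerns live here: locating the grid cell nearest a monitoring site,
merging the analysis-hour variables with the one-hour-forecast precipitation
(analysis files carry zero precipitation by construction), and repairing the
occasional missing hour by copying the nearest earlier available hour.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import FLAG_FILLED, FLAG_OBSERVED, FLAG_UNFILLABLE

logger = logging.getLogger(__name__)

_EARTH_RADIUS_M = 6_371_008.8


@dataclass
class GridSpec:
    """A regular grid of cell centers.

    ``cell_centers`` is an (n, 2) array: ``(lat, lon)`` pairs when
    ``coord_system == "latlon"`` (distances are great-circle), or projected
    ``(x, y)`` meters when ``coord_system == "projected"`` (Euclidean).
    ``cell_spacing`` is the center-to-center distance in meters (3000 for the
    3-km forecast grid).
    """

    cell_centers: np.ndarray
    cell_spacing: float = 3000.0
    coord_system: str = "projected"

    def __post_init__(self) -> None:
        self.cell_centers = np.asarray(self.cell_centers, dtype=float)
        if self.cell_centers.ndim != 2 or self.cell_centers.shape[1] != 2:
            raise ValueError("cell_centers must be an (n, 2) array")
        if self.cell_spacing <= 0:
            raise ValueError("cell_spacing must be positive")
        if self.coord_system not in ("projected", "latlon"):
            raise ValueError("coord_system must be 'projected' or 'latlon'")

    @classmethod
    def regular(
        cls,
        rows: int,
        cols: int,
        spacing: float = 3000.0,
        origin: tuple[float, float] = (0.0, 0.0),
    ) -> "GridSpec":
        """Planar regular grid with centers at ``origin + (i, j) * spacing``."""
        yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        centers = np.column_stack(
            [origin[0] + xx.ravel() * spacing, origin[1] + yy.ravel() * spacing]
        )
        return cls(cell_centers=centers, cell_spacing=spacing, coord_system="projected")


def _haversine_m(lat1: float, lon1: float, lat2: np.ndarray, lon2: np.ndarray) -> np.ndarray:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def select_grid_cell(site: tuple[float, float], grid: GridSpec) -> tuple[int, float]:
    """Return ``(cell_index, distance_m)`` of the grid cell nearest a site.

    ``site`` is ``(lat, lon)`` for a lat/lon grid or projected ``(x, y)``
    meters for a planar grid. A site outside the grid bounding box by more
    than one cell spacing triggers a warning but still returns the nearest
    cell.
    """
    if grid.cell_centers.size == 0:
        raise ValueError("grid has no cells")
    a, b = float(site[0]), float(site[1])
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("site coordinates must be finite")

    if grid.coord_system == "latlon":
        dist = _haversine_m(a, b, grid.cell_centers[:, 0], grid.cell_centers[:, 1])
        # bounding-box margin expressed in degrees of latitude
        margin = grid.cell_spacing / 111_320.0
    else:
        dist = np.hypot(grid.cell_centers[:, 0] - a, grid.cell_centers[:, 1] - b)
        margin = grid.cell_spacing
    lo = grid.cell_centers.min(axis=0) - margin
    hi = grid.cell_centers.max(axis=0) + margin
    if not (lo[0] <= a <= hi[0] and lo[1] <= b <= hi[1]):
        warnings.warn(
            f"site {site} lies outside the grid bounding box by more than one "
            "cell spacing; returning nearest cell anyway",
            stacklevel=2,
        )
    idx = int(np.argmin(dist))
    return idx, float(dist[idx])


def merge_precip(f00_series: pd.DataFrame, f01_precip: pd.Series) -> pd.DataFrame:
    """Attach one-hour-forecast precipitation to the analysis-hour series.

    Only the ``precip_1h`` column is taken from the forecast product; every
    other variable keeps its analysis value. The forecast series may arrive
    unsorted; it is aligned on timestamps. Analysis hours with no matching
    forecast hour raise an error listing the offending hours.
    """
    s = f01_precip.sort_index()
    missing = f00_series.index.difference(s.index)
    if len(missing) > 0:
        shown = ", ".join(str(t) for t in missing[:10])
        raise ValueError(
            f"{len(missing)} analysis hour(s) have no forecast precipitation: {shown}"
        )
    out = f00_series.copy()
    out["precip_1h"] = s.reindex(f00_series.index).to_numpy(dtype=float)
    return out


def fill_missing_hours(
    series: pd.DataFrame, max_backtrack: int = 6
) -> pd.DataFrame:
    """Repair gaps in an hourly series by copying the nearest earlier hour.

    Each missing hour between the first and last timestamp is filled with a
    copy of the closest available earlier hour, walking back at most
    ``max_backtrack`` hours; hours that cannot be filled within that window
    are kept as all-NaN rows flagged ``unfillable`` (they are excluded from
    .sfc output downstream). Filled hours are flagged ``filled_prior_hour``.
    Filling a complete series is a no-op apart from adding the flag column.
    """
    if max_backtrack < 1:
        raise ValueError("max_backtrack must be >= 1")
    df = series.sort_index()
    if df.index.has_duplicates:
        raise ValueError("duplicate timestamps in hourly series")
    if "fill_flag" not in df.columns:
        df = df.assign(fill_flag=FLAG_OBSERVED)
    if df.empty:
        return df

    full = pd.date_range(df.index[0], df.index[-1], freq="h")
    out = df.reindex(full)
    # an hour is usable as a fill source only if present and not itself a
    # previously unfillable placeholder
    usable = set(df.index[df["fill_flag"] != FLAG_UNFILLABLE])
    n_filled = n_unfillable = 0
    for ts in full[~full.isin(df.index)]:
        src = None
        for k in range(1, max_backtrack + 1):
            cand = ts - pd.Timedelta(hours=k)
            if cand in usable:
                src = cand
                break
        if src is None:
            out.loc[ts, "fill_flag"] = FLAG_UNFILLABLE
            n_unfillable += 1
        else:
            out.loc[ts] = df.loc[src]
            out.loc[ts, "fill_flag"] = FLAG_FILLED
            n_filled += 1
    out.index.name = df.index.name
    if n_filled or n_unfillable:
        logger.info(
            "filled %d missing hour(s) from prior hours; %d unfillable",
            n_filled,
            n_unfillable,
        )
    return out
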