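"""Habitat Concentration Area delineation.

A Habitat Concentration Area (HCA) is a contiguous region whose
neighborhood-averaged habitat quality exceeds a threshold derived from
observed home ranges: the adjusted quality raster is averaged over a
home-range-sized moving window, pixels strictly above the threshold are
extracted, and connected components become HCAs.  Region statistics are
computed from the ORIGINAL adjusted quality raster, not the smoothed one.
Oversized regions can be split manually with a polyline so the downstream
least-cost-path analysis produces more than one path across them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .errors import InvalidCutError
from .grids import Grid, focal_mean, grid_stats, label_components

__all__ = ["HCARegion", "delineate", "split_region", "hca_table"]


@dataclass
class HCARegion:
    """One habitat concentration area.

    ``smaller_than_min_range`` flags regions smaller than the smallest
    observed home range — potential "stepping stones" rather than areas that
    could hold a resident animal.
    """

    hca_id: str
    mask: Grid
    area_km2: float
    mean_quality: float
    sd_quality: float
    smaller_than_min_range: bool = False


def _region_from_mask(
    hca_id: str, mask: Grid, quality: Grid, min_range_area_km2: float
) -> HCARegion:
    stats = grid_stats(quality, region=mask)
    return HCARegion(
        hca_id=hca_id,
        mask=mask,
        area_km2=stats["area_km2"],
        mean_quality=stats["mean"],
        sd_quality=stats["sd"],
        smaller_than_min_range=stats["area_km2"] < min_range_area_km2,
    )


def delineate(
    quality_adj: Grid,
    window_area_km2: float,
    threshold: float,
    connectivity: int = 8,
    min_area_km2: float = 0.0,
    min_range_area_km2: float = 0.0,
    window_shape: str = "circle",
) -> list[HCARegion]:
    """Delineate HCAs on an adjusted habitat-quality raster.

    Moving-window mean, strict extraction (focal value > threshold),
    connected-component labeling, and an optional minimum mapping unit.
    Regions are ordered by descending area and assigned ids "1", "2", ...;
    an empty result (nothing above threshold) is returned, not raised.
    """
    smoothed = focal_mean(quality_adj, window_area_km2, shape=window_shape)
    above = smoothed.valid_mask() & (
        np.asarray(smoothed.values, dtype=float) > threshold
    )
    labeled = label_components(quality_adj.like(above), connectivity=connectivity)
    regions: list[HCARegion] = []
    for k in range(1, labeled.region_count + 1):
        mask = labeled.region_mask(k)
        area = float(mask.values.sum() * quality_adj.cell_size**2 / 1e6)
        if area < min_area_km2:
            continue
        regions.append(
            _region_from_mask(str(len(regions) + 1), mask, quality_adj, min_range_area_km2)
        )
    # label_components already orders by size; ids were assigned in that order
    return regions


def split_region(
    region: HCARegion,
    cut: list[tuple[float, float]],
    quality: Grid,
    id_suffixes: tuple[str, str] = ("a", "b"),
    min_range_area_km2: float = 0.0,
    connectivity: int = 8,
) -> tuple[HCARegion, HCARegion]:
    """Split one HCA in two along a polyline in map coordinates.

    Every region pixel is assigned to the left or right side of the polyline
    (sign of the cross product at the nearest point of the line); the cut is
    valid only if both sides are non-empty and each forms a single connected
    part.  Statistics are recomputed for each part from the quality raster;
    ids get the parent id plus a suffix (e.g. "2" -> "2a", "2b").
    """
    line = LineString(cut)
    m = np.asarray(region.mask.values, dtype=bool)
    xs, ys = region.mask.cell_centers()
    rows, cols = np.nonzero(m)
    side = np.zeros(rows.size, dtype=bool)
    coords = np.asarray(line.coords)
    for i, (r, c) in enumerate(zip(rows, cols)):
        p = Point(xs[r, c], ys[r, c])
        t = line.project(p)
        # direction of the segment containing the projected point
        seg_d = np.diff(coords, axis=0)
        seg_len = np.hypot(seg_d[:, 0], seg_d[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        j = int(np.clip(np.searchsorted(cum, t, side="right") - 1, 0, len(seg_d) - 1))
        near = line.interpolate(t)
        cross = seg_d[j, 0] * (p.y - near.y) - seg_d[j, 1] * (p.x - near.x)
        side[i] = cross > 0
    parts = []
    for sel in (side, ~side):
        part = np.zeros_like(m)
        part[rows[sel], cols[sel]] = True
        if not part.any():
            raise InvalidCutError("cut leaves one side empty")
        lab = label_components(region.mask.like(part), connectivity=connectivity)
        if lab.region_count != 1:
            raise InvalidCutError(
                f"cut yields {lab.region_count} connected parts on one side"
            )
        parts.append(region.mask.like(part))
    out = tuple(
        _region_from_mask(region.hca_id + suf, mask, quality, min_range_area_km2)
        for suf, mask in zip(id_suffixes, parts)
    )
    return out  # type: ignore[return-value]


def hca_table(regions: list[HCARegion], min_range_area_km2: float | None = None) -> pd.DataFrame:
    """Tabular HCA summary: id, area, mean/SD quality, small-area flag.

    ``min_range_area_km2`` recomputes the flag when given (strict <);
    otherwise each region's stored flag is reported.
    """
    rows = []
    for r in regions:
        flag = (
            r.area_km2 < min_range_area_km2
            if min_range_area_km2 is not None
            else r.smaller_than_min_range
        )
        rows.append(
            {
                "hca_id": r.hca_id,
                "area_km2": r.area_km2,
                "mean_quality": r.mean_quality,
                "sd_quality": r.sd_quality,
                "smaller_than_min_range": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "hca_id",
            "area_km2",
            "mean_quality",
            "sd_quality",
            "smaller_than_min_range",
        ],
    )
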