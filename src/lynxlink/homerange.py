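"""Minimum-convex-polygon home ranges and the parameters derived from them.

The analysis takes two scalars from the collared animals: the moving-window
area (the mean 95% MCP home-range area, excluding animals without a
localized range) and the habitat-concentration threshold (the lowest mean
habitat value observed inside any animal's home range — the most permissive
quality an animal demonstrably settled for).

The 95% MCP peels the 5% of fixes farthest from the centroid of all fixes
before taking the convex hull, the convention of the standard home-range
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon, mapping

from .errors import DegenerateGeometryError, EmptyRegionError, ParameterError
from .grids import Grid

__all__ = [
    "HomeRange",
    "DerivedParameters",
    "mcp",
    "range_habitat_summary",
    "derive_parameters",
    "home_range_table",
    "reference_home_ranges",
]


@dataclass
class HomeRange:
    """One animal's MCP home range with its habitat-value summary."""

    animal_id: str
    polygon: Polygon
    area_km2: float
    mean_habitat_value: float | None = None
    sd_habitat_value: float | None = None


@dataclass
class DerivedParameters:
    """Pipeline parameters taken from the observed home ranges."""

    window_area_km2: float
    hca_threshold: float
    min_range_area_km2: float
    excluded_for_window: list[str] = field(default_factory=list)
    excluded_for_threshold: list[str] = field(default_factory=list)


def mcp(points: np.ndarray, fraction: float = 0.95, animal_id: str = "") -> HomeRange:
    """Minimum convex polygon of a fraction of an animal's fixes.

    ``points`` is an (n, 2) array of map coordinates in meters.  The
    ``floor((1 - fraction) * n)`` points farthest (Euclidean) from the
    centroid of ALL points are removed; ties at the cutoff remove the
    later-indexed fix.  The hull of the remainder is returned with its area
    in km² (shoelace, via shapely).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be an (n, 2) array")
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    n = pts.shape[0]
    n_remove = int(np.floor((1.0 - fraction) * n))
    if n_remove > 0:
        centroid = pts.mean(axis=0)
        d = np.hypot(*(pts - centroid).T)
        # stable sort ascending on (distance, index); removing from the tail
        # drops the later-indexed fix first among ties
        order = np.lexsort((np.arange(n), d))
        keep = np.sort(order[: n - n_remove])
        pts = pts[keep]
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("fewer than 3 fixes retained for the hull")
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise DegenerateGeometryError("retained fixes are collinear")
    return HomeRange(animal_id=animal_id, polygon=hull, area_km2=hull.area / 1e6)


def range_habitat_summary(
    hr: HomeRange, quality: Grid, require_inside: bool = True
) -> HomeRange:
    """Mean/SD habitat value over pixels whose centers fall inside the polygon.

    Boundary-inclusive.  When ``require_inside`` and any part of the polygon
    leaves the raster extent, the summary is left absent (mirroring the
    exclusion of animals whose ranges extend past the mapped study area).
    """
    xmin, ymin, xmax, ymax = quality.extent
    bx0, by0, bx1, by1 = hr.polygon.bounds
    if require_inside and (bx0 < xmin or by0 < ymin or bx1 > xmax or by1 > ymax):
        hr.mean_habitat_value = None
        hr.sd_habitat_value = None
        return hr
    xs, ys = quality.cell_centers()
    # restrict the point-in-polygon test to the polygon's bounding box
    box = (xs >= bx0) & (xs <= bx1) & (ys >= by0) & (ys <= by1)
    inside = np.zeros(quality.shape, dtype=bool)
    if box.any():
        cand = np.flatnonzero(box.ravel())
        pts = shapely.points(xs.ravel()[cand], ys.ravel()[cand])
        cov = shapely.covers(hr.polygon, pts)  # boundary-inclusive
        inside.ravel()[cand[cov]] = True
    inside &= quality.valid_mask()
    vals = np.asarray(quality.values, dtype=float)[inside]
    if vals.size == 0:
        raise EmptyRegionError(f"no pixel centers inside home range {hr.animal_id!r}")
    hr.mean_habitat_value = float(np.mean(vals))
    hr.sd_habitat_value = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return hr


def derive_parameters(
    ranges: list[HomeRange],
    window_exclusions: list[str] | None = None,
    threshold_exclusions: list[str] | None = None,
) -> DerivedParameters:
    """Moving-window area and HCA threshold from a set of home ranges.

    window area = mean MCP area over ranges not excluded for the window;
    threshold = minimum mean habitat value over ranges that have one and are
    not excluded; the smallest area among window-eligible ranges is kept for
    flagging habitat patches smaller than any observed home range.
    """
    wex = list(window_exclusions or [])
    tex = list(threshold_exclusions or [])
    areas = [r.area_km2 for r in ranges if r.animal_id not in wex]
    means = [
        r.mean_habitat_value
        for r in ranges
        if r.animal_id not in tex and r.mean_habitat_value is not None
    ]
    if not areas or not means:
        raise ParameterError("no eligible home ranges for parameter derivation")
    return DerivedParameters(
        window_area_km2=float(np.mean(areas)),
        hca_threshold=float(np.min(means)),
        min_range_area_km2=float(np.min(areas)),
        excluded_for_window=wex,
        excluded_for_threshold=tex,
    )


def home_range_table(ranges: list[HomeRange]) -> pd.DataFrame:
    """Per-animal summary table (area, mean and SD habitat value)."""
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in ranges],
            "area_km2": [r.area_km2 for r in ranges],
            "mean_habitat_value": [r.mean_habitat_value for r in ranges],
            "sd_habitat_value": [r.sd_habitat_value for r in ranges],
        }
    )


def ranges_to_geojson(ranges: list[HomeRange]) -> dict:
    """GeoJSON FeatureCollection of home-range polygons."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {
                    "animal_id": r.animal_id,
                    "area_km2": r.area_km2,
                    "mean_habitat_value": r.mean_habitat_value,
                    "sd_habitat_value": r.sd_habitat_value,
                },
                "geometry": mapping(r.polygon),
            }
            for r in ranges
        ],
    }


def reference_home_ranges() -> pd.DataFrame:
    """Published MCP home-range estimates for GPS-collared Canada lynx in the
    North Cascades (area, mean and SD of habitat value per animal).

    Male 339 never localized (excluded from the window-area mean); Male 336's
    range crossed the mapped boundary, so his habitat summary is absent.
    """
    with resources.files("lynxlink.data").joinpath("lynx_home_ranges.csv").open() as fh:
        return pd.read_csv(fh)


def derive_reference_parameters() -> DerivedParameters:
    """Derived parameters from the published North Cascades home ranges:
    mean area excluding the non-localized male, and the lowest per-animal
    mean habitat value."""
    df = reference_home_ranges()
    ranges = [
        HomeRange(
            animal_id=row.animal_id,
            polygon=Polygon(),  # geometry not published; areas are
            area_km2=float(row.area_km2),
            mean_habitat_value=None
            if pd.isna(row.mean_habitat_value)
            else float(row.mean_habitat_value),
            sd_habitat_value=None
            if pd.isna(row.sd_habitat_value)
            else float(row.sd_habitat_value),
        )
        for row in df.itertuples()
    ]
    return derive_parameters(ranges, window_exclusions=["Male 339"])
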