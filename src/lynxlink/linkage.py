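"""Least-cost-path linkages between habitat concentration areas.

Two HCAs are adjacent when their cost-allocation zones (the pixels each is
nearest to, in cost-weighted terms) share an 8-connected border.  For each
adjacent pair the joint surface cwd_A + cwd_B is minimized at a saddle
pixel; tracing backlinks from the saddle into both HCAs yields the
pixel-wide least-cost path.  Subtracting the saddle value from the joint
surface gives the normalized linkage corridor: the least-cost path sits at
exactly zero and surrounding pixels price increasingly costly alternative
routes.  Per-pair statistics (cost-weighted distance, edge-to-edge
Euclidean distance, geometric path length, and their ratios) summarize
linkage quality — a cost/length ratio near 1 means the path crosses
essentially no resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .costdist import CostSurface, MosaicSurface, trace_backlinks
from .errors import ParameterError
from .grids import Grid
from .hca import HCARegion

__all__ = [
    "LinkageRecord",
    "adjacency",
    "least_cost_path",
    "corridor",
    "linkage_stats",
    "linkage_table",
]


@dataclass
class LinkageRecord:
    """One adjacent HCA pair's least-cost path and quality statistics."""

    pair: tuple[str, str]
    lcp_cells: list[tuple[int, int]] = field(default_factory=list)
    cwd_km: float = math.nan  # resistance-weighted km at the saddle
    euclid_km: float = math.nan  # nearest boundary-pixel centers, straight line
    path_km: float = math.nan  # geometric length of the traced path
    ratio_cwd_euclid: float = math.nan
    ratio_cwd_path: float = math.nan
    reachable: bool = True
    within_dispersal: bool | None = None


def adjacency(
    mosaic: MosaicSurface, hcas: list[HCARegion], all_pairs: bool = False
) -> list[tuple[str, str]]:
    """Adjacent HCA id pairs: allocation zones sharing an 8-connected border.

    Returns sorted, irreflexive pairs (a, b) with a < b by position in the
    mosaic's source order.  ``all_pairs`` short-circuits allocation adjacency
    for small landscapes.
    """
    ids = mosaic.source_ids
    if len(ids) < 2:
        return []
    if all_pairs:
        return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    alloc = np.asarray(mosaic.nearest_hca.values, dtype=int)
    pairs: set[tuple[int, int]] = set()
    # compare each pixel with its E, SE, S, SW neighbors (covers all 8 dirs)
    n_rows, n_cols = alloc.shape
    for dr, dc in [(0, 1), (1, 1), (1, 0), (1, -1)]:
        r0, c0 = max(0, -dr), max(0, -dc)
        r1, c1 = n_rows - max(0, dr), n_cols - max(0, dc)
        a = alloc[r0:r1, c0:c1]
        b = alloc[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        differ = (a != b) & (a > 0) & (b > 0)
        for i, j in zip(a[differ].ravel(), b[differ].ravel()):
            pairs.add((min(i, j) - 1, max(i, j) - 1))
    return sorted((ids[i], ids[j]) for i, j in pairs)


def least_cost_path(surface_a: CostSurface, surface_b: CostSurface) -> LinkageRecord:
    """Pixel-wide least-cost path between two HCAs from their cost surfaces.

    The saddle pixel minimizes cwd_A + cwd_B (ties resolve row-major first);
    the path is the backlink trace into A, reversed, concatenated with the
    trace into B.  An unreachable pair is returned flagged, not raised.
    """
    if not surface_a.cwd.same_georeference(surface_b.cwd):
        raise ParameterError("cost surfaces on different grids")
    joint = np.asarray(surface_a.cwd.values, dtype=float) + np.asarray(
        surface_b.cwd.values, dtype=float
    )
    rec = LinkageRecord(pair=(surface_a.source_id, surface_b.source_id))
    if not np.isfinite(joint).any():
        rec.reachable = False
        return rec
    flat = np.where(np.isfinite(joint), joint, np.inf)
    saddle = int(np.argmin(flat.ravel()))  # first minimum = row-major tie-break
    r, c = divmod(saddle, joint.shape[1])
    to_a = trace_backlinks(surface_a, r, c)
    to_b = trace_backlinks(surface_b, r, c)
    path = list(reversed(to_a)) + to_b[1:]
    seen = set()
    deduped = []
    for cell in path:
        if cell not in seen:
            seen.add(cell)
            deduped.append(cell)
    rec.lcp_cells = deduped
    rec.cwd_km = float(joint[r, c]) / 1000.0
    return rec


def corridor(
    surface_a: CostSurface,
    surface_b: CostSurface,
    lcp_cwd_km: float,
    truncation_cwd_km: float | None = None,
) -> Grid:
    """Normalized linkage corridor: cwd_A + cwd_B minus the saddle value.

    The least-cost path is valued exactly 0 and every other pixel shows the
    extra cost of routing through it.  Pixels above ``truncation_cwd_km``
    (resistance-weighted km), when given, are set to nodata to bound the
    mapped linkage.
    """
    joint = np.asarray(surface_a.cwd.values, dtype=float) + np.asarray(
        surface_b.cwd.values, dtype=float
    )
    vals = joint - lcp_cwd_km * 1000.0
    vals = np.maximum(vals, 0.0)  # guard float round-off at the saddle
    nodata = -1.0
    out = np.where(np.isfinite(vals), vals, nodata)
    if truncation_cwd_km is not None:
        out = np.where(out <= truncation_cwd_km * 1000.0, out, nodata)
    return surface_a.cwd.like(out, nodata=nodata)


def _boundary(mask: np.ndarray) -> np.ndarray:
    inner = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    return mask & ~inner


def linkage_stats(
    record: LinkageRecord,
    hca_a: HCARegion,
    hca_b: HCARegion,
    max_dispersal_km: float | None = None,
) -> LinkageRecord:
    """Complete a linkage record with distances and quality ratios.

    euclid_km: minimum center-to-center distance between boundary pixels of
    the two HCAs; path_km: sum of step lengths along the traced path;
    ratio_cwd_path is the mean resistance faced along the path (bounded by
    the path's min and max resistance).
    """
    if not record.lcp_cells:
        raise ParameterError("linkage record has an empty path")
    cs = hca_a.mask.cell_size
    ba = np.argwhere(_boundary(np.asarray(hca_a.mask.values, dtype=bool)))
    bb = np.argwhere(_boundary(np.asarray(hca_b.mask.values, dtype=bool)))
    tree = cKDTree(ba * cs)
    d_min, _ = tree.query(bb * cs, k=1)
    record.euclid_km = float(d_min.min()) / 1000.0
    cells = record.lcp_cells
    length_m = 0.0
    for (r0, c0), (r1, c1) in zip(cells[:-1], cells[1:]):
        length_m += cs * (math.sqrt(2.0) if abs(r0 - r1) + abs(c0 - c1) == 2 else 1.0)
    record.path_km = length_m / 1000.0
    if record.euclid_km > 0:
        record.ratio_cwd_euclid = record.cwd_km / record.euclid_km
    if record.path_km > 0:
        record.ratio_cwd_path = record.cwd_km / record.path_km
    if max_dispersal_km is not None:
        record.within_dispersal = (
            record.path_km <= max_dispersal_km and record.cwd_km <= max_dispersal_km
        )
    return record


def linkage_table(records: list[LinkageRecord]) -> pd.DataFrame:
    """Linkage-quality table, sorted ascending by cost/length ratio
    (ratios nearer 1 indicate higher-quality paths)."""
    rows = [
        {
            "pair": f"{r.pair[0]}-{r.pair[1]}",
            "cwd_km": r.cwd_km,
            "euclid_km": r.euclid_km,
            "path_km": r.path_km,
            "ratio_cwd_euclid": r.ratio_cwd_euclid,
            "ratio_cwd_path": r.ratio_cwd_path,
            "within_dispersal": r.within_dispersal,
        }
        for r in records
        if r.reachable
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "pair",
            "cwd_km",
            "euclid_km",
            "path_km",
            "ratio_cwd_euclid",
            "ratio_cwd_path",
            "within_dispersal",
        ],
    )
    if len(df):
        df = df.sort_values("ratio_cwd_path", kind="stable").reset_index(drop=True)
    return df
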