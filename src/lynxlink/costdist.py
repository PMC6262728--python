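"""Cost-weighted distance over a resistance surface.

Movement is modeled on the 8-connected pixel graph.  Stepping between two
pixels costs the mean of their resistance values times the pixel width
(times sqrt(2) for a diagonal step), so with unit resistance the accumulated
cost is plain geometric distance and higher-resistance pixels price each
meter crossed proportionally.  The accumulated cost from every pixel to the
nearest source (habitat concentration area) pixel is computed exactly with
Dijkstra's algorithm; ties are broken by lowest cost then row-major pixel
order so backlinks — and the least-cost paths traced from them — are
bit-reproducible.  Nodata cells are impassable.

Accumulated cost is in resistance-weighted meters; reports divide by 1,000
and call the unit a resistance-weighted kilometer (a weighted, not
geometric, kilometer).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .grids import Grid

__all__ = [
    "CostSurface",
    "MosaicSurface",
    "DIRECTIONS",
    "edge_cost",
    "cost_weighted_distance",
    "mosaic_min",
    "trace_backlinks",
]

# Backlink direction codes 1..8: the offset from a pixel TO ITS PREDECESSOR.
# 0 marks a source pixel.
DIRECTIONS: list[tuple[int, int]] = [
    (-1, 0),   # 1 N
    (-1, 1),   # 2 NE
    (0, 1),    # 3 E
    (1, 1),    # 4 SE
    (1, 0),    # 5 S
    (1, -1),   # 6 SW
    (0, -1),   # 7 W
    (-1, -1),  # 8 NW
]

_SQRT2 = math.sqrt(2.0)


@dataclass
class CostSurface:
    """Accumulated cost-weighted distance from one source (HCA) with backlinks."""

    source_id: str
    cwd: Grid  # resistance-weighted meters; +inf where unreachable
    backlink: Grid  # int codes, 0 = source, -1 = unreachable/nodata


@dataclass
class MosaicSurface:
    """Per-pixel minimum over per-HCA cost surfaces, with the arg-min allocation."""

    cwd_min: Grid
    nearest_hca: Grid  # integer index into the surface list order (1-based); 0 = none
    source_ids: list[str]


def edge_cost(r_a: float, r_b: float, cell_size: float, diagonal: bool = False) -> float:
    """Cost of one step between adjacent pixels with resistances r_a, r_b."""
    if r_a < 0 or r_b < 0:
        raise ParameterError("resistance must be non-negative")
    step = cell_size * (_SQRT2 if diagonal else 1.0)
    return 0.5 * (r_a + r_b) * step


def cost_weighted_distance(resistance: Grid, source: Grid, source_id: str = "") -> CostSurface:
    """Exact multi-source Dijkstra over the resistance-weighted pixel graph.

    ``source`` is a boolean mask of source pixels (cost 0); all non-nodata
    pixels reachable through non-nodata cells get a finite accumulated cost.
    Following backlinks from any reachable pixel walks a least-cost route
    back to a source with strictly decreasing cost.
    """
    if not resistance.same_georeference(source):
        raise ParameterError("source mask georeferencing differs from resistance")
    src = np.asarray(source.values, dtype=bool)
    if not src.any():
        raise ParameterError("empty source mask")
    n_rows, n_cols = resistance.shape
    cs = resistance.cell_size
    passable = resistance.valid_mask()
    res = np.asarray(resistance.values, dtype=float)

    # pad with an impassable border so neighbor arithmetic needs no bounds checks
    pr, pc = n_rows + 2, n_cols + 2
    half = np.full((pr, pc), np.inf)
    half[1:-1, 1:-1] = np.where(passable, 0.5 * res * cs, np.inf)
    half_flat = half.ravel()

    n = pr * pc
    inf = math.inf
    # plain Python containers: scalar indexing in the hot loop is several
    # times faster than numpy element access
    half_list = half_flat.tolist()
    dist = [inf] * n
    back = [-1] * n
    done = bytearray(n)

    # pair each neighbor offset with its diagonal flag and the predecessor
    # code (the reverse of the offset used to reach the neighbor)
    steps = [
        (dr * pc + dc, _SQRT2 if abs(dr) + abs(dc) == 2 else 1.0,
         DIRECTIONS.index((-dr, -dc)) + 1)
        for dr, dc in DIRECTIONS
    ]

    heap: list[tuple[float, int]] = []
    src_pad = np.zeros((pr, pc), dtype=bool)
    src_pad[1:-1, 1:-1] = src & passable
    for idx in np.flatnonzero(src_pad.ravel()):
        i = int(idx)
        dist[i] = 0.0
        back[i] = 0
        heap.append((0.0, i))
    heapq.heapify(heap)

    push = heapq.heappush
    pop = heapq.heappop
    while heap:
        d, u = pop(heap)
        if done[u]:
            continue
        done[u] = 1
        hu = half_list[u]
        for off, fac, code in steps:
            v = u + off
            if done[v]:
                continue
            hv = half_list[v]
            if hv == inf:
                continue
            nd = d + (hu + hv) * fac
            if nd < dist[v]:
                dist[v] = nd
                back[v] = code
                push(heap, (nd, v))

    cwd = np.array(dist).reshape(pr, pc)[1:-1, 1:-1].copy()
    backlink = np.array(back).reshape(pr, pc)[1:-1, 1:-1]
    return CostSurface(
        source_id=source_id,
        cwd=resistance.like(cwd, nodata=-1.0),
        backlink=resistance.like(backlink, nodata=-1),
    )


def trace_backlinks(surface: CostSurface, row: int, col: int) -> list[tuple[int, int]]:
    """Walk backlinks from a pixel to the source; returns the pixel list
    starting at (row, col) and ending on a source pixel."""
    back = np.asarray(surface.backlink.values, dtype=int)
    path = [(row, col)]
    r, c = row, col
    limit = back.size + 1
    while back[r, c] != 0:
        code = back[r, c]
        if code < 1 or code > 8:
            raise ParameterError(f"pixel ({r}, {c}) is unreachable from the source")
        dr, dc = DIRECTIONS[code - 1]
        r, c = r + dr, c + dc
        path.append((r, c))
        limit -= 1
        if limit == 0:  # pragma: no cover - cycle guard
            raise RuntimeError("backlink cycle detected")
    return path


def mosaic_min(surfaces: list[CostSurface]) -> MosaicSurface:
    """Per-pixel minimum cost-weighted distance across HCAs.

    ``nearest_hca`` holds the 1-based index (in input order) of the surface
    attaining the minimum; ties go to the earlier surface.  Surfaces should
    be passed in ascending HCA-id order so ties resolve to the lower id.
    """
    if not surfaces:
        raise ParameterError("need at least one cost surface")
    ref = surfaces[0].cwd
    for s in surfaces[1:]:
        if not ref.same_georeference(s.cwd):
            raise ParameterError("cost surfaces do not share georeferencing")
    stack = np.stack([np.asarray(s.cwd.values, dtype=float) for s in surfaces])
    cwd_min = stack.min(axis=0)
    arg = stack.argmin(axis=0) + 1  # argmin takes the first minimum: earlier surface
    arg = np.where(np.isfinite(cwd_min), arg, 0)
    return MosaicSurface(
        cwd_min=ref.like(cwd_min, nodata=-1.0),
        nearest_hca=ref.like(arg, nodata=0),
        source_ids=[s.source_id for s in surfaces],
    )
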