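"""Synthetic landscapes and telemetry with the structure the analysis assumes.

The generator emulates the inputs the connectivity analysis consumes, so the
whole pipeline is testable without proprietary GIS layers or collar data:

* a spatially autocorrelated core-habitat use-probability field in [0, 1]
  (white noise smoothed to a correlation length, rank-rescaled), with
  planted high-quality plateau patches fragmented by low-quality valleys;
* a matrix-habitat (travel) use-probability companion field — monotone in
  the core field but flatter and noisier, reflecting that traveling animals
  tolerate poorer habitat than residents;
* burn scars that suppress use probability (strongly for core, mildly for
  matrix) with unburned "skips" reverted inside the perimeter;
* highways routed through low-probability valleys, developed parcels
  clustered along them, and a cover-class layer including the four classes
  the expert table adjusts;
* known-truth fixtures: the planted patch footprints and a planted
  low-resistance travel channel between the two closest patches, for
  recovery tests of the downstream delineation and path extraction.

Telemetry is drawn per animal inside a home-range-sized disc anchored on a
planted patch, with fixes biased toward high-probability cells.  A single
integer seed drives every stochastic draw through a fixed splitting scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point

from .errors import GenerationError, ParameterError
from .grids import Grid, LabeledRegions, read_grid, write_grid
from .surfaces import COVER_CODES

__all__ = [
    "LandscapeBundle",
    "generate_landscape",
    "generate_locations",
    "write_bundle",
    "read_bundle",
]

# Fixed substream order for the seed-splitting scheme; reordering would
# silently change every generated landscape.
_STREAMS = ("base", "patches", "matrix", "highways", "burns", "developed", "cover", "locations")


@dataclass
class LandscapeBundle:
    """All layers of one synthetic landscape plus its known truth."""

    core_probability: Grid
    matrix_probability: Grid
    cover: Grid
    highways: Grid
    developed: Grid
    burn: Grid
    truth_patches: LabeledRegions
    truth_corridor: Grid
    matrix_domain: Grid  # where the matrix model applies (core use < 0.45)
    corridor_patch_ids: tuple[int, int]
    patch_centers_m: list[tuple[float, float]]
    patch_radius_m: float
    seed: int


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _smoothed_field(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    """Gaussian-smoothed white noise, rank-rescaled to [0, 1]."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")
    ranks = np.argsort(np.argsort(smooth.ravel())).reshape(shape)
    return ranks / max(ranks.size - 1, 1)


def _line_distance(template: Grid, line: LineString) -> np.ndarray:
    """Distance (m) from each cell center to a polyline, via an exact EDT on
    the rasterized line (cheap and adequate at cell resolution)."""
    xs, ys = template.cell_centers()
    n = max(int(line.length / (template.cell_size * 0.5)), 2)
    pts = [line.interpolate(i / n, normalized=True) for i in range(n + 1)]
    mask = np.zeros(template.shape, dtype=bool)
    for p in pts:
        r, c = template.index_of(p.x, p.y)
        if 0 <= r < template.n_rows and 0 <= c < template.n_cols:
            mask[r, c] = True
    if not mask.any():
        return np.full(template.shape, np.inf)
    return ndimage.distance_transform_edt(~mask, sampling=template.cell_size)


def generate_landscape(
    n_rows: int = 256,
    n_cols: int = 256,
    cell_size: float = 250.0,
    correlation_length: float = 2000.0,
    n_patches: int = 5,
    n_burns: int = 3,
    skip_fraction: float = 0.3,
    seed: int = 0,
    patch_radius_m: float = 6000.0,
) -> LandscapeBundle:
    """Generate one synthetic landscape bundle; deterministic for a fixed seed.

    Patches are planted as flat-topped bumps on a jittered lattice whose
    spacing keeps neighborhood-averaged quality between patches below any
    plausible concentration threshold, so each planted patch maps to its own
    habitat concentration area downstream.
    """
    if n_rows < 32 or n_cols < 32:
        raise ParameterError("landscape must be at least 32 x 32 cells")
    if correlation_length < cell_size:
        raise ParameterError("correlation_length must be >= cell_size")
    if not 0.0 <= skip_fraction <= 1.0:
        raise ParameterError("skip_fraction must be in [0, 1]")
    rngs = _rngs(seed)
    shape = (n_rows, n_cols)
    template = Grid(np.zeros(shape), cell_size=cell_size, origin_x=0.0,
                    origin_y=n_rows * cell_size, crs_label="synthetic-local")
    xs, ys = template.cell_centers()
    width_m, height_m = n_cols * cell_size, n_rows * cell_size

    # --- background core field -------------------------------------------
    base = _smoothed_field(rngs["base"], shape, correlation_length / cell_size)
    core = 0.05 + 0.35 * base

    # --- planted patches on a jittered lattice ---------------------------
    spacing = 3.5 * patch_radius_m
    margin = patch_radius_m + 2.0 * cell_size
    cand_x = np.arange(margin, width_m - margin + 1e-6, spacing)
    cand_y = np.arange(margin, height_m - margin + 1e-6, spacing)
    candidates = [(x, y) for y in cand_y for x in cand_x]
    if len(candidates) < n_patches:
        raise GenerationError(
            f"cannot pack {n_patches} patches of radius {patch_radius_m} m "
            f"into a {width_m / 1000:.0f} x {height_m / 1000:.0f} km landscape"
        )
    prng = rngs["patches"]
    chosen = prng.choice(len(candidates), size=n_patches, replace=False)
    centers = []
    for idx in chosen:
        cx, cy = candidates[idx]
        jitter = 0.15 * spacing
        centers.append(
            (cx + prng.uniform(-jitter, jitter), cy + prng.uniform(-jitter, jitter))
        )
    patch_labels = np.zeros(shape, dtype=int)
    for k, (cx, cy) in enumerate(centers, start=1):
        r2 = ((xs - cx) ** 2 + (ys - cy) ** 2) / patch_radius_m**2
        bump = np.exp(-(r2**2))  # flat-topped (super-Gaussian) profile
        core = core + (0.95 - core) * bump
        patch_labels[bump > 0.5] = k

    # --- highways through valley lanes between lattice rows/cols ---------
    hrng = rngs["highways"]
    lanes_y = [(a + b) / 2 for a, b in zip(cand_y[:-1], cand_y[1:])] or [height_m / 2]
    lanes_x = [(a + b) / 2 for a, b in zip(cand_x[:-1], cand_x[1:])] or [width_m / 2]
    highway_lines = []
    lane_y = float(lanes_y[hrng.integers(len(lanes_y))])
    t = np.linspace(0.0, width_m, 9)
    wiggle = hrng.uniform(-600.0, 600.0, size=t.size)
    highway_lines.append(LineString(np.column_stack([t, lane_y + wiggle])))
    lane_x = float(lanes_x[hrng.integers(len(lanes_x))])
    t = np.linspace(0.0, height_m, 9)
    wiggle = hrng.uniform(-600.0, 600.0, size=t.size)
    highway_lines.append(LineString(np.column_stack([lane_x + wiggle, t])))
    d_hwy = np.minimum.reduce([_line_distance(template, ln) for ln in highway_lines])
    highways = d_hwy <= cell_size * 0.75
    # carve a low-probability valley around each highway
    core = core * (1.0 - 0.65 * np.exp(-((d_hwy / 1500.0) ** 2)))

    # --- matrix companion field ------------------------------------------
    noise2 = _smoothed_field(rngs["matrix"], shape, correlation_length / cell_size)
    matrix = np.clip(0.30 + 0.45 * core + 0.18 * (noise2 - 0.5), 0.02, 0.98)

    # --- planted travel channel between the two closest patches ----------
    cen = np.asarray(centers)
    best, pair = np.inf, (0, 1)
    for i in range(len(cen)):
        for j in range(i + 1, len(cen)):
            d = float(np.hypot(*(cen[i] - cen[j])))
            if d < best:
                best, pair = d, (i, j)
    a, b = cen[pair[0]], cen[pair[1]]
    mid = (a + b) / 2.0
    seg = b - a
    perp = np.array([-seg[1], seg[0]]) / (np.hypot(*seg) + 1e-12)
    bend = mid + perp * 0.15 * best * (1 if rngs["patches"].random() < 0.5 else -1)
    channel_line = LineString([tuple(a), tuple(bend), tuple(b)])
    d_channel = _line_distance(template, channel_line)
    truth_corridor = d_channel <= 1.5 * cell_size

    # --- burns (kept off patches and the planted channel) ----------------
    brng = rngs["burns"]
    burn_mask = np.zeros(shape, dtype=bool)
    pre_core, pre_matrix = core.copy(), matrix.copy()
    for _ in range(n_burns):
        for _attempt in range(50):
            rb = brng.uniform(3000.0, 6000.0)
            cx = brng.uniform(margin, width_m - margin)
            cy = brng.uniform(margin, height_m - margin)
            d_pat = np.min(np.hypot(cen[:, 0] - cx, cen[:, 1] - cy))
            p = channel_line.distance(Point(cx, cy))
            if d_pat > patch_radius_m + rb + 1000.0 and p > rb + 1000.0:
                break
        else:
            continue  # no room for this burn; skip it
        theta = np.arctan2(ys - cy, xs - cx)
        phi, psi = brng.uniform(0, 2 * np.pi, size=2)
        r_edge = rb * (1.0 + 0.25 * np.sin(3 * theta + phi) + 0.15 * np.sin(5 * theta + psi))
        burn_mask |= np.hypot(xs - cx, ys - cy) <= r_edge
    core = np.where(burn_mask, core * 0.2, core)
    matrix = np.where(burn_mask, matrix * 0.6, matrix)
    # fire skips: revert a fraction of interior pixels and open mask holes
    interior = ndimage.binary_erosion(burn_mask, np.ones((3, 3), dtype=bool))
    if skip_fraction > 0 and interior.any():
        skips = interior & (brng.random(shape) < skip_fraction)
        core = np.where(skips, pre_core, core)
        matrix = np.where(skips, pre_matrix, matrix)
        burn_mask &= ~skips

    # plant the channel after burns so nothing overwrites it
    matrix = np.where(truth_corridor, np.maximum(matrix, 0.92), matrix)

    # --- developed parcels clustered along highways -----------------------
    drng = rngs["developed"]
    developed = np.zeros(shape, dtype=bool)
    for ln in highway_lines:
        n_par = max(int(ln.length / 3000.0), 1)
        for i in range(n_par):
            if drng.random() > 0.4:
                continue
            p = ln.interpolate(drng.random(), normalized=True)
            r0, c0 = template.index_of(p.x, p.y)
            dr, dc = drng.integers(-3, 4, size=2)
            r0, c0 = r0 + dr, c0 + dc
            if 1 <= r0 < n_rows - 1 and 1 <= c0 < n_cols - 1:
                developed[r0 : r0 + 2, c0 : c0 + 2] = True
    developed &= d_channel > 2.5 * cell_size  # keep the truth channel clean
    core = np.where(developed, np.minimum(core, 0.05), core)

    # --- cover classes ----------------------------------------------------
    cover = np.full(shape, COVER_CODES["open"], dtype=int)
    cover[core >= 0.2] = COVER_CODES["dry_forest"]
    cover[core >= 0.4] = COVER_CODES["mixed_forest"]
    cover[core >= 0.6] = COVER_CODES["subboreal_forest"]
    west = xs < 0.06 * width_m
    cover[west & (core >= 0.45)] = COVER_CODES["west_side_subboreal_forest"]
    cover[west & (core < 0.45)] = COVER_CODES["west_side_wet_forest"]
    crng = rngs["cover"]
    # one lake in a low-quality area away from patches and the channel
    for _attempt in range(50):
        lx = crng.uniform(margin, width_m - margin)
        ly = crng.uniform(margin, height_m - margin)
        rl = crng.uniform(1500.0, 2500.0)
        d_pat = np.min(np.hypot(cen[:, 0] - lx, cen[:, 1] - ly))
        if d_pat > patch_radius_m + rl + 1000.0 and channel_line.distance(Point(lx, ly)) > rl + 1000.0:
            lake = np.hypot(xs - lx, ys - ly) <= rl
            cover[lake] = COVER_CODES["water"]
            core = np.where(lake, np.minimum(core, 0.03), core)
            matrix = np.where(lake, np.minimum(matrix, 0.1), matrix)
            break
    agri = (d_hwy < 1200.0) & (base < 0.35) & (d_channel > 2.5 * cell_size)
    agri &= cover != COVER_CODES["water"]
    cover[agri] = COVER_CODES["agriculture"]

    core = np.clip(core, 0.0, 1.0)
    matrix = np.clip(matrix, 0.0, 1.0)

    g = template.like
    labels_grid = Grid(patch_labels, cell_size=cell_size, origin_x=template.origin_x,
                       origin_y=template.origin_y, nodata=0, crs_label=template.crs_label)
    return LandscapeBundle(
        core_probability=g(core),
        matrix_probability=g(matrix),
        cover=g(cover),
        highways=g(highways),
        developed=g(developed),
        burn=g(burn_mask),
        truth_patches=LabeledRegions(labels_grid, int(patch_labels.max())),
        truth_corridor=g(truth_corridor),
        matrix_domain=g(core < 0.45),
        corridor_patch_ids=(pair[0] + 1, pair[1] + 1),
        patch_centers_m=[tuple(c) for c in centers],
        patch_radius_m=patch_radius_m,
        seed=seed,
    )


def generate_locations(
    bundle: LandscapeBundle,
    n_animals: int = 8,
    fixes_per_animal: int = 200,
    home_range_area_km2: float = 88.0,
    selection_strength: float = 2.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-animal telemetry fixes inside home-range discs anchored on patches.

    Each animal's disc (area ``home_range_area_km2``) is centered at a random
    point within half a patch radius of a planted patch center; fixes are
    i.i.d. draws within the disc accepted with probability proportional to
    core use probability raised to ``selection_strength`` (0 = uniform).
    Returns a DataFrame with columns animal_id, x, y, t.
    """
    if n_animals < 1:
        raise ParameterError("need at least one animal")
    if fixes_per_animal < 6:
        raise ParameterError("need at least 6 fixes per animal")
    if selection_strength < 0:
        raise ParameterError("selection_strength must be >= 0")
    rng = (
        _rngs(bundle.seed)["locations"]
        if seed is None
        else np.random.default_rng(np.random.SeedSequence(seed))
    )
    grid = bundle.core_probability
    xmin, ymin, xmax, ymax = grid.extent
    r_m = float(np.sqrt(home_range_area_km2 * 1e6 / np.pi))
    if 2 * r_m > min(xmax - xmin, ymax - ymin):
        raise ParameterError("home-range disc does not fit in the landscape")
    core = np.asarray(grid.values, dtype=float)
    records = []
    for i in range(n_animals):
        patch = int(rng.integers(len(bundle.patch_centers_m)))
        px, py = bundle.patch_centers_m[patch]
        # anchor uniformly within the patch footprint (clipped so the disc
        # stays inside the landscape): ranges straddle the patch edge, so
        # polygon-mean habitat values sit well below patch-core quality,
        # as real home ranges spanning core and matrix habitat do
        ang = rng.uniform(0, 2 * np.pi)
        rad = bundle.patch_radius_m * np.sqrt(rng.random())
        cx = float(np.clip(px + rad * np.cos(ang), xmin + r_m, xmax - r_m))
        cy = float(np.clip(py + rad * np.sin(ang), ymin + r_m, ymax - r_m))
        xs_list: list[float] = []
        ys_list: list[float] = []
        while len(xs_list) < fixes_per_animal:
            m = 4 * (fixes_per_animal - len(xs_list)) + 16
            ang_s = rng.uniform(0, 2 * np.pi, size=m)
            rad_s = r_m * np.sqrt(rng.random(size=m))
            x = cx + rad_s * np.cos(ang_s)
            y = cy + rad_s * np.sin(ang_s)
            if selection_strength > 0:
                rows = np.clip(((grid.origin_y - y) / grid.cell_size).astype(int), 0, grid.n_rows - 1)
                cols = np.clip(((x - grid.origin_x) / grid.cell_size).astype(int), 0, grid.n_cols - 1)
                p = core[rows, cols] ** selection_strength
                accept = rng.random(m) * (0.95**selection_strength) < p
            else:
                accept = np.ones(m, dtype=bool)
            xs_list.extend(x[accept].tolist())
            ys_list.extend(y[accept].tolist())
        for t, (x, y) in enumerate(zip(xs_list[:fixes_per_animal], ys_list[:fixes_per_animal])):
            records.append({"animal_id": f"animal_{i + 1:02d}", "x": x, "y": y, "t": t})
    return pd.DataFrame(records, columns=["animal_id", "x", "y", "t"])


# ----------------------------------------------------------------------
# Bundle I/O
# ----------------------------------------------------------------------

_LAYERS = (
    "core_probability",
    "matrix_probability",
    "cover",
    "highways",
    "developed",
    "burn",
    "truth_corridor",
    "matrix_domain",
)


def write_bundle(bundle: LandscapeBundle, outdir, dialect: str = "ascii_grid") -> None:
    """Write every layer plus a JSON manifest of generation parameters."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "asc" if dialect == "ascii_grid" else "tif"
    for name in _LAYERS:
        grid: Grid = getattr(bundle, name)
        vals = grid.values
        if vals.dtype == bool:
            grid = grid.like(vals.astype(float), nodata=-1.0)
        write_grid(grid, out / f"{name}.{ext}", dialect=dialect)
    write_grid(
        bundle.truth_patches.labels.like(
            bundle.truth_patches.labels.values.astype(float), nodata=-1.0
        ),
        out / f"truth_patches.{ext}",
        dialect=dialect,
    )
    manifest = {
        "seed": bundle.seed,
        "corridor_patch_ids": list(bundle.corridor_patch_ids),
        "patch_centers_m": [list(c) for c in bundle.patch_centers_m],
        "patch_radius_m": bundle.patch_radius_m,
        "region_count": bundle.truth_patches.region_count,
        "dialect": dialect,
    }
    (out / "bundle.json").write_text(json.dumps(manifest, indent=2))


def read_bundle(indir) -> LandscapeBundle:
    """Read a bundle written by :func:`write_bundle`."""
    ind = Path(indir)
    manifest = json.loads((ind / "bundle.json").read_text())
    dialect = manifest.get("dialect", "ascii_grid")
    ext = "asc" if dialect == "ascii_grid" else "tif"
    grids: dict[str, Grid] = {}
    for name in _LAYERS:
        g = read_grid(ind / f"{name}.{ext}", dialect=dialect)
        if name in ("highways", "developed", "burn", "truth_corridor", "matrix_domain"):
            g = g.like(g.values > 0.5)
        elif name == "cover":
            g = g.like(g.values.astype(int), nodata=int(g.nodata))
        grids[name] = g
    labels = read_grid(ind / f"truth_patches.{ext}", dialect=dialect)
    labels = labels.like(np.asarray(labels.values).astype(int), nodata=0)
    return LandscapeBundle(
        truth_patches=LabeledRegions(labels, int(manifest["region_count"])),
        corridor_patch_ids=tuple(manifest["corridor_patch_ids"]),
        patch_centers_m=[tuple(c) for c in manifest["patch_centers_m"]],
        patch_radius_m=float(manifest["patch_radius_m"]),
        seed=int(manifest["seed"]),
        **grids,
    )
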