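# Methods

This note documents the models, conventions, and design choices behind
lynxlink: what each stage computes, which parameters matter, what the
synthetic-landscape generator does and does not emulate, and the numerical
decisions that make runs reproducible.

## Raster model and conventions

All layers are single-band rasters with square pixels. The origin is the
outer corner of the top-left pixel; rows increase southward; the center of
pixel (r, c) is `(origin_x + (c + 0.5)·s, origin_y − (r + 0.5)·s)` for cell
size `s` in meters. All distances are center-to-center. A nodata sentinel
is excluded from every statistic. The working resolution convention is
30 m pixels for field layers (the "30 m" in a source raster is read as the
pixel edge length, i.e. 900 m² pixels); the synthetic landscapes use 250 m
pixels to keep full-pipeline experiments fast (a 256×256 grid spans
64×64 km, about the extent of a regional study area at meso scale).

Standard deviations are the sample form (n − 1) everywhere, and 0.0 for a
single pixel.

**I/O.** ESRI ASCII grids round-trip float64 bit-exactly (values are
written with `repr`); GeoTIFF stores float32 and round-trips to float32
precision. Reprojection, non-square pixels and multiband rasters are out
of scope.

**Focal mean.** The moving-window kernel is, by default, the circle of the
given area under a pixel-center-in-radius test (boundary inclusive); a
square kernel of equal area is available for sensitivity checks. At the
grid edge the kernel shrinks to the available pixels rather than padding
with nodata — padding would erode habitat concentrations at the study-area
boundary. Large kernels use FFT convolution; the result is clamped to the
windowed min/max so the mean is exactly bounded by its inputs (a constant
grid maps to itself bit-exactly) despite accumulation round-off. This
matters because HCA extraction uses a strict `>` threshold.

## Quality, resistance, and expert adjustment

Scaling is affine: quality `= 1 + 9p` from core-habitat use probability,
resistance `= 1 + 9(1 − p)` from matrix-habitat use probability, so
`quality(p) + resistance(p) = 11`. The matrix surface parameterizes
resistance because traveling animals accept poorer habitat than residents;
using the core model instead would overstate resistance between patches.

The expert table holds per-feature point adjustments (averages across
elicited opinions): distance bands for developed parcels and highways
(bands are half-open — "0" applies only on-feature, "1–50" means
0 < d ≤ 50 m — and no band applies beyond 250 m) and four cover classes,
including a negative travel value for west-side sub-boreal forest (it
slightly eases travel). Each applicable feature contributes its full
tabled delta; contributions from distinct features sum, and sums are
applied once (the operation is not idempotent by design). Where highway
and developed buffers overlap, the deltas stack; this additive choice is
isolated in one function. Adjusted values are not clamped: quality may go
slightly negative and resistance above 10, mirroring the observed
post-adjustment ranges of such surfaces. Cover classes already encoded in
the probability surfaces (sub-boreal, mixed, dry, open) carry delta 0; an
unknown cover code is a configuration error, not a silent zero.

## Home ranges and derived parameters

The 95% MCP peels `⌊0.05 n⌋` fixes farthest (Euclidean) from the centroid
of all fixes — ties at the cutoff drop the later fix — then takes the
convex hull (shapely; area by the shoelace formula). Habitat summaries
average pixels whose centers fall inside the polygon, boundary inclusive;
an animal whose polygon leaves the raster gets no summary and is thereby
excluded from the threshold. Eligibility is a minimum fix count (default
6) rather than a calendar span, which has no meaning for synthetic fixes.
Exclusion lists are explicit configuration, not heuristics.

Two scalars feed the delineation: the moving-window area (mean MCP area
over window-eligible animals) and the HCA threshold (minimum per-animal
mean habitat value). The per-animal means use the **adjusted** quality
raster — the raster subsequently windowed — controlled by a config flag.
The smallest eligible MCP area is retained to flag HCAs smaller than any
observed home range.

## HCA delineation

Focal mean at the window area, strict extraction (focal value >
threshold), 8-connected component labeling (consistent with the
8-connected movement graph), optional minimum mapping unit (default 0 km²
— small HCAs are flagged as potential stepping stones, not dropped), and
region statistics computed from the original adjusted quality raster, not
the smoothed one. Regions are ordered by descending area with ids "1",
"2", …. Splitting an oversized HCA is config-driven (an explicit polyline
per named HCA): each region pixel is assigned to the side of the polyline
given by the cross-product sign at its nearest point on the line; a valid
cut yields exactly two connected, non-empty parts, whose ids append
suffixes ("2" → "2a"/"2b") and whose areas and area-weighted means conserve
the parent's exactly.

## Cost-weighted distance

A step between adjacent pixels costs the mean of the two endpoint
resistances times the pixel width, ×√2 for diagonal steps — the standard
grid cost-distance convention; it makes cost symmetric and path-additive
while reducing to geometric distance at unit resistance. Costs are exact
shortest paths on the 8-connected graph by multi-source Dijkstra (all HCA
pixels enter at cost 0). The priority queue orders by (cost, row-major
pixel index), so backlinks — and every path traced from them — are
bit-reproducible. Backlink codes 1–8 point from a pixel to its
predecessor; 0 marks a source. Nodata cells are impassable and are the
only barrier mechanism. Accumulated cost is in resistance-weighted meters
and is reported divided by 1,000 as a *resistance-weighted kilometer* — a
weighted, not geometric, unit. Per-HCA surfaces are mosaicked by per-pixel
minimum with the arg-min HCA recorded as the allocation (ties to the
lower id).

## Linkages

Adjacency follows the allocation-zone convention: two HCAs are adjacent
iff their allocation zones share an 8-connected pixel border (an
`all_pairs` flag exists for small landscapes). The saddle pixel minimizes
`cwd_A + cwd_B` (row-major on ties); the LCP is the backlink trace into A,
reversed, concatenated with the trace into B, and its cost is the saddle
value. Corridors are `cwd_A + cwd_B − saddle`, clipped at zero against
float round-off, optionally truncated to nodata above a configurable
cutoff (the drawn linkage width is a free parameter). Euclidean distance
is edge-to-edge between nearest boundary-pixel centers — centroid
separation would overstate the gap between large neighboring HCAs.
`cwd/path-length` is the mean resistance faced along the path and is
bounded by the path's resistance extremes. Secondary (non-optimal but
cheap) routes are represented by the truncated corridor raster; discrete
k-shortest-path enumeration, circuit-theory mapping, and network metrics
beyond adjacency-graph connectivity are non-goals. A dispersal screen
(flagging paths longer than a maximum dispersal distance) is available and
off by default.

## Synthetic landscapes and telemetry

The generator emulates the statistical structure the analysis assumes, on
a single integer seed split into fixed, named substreams (reordering the
substreams would change every landscape, so the order is frozen).

Default study conditions (chosen once, as a realistic meso-scale setting):
256×256 cells at 250 m (64×64 km); background core-use probability from
Gaussian-smoothed white noise (correlation length 2 km) rank-rescaled to
[0, 1] and mapped to [0.05, 0.40]; five planted flat-topped patches
(super-Gaussian profile, radius 6 km, peak use probability 0.95) on a
jittered lattice with ≥ ~21 km spacing so neighborhood-averaged quality
between patches stays far below any plausible threshold; two highways in
the valley lanes between patch rows/columns, each carving a low-use valley;
matrix probability = 0.30 + 0.45·core + noise, clipped — monotone in core
but flatter and noisier (traveling animals lower their standards); three
blobby burns (radius 3–6 km, kept off patches and the planted channel)
multiplying core probability by 0.2 but matrix by only 0.6 (travel is more
tolerant of burns), with a 30% skip fraction of interior pixels reverted
and opened in the burn mask; developed parcels clustered along highways;
cover classes from core-probability bands plus a west-side strip, one
lake, and agriculture along the valleys. The known truth comprises the
patch footprints and a 3-pixel-wide high-matrix-probability (0.92) channel
bent between the two closest patches.

Telemetry: each animal's home-range disc (default 88 km², the mean
observed for the species in this region) is anchored uniformly within a
patch footprint — so ranges straddle the patch edge and polygon-mean
habitat values sit well below patch-core focal values, as real home ranges
spanning core and matrix habitat do. Fixes are i.i.d. draws in the disc
accepted with probability ∝ core^s (default s = 2; s = 0 is uniform).
Defaults: 8 animals × 200 fixes.

What the generator does **not** emulate: movement autocorrelation
(fixes are independent, not a correlated random walk), fire-spread
geometry, seasonal or climate layers, and the full multivariate predictor
set of a fitted habitat model. Passing recovery tests therefore shows the
pipeline recovers planted structure under the stated statistical
conditions — not that a fitted habitat model would be recovered from real
telemetry.

## Reference inputs

Published per-animal MCP areas and habitat values for North Cascades lynx
ship as a packaged CSV; deriving parameters from it reproduces the 88 km²
window (mean area excluding the one non-localized male) and the 3.8
threshold (minimum mean habitat value; one animal's range left the mapped
area and has no value). The packaged expert table is the six-expert
average set. Fire-impact arithmetic uses the published extents: 35,445 ha
of burned core habitat over the 1,459 km² of the largest occupied HCA
(≈24%), and the 39,326 ha Washington-side extent expressed in mean
home-range multiples (≈4.5). These sources round their printed ratios
from unrounded inputs, so printed ratio columns are not used as numeric
targets.

## Numerical choices and known limitations

- Strict `>` at the HCA threshold, made reliable by the clamped focal mean.
- Dijkstra relaxes on strictly smaller cost; pop order (cost, row-major
  index) fixes backlinks deterministically.
- Corridor values are clipped at 0 (round-off at the saddle only).
- The distance-transform, labeling, convex-hull and shortest-path
  primitives are validated against independent oracles (exhaustive scans,
  flood fill, gift wrapping, sparse-graph Dijkstra) in the test suite.
- Staged CLI execution and the monolithic runner write byte-identical
  artifacts for a fixed seed; the manifest (config echo, seed, versions,
  SHA-256 per file) suffices to reproduce a run.
- Limitations: single-band rasters in one CRS; no circuit-theoretic
  connectivity; no anisotropic or slope-dependent costs; LCPs are
  pixel-wide and sensitive to resistance-surface error, so corridors, not
  bare paths, are the interpretable product.
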