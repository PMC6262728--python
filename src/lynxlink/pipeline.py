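"""End-to-end pipeline: synthetic bundle (or user rasters) to linkage tables.

Stages run in a fixed order, each reading its inputs from and writing its
outputs to a shared run directory, so a monolithic :func:`run_pipeline` call
and the stage-by-stage CLI subcommands produce bit-identical artifacts:

    simulate -> surfaces -> homerange -> hca -> cost -> linkage -> report

A JSON manifest records the seed, the configuration echoed verbatim, package
versions, and a checksum for every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .costdist import CostSurface, MosaicSurface, cost_weighted_distance, mosaic_min
from .errors import ConfigError, MissingPrerequisiteError
from .grids import Grid, read_grid, write_grid
from .hca import HCARegion, delineate, hca_table, split_region
from .homerange import (
    derive_parameters,
    home_range_table,
    mcp,
    range_habitat_summary,
    ranges_to_geojson,
)
from .landscape import generate_landscape, generate_locations, read_bundle, write_bundle
from .linkage import adjacency, corridor, least_cost_path, linkage_stats, linkage_table
from .surfaces import (
    apply_adjustments,
    default_adjustments,
    load_adjustments,
    quality_from_probability,
    resistance_from_probability,
)

log = logging.getLogger("lynxlink")

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from a YAML file."""

    seed: int = 0
    dialect: str = "ascii_grid"
    # synthetic generation (ignored when input_dir is given)
    input_dir: str | None = None
    landscape: dict = field(
        default_factory=lambda: dict(
            n_rows=256,
            n_cols=256,
            cell_size=250.0,
            correlation_length=2000.0,
            n_patches=5,
            n_burns=3,
            skip_fraction=0.3,
            patch_radius_m=6000.0,
        )
    )
    locations: dict = field(
        default_factory=lambda: dict(
            n_animals=8,
            fixes_per_animal=200,
            home_range_area_km2=88.0,
            selection_strength=2.0,
        )
    )
    # surfaces
    adjustment_table: str | None = None  # None = packaged expert table
    # home ranges
    mcp_fraction: float = 0.95
    min_fixes: int = 6
    use_adjusted_quality: bool = True
    window_exclusions: list = field(default_factory=list)
    threshold_exclusions: list = field(default_factory=list)
    # HCA
    window_area_km2: object = "derive"  # km² or "derive"
    hca_threshold: object = "derive"  # quality points or "derive"
    window_shape: str = "circle"
    connectivity: int = 8
    min_area_km2: float = 0.0
    splits: dict = field(default_factory=dict)  # hca_id -> [[x, y], ...]
    # linkages
    all_pairs: bool = False
    truncation_cwd_km: float | None = None
    max_dispersal_km: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.mcp_fraction <= 1:
            raise ConfigError("mcp_fraction must be in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if self.window_shape not in ("circle", "square"):
            raise ConfigError("window_shape must be 'circle' or 'square'")
        for key in ("window_area_km2", "hca_threshold"):
            v = getattr(self, key)
            if v != "derive" and not isinstance(v, (int, float)):
                raise ConfigError(f"{key} must be a number or 'derive'")
        if self.dialect not in ("ascii_grid", "geotiff"):
            raise ConfigError("dialect must be 'ascii_grid' or 'geotiff'")


def _ext(cfg: PipelineConfig) -> str:
    return "asc" if cfg.dialect == "ascii_grid" else "tif"


def _adjustments(cfg: PipelineConfig):
    if cfg.adjustment_table:
        return load_adjustments(cfg.adjustment_table)
    return default_adjustments()


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingPrerequisiteError(
            f"stage '{stage}' needs {path.name}; run the earlier stages first"
        )
    return path


# ----------------------------------------------------------------------
# Stages
# ----------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    """Generate (or import) the landscape bundle and telemetry."""
    land = outdir / "landscape"
    if cfg.input_dir:
        bundle = read_bundle(cfg.input_dir)
        write_bundle(bundle, land, dialect=cfg.dialect)
        src_loc = Path(cfg.input_dir) / "locations.csv"
        if src_loc.exists():
            (land / "locations.csv").write_text(src_loc.read_text())
            return
    else:
        bundle = generate_landscape(seed=cfg.seed, **cfg.landscape)
        write_bundle(bundle, land, dialect=cfg.dialect)
    locs = generate_locations(bundle, **cfg.locations)
    locs.to_csv(land / "locations.csv", index=False)


def stage_surfaces(cfg: PipelineConfig, outdir: Path) -> None:
    """Scale probabilities to quality/resistance and apply expert adjustments."""
    land = outdir / "landscape"
    _need(land / "bundle.json", "surfaces")
    bundle = read_bundle(land)
    table = _adjustments(cfg)
    quality = apply_adjustments(
        quality_from_probability(bundle.core_probability),
        table,
        highways=bundle.highways,
        developed=bundle.developed,
        cover=bundle.cover,
        mode="core",
    )
    resistance = apply_adjustments(
        resistance_from_probability(bundle.matrix_probability),
        table,
        highways=bundle.highways,
        developed=bundle.developed,
        cover=bundle.cover,
        mode="travel",
    )
    sdir = outdir / "surfaces"
    sdir.mkdir(parents=True, exist_ok=True)
    ext = _ext(cfg)
    write_grid(quality, sdir / f"quality_adjusted.{ext}", dialect=cfg.dialect)
    write_grid(resistance, sdir / f"resistance_adjusted.{ext}", dialect=cfg.dialect)


def stage_homerange(cfg: PipelineConfig, outdir: Path) -> None:
    """MCP home ranges, habitat summaries, and the derived parameters."""
    ext = _ext(cfg)
    locs = pd.read_csv(_need(outdir / "landscape" / "locations.csv", "homerange"))
    qpath = _need(outdir / "surfaces" / f"quality_adjusted.{ext}", "homerange")
    quality = read_grid(qpath, dialect=cfg.dialect)
    if not cfg.use_adjusted_quality:
        core = read_bundle(outdir / "landscape").core_probability
        quality = quality_from_probability(core)
    ranges = []
    for animal_id, df in locs.groupby("animal_id", sort=True):
        if len(df) < cfg.min_fixes:
            continue
        df = df.sort_values("t", kind="stable")
        hr = mcp(df[["x", "y"]].to_numpy(), fraction=cfg.mcp_fraction, animal_id=str(animal_id))
        ranges.append(range_habitat_summary(hr, quality))
    hdir = outdir / "homerange"
    hdir.mkdir(parents=True, exist_ok=True)
    home_range_table(ranges).to_csv(hdir / "home_ranges.csv", index=False)
    (hdir / "home_ranges.geojson").write_text(json.dumps(ranges_to_geojson(ranges)))
    params = derive_parameters(
        ranges,
        window_exclusions=list(cfg.window_exclusions),
        threshold_exclusions=list(cfg.threshold_exclusions),
    )
    derived = asdict(params)
    derived["window_area_km2_used"] = (
        params.window_area_km2 if cfg.window_area_km2 == "derive" else float(cfg.window_area_km2)
    )
    derived["hca_threshold_used"] = (
        params.hca_threshold if cfg.hca_threshold == "derive" else float(cfg.hca_threshold)
    )
    (hdir / "derived_parameters.json").write_text(json.dumps(derived, indent=2))


def _load_regions(cfg: PipelineConfig, outdir: Path, stage: str) -> list[HCARegion]:
    ext = _ext(cfg)
    labels = read_grid(_need(outdir / "hca" / f"hca_labels.{ext}", stage), dialect=cfg.dialect)
    table = pd.read_csv(_need(outdir / "hca" / "hca_table.csv", stage))
    lab = np.asarray(labels.values).astype(int)
    regions = []
    for i, row in enumerate(table.itertuples(), start=1):
        regions.append(
            HCARegion(
                hca_id=str(row.hca_id),
                mask=labels.like(lab == i),
                area_km2=float(row.area_km2),
                mean_quality=float(row.mean_quality),
                sd_quality=float(row.sd_quality),
                smaller_than_min_range=bool(row.smaller_than_min_range),
            )
        )
    return regions


def stage_hca(cfg: PipelineConfig, outdir: Path) -> None:
    """Delineate habitat concentration areas and apply configured splits."""
    ext = _ext(cfg)
    quality = read_grid(
        _need(outdir / "surfaces" / f"quality_adjusted.{ext}", "hca"), dialect=cfg.dialect
    )
    derived = json.loads(_need(outdir / "homerange" / "derived_parameters.json", "hca").read_text())
    window = float(derived["window_area_km2_used"])
    threshold = float(derived["hca_threshold_used"])
    min_range = float(derived["min_range_area_km2"])
    regions = delineate(
        quality,
        window_area_km2=window,
        threshold=threshold,
        connectivity=cfg.connectivity,
        min_area_km2=cfg.min_area_km2,
        min_range_area_km2=min_range,
        window_shape=cfg.window_shape,
    )
    log.info("delineated %d habitat concentration areas", len(regions))
    for hca_id, polyline in sorted(cfg.splits.items()):
        match = [r for r in regions if r.hca_id == str(hca_id)]
        if not match:
            raise ConfigError(f"split requested for unknown HCA id {hca_id!r}")
        parent = match[0]
        part_a, part_b = split_region(
            parent,
            [tuple(p) for p in polyline],
            quality,
            min_range_area_km2=min_range,
            connectivity=cfg.connectivity,
        )
        i = regions.index(parent)
        regions[i : i + 1] = [part_a, part_b]
    hdir = outdir / "hca"
    hdir.mkdir(parents=True, exist_ok=True)
    lab = np.zeros(quality.shape, dtype=float)
    for i, r in enumerate(regions, start=1):
        lab[np.asarray(r.mask.values, dtype=bool)] = i
    write_grid(quality.like(lab, nodata=0.0), hdir / f"hca_labels.{ext}", dialect=cfg.dialect)
    hca_table(regions).to_csv(hdir / "hca_table.csv", index=False)


def stage_cost(cfg: PipelineConfig, outdir: Path, only_hca: str | None = None) -> None:
    """Per-HCA cost-weighted distance surfaces and the minimum mosaic."""
    ext = _ext(cfg)
    resistance = read_grid(
        _need(outdir / "surfaces" / f"resistance_adjusted.{ext}", "cost"), dialect=cfg.dialect
    )
    regions = _load_regions(cfg, outdir, "cost")
    cdir = outdir / "cost"
    cdir.mkdir(parents=True, exist_ok=True)
    surfaces = []
    for r in regions:
        if only_hca is not None and r.hca_id != only_hca:
            continue
        t0 = time.perf_counter()
        surf = cost_weighted_distance(resistance, r.mask, source_id=r.hca_id)
        log.info("cwd for HCA %s in %.2f s", r.hca_id, time.perf_counter() - t0)
        cwd_out = surf.cwd.like(
            np.where(np.isfinite(surf.cwd.values), surf.cwd.values, -1.0), nodata=-1.0
        )
        write_grid(cwd_out, cdir / f"cwd_{r.hca_id}.{ext}", dialect=cfg.dialect)
        write_grid(
            surf.backlink.like(surf.backlink.values.astype(float), nodata=-1.0),
            cdir / f"backlink_{r.hca_id}.{ext}",
            dialect=cfg.dialect,
        )
        surfaces.append(surf)
    if only_hca is None and surfaces:
        mosaic = mosaic_min(surfaces)
        cwd_out = mosaic.cwd_min.like(
            np.where(np.isfinite(mosaic.cwd_min.values), mosaic.cwd_min.values, -1.0),
            nodata=-1.0,
        )
        write_grid(cwd_out, cdir / f"mosaic_cwd.{ext}", dialect=cfg.dialect)
        write_grid(
            mosaic.nearest_hca.like(mosaic.nearest_hca.values.astype(float), nodata=0.0),
            cdir / f"allocation.{ext}",
            dialect=cfg.dialect,
        )


def _load_cost_surfaces(cfg: PipelineConfig, outdir: Path, regions, stage: str):
    ext = _ext(cfg)
    surfaces = []
    for r in regions:
        cwd = read_grid(_need(outdir / "cost" / f"cwd_{r.hca_id}.{ext}", stage), cfg.dialect)
        vals = np.asarray(cwd.values, dtype=float)
        cwd = cwd.like(np.where(vals < 0, np.inf, vals))
        back = read_grid(_need(outdir / "cost" / f"backlink_{r.hca_id}.{ext}", stage), cfg.dialect)
        back = back.like(np.asarray(back.values).astype(int), nodata=-1)
        surfaces.append(CostSurface(source_id=r.hca_id, cwd=cwd, backlink=back))
    return surfaces


def stage_linkage(cfg: PipelineConfig, outdir: Path) -> None:
    """Adjacency, least-cost paths, normalized corridors, and statistics."""
    ext = _ext(cfg)
    regions = _load_regions(cfg, outdir, "linkage")
    surfaces = _load_cost_surfaces(cfg, outdir, regions, "linkage")
    alloc = read_grid(_need(outdir / "cost" / f"allocation.{ext}", "linkage"), cfg.dialect)
    cwd_min = read_grid(_need(outdir / "cost" / f"mosaic_cwd.{ext}", "linkage"), cfg.dialect)
    mosaic = MosaicSurface(
        cwd_min=cwd_min,
        nearest_hca=alloc.like(np.asarray(alloc.values).astype(int), nodata=0),
        source_ids=[r.hca_id for r in regions],
    )
    pairs = adjacency(mosaic, regions, all_pairs=cfg.all_pairs)
    log.info("%d adjacent HCA pairs", len(pairs))
    by_id = {r.hca_id: r for r in regions}
    surf_by_id = {s.source_id: s for s in surfaces}
    ldir = outdir / "linkage"
    ldir.mkdir(parents=True, exist_ok=True)
    records = []
    for a, b in pairs:
        rec = least_cost_path(surf_by_id[a], surf_by_id[b])
        if not rec.reachable:
            log.warning("HCA pair %s-%s unreachable; excluded from tables", a, b)
            continue
        rec = linkage_stats(rec, by_id[a], by_id[b], max_dispersal_km=cfg.max_dispersal_km)
        records.append(rec)
        pd.DataFrame(rec.lcp_cells, columns=["row", "col"]).to_csv(
            ldir / f"lcp_{a}_{b}.csv", index=False
        )
        corr = corridor(
            surf_by_id[a], surf_by_id[b], rec.cwd_km, truncation_cwd_km=cfg.truncation_cwd_km
        )
        write_grid(corr, ldir / f"corridor_{a}_{b}.{ext}", dialect=cfg.dialect)
    linkage_table(records).to_csv(ldir / "linkages.csv", index=False)


def stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    """Bundle the three summary tables into report/."""
    rdir = outdir / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    for src, dst in [
        (outdir / "homerange" / "home_ranges.csv", rdir / "home_ranges.csv"),
        (outdir / "hca" / "hca_table.csv", rdir / "hca_table.csv"),
        (outdir / "linkage" / "linkages.csv", rdir / "linkages.csv"),
    ]:
        _need(src, "report")
        dst.write_text(src.read_text())


STAGES = {
    "simulate": stage_simulate,
    "surfaces": stage_surfaces,
    "homerange": stage_homerange,
    "hca": stage_hca,
    "cost": stage_cost,
    "linkage": stage_linkage,
    "report": stage_report,
}


def _checksums(outdir: Path) -> dict[str, str]:
    sums = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            sums[str(path.relative_to(outdir))] = hashlib.sha256(path.read_bytes()).hexdigest()
    return sums


def write_manifest(cfg: PipelineConfig, outdir: Path) -> dict:
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "versions": {"lynxlink": __version__, "numpy": np.__version__},
        "checksums": _checksums(outdir),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage in order and write the manifest; returns the manifest."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, stage in STAGES.items():
        t0 = time.perf_counter()
        stage(cfg, out)
        log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
    return write_manifest(cfg, out)


# ----------------------------------------------------------------------
# In-memory analysis (no intermediate files)
# ----------------------------------------------------------------------


@dataclass
class AnalysisResult:
    """Everything one in-memory analysis produces."""

    quality: Grid
    resistance: Grid
    ranges: list
    params: object
    regions: list
    surfaces: list
    mosaic: MosaicSurface | None
    pairs: list
    records: list
    corridors: dict


def analyze(bundle, locations=None, cfg: PipelineConfig | None = None) -> AnalysisResult:
    """Run the full analysis on an in-memory bundle, returning all results.

    Functionally identical to the staged pipeline but without file handoff;
    convenient for parameter sweeps and recovery experiments.
    """
    cfg = cfg or PipelineConfig()
    table = _adjustments(cfg)
    quality = apply_adjustments(
        quality_from_probability(bundle.core_probability), table,
        highways=bundle.highways, developed=bundle.developed,
        cover=bundle.cover, mode="core",
    )
    resistance = apply_adjustments(
        resistance_from_probability(bundle.matrix_probability), table,
        highways=bundle.highways, developed=bundle.developed,
        cover=bundle.cover, mode="travel",
    )
    if locations is None:
        locations = generate_locations(bundle, **cfg.locations)
    ranges = []
    for animal_id, df in locations.groupby("animal_id", sort=True):
        if len(df) < cfg.min_fixes:
            continue
        df = df.sort_values("t", kind="stable")
        hr = mcp(df[["x", "y"]].to_numpy(), fraction=cfg.mcp_fraction,
                 animal_id=str(animal_id))
        ranges.append(range_habitat_summary(hr, quality))
    params = derive_parameters(
        ranges,
        window_exclusions=list(cfg.window_exclusions),
        threshold_exclusions=list(cfg.threshold_exclusions),
    )
    window = (params.window_area_km2 if cfg.window_area_km2 == "derive"
              else float(cfg.window_area_km2))
    threshold = (params.hca_threshold if cfg.hca_threshold == "derive"
                 else float(cfg.hca_threshold))
    regions = delineate(
        quality, window_area_km2=window, threshold=threshold,
        connectivity=cfg.connectivity, min_area_km2=cfg.min_area_km2,
        min_range_area_km2=params.min_range_area_km2,
        window_shape=cfg.window_shape,
    )
    surfaces = [
        cost_weighted_distance(resistance, r.mask, source_id=r.hca_id)
        for r in regions
    ]
    mosaic = mosaic_min(surfaces) if surfaces else None
    pairs = adjacency(mosaic, regions, all_pairs=cfg.all_pairs) if mosaic else []
    by_id = {r.hca_id: r for r in regions}
    surf_by_id = {s.source_id: s for s in surfaces}
    records, corridors = [], {}
    for a, b in pairs:
        rec = least_cost_path(surf_by_id[a], surf_by_id[b])
        if not rec.reachable:
            continue
        rec = linkage_stats(rec, by_id[a], by_id[b],
                            max_dispersal_km=cfg.max_dispersal_km)
        records.append(rec)
        corridors[(a, b)] = corridor(
            surf_by_id[a], surf_by_id[b], rec.cwd_km,
            truncation_cwd_km=cfg.truncation_cwd_km,
        )
    return AnalysisResult(
        quality=quality, resistance=resistance, ranges=ranges, params=params,
        regions=regions, surfaces=surfaces, mosaic=mosaic, pairs=pairs,
        records=records, corridors=corridors,
    )
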