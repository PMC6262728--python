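"""Habitat-quality and resistance surfaces, with expert-opinion adjustments.

Use-probability surfaces (probability of a lynx using a pixel, in [0, 1])
become a habitat-quality raster scaled 1 (poor) to 10 (good) and a resistance
raster scaled 1 (no resistance to movement) to 10 (high resistance).  Six
landscape variables absent from the underlying habitat models — distance to
developed parcels, distance to highways, and four cover classes — are then
applied as additive point adjustments elicited from experts.  Adjustments
are deliberately NOT clamped: the adjusted quality surface may go slightly
negative and the adjusted resistance surface may exceed 10, matching the
nominal-scale overshoot seen in practice.

Distance bands are half-open: band "0" applies only on-feature (d = 0),
band "1-50" means 0 < d <= 50 m, and so on; no band applies beyond 250 m.
Deltas from distinct features accumulate additively, in any order.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError
from .grids import Grid, distance_to

__all__ = [
    "COVER_CLASSES",
    "COVER_CODES",
    "ExpertAdjustmentTable",
    "default_adjustments",
    "load_adjustments",
    "scale_quality",
    "scale_resistance",
    "apply_adjustments",
]

# Integer cover-class codes.  The first four classes are already encoded in
# the use-probability surfaces, so they carry zero adjustment; the last four
# were absent from the habitat models and take the expert deltas.
COVER_CLASSES = {
    0: "subboreal_forest",
    1: "mixed_forest",
    2: "dry_forest",
    3: "open",
    4: "west_side_subboreal_forest",
    5: "west_side_wet_forest",
    6: "agriculture",
    7: "water",
}
COVER_CODES = {name: code for code, name in COVER_CLASSES.items()}

_MODELED_CLASSES = ("subboreal_forest", "mixed_forest", "dry_forest", "open")


@dataclass
class ExpertAdjustmentTable:
    """Expert-opinion point adjustments for features missing from the habitat models.

    ``bands``: feature name -> list of (low_m, high_m, core_delta,
    travel_delta); the band (0, 0) applies at d = 0 exactly and band
    (low, high) applies for low < d <= high.  ``cover``: class name ->
    (core_delta, travel_delta).
    """

    bands: dict[str, list[tuple[float, float, float, float]]]
    cover: dict[str, tuple[float, float]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpertAdjustmentTable":
        bands: dict[str, list] = {}
        cover: dict[str, tuple[float, float]] = {}
        for _, row in df.iterrows():
            feature = str(row["feature"])
            core = float(row["core_delta"])
            travel = float(row["travel_delta"])
            if feature == "cover":
                cover[str(row["class_name"])] = (core, travel)
            else:
                bands.setdefault(feature, []).append(
                    (float(row["band_low_m"]), float(row["band_high_m"]), core, travel)
                )
        for name in _MODELED_CLASSES:
            cover.setdefault(name, (0.0, 0.0))
        return cls(bands=bands, cover=cover)

    def band_delta(self, feature: str, distance_m: np.ndarray, mode: str) -> np.ndarray:
        """Per-pixel delta for one distance-banded feature."""
        k = 2 if mode == "core" else 3
        out = np.zeros_like(distance_m, dtype=float)
        for low, high, *deltas in self.bands.get(feature, []):
            if low == high:  # the on-feature band, d == 0
                sel = distance_m == low
            else:
                sel = (distance_m > low) & (distance_m <= high)
            out[sel] = deltas[k - 2]
        return out

    def cover_delta(self, cover_codes: np.ndarray, mode: str) -> np.ndarray:
        k = 0 if mode == "core" else 1
        lut = np.zeros(max(COVER_CLASSES) + 1, dtype=float)
        present = np.unique(cover_codes[cover_codes >= 0])
        for code in present:
            name = COVER_CLASSES.get(int(code))
            if name is None or name not in self.cover:
                raise ConfigError(
                    f"cover class {code} ({name or 'unknown'}) absent from adjustment table"
                )
            lut[int(code)] = self.cover[name][k]
        return lut[np.clip(cover_codes, 0, None).astype(int)]


def load_adjustments(path) -> ExpertAdjustmentTable:
    """Read an adjustment table from CSV (columns: feature, band_low_m,
    band_high_m, class_name, core_delta, travel_delta)."""
    return ExpertAdjustmentTable.from_frame(pd.read_csv(path))


def default_adjustments() -> ExpertAdjustmentTable:
    """The packaged expert-opinion table (six-expert averages for the
    North Cascades: developed parcels, highways, and four cover classes)."""
    with resources.files("lynxlink.data").joinpath("expert_adjustments.csv").open() as fh:
        return ExpertAdjustmentTable.from_frame(pd.read_csv(fh))


# ----------------------------------------------------------------------
# Scaling
# ----------------------------------------------------------------------


def scale_quality(p):
    """Map core-habitat use probability in [0, 1] to quality in [1, 10].

    Affine and strictly increasing: quality = 1 + 9 p.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ParameterError("use probability outside [0, 1]")
    out = 1.0 + 9.0 * arr
    return float(out) if np.isscalar(p) else out


def scale_resistance(q):
    """Map matrix-habitat use probability in [0, 1] to resistance in [1, 10].

    Affine and strictly decreasing: resistance = 1 + 9 (1 - q); a pixel a
    traveling animal is certain to use offers no resistance (1), a pixel it
    never uses offers full resistance (10).
    """
    arr = np.asarray(q, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ParameterError("use probability outside [0, 1]")
    out = 1.0 + 9.0 * (1.0 - arr)
    return float(out) if np.isscalar(q) else out


def quality_from_probability(prob: Grid) -> Grid:
    """Grid version of :func:`scale_quality`, preserving nodata."""
    valid = prob.valid_mask()
    vals = np.asarray(prob.values, dtype=float)
    out = np.where(valid, 1.0 + 9.0 * np.clip(vals, 0.0, 1.0), prob.nodata)
    return prob.like(out)


def resistance_from_probability(prob: Grid) -> Grid:
    """Grid version of :func:`scale_resistance`, preserving nodata."""
    valid = prob.valid_mask()
    vals = np.asarray(prob.values, dtype=float)
    out = np.where(valid, 1.0 + 9.0 * (1.0 - np.clip(vals, 0.0, 1.0)), prob.nodata)
    return prob.like(out)


# ----------------------------------------------------------------------
# Expert adjustment
# ----------------------------------------------------------------------


def apply_adjustments(
    surface: Grid,
    table: ExpertAdjustmentTable,
    highways: Grid | None = None,
    developed: Grid | None = None,
    cover: Grid | None = None,
    mode: str = "core",
) -> Grid:
    """Apply expert point adjustments to a quality or resistance surface.

    ``mode="core"`` subtracts deltas from habitat quality; ``mode="travel"``
    adds them to resistance (a decrease in travel-habitat quality is an
    increase in resistance; the negative west-side sub-boreal delta lowers
    resistance).  Each applicable feature contributes its full tabled delta
    and contributions sum across features.  Values are not clamped.
    """
    if mode not in ("core", "travel"):
        raise ParameterError("mode must be 'core' or 'travel'")
    total = np.zeros(surface.shape, dtype=float)
    for feature, mask in (("highway", highways), ("developed", developed)):
        if mask is None:
            continue
        if not surface.same_georeference(mask):
            raise ParameterError(f"{feature} mask georeferencing differs from surface")
        d = distance_to(mask).values
        total += table.band_delta(feature, d, mode)
    if cover is not None:
        if not surface.same_georeference(cover):
            raise ParameterError("cover grid georeferencing differs from surface")
        total += table.cover_delta(np.asarray(cover.values), mode)
    valid = surface.valid_mask()
    vals = np.asarray(surface.values, dtype=float)
    if mode == "core":
        out = vals - total
    else:
        out = vals + total
    return surface.like(np.where(valid, out, surface.nodata))
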