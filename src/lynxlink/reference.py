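"""Published North Cascades reference figures used for cross-checks.

These are printed study results treated as inputs: the area of the largest
occupied habitat concentration area, the extent of the 2017 Diamond Creek
fire, and the longest dispersal distance recorded for a collared lynx.
"""

from __future__ import annotations

from .homerange import derive_reference_parameters

__all__ = [
    "HCA2_AREA_KM2",
    "DIAMOND_CREEK_CORE_BURNED_HA",
    "DIAMOND_CREEK_WA_BURNED_HA",
    "LONGEST_DISPERSAL_KM",
    "burn_impact_pct_of_hca2",
    "burn_area_in_mean_home_ranges",
]

#: Area of habitat concentration area 2, the largest occupied one (km²).
HCA2_AREA_KM2 = 1459.0

#: Core habitat burned by the 2017 Diamond Creek fire (ha), within HCA 2's
#: part of the study area.
DIAMOND_CREEK_CORE_BURNED_HA = 35445.0

#: Diamond Creek fire extent on the Washington side of the border (ha).
DIAMOND_CREEK_WA_BURNED_HA = 39326.0

#: Longest recorded dispersal by a collared lynx in the study (km).
LONGEST_DISPERSAL_KM = 367.0


def burn_impact_pct_of_hca2() -> float:
    """Percentage of habitat concentration area 2 impacted by the Diamond
    Creek fire: burned core habitat over the HCA's area."""
    return DIAMOND_CREEK_CORE_BURNED_HA / 100.0 / HCA2_AREA_KM2 * 100.0


def burn_area_in_mean_home_ranges() -> float:
    """The Washington-side burned area expressed in multiples of the mean
    observed home-range area."""
    params = derive_reference_parameters()
    return DIAMOND_CREEK_WA_BURNED_HA / 100.0 / params.window_area_km2
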