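"""Vegetation community codes and default elevation parameters.

The model works with nine natural communities of a micro-tidal barrier-island
landscape, ordered from the most hydric (saltwater marsh) to the most xeric
(oak scrub).  Elevations are always expressed in meters above mean lagoon
high water (MLHW); mean lagoon water (MLW) sits ``MLW_OFFSET`` meters lower
and is the threshold below which a cell is open water.

The default per-community mean elevations and stratum standard deviations
are the published stratified-GLS estimates for the Cape Canaveral Barrier
Island Complex; the default landscape weights are the observed share of
pixels in each community, normalised to sum to one.
"""

from __future__ import annotations

import numpy as np

#: The nine natural community codes, hydric -> xeric display order.
COMMUNITIES: tuple[str, ...] = (
    "SMAR",  # Saltwater Marsh
    "WETS",  # Wet Scrub-Shrub
    "MANG",  # Mangrove
    "PALM",  # Cabbage Palm
    "FWET",  # Freshwater Wetland
    "HAMM",  # Hardwood Hammock
    "PINE",  # Pine Flatwoods
    "FRST",  # Upland Forest
    "SCRB",  # Oak Scrub
)

COMMUNITY_NAMES: dict[str, str] = {
    "SMAR": "Saltwater Marsh",
    "WETS": "Wet Scrub-Shrub",
    "MANG": "Mangrove",
    "PALM": "Cabbage Palm",
    "FWET": "Freshwater Wetland",
    "HAMM": "Hardwood Hammock",
    "PINE": "Pine Flatwoods",
    "FRST": "Upland Forest",
    "SCRB": "Oak Scrub",
}

#: Sentinel codes for non-community cells.
WATER = "WATER"
NODATA = "NODATA"
ABSORBED = "ABSORBED"

#: Default vertical geometry (meters).  MLHW is the elevation zero; MLW is
#: ``MLW_OFFSET`` m below it and marks the open-water boundary.
MLW_OFFSET = 0.2

#: Stratified-GLS mean elevation (m MLHW) per community.
DEFAULT_MEAN = {
    "SMAR": 0.14,
    "WETS": 0.34,
    "MANG": 0.32,
    "PALM": 0.78,
    "FWET": 0.77,
    "HAMM": 0.88,
    "PINE": 1.09,
    "FRST": 1.83,
    "SCRB": 1.96,
}

#: Stratum standard deviation (m) per community.
DEFAULT_SD = {
    "SMAR": 0.55,
    "WETS": 0.87,
    "MANG": 1.00,
    "PALM": 1.26,
    "FWET": 1.07,
    "HAMM": 1.40,
    "PINE": 1.00,
    "FRST": 1.80,
    "SCRB": 1.65,
}

# Observed percent of landscape pixels per community (sums to 100.01 as
# printed; normalised below).
_PERCENT_ORIGINAL = {
    "SMAR": 15.48,
    "WETS": 4.49,
    "MANG": 5.60,
    "PALM": 5.30,
    "FWET": 14.02,
    "HAMM": 16.31,
    "PINE": 14.38,
    "FRST": 6.54,
    "SCRB": 17.89,
}

_total = sum(_PERCENT_ORIGINAL.values())
#: Default landscape community weights (proportions, sum to 1).
DEFAULT_WEIGHT = {c: p / _total for c, p in _PERCENT_ORIGINAL.items()}


def weight_array(weights: dict[str, float] | None = None,
                 communities: tuple[str, ...] = COMMUNITIES) -> np.ndarray:
    """Return weights as an array aligned with ``communities``."""
    w = weights or DEFAULT_WEIGHT
    return np.array([w[c] for c in communities], dtype=float)
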