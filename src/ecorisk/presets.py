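"""Shipped parameter presets: fragility scores, carbon-pool densities,
scenario adjustments, transfer-cost matrices and fixed risk breakpoints.

Class coding convention throughout: 1=construction, 2=water, 3=forest,
4=grassland, 5=cropland.
"""

from __future__ import annotations

import numpy as np

from .geodata import DEFAULT_CLASS_NAMES, LandClassTable

CLASS_CODES = (1, 2, 3, 4, 5)

#: Expert-scored landscape fragility: construction 1, water 2, forest 3,
#: grassland 4, cropland 5 (cropland most vulnerable to disturbance).
FRAGILITY = {1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0, 5: 5.0}

#: Plausible temperate-coastal carbon-pool densities (above, below, soil,
#: dead; t/km²).  Real applications supply their own regional table; these
#: defaults preserve the qualitative ordering forest > grassland > cropland
#: > water > construction used in carbon-storage assessments.
CARBON_POOLS = {
    1: (1200.0, 400.0, 3500.0, 0.0),      # construction
    2: (300.0, 0.0, 1500.0, 0.0),         # water
    3: (4500.0, 1800.0, 14500.0, 900.0),  # forest
    4: (1600.0, 2900.0, 9500.0, 300.0),   # grassland
    5: (2200.0, 800.0, 8200.0, 200.0),    # cropland
}


def default_class_table() -> LandClassTable:
    return LandClassTable.from_dict(FRAGILITY, CARBON_POOLS, DEFAULT_CLASS_NAMES)


#: Five-class risk breakpoints used with classification mode "fixed":
#: low <= 0.243 < lower <= 0.404 < medium <= 0.550 < high <= 0.643 < higher.
ERI_FIXED_BREAKS = (0.243, 0.404, 0.550, 0.643)

RISK_LABELS = ("low", "lower", "medium", "high", "higher")

# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

#: Scenario adjustment lists: (source class, target class, direction, D).
#: ND sets no conversion adjustments.  UD raises the probability of
#: grassland/forest/cropland converting to construction by 20% and reduces
#: construction converting to anything but cropland by 30%.  CP reduces
#: cropland→construction by 60% and cropland→grassland by 40%.
SCENARIO_ADJUSTMENTS: dict[str, list[tuple[int, int, str, float]]] = {
    "ND": [],
    "UD": [
        (4, 1, "raise", 0.20),
        (3, 1, "raise", 0.20),
        (5, 1, "raise", 0.20),
        (1, 2, "reduce", 0.30),
        (1, 3, "reduce", 0.30),
        (1, 4, "reduce", 0.30),
    ],
    "CP": [
        (5, 1, "reduce", 0.60),
        (5, 4, "reduce", 0.40),
    ],
}

#: Binary transfer-cost matrices per scenario (row = source class, column =
#: target class, order construction/water/forest/grassland/cropland;
#: 1 = transition permitted).  The natural matrix lets built land, water and
#: forest convert freely but holds grassland and cropland in place; the
#: urban matrix locks construction except for reversion to cropland; the
#: cropland-protection matrix additionally allows grassland→cropland.
TRANSFER_COST = {
    "ND": np.array(
        [
            [1, 1, 1, 1, 1],
            [1, 1, 1, 1, 1],
            [1, 1, 1, 1, 1],
            [0, 0, 0, 1, 0],
            [0, 0, 0, 0, 1],
        ],
        dtype=np.int8,
    ),
    "UD": np.array(
        [
            [1, 0, 0, 0, 1],
            [1, 1, 1, 0, 1],
            [1, 1, 1, 1, 1],
            [0, 0, 0, 1, 1],
            [0, 0, 0, 0, 1],
        ],
        dtype=np.int8,
    ),
    "CP": np.array(
        [
            [1, 0, 0, 0, 0],
            [1, 1, 1, 0, 1],
            [1, 1, 1, 1, 1],
            [1, 0, 0, 1, 0],
            [0, 0, 0, 0, 1],
        ],
        dtype=np.int8,
    ),
}

#: Fully permissive transfer matrix, useful when demand feasibility matters
#: more than scenario policy (e.g. recovery experiments).
TRANSFER_ALLOW_ALL = np.ones((5, 5), dtype=np.int8)
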