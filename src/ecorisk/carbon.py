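"""Carbon-stock mapping by land-class lookup.

Each cell's carbon density is the sum of its class's four pools,

    C_total = C_above + C_below + C_soil + C_dead   (t/km²),

so the landscape total is the closed form Σ_classes area_i × density_i
(tonnes).  Change between two dates is plain cellwise differencing; the
aggregate change equals class-area bookkeeping whenever both surfaces share
one class table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import (
    EvaluationGrid,
    FloatRaster,
    LandClassTable,
    LandUseRaster,
)


@dataclass
class CarbonSurface:
    """Per-cell carbon density (t/km²) with landscape aggregates."""

    density: FloatRaster  # t/km², NaN on nodata
    total_t: float  # landscape stock in tonnes
    per_class_t: dict[int, float]
    source: LandUseRaster

    @property
    def mean_density(self) -> float:
        return float(np.nanmean(self.density.grid))

    def unit_mean_density(self, grid: EvaluationGrid) -> np.ndarray:
        """Mean density per evaluation unit (NaN for empty units)."""
        d = self.density.grid
        idx = grid.unit_index
        ok = (idx >= 0) & np.isfinite(d)
        sums = np.bincount(idx[ok], weights=d[ok], minlength=grid.n_units)
        counts = np.bincount(idx[ok], minlength=grid.n_units)
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.per_class_t),
                "stock_t": list(self.per_class_t.values()),
            }
        )


def carbon_map(raster: LandUseRaster, classes: LandClassTable) -> CarbonSurface:
    """Carbon density surface and totals for one land-use raster."""
    classes.validate_against(raster)
    density_by_class = classes.carbon_density()
    lut = np.zeros(max(density_by_class) + 1)
    for code, dens in density_by_class.items():
        lut[code] = dens
    grid = np.where(raster.valid_mask, lut[np.clip(raster.grid, 0, len(lut) - 1)], np.nan)
    cell_area = raster.cell_area_km2
    per_class = {
        code: float((raster.grid == code).sum()) * cell_area * density_by_class[code]
        for code in sorted(raster.class_codes)
    }
    return CarbonSurface(
        density=FloatRaster(grid, cell_size=raster.cell_size, origin=raster.origin),
        total_t=float(sum(per_class.values())),
        per_class_t=per_class,
        source=raster,
    )


@dataclass
class CarbonDelta:
    """Cellwise and aggregate carbon change between two dates (b − a)."""

    delta: FloatRaster
    total_change_t: float
    per_class_change_t: dict[int, float]


def carbon_delta(a: CarbonSurface, b: CarbonSurface) -> CarbonDelta:
    a.source.require_aligned(b.source)
    grid = b.density.grid - a.density.grid
    per_class = {
        code: b.per_class_t.get(code, 0.0) - a.per_class_t.get(code, 0.0)
        for code in sorted(set(a.per_class_t) | set(b.per_class_t))
    }
    return CarbonDelta(
        delta=FloatRaster(grid, cell_size=a.density.cell_size, origin=a.density.origin),
        total_change_t=b.total_t - a.total_t,
        per_class_change_t=per_class,
    )
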