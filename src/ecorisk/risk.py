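"""Landscape ecological risk: per-unit pattern indices and the ERI surface.

For each evaluation unit k and land class i the module computes the
standard landscape-pattern chain

    n_i  patch-count density (patches of class i per unit landscape area)
    p_i  area share A_ki / A_k
    L_i  patch-count share within the unit
    H_i  patch density (aliased to n_i; the two definitions coincide here)
    N_i  separation index  sqrt(n_i / (2 p_i))
    D_i  dominance index   0.6 L_i + 0.4 p_i
    E_i  disturbance index 0.5 H_i + 0.3 N_i + 0.2 D_i
    Y_i  normalized fragility (F_i - F_min) / (F_max - F_min), table-wide
    C_i  loss index        E_i * Y_i

and aggregates them into the landscape ecological risk index

    ERI_k = sum_i (A_ki / A_k) * C_i = sum_i p_i * C_i,

an area-weighted (convex) combination of the per-class loss indices.
Patches are connected components of same-class cells (connectivity 4 or 8)
relabelled within each unit, so a patch crossing a unit boundary counts
once in every unit it intersects and unit metrics depend only on unit
content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geodata import (
    EvaluationGrid,
    FloatRaster,
    LandClassTable,
    LandUseRaster,
)

_STRUCTS = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}

DISTURBANCE_WEIGHTS = (0.5, 0.3, 0.2)  # H, N, D
DOMINANCE_WEIGHTS = (0.6, 0.4)  # L, p


@dataclass
class PatchLabeling:
    """Connected-component labelling of same-class cell regions."""

    labels: np.ndarray  # per-cell patch id, 0 = nodata
    patch_class: np.ndarray  # class code per patch id (index 0 unused)
    patch_cells: np.ndarray  # cell count per patch id (index 0 unused)
    connectivity: int

    @property
    def n_patches(self) -> int:
        return len(self.patch_class) - 1


def label_patches(raster: LandUseRaster, connectivity: int = 8) -> PatchLabeling:
    """Label maximal same-class connected regions with dense positive ids."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCTS[connectivity]
    labels = np.zeros(raster.shape, dtype=np.int64)
    classes: list[int] = [0]
    next_id = 1
    for code in sorted(raster.class_codes):
        mask = raster.grid == code
        if not mask.any():
            continue
        lab, n = ndimage.label(mask, structure=struct)
        labels[mask] = lab[mask] + (next_id - 1)
        classes.extend([code] * n)
        next_id += n
    patch_class = np.asarray(classes, dtype=np.int64)
    patch_cells = np.bincount(labels[labels > 0], minlength=next_id)
    return PatchLabeling(
        labels=labels,
        patch_class=patch_class,
        patch_cells=patch_cells,
        connectivity=connectivity,
    )


@dataclass
class UnitMetrics:
    """Per-unit, per-class landscape metric block.

    Every attribute is an (n_units, n_classes) array; entries are zero for
    classes absent from a unit (they carry no weight in the ERI sum).
    """

    classes: np.ndarray  # class codes in column order
    area_km2: np.ndarray  # A_ki
    n_density: np.ndarray  # n_i
    area_share: np.ndarray  # p_i
    count_share: np.ndarray  # L_i
    patch_density: np.ndarray  # H_i (== n_i)
    separation: np.ndarray  # N_i
    dominance: np.ndarray  # D_i
    disturbance: np.ndarray  # E_i
    fragility_norm: np.ndarray  # Y_i (per class, broadcast over units)
    loss: np.ndarray  # C_i
    unit_area_km2: np.ndarray  # A_k
    retained: np.ndarray  # bool per unit

    def to_frame(self) -> pd.DataFrame:
        records = []
        for k in range(len(self.unit_area_km2)):
            for j, code in enumerate(self.classes):
                records.append(
                    {
                        "unit": k,
                        "class": int(code),
                        "A_ki": self.area_km2[k, j],
                        "n_i": self.n_density[k, j],
                        "p_i": self.area_share[k, j],
                        "L_i": self.count_share[k, j],
                        "H_i": self.patch_density[k, j],
                        "N_i": self.separation[k, j],
                        "D_i": self.dominance[k, j],
                        "E_i": self.disturbance[k, j],
                        "Y_i": self.fragility_norm[j],
                        "C_i": self.loss[k, j],
                    }
                )
        return pd.DataFrame.from_records(records)


def normalized_fragility(classes: LandClassTable) -> dict[int, float]:
    """Y_i = (F_i - F_min) / (F_max - F_min) over the whole class table."""
    frag = classes.fragility()
    lo, hi = min(frag.values()), max(frag.values())
    if hi == lo:
        raise ValueError("degenerate fragility table: max equals min")
    return {c: (f - lo) / (hi - lo) for c, f in frag.items()}


def unit_metrics(
    raster: LandUseRaster,
    grid: EvaluationGrid,
    classes: LandClassTable,
    connectivity: int = 8,
    min_unit_area_fraction: float = 0.5,
) -> UnitMetrics:
    """Compute the full Table-of-indices chain for every evaluation unit.

    Patches are relabelled inside each unit tile, so boundary-crossing
    patches contribute one patch to every unit they touch.  Classes absent
    from a unit get zeros throughout.  Areas are in km².
    """
    classes.validate_against(raster)
    code_list = np.asarray(sorted(raster.class_codes), dtype=np.int64)
    n_classes = len(code_list)
    n_units = grid.n_units
    cell_area = raster.cell_area_km2

    ynorm_map = normalized_fragility(classes)
    ynorm = np.asarray([ynorm_map[int(c)] for c in code_list])

    patch_count = np.zeros((n_units, n_classes))
    cell_count = np.zeros((n_units, n_classes))
    struct = _STRUCTS[connectivity]

    for k in range(n_units):
        rs, cs = grid.unit_slices(k)
        sub = raster.grid[rs, cs]
        for j, code in enumerate(code_list):
            mask = sub == code
            if not mask.any():
                continue
            _, n = ndimage.label(mask, structure=struct)
            patch_count[k, j] = n
            cell_count[k, j] = mask.sum()

    a_ki = cell_count * cell_area
    a_k = grid.area_km2
    with np.errstate(divide="ignore", invalid="ignore"):
        safe_ak = np.where(a_k > 0, a_k, np.nan)
        n_i = patch_count / safe_ak[:, None]
        p_i = a_ki / safe_ak[:, None]
        total_patches = patch_count.sum(axis=1)
        l_i = patch_count / np.where(total_patches > 0, total_patches, np.nan)[:, None]
        sep = np.sqrt(n_i / (2.0 * p_i))
    for arr in (n_i, p_i, l_i, sep):
        np.nan_to_num(arr, copy=False)
    h_i = n_i.copy()
    d_i = DOMINANCE_WEIGHTS[0] * l_i + DOMINANCE_WEIGHTS[1] * p_i
    e_i = (
        DISTURBANCE_WEIGHTS[0] * h_i
        + DISTURBANCE_WEIGHTS[1] * sep
        + DISTURBANCE_WEIGHTS[2] * d_i
    )
    present = p_i > 0
    d_i *= present
    e_i *= present
    c_i = e_i * ynorm[None, :]

    return UnitMetrics(
        classes=code_list,
        area_km2=a_ki,
        n_density=n_i,
        area_share=p_i,
        count_share=l_i,
        patch_density=h_i,
        separation=sep,
        dominance=d_i,
        disturbance=e_i,
        fragility_norm=ynorm,
        loss=c_i,
        unit_area_km2=a_k.copy(),
        retained=grid.retained(min_unit_area_fraction),
    )


@dataclass
class ERISurface:
    """Per-unit landscape ecological risk values plus raster broadcast."""

    values: np.ndarray  # ERI_k per unit (NaN where not retained)
    retained: np.ndarray
    grid: EvaluationGrid

    @property
    def n_units(self) -> int:
        return len(self.values)

    def as_raster(self) -> FloatRaster:
        return self.grid.unit_value_raster(self.values)

    def to_frame(self) -> pd.DataFrame:
        ur, uc = np.divmod(np.arange(self.n_units), self.grid.unit_cols)
        return pd.DataFrame(
            {
                "unit": np.arange(self.n_units),
                "row0": ur * self.grid.unit_size,
                "col0": uc * self.grid.unit_size,
                "A_k": self.grid.area_km2,
                "retained": self.retained,
                "eri": self.values,
            }
        )


def eri_surface(metrics: UnitMetrics, grid: EvaluationGrid) -> ERISurface:
    """ERI_k = Σ_i p_i · C_i per evaluation unit.

    Units below the retained-area threshold get NaN so sliver tiles never
    feed the classification or conflict stages.
    """
    eri = (metrics.area_share * metrics.loss).sum(axis=1)
    eri = np.where(metrics.retained, eri, np.nan)
    return ERISurface(values=eri, retained=metrics.retained.copy(), grid=grid)


def eri_pipeline(
    raster: LandUseRaster,
    grid: EvaluationGrid,
    classes: LandClassTable,
    connectivity: int = 8,
    min_unit_area_fraction: float = 0.5,
) -> tuple[UnitMetrics, ERISurface]:
    """Convenience wrapper: metrics + ERI for one raster."""
    m = unit_metrics(
        raster, grid, classes, connectivity=connectivity,
        min_unit_area_fraction=min_unit_area_fraction,
    )
    return m, eri_surface(m, grid)
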