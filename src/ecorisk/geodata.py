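"""Domain types and raster I/O shared by every pipeline stage.

The common currency is the :class:`LandUseRaster`: a single-band integer
grid whose codes index land classes (by convention 1=construction, 2=water,
3=forest, 4=grassland, 5=cropland).  Rasters are row-major, origin at the
top-left corner, addressed ``(row, col)`` 0-based; all areas are derived
from cell counts times ``cell_size**2``, never from vector geometry.

Files are written as single-band TIFF (via :mod:`tifffile`) with a JSON
sidecar (``<name>.json``) carrying the georeference — cell size, top-left
origin, nodata code and valid class codes — or as plain-text ESRI ASCII
grids (``.asc``).  Multi-raster operations require *alignment*: identical
shape, cell size and origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

DEFAULT_CLASS_CODES = frozenset({1, 2, 3, 4, 5})
DEFAULT_CLASS_NAMES = {
    1: "construction",
    2: "water",
    3: "forest",
    4: "grassland",
    5: "cropland",
}


class RasterAlignmentError(ValueError):
    """Raised when an operation receives rasters that are not aligned."""


class ClassCodeError(ValueError):
    """Raised when a raster contains codes outside the expected set."""


@dataclass(frozen=True)
class LandUseRaster:
    """Georeferenced categorical land-use grid.

    Parameters
    ----------
    grid
        2-D integer array of class codes (nodata cells carry ``nodata_code``).
    cell_size
        Edge length of a square cell in metres.
    nodata_code
        Integer marking cells outside the landscape.
    origin
        ``(x, y)`` map coordinates of the top-left corner.
    class_codes
        Valid class codes; every non-nodata cell must be a member.
    """

    grid: np.ndarray
    cell_size: float = 30.0
    nodata_code: int = 0
    origin: tuple[float, float] = (0.0, 0.0)
    class_codes: frozenset[int] = DEFAULT_CLASS_CODES

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError(f"grid must be 2-D, got shape {grid.shape}")
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValueError(f"grid must be integer-typed, got {grid.dtype}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "class_codes", frozenset(self.class_codes))
        bad = np.setdiff1d(
            np.unique(grid), sorted(self.class_codes | {self.nodata_code})
        )
        if bad.size:
            counts = {int(c): int((grid == c).sum()) for c in bad}
            raise ClassCodeError(
                f"unexpected class code(s) {counts} (code: cell count); "
                f"expected {sorted(self.class_codes)} or nodata {self.nodata_code}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def cell_area_km2(self) -> float:
        """Area of one cell in km²."""
        return (self.cell_size / 1000.0) ** 2

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata_code

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def is_aligned(self, other: "LandUseRaster | FloatRaster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_aligned(self, other: "LandUseRaster | FloatRaster") -> None:
        if not self.is_aligned(other):
            raise RasterAlignmentError(
                f"rasters not aligned: {self.shape}/{self.cell_size}/{self.origin}"
                f" vs {other.shape}/{other.cell_size}/{other.origin}"
            )

    def class_areas_km2(self) -> dict[int, float]:
        """Area of each class in km² (absent classes report 0)."""
        out = {}
        for c in sorted(self.class_codes):
            out[c] = float((self.grid == c).sum()) * self.cell_area_km2
        return out

    def with_grid(self, grid: np.ndarray) -> "LandUseRaster":
        return replace(self, grid=np.asarray(grid, dtype=self.grid.dtype))


@dataclass(frozen=True)
class FloatRaster:
    """Aligned continuous surface (ERI, carbon density, suitability, ...)."""

    grid: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_value: float = float("nan")

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        object.__setattr__(self, "grid", grid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2


@dataclass(frozen=True)
class LandClassTable:
    """Per-class fragility score and the four carbon-pool densities.

    Fragility is the ordinal vulnerability score F_i used for the normalized
    fragility Y_i; the pools are above-ground, below-ground, soil and
    dead-organic-matter carbon densities in t/km².
    """

    table: pd.DataFrame  # index = class code; columns below

    COLUMNS = ("name", "fragility", "c_above", "c_below", "c_soil", "c_dead")

    def __post_init__(self) -> None:
        t = self.table
        missing = set(self.COLUMNS) - set(t.columns)
        if missing:
            raise ValueError(f"class table missing columns {sorted(missing)}")
        if t.index.has_duplicates:
            raise ValueError("duplicate class codes in table")
        if (t["fragility"] <= 0).any():
            raise ValueError("fragility scores must be positive")
        if t["fragility"].nunique() < 2:
            raise ValueError(
                "fragility table is degenerate: need at least two distinct "
                "scores for the Y_i normalization"
            )
        pools = t[["c_above", "c_below", "c_soil", "c_dead"]]
        if (pools.to_numpy(dtype=float) < 0).any():
            raise ValueError("carbon densities must be >= 0")

    @classmethod
    def from_dict(
        cls,
        fragility: Mapping[int, float],
        pools: Mapping[int, tuple[float, float, float, float]],
        names: Mapping[int, str] | None = None,
    ) -> "LandClassTable":
        names = names or DEFAULT_CLASS_NAMES
        rows = []
        for code in sorted(fragility):
            a, b, s, d = pools[code]
            rows.append(
                {
                    "code": code,
                    "name": names.get(code, str(code)),
                    "fragility": float(fragility[code]),
                    "c_above": float(a),
                    "c_below": float(b),
                    "c_soil": float(s),
                    "c_dead": float(d),
                }
            )
        return cls(pd.DataFrame(rows).set_index("code"))

    @classmethod
    def read_csv(cls, path: str | Path) -> "LandClassTable":
        df = pd.read_csv(path)
        if "code" not in df.columns:
            raise ValueError("class table CSV must have a 'code' column")
        return cls(df.set_index("code"))

    def write_csv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, index=False)

    def codes(self) -> list[int]:
        return [int(c) for c in self.table.index]

    def fragility(self) -> dict[int, float]:
        return {int(c): float(v) for c, v in self.table["fragility"].items()}

    def carbon_density(self) -> dict[int, float]:
        """Total carbon density per class: sum of the four pools (t/km²)."""
        pools = self.table[["c_above", "c_below", "c_soil", "c_dead"]]
        return {int(c): float(v) for c, v in pools.sum(axis=1).items()}

    def validate_against(self, raster: LandUseRaster) -> None:
        missing = raster.class_codes - set(self.codes())
        if missing:
            raise ClassCodeError(
                f"raster classes {sorted(missing)} missing from class table"
            )


@dataclass
class EvaluationGrid:
    """Fishnet of square evaluation units tiling a raster from the top-left.

    ``unit_index`` assigns each cell to a unit id (row-major over unit tiles);
    edge units may be partial and are flagged.  ``area_km2[k]`` is the total
    landscape (non-nodata) area of unit k.
    """

    unit_size: int
    shape: tuple[int, int]
    unit_index: np.ndarray  # per-cell unit id
    n_units: int
    unit_rows: int
    unit_cols: int
    area_km2: np.ndarray  # per-unit landscape area
    cell_count: np.ndarray  # per-unit valid cell count
    partial: np.ndarray  # per-unit bool: tile extends past raster edge
    cell_size: float
    origin: tuple[float, float]

    def unit_slices(self, k: int) -> tuple[slice, slice]:
        ur, uc = divmod(k, self.unit_cols)
        r0, c0 = ur * self.unit_size, uc * self.unit_size
        return (
            slice(r0, min(r0 + self.unit_size, self.shape[0])),
            slice(c0, min(c0 + self.unit_size, self.shape[1])),
        )

    def retained(self, min_area_fraction: float = 0.5) -> np.ndarray:
        """Boolean mask of units with enough landscape area to be stable.

        Units whose valid-cell count falls below ``min_area_fraction`` of a
        full tile are excluded from downstream statistics.
        """
        full = self.unit_size**2 * (self.cell_size / 1000.0) ** 2
        return self.area_km2 >= min_area_fraction * full

    def unit_value_raster(self, values: np.ndarray, fill: float = np.nan) -> FloatRaster:
        """Broadcast one value per unit back onto the cell grid."""
        values = np.asarray(values, dtype=float)
        grid = np.full(self.shape, fill)
        ok = self.unit_index >= 0
        grid[ok] = values[self.unit_index[ok]]
        return FloatRaster(grid, cell_size=self.cell_size, origin=self.origin)

    def unit_centroids(self) -> np.ndarray:
        """(n_units, 2) array of unit-tile (row, col) centres in cell units."""
        ur, uc = np.divmod(np.arange(self.n_units), self.unit_cols)
        return np.stack(
            [(ur + 0.5) * self.unit_size, (uc + 0.5) * self.unit_size], axis=1
        )


def build_evaluation_grid(raster: LandUseRaster, unit_size: int) -> EvaluationGrid:
    """Tile ``raster`` into square evaluation units of ``unit_size`` cells.

    Units tile from the top-left corner; units at the right/bottom edges may
    be partial (flagged).  Nodata cells belong to no unit and contribute no
    area.
    """
    if unit_size < 2:
        raise ValueError("unit_size must be >= 2 cells")
    rows, cols = raster.shape
    if unit_size > rows and unit_size > cols:
        raise ValueError(
            f"unit_size {unit_size} exceeds both raster dimensions {raster.shape}"
        )
    unit_rows = -(-rows // unit_size)
    unit_cols = -(-cols // unit_size)
    n_units = unit_rows * unit_cols

    rr, cc = np.indices((rows, cols))
    unit_index = (rr // unit_size) * unit_cols + (cc // unit_size)
    unit_index = unit_index.astype(np.int64)
    unit_index[~raster.valid_mask] = -1

    cell_count = np.bincount(unit_index[unit_index >= 0], minlength=n_units)
    area = cell_count.astype(float) * raster.cell_area_km2

    ur = np.arange(n_units) // unit_cols
    uc = np.arange(n_units) % unit_cols
    partial = ((ur + 1) * unit_size > rows) | ((uc + 1) * unit_size > cols)

    return EvaluationGrid(
        unit_size=unit_size,
        shape=(rows, cols),
        unit_index=unit_index,
        n_units=n_units,
        unit_rows=unit_rows,
        unit_cols=unit_cols,
        area_km2=area,
        cell_count=cell_count,
        partial=partial,
        cell_size=raster.cell_size,
        origin=raster.origin,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (serialized as YAML)."""

    unit_size: int = 10
    connectivity: int = 8  # 4 or 8
    classification_mode: str = "jenks"  # "jenks" | "fixed"
    fixed_breaks: tuple[float, ...] | None = None
    permutations: int = 999
    seed: int = 0
    weights_scheme: str = "queen"  # "rook" | "queen"
    weights_standardization: str = "row"  # "binary" | "row"
    alpha: float = 0.05
    min_unit_area_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.classification_mode not in ("jenks", "fixed"):
            raise ValueError("classification_mode must be 'jenks' or 'fixed'")
        if self.weights_scheme not in ("rook", "queen"):
            raise ValueError("weights_scheme must be 'rook' or 'queen'")
        if self.weights_standardization not in ("binary", "row"):
            raise ValueError("weights_standardization must be 'binary' or 'row'")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "fixed_breaks" in data and data["fixed_breaks"] is not None:
            data["fixed_breaks"] = tuple(data["fixed_breaks"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_landuse_raster(raster: LandUseRaster, path: str | Path) -> None:
    """Write a categorical raster as single-band TIFF + JSON georeference,
    or as an ESRI ASCII grid if the path ends in ``.asc``."""
    path = Path(path)
    if path.suffix == ".asc":
        _write_ascii_grid(
            raster.grid, path, raster.cell_size, raster.origin, raster.nodata_code
        )
        meta = {
            "class_codes": sorted(raster.class_codes),
        }
        _sidecar(path).write_text(json.dumps(meta))
        return
    tifffile.imwrite(path, raster.grid.astype(np.int32))
    meta = {
        "cell_size": raster.cell_size,
        "origin": list(raster.origin),
        "nodata_code": raster.nodata_code,
        "class_codes": sorted(raster.class_codes),
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_landuse_raster(
    path: str | Path, expected_codes: Iterable[int] | None = None
) -> LandUseRaster:
    """Read a single-band integer raster written by :func:`write_landuse_raster`.

    Cells carrying codes outside ``expected_codes`` plus the nodata code raise
    :class:`ClassCodeError` naming the offending codes and their cell counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".asc":
        grid, cell_size, origin, nodata = _read_ascii_grid(path)
        side = _sidecar(path)
        codes = None
        if side.exists():
            codes = json.loads(side.read_text()).get("class_codes")
    else:
        grid = tifffile.imread(path)
        if not np.issubdtype(grid.dtype, np.integer):
            if np.any(grid != np.round(grid)):
                raise ValueError(f"{path} is not an integer band")
            grid = grid.astype(np.int64)
        side = _sidecar(path)
        if side.exists():
            meta = json.loads(side.read_text())
            cell_size = meta.get("cell_size", 30.0)
            origin = tuple(meta.get("origin", (0.0, 0.0)))
            nodata = meta.get("nodata_code", 0)
            codes = meta.get("class_codes")
        else:
            cell_size, origin, nodata, codes = 30.0, (0.0, 0.0), 0, None
    if expected_codes is not None:
        codes = set(expected_codes)
    elif codes is not None:
        codes = set(codes)
    else:
        codes = set(np.unique(grid[grid != nodata]).tolist())
    return LandUseRaster(
        grid=np.asarray(grid, dtype=np.int32),
        cell_size=cell_size,
        origin=origin,
        nodata_code=nodata,
        class_codes=frozenset(int(c) for c in codes),
    )


def write_float_raster(surface: FloatRaster, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".asc":
        _write_ascii_grid(surface.grid, path, surface.cell_size, surface.origin, -9999)
        return
    tifffile.imwrite(path, surface.grid.astype(np.float32))
    meta = {"cell_size": surface.cell_size, "origin": list(surface.origin)}
    _sidecar(path).write_text(json.dumps(meta))


def read_float_raster(path: str | Path) -> FloatRaster:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".asc":
        grid, cell_size, origin, nodata = _read_ascii_grid(path)
        grid = grid.astype(float)
        grid[grid == nodata] = np.nan
        return FloatRaster(grid, cell_size=cell_size, origin=origin)
    grid = tifffile.imread(path).astype(np.float64)
    side = _sidecar(path)
    cell_size, origin = 30.0, (0.0, 0.0)
    if side.exists():
        meta = json.loads(side.read_text())
        cell_size = meta.get("cell_size", 30.0)
        origin = tuple(meta.get("origin", (0.0, 0.0)))
    return FloatRaster(grid, cell_size=cell_size, origin=origin)


def _write_ascii_grid(grid, path, cell_size, origin, nodata) -> None:
    rows, cols = grid.shape
    x0, y0 = origin
    # ESRI convention anchors at the lower-left corner
    yll = y0 - rows * cell_size
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner {x0}\nyllcorner {yll}\n"
        f"cellsize {cell_size}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt="%d" if np.issubdtype(grid.dtype, np.integer) else "%.8g")


def _read_ascii_grid(path: Path):
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline().split()
            if len(line) != 2 or not line[0][0].isalpha():
                fh.seek(pos)
                break
            header[line[0].lower()] = float(line[1])
            pos = fh.tell()
        data = np.loadtxt(fh)
    rows = int(header.get("nrows", data.shape[0]))
    cols = int(header.get("ncols", data.shape[1] if data.ndim > 1 else data.size))
    grid = data.reshape(rows, cols)
    cell_size = header.get("cellsize", 30.0)
    x0 = header.get("xllcorner", 0.0)
    y0 = header.get("yllcorner", 0.0) + rows * cell_size
    nodata = header.get("nodata_value", -9999)
    if np.all(grid == np.round(grid)):
        grid = grid.astype(np.int64)
        nodata = int(nodata)
    return grid, cell_size, (x0, y0), nodata
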