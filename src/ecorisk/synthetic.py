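"""Synthetic multi-temporal landscapes with known ground truth.

Every downstream stage is tested against landscapes produced here: patchy
categorical land-use maps with controlled class proportions and spatial
smoothness, cell-wise Markov evolution with a known transition matrix, and
spatially autocorrelated continuous driver surfaces (stand-ins for DEM,
slope, population density, GDP and road distance).

Landscapes are synthesized by thresholding a smoothed Gaussian random
latent field at the quantiles of the requested class proportions: a short
correlation length yields salt-and-pepper mosaics, a long one yields large
contiguous patches, and realized proportions track the request closely on
grids of 200x200 and up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geodata import DEFAULT_CLASS_CODES, LandUseRaster


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic multi-temporal landscape.

    Attributes
    ----------
    shape
        (rows, cols) of the grid; each dimension must be >= 10.
    proportions
        Target class-area shares over the 5 classes, summing to 1.
    smoothness
        Correlation length of the latent field in cells (>= 0); 0 gives
        spatially independent cells.
    transition
        True 5x5 row-stochastic one-step transition matrix P_true.
    n_steps
        Number of evolution steps to generate beyond t0.
    seed
        Master seed; all generators are deterministic given it.
    """

    shape: tuple[int, int] = (200, 200)
    proportions: tuple[float, ...] = (0.18, 0.10, 0.30, 0.17, 0.25)
    smoothness: float = 12.0
    transition: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.96, 0.00, 0.01, 0.01, 0.02],
                [0.02, 0.95, 0.01, 0.01, 0.01],
                [0.03, 0.00, 0.93, 0.02, 0.02],
                [0.05, 0.00, 0.03, 0.89, 0.03],
                [0.07, 0.00, 0.02, 0.02, 0.89],
            ]
        )
    )
    n_steps: int = 2
    seed: int = 0
    #: 1 km cells keep patch-count densities (patches/km²) on the unit
    #: scale that the shipped fixed risk breakpoints presume
    cell_size: float = 1000.0

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.size != 5 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be 5 non-negative values summing to 1")
        if min(self.shape) < 10:
            raise ValueError("degenerate spec: each dimension must be >= 10")
        if self.smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        _check_stochastic(np.asarray(self.transition, dtype=float))


def _check_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape != (5, 5):
        raise ValueError("transition matrix must be 5x5")
    if (P < 0).any() or np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    return P


def largest_remainder_round(targets: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative ``targets`` to integers summing exactly to ``total``.

    Floors every entry, then hands the remaining units to the largest
    fractional parts (ties broken by index order).
    """
    targets = np.asarray(targets, dtype=float)
    floors = np.floor(targets).astype(np.int64)
    short = int(total - floors.sum())
    if short < 0:
        raise ValueError("targets exceed total")
    frac = targets - floors
    for idx in np.argsort(-frac, kind="stable")[:short]:
        floors[idx] += 1
    return floors


def _smooth_field(shape, smoothness, rng) -> np.ndarray:
    z = rng.standard_normal(shape)
    if smoothness > 0:
        z = ndimage.gaussian_filter(z, sigma=smoothness, mode="reflect")
    return z


def generate_landscape(spec: SyntheticSpec) -> LandUseRaster:
    """Draw one categorical landscape from ``spec``.

    A Gaussian latent field with correlation length ``spec.smoothness`` is
    thresholded at the quantiles of the cumulative class proportions, so the
    realized shares match the target (exactly, up to rank ties) while the
    class regions inherit the field's spatial contiguity.
    """
    rng = np.random.default_rng(spec.seed)
    z = _smooth_field(spec.shape, spec.smoothness, rng)
    p = np.asarray(spec.proportions, dtype=float)
    n = z.size
    counts = largest_remainder_round(p * n, n)
    # rank-based thresholding: the lowest counts[0] cells of the latent
    # field become class 1, the next counts[1] class 2, and so on; exact
    # shares, contiguity inherited from the field
    order = np.argsort(z, axis=None, kind="stable")
    flat = np.empty(n, dtype=np.int32)
    flat[order] = np.repeat(np.arange(1, 6, dtype=np.int32), counts)
    grid = flat.reshape(spec.shape)
    present = frozenset(np.unique(grid).tolist()) | DEFAULT_CLASS_CODES
    return LandUseRaster(
        grid=grid,
        cell_size=spec.cell_size,
        nodata_code=0,
        class_codes=present,
    )


def evolve_landscape(
    raster: LandUseRaster,
    transition: np.ndarray,
    seed: int,
    frozen: np.ndarray | None = None,
) -> LandUseRaster:
    """Redraw each cell's class from the transition-matrix row of its
    current class (cell-independent Markov step).

    ``frozen`` is an optional boolean mask of cells that keep their class
    (e.g. water under a restriction policy).
    """
    P = _check_stochastic(transition)
    rng = np.random.default_rng(seed)
    grid = raster.grid
    out = grid.copy()
    valid = raster.valid_mask
    if frozen is not None:
        valid = valid & ~np.asarray(frozen, dtype=bool)
    u = rng.random(grid.shape)
    cdf = np.cumsum(P, axis=1)
    cdf[:, -1] = 1.0  # guard against cumulative round-off
    for code in range(1, 6):
        sel = valid & (grid == code)
        if not sel.any():
            continue
        out[sel] = np.searchsorted(cdf[code - 1], u[sel], side="left") + 1
    return raster.with_grid(out)


def generate_drivers(
    raster: LandUseRaster, k: int, smoothness: float, seed: int
) -> np.ndarray:
    """``k`` aligned continuous driver surfaces, each a smoothed Gaussian
    field min-max scaled to [0, 1].  Returns an array of shape (k, rows, cols).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((k,) + raster.shape)
    for i in range(k):
        z = _smooth_field(raster.shape, smoothness, rng)
        lo, hi = z.min(), z.max()
        out[i] = (z - lo) / (hi - lo) if hi > lo else np.zeros_like(z)
    return out


def generate_fixture_set(spec: SyntheticSpec, n_drivers: int = 5) -> dict:
    """A complete test fixture: t0..t_n land-use rasters evolved with the
    spec's true transition matrix, driver surfaces, and the spec itself."""
    rasters = [generate_landscape(spec)]
    for step in range(spec.n_steps):
        rasters.append(
            evolve_landscape(rasters[-1], spec.transition, seed=spec.seed + 1 + step)
        )
    drivers = generate_drivers(
        rasters[0], n_drivers, smoothness=max(spec.smoothness, 5.0),
        seed=spec.seed + 1000,
    )
    return {"rasters": rasters, "drivers": drivers, "spec": spec}
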