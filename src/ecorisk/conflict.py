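"""Bivariate spatial autocorrelation between carbon density and risk.

The conflict stage asks where high carbon stock sits next to high
landscape ecological risk.  For unit values x_h (carbon density) and x_k
(risk) on a fishnet with spatial weights W, the global bivariate Moran
statistic is

    I_hk = n · Σ_i Σ_j W_ij · z_h(i) · z_k(j) / ((n − 1) · Σ_i Σ_j W_ij),

with z the variable centred by its mean and scaled by its population
standard deviation, and the local statistic is

    I_i = z_h(i) · Σ_j W_ij · z_k(j),

the unit's own (standardized) carbon level times the spatial lag of risk
at its neighbours.  Significance comes from conditional permutation: unit
i keeps its own values while its neighbours' risk values are redrawn from
the remaining units without replacement.  Significant units are labelled
by sign quadrant — high–high (the conflict hotspot: high carbon adjacent
to high risk), low–low, high–low, low–high — and the rest not-significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .geodata import EvaluationGrid, FloatRaster

LABELS = ("not-significant", "high-high", "low-low", "high-low", "low-high")
LABEL_CODES = {name: i for i, name in enumerate(LABELS)}


@dataclass
class SpatialWeights:
    """Sparse contiguity weights over fishnet units."""

    W: sparse.csr_matrix
    scheme: str  # "rook" | "queen"
    standardization: str  # "binary" | "row"
    ids: np.ndarray  # unit ids the rows refer to (islands excluded)
    island_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def cardinalities(self) -> np.ndarray:
        return np.diff(self.W.indptr)


def build_weights(
    grid: EvaluationGrid,
    scheme: str = "queen",
    standardization: str = "row",
    retained: np.ndarray | None = None,
) -> SpatialWeights:
    """Contiguity weights from the fishnet layout.

    ``retained`` restricts the graph to a subset of units (e.g. those with
    enough landscape area); units left with no neighbour are flagged
    islands and excluded.
    """
    if scheme not in ("rook", "queen"):
        raise ValueError("scheme must be 'rook' or 'queen'")
    if standardization not in ("binary", "row"):
        raise ValueError("standardization must be 'binary' or 'row'")
    nr, nc = grid.unit_rows, grid.unit_cols
    if nr * nc < 2:
        raise ValueError("need at least 2 units")
    keep = np.ones(grid.n_units, dtype=bool) if retained is None else np.asarray(retained, dtype=bool)

    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows_idx, cols_idx = [], []
    ur, uc = np.divmod(np.arange(grid.n_units), nc)
    for dr, dc in offsets:
        nr_, nc_ = ur + dr, uc + dc
        ok = (nr_ >= 0) & (nr_ < nr) & (nc_ >= 0) & (nc_ < nc)
        src = np.flatnonzero(ok)
        dst = nr_[ok] * nc + nc_[ok]
        sel = keep[src] & keep[dst]
        rows_idx.append(src[sel])
        cols_idx.append(dst[sel])
    rows_idx = np.concatenate(rows_idx)
    cols_idx = np.concatenate(cols_idx)

    # relabel to the retained subset
    kept_ids = np.flatnonzero(keep)
    remap = -np.ones(grid.n_units, dtype=np.int64)
    remap[kept_ids] = np.arange(len(kept_ids))
    W = sparse.coo_matrix(
        (np.ones(len(rows_idx)), (remap[rows_idx], remap[cols_idx])),
        shape=(len(kept_ids), len(kept_ids)),
    ).tocsr()

    card = np.asarray(W.sum(axis=1)).ravel()
    islands = card == 0
    if islands.all():
        raise ValueError("all units are islands")
    if islands.any():
        ok = ~islands
        W = W[ok][:, ok]
        island_ids = kept_ids[islands]
        kept_ids = kept_ids[ok]
    else:
        island_ids = np.array([], dtype=np.int64)

    if standardization == "row":
        inv = 1.0 / np.asarray(W.sum(axis=1)).ravel()
        W = sparse.diags(inv) @ W
        W = W.tocsr()
    return SpatialWeights(
        W=W, scheme=scheme, standardization=standardization,
        ids=kept_ids, island_ids=island_ids,
    )


def _zscore(x: np.ndarray, ddof: int = 0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero variance: degenerate input to Moran statistic")
    return (x - x.mean()) / sd


@dataclass
class BivariateMoranResult:
    """Global + local bivariate Moran statistics with permutation inference."""

    I_global: float
    local: np.ndarray  # I_i per retained unit
    p_local: np.ndarray  # conditional-permutation two-sided pseudo p-values
    p_global: float
    z_h: np.ndarray
    z_k: np.ndarray
    lag_k: np.ndarray  # spatial lag of z_k
    weights: SpatialWeights
    permutations: int
    seed: int


def bivariate_moran(
    x_h: np.ndarray,
    x_k: np.ndarray,
    weights: SpatialWeights,
    permutations: int = 999,
    seed: int = 0,
    ddof: int = 0,
) -> BivariateMoranResult:
    """Global and local bivariate Moran's I with permutation p-values.

    ``x_h`` plays the focal role (value at unit i), ``x_k`` the neighbour
    role (spatially lagged).  Scale parameters are population standard
    deviations by default (``ddof=0``); pass ``ddof=1`` for the sample
    convention.  Deterministic given ``seed``.
    """
    x_h = np.asarray(x_h, dtype=float)
    x_k = np.asarray(x_k, dtype=float)
    n = weights.n
    if len(x_h) != n or len(x_k) != n:
        raise ValueError("variable length must match number of weight units")
    if n < 4:
        raise ValueError("need at least 4 units")
    z_h = _zscore(x_h, ddof)
    z_k = _zscore(x_k, ddof)
    W = weights.W
    s0 = W.sum()
    lag_k = W @ z_k
    local = z_h * lag_k
    I_obs = n * float(z_h @ lag_k) / ((n - 1) * s0)

    rng = np.random.default_rng(seed)

    # global inference: full permutation of the neighbour variable
    perm_I = np.empty(permutations)
    for b in range(permutations):
        zp = z_k[rng.permutation(n)]
        perm_I[b] = n * float(z_h @ (W @ zp)) / ((n - 1) * s0)
    p_global = (np.count_nonzero(np.abs(perm_I) >= abs(I_obs)) + 1) / (
        permutations + 1
    )

    # local inference: conditional permutation — hold unit i, redraw its
    # neighbours' k-values from the other n-1 units without replacement
    card = weights.cardinalities()
    k_max = int(card.max())
    straws = np.empty((permutations, k_max), dtype=np.int64)
    for b in range(permutations):
        straws[b] = rng.permutation(n - 1)[:k_max]
    p_local = np.empty(n)
    indptr, indices, data = W.indptr, W.indices, W.data
    others = np.arange(n - 1)
    for i in range(n):
        c = int(card[i])
        if c == 0:
            p_local[i] = 1.0
            continue
        idsi = np.delete(np.arange(n), i)
        draw = idsi[straws[:, :c]]  # (permutations, c)
        w_i = data[indptr[i]:indptr[i + 1]]
        lag_star = z_k[draw] @ w_i
        local_star = z_h[i] * lag_star
        p_local[i] = (np.count_nonzero(np.abs(local_star) >= abs(local[i])) + 1) / (
            permutations + 1
        )

    return BivariateMoranResult(
        I_global=I_obs,
        local=local,
        p_local=p_local,
        p_global=float(p_global),
        z_h=z_h,
        z_k=z_k,
        lag_k=lag_k,
        weights=weights,
        permutations=permutations,
        seed=seed,
    )


def lisa_labels(result: BivariateMoranResult, alpha: float = 0.05) -> np.ndarray:
    """Cluster label per unit from the sign quadrant of (z_h, lag z_k).

    Returns an array of label strings; units with p > alpha are
    "not-significant".  High–high units are the carbon–risk conflict
    hotspots.
    """
    z_h, lag = result.z_h, result.lag_k
    labels = np.full(result.weights.n, "not-significant", dtype=object)
    sig = result.p_local <= alpha
    hh = sig & (z_h > 0) & (lag > 0)
    ll = sig & (z_h < 0) & (lag < 0)
    hl = sig & (z_h > 0) & (lag < 0)
    lh = sig & (z_h < 0) & (lag > 0)
    labels[hh] = "high-high"
    labels[ll] = "low-low"
    labels[hl] = "high-low"
    labels[lh] = "low-high"
    return labels


@dataclass
class ConflictReport:
    """Label counts, areas and landscape shares; hotspot = high–high."""

    table: pd.DataFrame  # label, count, area_km2, percent
    hotspot_share: float  # % of analysed landscape in high-high units
    label_raster: FloatRaster  # integer label codes broadcast to cells


def conflict_summary(
    labels: np.ndarray, result: BivariateMoranResult, grid: EvaluationGrid
) -> ConflictReport:
    """Aggregate LISA labels into counts, areas and percentage shares."""
    ids = result.weights.ids
    areas = grid.area_km2[ids]
    total = areas.sum()
    rows = []
    for name in LABELS:
        sel = labels == name
        rows.append(
            {
                "label": name,
                "count": int(sel.sum()),
                "area_km2": float(areas[sel].sum()),
                "percent": 100.0 * float(areas[sel].sum()) / total if total else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    hotspot = float(table.loc[table["label"] == "high-high", "percent"].iloc[0])

    unit_codes = np.full(grid.n_units, np.nan)
    unit_codes[ids] = [LABEL_CODES[l] for l in labels]
    return ConflictReport(
        table=table,
        hotspot_share=hotspot,
        label_raster=grid.unit_value_raster(unit_codes),
    )
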