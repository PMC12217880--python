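"""Markov/cellular-automata land-use scenario simulation.

The stage mirrors a patch-generating land-use simulation at desk scale:

1. *Demand*: a Markov transition matrix estimated from two observed dates
   (cellwise cross-tabulation) gives next-step class demand.
2. *Scenario adjustment*: a named scenario multiplies selected transition
   probabilities by (1 ± D) and rescales the remaining entries of the row
   by a common factor X so the row still sums to one.
3. *Suitability*: a probabilistic classifier (random forest) maps driver
   surfaces to per-class membership probabilities.
4. *Allocation*: a transparent greedy cellular automaton converts the
   best-scoring permitted cells (suitability × 3×3 neighbourhood
   enrichment) until each class meets its demand, honouring a binary
   transfer-cost matrix and a frozen-cell restriction mask.
5. *Validation*: overall accuracy and Cohen's kappa against an observed
   map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .geodata import LandUseRaster
from .presets import SCENARIO_ADJUSTMENTS, TRANSFER_COST
from .synthetic import largest_remainder_round

N_CLASSES = 5
CODES = np.arange(1, N_CLASSES + 1)


@dataclass
class TransitionModel:
    """Markov demand model plus scenario constraints."""

    P: np.ndarray  # 5x5 row-stochastic one-step matrix
    transfer_cost: np.ndarray = field(
        default_factory=lambda: np.ones((N_CLASSES, N_CLASSES), dtype=np.int8)
    )
    restriction_mask: np.ndarray | None = None  # True = frozen cell
    step_years: float = 2.0

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("P must be 5x5")
        if (P < 0).any() or np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("P rows must be non-negative and sum to 1")
        M = np.asarray(self.transfer_cost)
        if (np.diag(M) != 1).any():
            raise ValueError("transfer-cost diagonal must be 1 (staying permitted)")
        self.P = P

    def constrained_P(self) -> np.ndarray:
        """P with forbidden transitions zeroed and rows renormalized."""
        P = self.P * (self.transfer_cost != 0)
        rows = P.sum(axis=1)
        for i in range(N_CLASSES):
            if rows[i] <= 0:
                P[i] = 0.0
                P[i, i] = 1.0
            else:
                P[i] /= rows[i]
        return P


@dataclass(frozen=True)
class ScenarioSpec:
    """Named scenario: list of (source, target, direction, D) adjustments."""

    name: str
    adjustments: tuple[tuple[int, int, str, float], ...] = ()

    def __post_init__(self) -> None:
        for s, t, direction, d in self.adjustments:
            if s == t:
                raise ValueError("adjustment source must differ from target")
            if direction not in ("raise", "reduce"):
                raise ValueError("direction must be 'raise' or 'reduce'")
            if not (0.0 < d < 1.0):
                raise ValueError("magnitude D must lie in (0, 1)")

    @classmethod
    def preset(cls, name: str) -> "ScenarioSpec":
        return cls(name=name, adjustments=tuple(SCENARIO_ADJUSTMENTS[name]))


def scenario_transfer_cost(name: str) -> np.ndarray:
    return TRANSFER_COST[name].copy()


# ---------------------------------------------------------------------------
# Markov demand
# ---------------------------------------------------------------------------


def cross_tabulate(t0: LandUseRaster, t1: LandUseRaster) -> np.ndarray:
    """5x5 count matrix of class transitions between two aligned dates."""
    t0.require_aligned(t1)
    both = t0.valid_mask & t1.valid_mask
    if not both.any():
        raise ValueError("no overlapping valid cells")
    a = t0.grid[both].astype(np.int64) - 1
    b = t1.grid[both].astype(np.int64) - 1
    return np.bincount(a * N_CLASSES + b, minlength=N_CLASSES**2).reshape(
        N_CLASSES, N_CLASSES
    ).astype(float)


def estimate_transition_matrix(
    t0: LandUseRaster, t1: LandUseRaster, **model_kwargs
) -> TransitionModel:
    """Maximum-likelihood Markov matrix: P[i,j] = n(i→j) / n(i at t0).

    Classes absent at t0 get identity rows (no evidence, no movement).
    """
    counts = cross_tabulate(t0, t1)
    totals = counts.sum(axis=1)
    P = np.eye(N_CLASSES)
    nonzero = totals > 0
    P[nonzero] = counts[nonzero] / totals[nonzero, None]
    return TransitionModel(P=P, **model_kwargs)


def adjust_scenario(P: np.ndarray, spec: ScenarioSpec) -> np.ndarray:
    """Apply multiplicative scenario adjustments with row renormalization.

    For each adjustment on row s targeting t the entry becomes
    p'_st = p_st·(1+D) (raise) or p_st·(1−D) (reduce), clipped to [0, 1];
    the remaining entries of the row are rescaled by the common factor
    X = (1 − Σ adjusted) / (Σ unadjusted) so the row sums to one again.
    Rows with several adjustments apply them jointly before rescaling.
    """
    P = np.asarray(P, dtype=float).copy()
    by_row: dict[int, list[tuple[int, str, float]]] = {}
    for s, t, direction, d in spec.adjustments:
        by_row.setdefault(s - 1, []).append((t - 1, direction, d))
    for row, adjs in by_row.items():
        p = P[row].copy()
        adjusted_cols = []
        for col, direction, d in adjs:
            factor = 1.0 + d if direction == "raise" else 1.0 - d
            p[col] = min(max(p[col] * factor, 0.0), 1.0)
            adjusted_cols.append(col)
        adj_mask = np.zeros(N_CLASSES, dtype=bool)
        adj_mask[adjusted_cols] = True
        adj_sum = p[adj_mask].sum()
        rest_sum = P[row][~adj_mask].sum()
        if adj_sum > 1.0 + 1e-12:
            raise ValueError(
                f"scenario {spec.name!r}: adjusted entries of row {row + 1} "
                f"sum to {adj_sum:.4f} > 1"
            )
        if rest_sum > 0:
            X = (1.0 - adj_sum) / rest_sum
            p[~adj_mask] = P[row][~adj_mask] * X
        elif abs(adj_sum - 1.0) > 1e-9:
            raise ValueError(
                f"scenario {spec.name!r}: row {row + 1} has no mass to rescale"
            )
        P[row] = p
    return P


def demand_from_matrix(
    t0: LandUseRaster, P: np.ndarray, frozen: np.ndarray | None = None
) -> np.ndarray:
    """Integer class demand for the next step.

    The Markov step counts(t0) @ P runs over unrestricted cells only;
    frozen cells keep their class and enter the demand as fixed counts.
    Largest-remainder rounding makes Σ demand equal the valid cell count.
    """
    valid = t0.valid_mask
    if frozen is None:
        frozen = np.zeros(t0.shape, dtype=bool)
    else:
        frozen = np.asarray(frozen, dtype=bool)
    free = valid & ~frozen
    counts_free = np.array([(t0.grid[free] == c).sum() for c in CODES], dtype=float)
    counts_frozen = np.array(
        [(t0.grid[valid & frozen] == c).sum() for c in CODES], dtype=np.int64
    )
    target = counts_free @ np.asarray(P, dtype=float)
    return counts_frozen + largest_remainder_round(target, int(counts_free.sum()))


# ---------------------------------------------------------------------------
# Suitability
# ---------------------------------------------------------------------------

MIN_CLASS_SAMPLES = 10


def fit_suitability(
    t0: LandUseRaster,
    t1: LandUseRaster,
    drivers: np.ndarray,
    seed: int,
    max_samples: int = 20_000,
) -> np.ndarray:
    """Per-class membership-probability surfaces from driver rasters.

    A random forest is trained on sampled cells (driver vector → class at
    t1) and evaluated over the whole grid.  Classes with fewer than
    ``MIN_CLASS_SAMPLES`` training cells get a uniform surface (with a
    warning).  Returns an array of shape (5, rows, cols); per-cell
    probabilities sum to one.
    """
    t0.require_aligned(t1)
    drivers = np.asarray(drivers, dtype=float)
    if drivers.ndim != 3 or drivers.shape[1:] != t0.shape:
        raise ValueError("drivers must be a (k, rows, cols) stack aligned with t0")
    valid = t1.valid_mask
    rows, cols = t0.shape
    X_all = drivers.reshape(len(drivers), -1).T
    y_all = t1.grid.ravel()
    idx = np.flatnonzero(valid.ravel())
    rng = np.random.default_rng(seed)
    if len(idx) > max_samples:
        idx = rng.choice(idx, size=max_samples, replace=False)
    X, y = X_all[idx], y_all[idx]

    class_counts = {int(c): int((y == c).sum()) for c in CODES}
    trainable = [c for c, n in class_counts.items() if n >= MIN_CLASS_SAMPLES]
    starved = [c for c in class_counts if c not in trainable]
    if starved:
        warnings.warn(
            f"classes {starved} have < {MIN_CLASS_SAMPLES} training cells; "
            "assigning uniform suitability",
            stacklevel=2,
        )
    if len(trainable) < 2:
        raise ValueError("need at least 2 classes with enough samples at t1")

    keep = np.isin(y, trainable)
    clf = RandomForestClassifier(
        n_estimators=60, min_samples_leaf=5, random_state=int(seed) % (2**32),
        n_jobs=1,
    )
    clf.fit(X[keep], y[keep])
    proba = clf.predict_proba(X_all)  # (n_cells, n_trainable)
    stack = np.zeros((N_CLASSES, rows * cols))
    for j, c in enumerate(clf.classes_):
        stack[int(c) - 1] = proba[:, j]
    for c in starved:
        stack[c - 1] = 1.0 / N_CLASSES
    stack /= stack.sum(axis=0, keepdims=True)
    return stack.reshape(N_CLASSES, rows, cols)


# ---------------------------------------------------------------------------
# Allocation CA
# ---------------------------------------------------------------------------


@dataclass
class AllocationResult:
    raster: LandUseRaster
    demand: np.ndarray
    achieved: np.ndarray
    shortfall: np.ndarray  # demand − achieved where candidates ran out
    log: pd.DataFrame


def _neighbour_fraction(grid: np.ndarray, code: int) -> np.ndarray:
    """Fraction of the 3×3 window (centre excluded) holding ``code``."""
    is_c = (grid == code).astype(float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    hits = ndimage.convolve(is_c, kernel, mode="constant", cval=0.0)
    cnt = ndimage.convolve(np.ones_like(is_c), kernel, mode="constant", cval=0.0)
    return hits / cnt


def allocate(
    t0: LandUseRaster,
    model: TransitionModel,
    suitability: np.ndarray,
    spec: ScenarioSpec,
    seed: int,
) -> AllocationResult:
    """Greedy CA allocation of scenario-adjusted Markov demand.

    Demand per class is counts(t0) @ adjust_scenario(P).  Classes above
    demand donate cells; classes below demand claim the best-scoring
    permitted cells, ranked by suitability × (neighbourhood enrichment + ε)
    with seeded jitter breaking ties.  Frozen cells never change and the
    transfer-cost matrix gates every conversion.  Infeasible demand is
    allocated as far as possible and the shortfall reported.
    """
    P_adj = adjust_scenario(model.P, spec)
    grid = t0.grid.copy()
    valid = t0.valid_mask
    frozen = np.zeros(t0.shape, dtype=bool)
    if model.restriction_mask is not None:
        frozen = np.asarray(model.restriction_mask, dtype=bool)
    demand = demand_from_matrix(t0, P_adj, frozen=frozen)
    M = np.asarray(model.transfer_cost) != 0
    rng = np.random.default_rng(seed)

    counts = np.array([(grid == c)[valid].sum() for c in CODES], dtype=np.int64)
    converted = np.zeros(t0.shape, dtype=bool)
    log_rows = []

    # classes needing gain, largest deficit first: they compete for donors
    deficits = demand - counts
    order = np.argsort(-deficits)
    eps = 1e-6
    for j in order:
        need = int(demand[j] - counts[j])
        if need <= 0:
            continue
        target_code = int(CODES[j])
        enrich = _neighbour_fraction(t0.grid, target_code)
        score = suitability[j] * (enrich + eps)
        score = score + rng.random(score.shape) * 1e-12  # seeded tie-break
        donor_ok = np.zeros(t0.shape, dtype=bool)
        for i in range(N_CLASSES):
            if i == j or not M[i, j]:
                continue
            if counts[i] > demand[i]:  # donor has surplus
                donor_ok |= grid == CODES[i]
        cand = donor_ok & valid & ~frozen & ~converted
        cand_idx = np.flatnonzero(cand.ravel())
        if not len(cand_idx):
            log_rows.append((spec.name, target_code, need, 0))
            continue
        ranked = cand_idx[np.argsort(-score.ravel()[cand_idx], kind="stable")]
        taken = 0
        flat = grid.ravel()
        conv_flat = converted.ravel()
        for cell in ranked:
            if taken >= need:
                break
            src = int(flat[cell]) - 1
            if counts[src] <= demand[src]:  # donor exhausted its surplus
                continue
            flat[cell] = target_code
            conv_flat[cell] = True
            counts[src] -= 1
            counts[j] += 1
            taken += 1
        log_rows.append((spec.name, target_code, need, taken))

    achieved = np.array([(grid == c)[valid].sum() for c in CODES], dtype=np.int64)
    log = pd.DataFrame(
        log_rows, columns=["scenario", "target_class", "need", "converted"]
    )
    return AllocationResult(
        raster=t0.with_grid(grid),
        demand=demand,
        achieved=achieved,
        shortfall=np.maximum(demand - achieved, 0),
        log=log,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class AccuracyReport:
    """Confusion-matrix agreement between simulated and observed maps."""

    confusion: np.ndarray  # rows = observed, cols = simulated
    overall_accuracy: float
    kappa: float

    @classmethod
    def from_confusion(cls, confusion: np.ndarray) -> "AccuracyReport":
        c = np.asarray(confusion, dtype=float)
        total = c.sum()
        if total <= 0:
            raise ValueError("empty confusion matrix")
        p_o = np.trace(c) / total
        p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total**2
        kappa = 1.0 if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
        return cls(confusion=c, overall_accuracy=float(p_o), kappa=float(kappa))


def validate_simulation(
    simulated: LandUseRaster, observed: LandUseRaster
) -> AccuracyReport:
    """Overall accuracy and Cohen's kappa over jointly valid cells."""
    counts = cross_tabulate(observed, simulated)
    return AccuracyReport.from_confusion(counts)
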