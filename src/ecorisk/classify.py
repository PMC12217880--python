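"""Five-class discretization of continuous surfaces.

Two modes: Jenks natural breaks (Fisher's optimal univariate partitioning
by dynamic programming — the classification minimizing total within-class
sum of squared deviations) and fixed thresholds (e.g. the shipped risk
breakpoints in :mod:`ecorisk.presets`).  Class intervals are closed on the
upper end: (−∞, t1], (t1, t2], …, (t4, ∞).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import FloatRaster

DEFAULT_LABELS = ("low", "lower", "medium", "high", "higher")

#: above this many values the exact DP switches to a seeded subsample
JENKS_SAMPLE_CAP = 20_000


@dataclass(frozen=True)
class ClassBreaks:
    """Ordered thresholds t1 < … < t_{k-1} defining k classes."""

    thresholds: tuple[float, ...]
    mode: str  # "jenks" | "fixed"
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        t = self.thresholds
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.labels) != len(t) + 1:
            raise ValueError("need one label per class")

    @property
    def n_classes(self) -> int:
        return len(self.thresholds) + 1


def _jenks_dp(values: np.ndarray, k: int) -> np.ndarray:
    """Fisher optimal partitioning: split points minimizing within-class SSD.

    Returns the sorted class boundaries as the last member of each of the
    first k−1 classes.  O(k·n²) with prefix-sum cost evaluation.
    """
    x = np.sort(values)
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:
        # within-class sum of squared deviations of x[i:j]
        m = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / m

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=np.int64)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        # class m covers x[i:j]; vectorize over split point i for each j
        for j in range(m, n + 1):
            i_lo, i_hi = m - 1, j
            ii = np.arange(i_lo, i_hi)
            cnt = j - ii
            s = s1[j] - s1[ii]
            w = (s2[j] - s2[ii]) - s * s / cnt
            tot = cost[m - 1, ii] + w
            best = int(np.argmin(tot))
            cost[m, j] = tot[best]
            back[m, j] = ii[best]
    # recover boundaries
    bounds = []
    j = n
    for m in range(k, 0, -1):
        i = back[m, j]
        bounds.append(i)
        j = i
    bounds = bounds[::-1][1:]  # drop the leading 0; k-1 split indices
    return x[np.asarray(bounds, dtype=np.int64) - 1]


def jenks_breaks(
    values: np.ndarray, k: int = 5, seed: int = 0, labels=DEFAULT_LABELS
) -> ClassBreaks:
    """Natural-breaks thresholds for ``values`` into ``k`` classes.

    Deterministic: exact dynamic programming up to ``JENKS_SAMPLE_CAP``
    finite values, a seeded subsample beyond.  Thresholds are the maxima of
    the first k−1 classes (upper-closed binning).
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(v)) < k:
        raise ValueError(
            f"need at least {k} distinct finite values, got {len(np.unique(v))}"
        )
    if len(v) > JENKS_SAMPLE_CAP:
        rng = np.random.default_rng(seed)
        v = rng.choice(v, size=JENKS_SAMPLE_CAP, replace=False)
        if len(np.unique(v)) < k:  # pathological subsample
            v = np.unique(v)
    t = _jenks_dp(v, k)
    labels = tuple(labels) if len(labels) == k else tuple(f"class{i+1}" for i in range(k))
    return ClassBreaks(thresholds=tuple(float(x) for x in t), mode="jenks", labels=labels)


def fixed_breaks(thresholds, labels=DEFAULT_LABELS) -> ClassBreaks:
    return ClassBreaks(thresholds=tuple(thresholds), mode="fixed", labels=tuple(labels))


def within_class_ssd(values: np.ndarray, breaks: ClassBreaks) -> float:
    """Objective the Jenks partition minimizes (for oracle comparisons)."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    idx = np.digitize(v, breaks.thresholds, right=True)
    total = 0.0
    for c in range(breaks.n_classes):
        grp = v[idx == c]
        if grp.size:
            total += float(((grp - grp.mean()) ** 2).sum())
    return total


@dataclass
class ClassifiedSurface:
    """Categorical raster (1..k; 0 = nodata) with class-area accounting."""

    classes: np.ndarray  # int grid
    breaks: ClassBreaks
    areas: pd.DataFrame  # class, label, area_km2, percent
    cell_size: float


def apply_breaks(surface: FloatRaster, breaks: ClassBreaks) -> ClassifiedSurface:
    """Bin a continuous surface; upper-closed intervals; NaN → class 0."""
    g = surface.grid
    finite = np.isfinite(g)
    cls = np.zeros(g.shape, dtype=np.int32)
    cls[finite] = np.digitize(g[finite], breaks.thresholds, right=True) + 1
    cell_area = surface.cell_area_km2
    n_valid = int(finite.sum())
    rows = []
    for c in range(1, breaks.n_classes + 1):
        cnt = int((cls == c).sum())
        rows.append(
            {
                "class": c,
                "label": breaks.labels[c - 1],
                "area_km2": cnt * cell_area,
                "percent": 100.0 * cnt / n_valid if n_valid else 0.0,
            }
        )
    return ClassifiedSurface(
        classes=cls,
        breaks=breaks,
        areas=pd.DataFrame(rows),
        cell_size=surface.cell_size,
    )
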