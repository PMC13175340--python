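"""Barcode summaries: Betti curves, persistence landscapes, and group statistics.

Conventions
-----------
Bars are right-open ``[birth, death)`` on the 256-level intensity scale; the
essential dimension-0 bar is counted alive through level 255 inclusive, so the
integrated Betti number equals the total persistence of all bars.

Landscapes are evaluated on a half-integer grid over ``[0, 255]`` (511 points).
Tent functions of integer bars, and every k-th pointwise maximum of them, are
piecewise linear with breakpoints on that grid, so trapezoidal integrals of
landscapes (areas, L1 distances) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cubical import PersistencePair

__all__ = [
    "LANDSCAPE_GRID",
    "PersistenceLandscape",
    "betti_curve",
    "integrated_betti",
    "landscape",
    "landscape_from_bars",
    "landscape_area",
    "average_landscape",
    "l1_distance",
    "landscape_permutation_test",
    "hedges_g",
]

#: Half-integer evaluation grid on the 256-level scale.
LANDSCAPE_GRID = np.arange(0, 255.0001, 0.5)

#: Landscape default: keep only bars with persistence strictly greater than 5.
DEFAULT_MIN_PERSISTENCE = 5


@dataclass
class PersistenceLandscape:
    """Ordered landscape layers sampled on :data:`LANDSCAPE_GRID`.

    ``layers`` has shape (k, len(grid)) with layer 0 the pointwise maximum;
    layers are nested (each dominates the next) and an empty landscape has
    zero layers.
    """

    layers: np.ndarray

    def __post_init__(self):
        self.layers = np.atleast_2d(np.asarray(self.layers, dtype=float))
        if self.layers.size == 0:
            self.layers = np.zeros((0, LANDSCAPE_GRID.size))
        if self.layers.shape[1] != LANDSCAPE_GRID.size:
            raise ValueError(
                f"layers must be sampled on the {LANDSCAPE_GRID.size}-point grid, "
                f"got {self.layers.shape[1]} columns"
            )

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    def layer(self, k: int) -> np.ndarray:
        """k-th layer (1-based beyond the stored range is identically zero)."""
        if k < self.n_layers:
            return self.layers[k]
        return np.zeros(LANDSCAPE_GRID.size)

    def area(self) -> float:
        return landscape_area(self)


def _alive_matrix(pairs: Iterable[PersistencePair], dim: int) -> np.ndarray:
    """Boolean (n_bars, 256) aliveness with the right-open/essential convention."""
    f = np.arange(256)
    rows = []
    for p in pairs:
        if p.dim != dim:
            continue
        if p.essential:
            rows.append((p.birth <= f))  # alive through 255 inclusive
        else:
            rows.append((p.birth <= f) & (f < p.death))
    if not rows:
        return np.zeros((0, 256), dtype=bool)
    return np.array(rows)


def betti_curve(pairs: Iterable[PersistencePair], dim: int) -> np.ndarray:
    """Betti curve beta(f) for f = 0..255: number of bars alive at level f."""
    return _alive_matrix(pairs, dim).sum(axis=0).astype(np.int64)


def integrated_betti(curve: np.ndarray) -> float:
    """Discrete integral of a Betti curve: one unit step per filtration level.

    Equals the total persistence of the underlying bars (an essential bar born
    at b contributes 256 - b).
    """
    curve = np.asarray(curve)
    if curve.ndim != 1 or curve.size != 256:
        raise ValueError(f"expected a 256-level Betti curve, got shape {curve.shape}")
    if (curve < 0).any():
        raise ValueError("Betti curves are nonnegative")
    return float(curve.sum())


def _bars_of_dim(
    pairs: Iterable[PersistencePair], dim: int, min_persistence: float
) -> np.ndarray:
    bars = [
        (p.birth, p.death)
        for p in pairs
        if p.dim == dim and (p.death - p.birth) > min_persistence
    ]
    return np.asarray(bars, dtype=float).reshape(-1, 2)


def landscape_from_bars(bars: np.ndarray | Sequence[tuple[float, float]]) -> PersistenceLandscape:
    """Landscape of explicit (birth, death) bars, no filtering."""
    bars = np.asarray(bars, dtype=float).reshape(-1, 2)
    if bars.size == 0:
        return PersistenceLandscape(np.zeros((0, LANDSCAPE_GRID.size)))
    f = LANDSCAPE_GRID[None, :]
    b, d = bars[:, 0:1], bars[:, 1:2]
    tents = np.maximum(0.0, np.minimum(f - b, d - f))
    layers = -np.sort(-tents, axis=0)
    keep = (layers > 0).any(axis=1)
    return PersistenceLandscape(layers[keep].reshape(-1, LANDSCAPE_GRID.size))


def landscape(
    pairs: Iterable[PersistencePair],
    dim: int,
    min_persistence: float = DEFAULT_MIN_PERSISTENCE,
) -> PersistenceLandscape:
    """Persistence landscape of one dimension's bars.

    Bars with persistence <= ``min_persistence`` are discarded (the group-level
    summaries keep only cycles with persistence greater than 5 intensity
    levels by default).  The essential bar enters with its capped death.
    """
    if min_persistence < 0:
        raise ValueError(f"min_persistence must be nonnegative, got {min_persistence}")
    return landscape_from_bars(_bars_of_dim(pairs, dim, min_persistence))


def landscape_area(ls: PersistenceLandscape) -> float:
    """Total area under all layers (the landscape's L1 norm)."""
    if ls.n_layers == 0:
        return 0.0
    return float(np.trapezoid(ls.layers, LANDSCAPE_GRID, axis=1).sum())


def _padded_stack(landscapes: Sequence[PersistenceLandscape]) -> np.ndarray:
    """(n, k_max, grid) array, missing layers zero-padded."""
    kmax = max((ls.n_layers for ls in landscapes), default=0)
    kmax = max(kmax, 1)
    out = np.zeros((len(landscapes), kmax, LANDSCAPE_GRID.size))
    for i, ls in enumerate(landscapes):
        if ls.n_layers:
            out[i, : ls.n_layers] = ls.layers
    return out


def average_landscape(landscapes: Sequence[PersistenceLandscape]) -> PersistenceLandscape:
    """Layer-wise, pointwise arithmetic mean (missing layers count as zero)."""
    if len(landscapes) == 0:
        raise ValueError("cannot average an empty list of landscapes")
    mean = _padded_stack(landscapes).mean(axis=0)
    keep = (mean > 0).any(axis=1)
    return PersistenceLandscape(mean[keep].reshape(-1, LANDSCAPE_GRID.size))


def l1_distance(ls1: PersistenceLandscape, ls2: PersistenceLandscape) -> float:
    """L1 distance: sum over layers of the integral of |lambda_k^1 - lambda_k^2|."""
    k = max(ls1.n_layers, ls2.n_layers)
    if k == 0:
        return 0.0
    a = np.zeros((k, LANDSCAPE_GRID.size))
    b = np.zeros((k, LANDSCAPE_GRID.size))
    if ls1.n_layers:
        a[: ls1.n_layers] = ls1.layers
    if ls2.n_layers:
        b[: ls2.n_layers] = ls2.layers
    return float(np.trapezoid(np.abs(a - b), LANDSCAPE_GRID, axis=1).sum())


def landscape_permutation_test(
    group_a: Sequence[PersistenceLandscape],
    group_b: Sequence[PersistenceLandscape],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-group permutation test on mean landscapes.

    The statistic is the L1 distance between the two group-mean landscapes;
    group labels are permuted ``n_perm`` times and the p-value is
    ``(1 + #{permuted >= observed}) / (n_perm + 1)``.

    Returns (observed statistic, p-value).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    pooled = list(group_a) + list(group_b)
    stack = _padded_stack(pooled)  # (n, k, grid)
    na = len(group_a)
    n = len(pooled)

    def stat(idx_a: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[idx_a] = True
        diff = stack[mask].mean(axis=0) - stack[~mask].mean(axis=0)
        return float(np.trapezoid(np.abs(diff), LANDSCAPE_GRID, axis=1).sum())

    observed = stat(np.arange(na))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)[:na]
        if stat(idx) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return observed, p


def hedges_g(x: Sequence[float], y: Sequence[float]) -> float:
    """Hedges' g effect size with the small-sample correction.

    ``g = (mean x - mean y) / s_pooled * J`` where
    ``J = 1 - 3 / (4 (n_x + n_y) - 9)`` and ``s_pooled`` is the usual
    pooled standard deviation with ``n_x + n_y - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("both samples need at least two observations")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (nx + ny) - 9.0)
    return float((x.mean() - y.mean()) / np.sqrt(sp2) * j)
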