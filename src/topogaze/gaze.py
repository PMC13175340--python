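"""Fixation heatmaps and gaze-weighted ECDF comparison of feature maps.

A fixation heatmap deposits, for every fixation longer than the qualifying
threshold (75 ms), a duration-proportional isotropic Gaussian at the fixation
position, then normalises the map to unit sum.  Feature-map windows are then
weighted three ways — uniformly (the image's intrinsic distribution), by the
gaze heatmap ("looking"), and uniformly over windows the gaze missed
("not looking") — and the resulting weighted ECDFs are compared with MSE,
signed mean error (ME), and the Kolmogorov-Smirnov statistic.

Sign convention: ``me_ecdf(e_looking, e_not_looking) > 0`` means the looking
distribution sits at *higher* feature values (its ECDF lies below and to the
right of the not-looking ECDF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .feature_maps import FeatureMap, grid_shape

__all__ = [
    "Fixation",
    "GazeHeatmap",
    "WeightedECDF",
    "fixations_to_frame",
    "frame_to_fixations",
    "heatmap",
    "window_weights",
    "complement_weights",
    "weighted_ecdf",
    "uniform_weights",
    "mse_ecdf",
    "me_ecdf",
    "ks_stat",
    "gaze_comparison",
]

MIN_FIXATION_MS = 75.0
DEFAULT_SIGMA = 50.0
DEFAULT_COMPLEMENT_EPS = 0.05


@dataclass(frozen=True)
class Fixation:
    """One gaze fixation: pixel position, duration, and optional identifiers."""

    x: float
    y: float
    duration_ms: float
    participant: str = ""
    image: str = ""
    session: str = ""

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError(f"fixation duration must be positive, got {self.duration_ms}")


def fixations_to_frame(fixations: Iterable[Fixation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant": f.participant,
                "image": f.image,
                "session": f.session,
                "x": f.x,
                "y": f.y,
                "duration_ms": f.duration_ms,
            }
            for f in fixations
        ],
        columns=["participant", "image", "session", "x", "y", "duration_ms"],
    )


def frame_to_fixations(df: pd.DataFrame) -> list[Fixation]:
    return [
        Fixation(
            x=float(r.x),
            y=float(r.y),
            duration_ms=float(r.duration_ms),
            participant=str(getattr(r, "participant", "")),
            image=str(getattr(r, "image", "")),
            session=str(getattr(r, "session", "")),
        )
        for r in df.itertuples()
    ]


@dataclass
class GazeHeatmap:
    """Per-pixel gaze intensity, unit sum unless no fixation qualified."""

    values: np.ndarray
    empty: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("heatmap intensities must be nonnegative")


def heatmap(
    fixations: Sequence[Fixation],
    image_shape: tuple[int, int],
    sigma: float = DEFAULT_SIGMA,
    min_duration: float = MIN_FIXATION_MS,
) -> GazeHeatmap:
    """Duration-weighted Gaussian fixation heatmap.

    Fixations with duration <= ``min_duration`` (default 75 ms) are discarded.
    Each remaining fixation deposits mass proportional to its duration at its
    (clamped) pixel position; the deposit image is smoothed with an isotropic
    Gaussian of width ``sigma`` and normalised to unit sum.  With no
    qualifying fixation the all-zero sentinel map is returned.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    h, w = image_shape
    acc = np.zeros((h, w))
    n_used = 0
    for f in fixations:
        if f.duration_ms <= min_duration:
            continue
        r, c = int(round(f.y)), int(round(f.x))
        if not (0 <= r < h and 0 <= c < w):
            warnings.warn(
                f"fixation at (x={f.x}, y={f.y}) outside the {h}x{w} image; clamping",
                stacklevel=2,
            )
            r, c = min(max(r, 0), h - 1), min(max(c, 0), w - 1)
        acc[r, c] += f.duration_ms
        n_used += 1
    if n_used == 0:
        return GazeHeatmap(values=acc, empty=True)
    sm = ndimage.gaussian_filter(acc, sigma=sigma, mode="constant")
    return GazeHeatmap(values=sm / sm.sum(), empty=False)


def _pool_windows(values: np.ndarray, window: int) -> np.ndarray:
    h, w = values.shape
    gh, gw = grid_shape((h, w), window)
    out = np.zeros((gh, gw))
    for i in range(gh):
        for j in range(gw):
            out[i, j] = values[i * window : (i + 1) * window, j * window : (j + 1) * window].sum()
    return out


def window_weights(hm: GazeHeatmap, window: int) -> np.ndarray:
    """Gaze weight of each grid window: heatmap mass inside it, normalised."""
    if hm.empty:
        raise ValueError("sentinel (empty) heatmap has no gaze weights; use uniform weights")
    pooled = _pool_windows(hm.values, window)
    return pooled / pooled.sum()


def complement_weights(
    hm: GazeHeatmap, window: int, eps: float = DEFAULT_COMPLEMENT_EPS
) -> np.ndarray:
    """Uniform weights over the windows the gaze (essentially) missed.

    A window counts as unvisited when its gaze weight is <= ``eps`` times the
    maximum window weight.  Raises if every window was visited.
    """
    gw = window_weights(hm, window)
    mask = gw <= eps * gw.max()
    if not mask.any():
        raise ValueError("gaze covers every window; no 'not-looking' region exists")
    out = np.zeros_like(gw)
    out[mask] = 1.0 / mask.sum()
    return out


def uniform_weights(fmap: FeatureMap) -> np.ndarray:
    g = np.ones_like(fmap.grid)
    return g / g.size


@dataclass
class WeightedECDF:
    """Right-continuous step function from feature values to cumulative weight."""

    support: np.ndarray  # ascending unique feature values
    cumulative: np.ndarray  # same length, ending at 1

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.support.size == 0:
            raise ValueError("ECDF support is empty")
        if (np.diff(self.support) <= 0).any():
            raise ValueError("ECDF support must be strictly ascending")
        if (np.diff(self.cumulative) < -1e-12).any():
            raise ValueError("ECDF must be nondecreasing")
        if not np.isclose(self.cumulative[-1], 1.0):
            raise ValueError("ECDF must end at 1")

    def __call__(self, v: np.ndarray | float) -> np.ndarray | float:
        idx = np.searchsorted(self.support, v, side="right") - 1
        out = np.where(np.asarray(idx) >= 0, self.cumulative[np.maximum(idx, 0)], 0.0)
        return float(out) if np.isscalar(v) else out


def weighted_ecdf(fmap: FeatureMap, weights: np.ndarray) -> WeightedECDF:
    """ECDF of feature-map values under per-window weights summing to 1."""
    w = np.asarray(weights, dtype=float)
    if w.shape != fmap.grid.shape:
        raise ValueError(f"weights {w.shape} do not align with map grid {fmap.grid.shape}")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError(f"weights must sum to 1, got {w.sum():.6f}")
    vals = fmap.grid.ravel()
    wts = w.ravel()
    order = np.argsort(vals, kind="stable")
    vals, wts = vals[order], wts[order]
    support, start = np.unique(vals, return_index=True)
    cum = np.cumsum(wts)
    # cumulative weight at each unique value = cumsum at the last tied entry
    last = np.r_[start[1:] - 1, vals.size - 1]
    cumulative = cum[last]
    cumulative = np.minimum(cumulative / cumulative[-1], 1.0)  # guard rounding
    return WeightedECDF(support=support, cumulative=cumulative)


def _merged_eval(e1: WeightedECDF, e2: WeightedECDF) -> tuple[np.ndarray, np.ndarray]:
    grid = np.union1d(e1.support, e2.support)
    if grid.size == 0:
        raise ValueError("empty merged support")
    return e1(grid), e2(grid)


def mse_ecdf(e1: WeightedECDF, e2: WeightedECDF) -> float:
    """Mean squared difference of two ECDFs on their merged support; in [0, 1]."""
    a, b = _merged_eval(e1, e2)
    return float(np.mean((a - b) ** 2))


def me_ecdf(e1: WeightedECDF, e2: WeightedECDF) -> float:
    """Signed mean ECDF difference, positive when e1 sits at higher values.

    Computed as the mean of ``e2 - e1`` over the merged support: if e1 is
    stochastically larger its ECDF lies below e2's, making the result
    positive.  With e1 = looking and e2 = not-looking, a positive ME means
    the viewer looked at regions with higher feature values.
    """
    a, b = _merged_eval(e1, e2)
    return float(np.mean(b - a))


def ks_stat(e1: WeightedECDF, e2: WeightedECDF) -> float:
    """Kolmogorov-Smirnov statistic: sup |e1 - e2| over the merged support."""
    a, b = _merged_eval(e1, e2)
    return float(np.max(np.abs(a - b)))


def gaze_comparison(
    fmap: FeatureMap,
    hm: GazeHeatmap,
    eps: float = DEFAULT_COMPLEMENT_EPS,
) -> dict[str, float]:
    """The standard per-(participant, image) comparison battery.

    Returns intrinsic-vs-looking MSE and KS, looking-vs-not-looking MSE and
    signed ME.
    """
    e_intrinsic = weighted_ecdf(fmap, uniform_weights(fmap))
    e_look = weighted_ecdf(fmap, window_weights(hm, fmap.window))
    e_not = weighted_ecdf(fmap, complement_weights(hm, fmap.window, eps=eps))
    return {
        "mse_intrinsic_vs_looking": mse_ecdf(e_intrinsic, e_look),
        "ks_intrinsic_vs_looking": ks_stat(e_intrinsic, e_look),
        "mse_looking_vs_notlooking": mse_ecdf(e_look, e_not),
        "me_looking_vs_notlooking": me_ecdf(e_look, e_not),
    }
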