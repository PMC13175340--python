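"""Grid-window feature maps built from dimension-1 cycle representatives.

A square mesh of non-overlapping windows (default 50x50 px) is laid over the
image; each window records one topological descriptor of the cycles meeting
it: cycle density (a count), maximal persistence, or maximal cycle perimeter.
Density is anchored — each cycle is counted in exactly one window, the one
containing its representative's bounding-box centroid — while persistence and
perimeter contribute to every window the representative loop intersects.
Composite maps combine the BW and WB filtrations (densities add, maxima are
taken cellwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cubical import PersistencePair

__all__ = ["FeatureMap", "feature_map", "composite_map", "grid_shape", "DEFAULT_WINDOW"]

DEFAULT_WINDOW = 50
KINDS = ("density", "max_persistence", "max_perimeter")


def grid_shape(shape: tuple[int, int], window: int) -> tuple[int, int]:
    h, w = shape
    return (-(-h // window), -(-w // window))  # ceil division


@dataclass
class FeatureMap:
    """Per-window grid of one topological descriptor."""

    kind: str
    window: int
    grid: np.ndarray
    image_shape: tuple[int, int]
    source: str = "BW"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != grid_shape(self.image_shape, self.window):
            raise ValueError(
                f"grid shape {self.grid.shape} inconsistent with image "
                f"{self.image_shape} and window {self.window}"
            )
        if (self.grid < 0).any():
            raise ValueError("feature-map entries must be nonnegative")

    def cell_areas(self) -> np.ndarray:
        """Pixel count of each window (ragged right/bottom windows are smaller)."""
        h, w = self.image_shape
        gh, gw = self.grid.shape
        rows = np.minimum((np.arange(gh) + 1) * self.window, h) - np.arange(gh) * self.window
        cols = np.minimum((np.arange(gw) + 1) * self.window, w) - np.arange(gw) * self.window
        return rows[:, None] * cols[None, :]

    def per_unit_area(self) -> np.ndarray:
        """Grid values divided by window pixel area (density per pixel).

        Makes density distributions comparable across window sizes.
        """
        return self.grid / self.cell_areas()

    def values(self, drop_ragged: bool = False) -> np.ndarray:
        """Flattened window values, optionally excluding partial edge windows."""
        if not drop_ragged:
            return self.grid.ravel()
        h, w = self.image_shape
        gh = h // self.window
        gw = w // self.window
        return self.grid[:gh, :gw].ravel()


def _rep_windows(pixels: Sequence[tuple[int, int]], window: int) -> set[tuple[int, int]]:
    return {(r // window, c // window) for r, c in pixels}


def _anchor_window(pixels: Sequence[tuple[int, int]], window: int) -> tuple[int, int]:
    rows = [p[0] for p in pixels]
    cols = [p[1] for p in pixels]
    cr = (min(rows) + max(rows)) // 2
    cc = (min(cols) + max(cols)) // 2
    return (cr // window, cc // window)


def feature_map(
    pairs: Iterable[PersistencePair],
    image_shape: tuple[int, int],
    kind: str,
    window: int = DEFAULT_WINDOW,
    source: str | None = None,
) -> FeatureMap:
    """One descriptor's window grid from dimension-1 pairs with representatives.

    ``density``: number of cycles anchored in the window (bounding-box centroid
    rule, no double counting).  ``max_persistence`` / ``max_perimeter``: the
    maximum over all cycles whose representative loop touches the window
    (0 where none does); perimeter is the number of distinct pixels on the
    representative loop.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2 pixels, got {window}")
    d1 = [p for p in pairs if p.dim == 1]
    if source is None:
        source = d1[0].direction if d1 else "BW"
    grid = np.zeros(grid_shape(image_shape, window))
    for p in d1:
        if not p.representative:
            raise ValueError(
                f"pair dim={p.dim} birth={p.birth} death={p.death} has no "
                "representative; recompute persistence with representatives=True"
            )
        if kind == "density":
            grid[_anchor_window(p.representative, window)] += 1
        elif kind == "max_persistence":
            for cell in _rep_windows(p.representative, window):
                grid[cell] = max(grid[cell], p.persistence)
        elif kind == "max_perimeter":
            perim = len(set(p.representative))
            for cell in _rep_windows(p.representative, window):
                grid[cell] = max(grid[cell], perim)
        else:
            raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    return FeatureMap(kind=kind, window=window, grid=grid, image_shape=image_shape, source=source)


def composite_map(bw: FeatureMap, wb: FeatureMap) -> FeatureMap:
    """Combine maps of both filtrations: densities add, maxima are cellwise max."""
    if bw.kind != wb.kind:
        raise ValueError(f"kind mismatch: {bw.kind} vs {wb.kind}")
    if bw.grid.shape != wb.grid.shape or bw.window != wb.window:
        raise ValueError(
            f"grid mismatch: {bw.grid.shape}@{bw.window} vs {wb.grid.shape}@{wb.window}"
        )
    if bw.kind == "density":
        grid = bw.grid + wb.grid
    else:
        grid = np.maximum(bw.grid, wb.grid)
    return FeatureMap(
        kind=bw.kind,
        window=bw.window,
        grid=grid,
        image_shape=bw.image_shape,
        source="composite",
    )
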