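"""Image loading, greyscale conversion, matching, and contrast transforms.

All routines operate on integer intensity lattices in ``[0, 255]``.  Greyscale
conversion uses the CCIR-601 luma weights, and every transform rounds half-up
exactly once so that downstream filtrations always see an integer lattice.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "load_image",
    "save_image",
    "to_greyscale",
    "mean_abs_diff",
    "select_matched",
    "contrast_transform",
    "rescale",
]

#: CCIR-601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round half-up (0.5 -> 1), unlike numpy's banker's rounding."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def _validate_8bit(img: np.ndarray, name: str = "image") -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim not in (2, 3) or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty HxW or HxWx3 array, got shape {arr.shape}")
    if arr.ndim == 3 and arr.shape[2] != 3:
        raise ValueError(f"{name} must have 3 channels if 3-D, got shape {arr.shape}")
    lo, hi = arr.min(), arr.max()
    if lo < 0 or hi > 255:
        raise ValueError(f"{name} is not 8-bit: values span [{lo}, {hi}], expected [0, 255]")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{name} has non-integer values; expected an 8-bit lattice")
        arr = arr.astype(np.int64)
    return arr


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file as an 8-bit array (HxW grey or HxWx3 RGB)."""
    with Image.open(path) as im:
        if im.mode in ("L", "I;16", "I"):
            im = im.convert("L")
            return np.asarray(im, dtype=np.int64)
        im = im.convert("RGB")
        return np.asarray(im, dtype=np.int64)


def save_image(img: np.ndarray, path: str | Path) -> None:
    arr = _validate_8bit(img).astype(np.uint8)
    Image.fromarray(arr).save(path)


def to_greyscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to greyscale via Y = 0.299 R + 0.587 G + 0.114 B.

    Values are rounded half-up and clamped to ``[0, 255]``.  A 2-D (already
    greyscale) input passes through unchanged, making the map idempotent.
    """
    arr = _validate_8bit(img)
    if arr.ndim == 2:
        return arr.astype(np.int64)
    wr, wg, wb = LUMA_WEIGHTS
    y = wr * arr[..., 0] + wg * arr[..., 1] + wb * arr[..., 2]
    return np.clip(_round_half_up(y), 0, 255).astype(np.int64)


def mean_abs_diff(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute pixel-intensity difference between two same-shape images."""
    aa, bb = np.asarray(a), np.asarray(b)
    if aa.shape != bb.shape:
        raise ValueError(f"shape mismatch: {aa.shape} vs {bb.shape}")
    return float(np.mean(np.abs(aa.astype(np.int64) - bb.astype(np.int64))))


def select_matched(
    candidates: Sequence[np.ndarray],
    references: Sequence[np.ndarray],
    k: int,
) -> list[int]:
    """Rank candidates by average distance to a reference set; return the k best.

    For each candidate the score is the mean of :func:`mean_abs_diff` over all
    references; indices of the ``k`` smallest scores are returned ascending by
    score, ties broken by candidate index.
    """
    if len(references) == 0:
        raise ValueError("reference set is empty")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds number of candidates ({len(candidates)})")
    scores = np.array(
        [np.mean([mean_abs_diff(c, r) for r in references]) for c in candidates]
    )
    order = np.argsort(scores, kind="stable")
    return [int(i) for i in order[:k]]


def contrast_transform(img: np.ndarray, kind: str, **params) -> np.ndarray:
    """Apply a monotone contrast transform: gamma, linear or percentile stretch.

    ``gamma``: Y' = 255 (Y/255)^gamma with ``gamma > 0``.
    ``linear_stretch``: affine map of ``[lo, hi]`` onto ``[0, 255]``, clamped.
    ``percentile_stretch``: linear stretch with lo/hi at the given percentiles
    (``p_lo``, ``p_hi``) of the image histogram.

    All transforms preserve the order of pixel values, which is what makes the
    barcode structure robust to global contrast changes.
    """
    arr = _validate_8bit(img).astype(float)
    if kind == "gamma":
        gamma = params.get("gamma", 1.0)
        if gamma <= 0:
            raise ValueError(f"gamma must be positive, got {gamma}")
        out = 255.0 * (arr / 255.0) ** gamma
    elif kind == "linear_stretch":
        lo, hi = params["lo"], params["hi"]
        if lo >= hi:
            raise ValueError(f"stretch bounds must satisfy lo < hi, got lo={lo}, hi={hi}")
        out = (arr - lo) * 255.0 / (hi - lo)
    elif kind == "percentile_stretch":
        p_lo, p_hi = params.get("p_lo", 2.0), params.get("p_hi", 98.0)
        if p_lo >= p_hi:
            raise ValueError(f"percentiles must satisfy p_lo < p_hi, got {p_lo}, {p_hi}")
        lo, hi = np.percentile(arr, [p_lo, p_hi])
        if lo >= hi:  # near-constant image: nothing to stretch
            return arr.astype(np.int64)
        out = (arr - lo) * 255.0 / (hi - lo)
    else:
        raise ValueError(f"unknown contrast transform kind: {kind!r}")
    return np.clip(_round_half_up(out), 0, 255).astype(np.int64)


def rescale(img: np.ndarray, factor: float) -> np.ndarray:
    """Bilinear rescale preserving aspect ratio (robustness checks)."""
    arr = _validate_8bit(img)
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    h, w = arr.shape[:2]
    size = (max(1, round(w * factor)), max(1, round(h * factor)))
    im = Image.fromarray(arr.astype(np.uint8))
    return np.asarray(im.resize(size, Image.BILINEAR), dtype=np.int64)
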