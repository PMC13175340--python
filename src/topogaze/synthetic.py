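"""Synthetic greyscale scenes with exact topological ground truth.

Scenes are built from hard-edged, axis-aligned primitives (disk, annulus,
rectangle, frame-crossing stripe) on a constant background, optionally with a
speckle texture field of small dark squares.  Because edges are hard and
intensities are exact integers, every primitive's persistence bars are
predictable analytically: a dark blob of intensity ``p`` on background ``b``
is a BW dimension-0 bar born at ``p`` dying at ``b`` and, unless it touches
the frame, a WB dimension-1 bar of equal persistence — the Alexander-dual
partner.  Frame-crossing stripes break the duality on both sides by exactly
one bar each, which is what the ADV statistic measures.

The speckle field emulates pictorial texture: real paintings show patches of
dense micro-structure next to smooth regions, so the default texture is a
stationary random-rate process (a smoothed-noise rate field with a long
correlation length) rather than a homogeneous Poisson scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import json
import warnings

import numpy as np
from scipy import ndimage

from .cubical import build_filtration, persistence
from .feature_maps import FeatureMap, grid_shape
from .gaze import Fixation

__all__ = [
    "Disk",
    "Annulus",
    "Rectangle",
    "FrameStripe",
    "SpeckleField",
    "SceneSpec",
    "GroundTruth",
    "render",
    "simulate_fixations",
]


@dataclass(frozen=True)
class Disk:
    row: int
    col: int
    radius: int
    intensity: int

    def bbox(self):
        return (self.row - self.radius, self.col - self.radius,
                self.row + self.radius, self.col + self.radius)

    def draw(self, img: np.ndarray) -> None:
        h, w = img.shape
        rr, cc = np.ogrid[:h, :w]
        img[(rr - self.row) ** 2 + (cc - self.col) ** 2 <= self.radius**2] = self.intensity

    def expected_bars(self, background: int):
        p = self.intensity
        return {
            ("BW", 0): [(p, background)],
            ("WB", 1): [(255 - background, 255 - p)],
        }


@dataclass(frozen=True)
class Rectangle:
    row0: int
    col0: int
    row1: int  # inclusive
    col1: int
    intensity: int

    def bbox(self):
        return (self.row0, self.col0, self.row1, self.col1)

    def draw(self, img: np.ndarray) -> None:
        img[self.row0 : self.row1 + 1, self.col0 : self.col1 + 1] = self.intensity

    def expected_bars(self, background: int):
        p = self.intensity
        return {
            ("BW", 0): [(p, background)],
            ("WB", 1): [(255 - background, 255 - p)],
        }


@dataclass(frozen=True)
class Annulus:
    """Dark ring with a lighter interior: a hole in both filtrations.

    Requires ``ring_intensity < interior_intensity <= background``.
    """

    row: int
    col: int
    outer_radius: int
    inner_radius: int
    ring_intensity: int
    interior_intensity: int

    def bbox(self):
        return (self.row - self.outer_radius, self.col - self.outer_radius,
                self.row + self.outer_radius, self.col + self.outer_radius)

    def draw(self, img: np.ndarray) -> None:
        h, w = img.shape
        rr, cc = np.ogrid[:h, :w]
        d2 = (rr - self.row) ** 2 + (cc - self.col) ** 2
        img[d2 <= self.outer_radius**2] = self.ring_intensity
        img[d2 <= self.inner_radius**2] = self.interior_intensity

    def expected_bars(self, background: int):
        p, q = self.ring_intensity, self.interior_intensity
        return {
            ("BW", 0): [(p, background)],
            ("BW", 1): [(p, q)],
            ("WB", 0): [(255 - q, 255 - p)],
            ("WB", 1): [(255 - background, 255 - p)],
        }


@dataclass(frozen=True)
class FrameStripe:
    """Full-width (or full-height) dark stripe touching both opposite borders.

    It splits the background, so it has no dimension-1 dual partner in either
    filtration: the canonical Alexander-duality violator.
    """

    orientation: str  # 'h' (spans all columns) or 'v' (spans all rows)
    position: int  # first row (h) or column (v)
    thickness: int
    intensity: int

    def bbox(self):
        big = 10**9
        if self.orientation == "h":
            return (self.position, -big, self.position + self.thickness - 1, big)
        return (-big, self.position, big, self.position + self.thickness - 1)

    def draw(self, img: np.ndarray) -> None:
        if self.orientation == "h":
            img[self.position : self.position + self.thickness, :] = self.intensity
        elif self.orientation == "v":
            img[:, self.position : self.position + self.thickness] = self.intensity
        else:
            raise ValueError(f"orientation must be 'h' or 'v', got {self.orientation!r}")

    def expected_bars(self, background: int):
        p = self.intensity
        return {
            ("BW", 0): [(p, background)],
            ("WB", 0): [(255 - background, 255 - p)],  # one extra split-off background part
        }


@dataclass(frozen=True)
class SpeckleField:
    """Non-overlapping dark micro-squares with a spatially varying rate.

    ``n`` squares of side ``size`` and the given intensity are scattered over
    the region left free by the primitives, separated by at least one
    background pixel (each speckle is then its own component/hole).  With
    ``patchiness > 0`` the acceptance probability follows a smoothed-noise
    rate field with correlation length ``correlation_px``, emulating texture
    patches; ``patchiness = 0`` gives a homogeneous scatter.
    """

    n: int
    size: int = 2
    intensity: int = 0
    patchiness: float = 0.0
    correlation_px: float = 150.0


@dataclass
class SceneSpec:
    """Declarative scene: size, background, primitives, texture, noise, seed."""

    height: int
    width: int
    background: int = 255
    primitives: Sequence[object] = field(default_factory=tuple)
    speckle: SpeckleField | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def to_json(self) -> str:
        def enc(o):
            d = dict(o.__dict__)
            d["_type"] = type(o).__name__
            return d

        return json.dumps(
            {
                "height": self.height,
                "width": self.width,
                "background": self.background,
                "primitives": [enc(p) for p in self.primitives],
                "speckle": enc(self.speckle) if self.speckle else None,
                "noise_sigma": self.noise_sigma,
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        types = {c.__name__: c for c in (Disk, Annulus, Rectangle, FrameStripe, SpeckleField)}

        def dec(d):
            t = d.pop("_type")
            return types[t](**d)

        raw = json.loads(text)
        return cls(
            height=raw["height"],
            width=raw["width"],
            background=raw["background"],
            primitives=tuple(dec(p) for p in raw["primitives"]),
            speckle=dec(raw["speckle"]) if raw.get("speckle") else None,
            noise_sigma=raw.get("noise_sigma", 0.0),
            seed=raw.get("seed", 0),
        )


@dataclass
class GroundTruth:
    """Expected positive-persistence topology of a rendered scene.

    ``bars[(direction, dim)]`` lists expected (birth, death) tuples of all
    non-essential-convention bars, with the essential class folded in (its
    death is the capped level).  ``n_unmatched[(direction of dim-1 pairs)]``
    is the expected number of reverse-filtration dimension-0 bars without a
    dimension-1 dual partner.  ``exact`` is False when noise makes the counts
    approximate.
    """

    bars: dict[tuple[str, int], list[tuple[int, int]]]
    n_unmatched: dict[str, int]
    exact: bool = True

    def n_bars(self, direction: str, dim: int) -> int:
        return len(self.bars.get((direction, dim), []))


def _validate_spec(spec: SceneSpec) -> None:
    h, w = spec.height, spec.width
    if h < 3 or w < 3:
        raise ValueError("scene must be at least 3x3")
    if not (0 <= spec.background <= 255):
        raise ValueError("background intensity must be in [0, 255]")
    boxes = []
    for p in spec.primitives:
        if isinstance(p, Annulus):
            if not (p.ring_intensity < p.interior_intensity < spec.background):
                raise ValueError(
                    "annulus needs ring_intensity < interior_intensity < background "
                    f"(got {p.ring_intensity}, {p.interior_intensity}, {spec.background})"
                )
            if not (0 < p.inner_radius < p.outer_radius - 1):
                raise ValueError("annulus needs 0 < inner_radius < outer_radius - 1")
        inten = getattr(p, "intensity", getattr(p, "ring_intensity", None))
        if not (0 <= inten < spec.background):
            raise ValueError(
                f"primitive intensity {inten} must lie in [0, background) = [0, {spec.background})"
            )
        if isinstance(p, FrameStripe):
            if p.orientation not in ("h", "v"):
                raise ValueError(f"stripe orientation must be 'h'/'v', got {p.orientation!r}")
            limit = h if p.orientation == "h" else w
            if not (0 < p.position and p.position + p.thickness < limit):
                raise ValueError("stripe must leave background on both sides")
        else:
            r0, c0, r1, c1 = p.bbox()
            if not (1 <= r0 and 1 <= c0 and r1 <= h - 2 and c1 <= w - 2):
                raise ValueError(
                    f"primitive {p} touches or exceeds the frame; only FrameStripe may"
                )
        boxes.append(p.bbox())
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            a, b = boxes[i], boxes[j]
            # require a >=1 px background gap: dilate one box by 1
            if not (a[2] + 1 < b[0] or b[2] + 1 < a[0] or a[3] + 1 < b[1] or b[3] + 1 < a[1]):
                raise ValueError(
                    f"primitives {spec.primitives[i]} and {spec.primitives[j]} overlap or "
                    "touch; ground truth would be ambiguous"
                )


def _place_speckles(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> int:
    sp = spec.speckle
    h, w = img.shape
    s = sp.size
    free = img == spec.background
    # keep one frame pixel and one pixel around primitives clear
    free = ndimage.binary_erosion(free, iterations=s + 1, border_value=0)
    rate = None
    if sp.patchiness > 0:
        noise = rng.normal(size=(h, w))
        smooth = ndimage.gaussian_filter(noise, sigma=sp.correlation_px / 3.0)
        smooth = (smooth - smooth.min()) / (np.ptp(smooth) + 1e-12)
        rate = (1.0 - sp.patchiness) + sp.patchiness * smooth**2
        rate /= rate.max()
    occupied = np.zeros_like(img, dtype=bool)
    placed = 0
    attempts = 0
    max_attempts = 200 * sp.n + 1000
    while placed < sp.n and attempts < max_attempts:
        attempts += 1
        r = int(rng.integers(0, h - s))
        c = int(rng.integers(0, w - s))
        if rate is not None and rng.random() > rate[r, c]:
            continue
        if not free[r : r + s, c : c + s].all():
            continue
        # one-pixel halo so speckles never touch each other
        r0, c0 = max(r - 1, 0), max(c - 1, 0)
        if occupied[r0 : r + s + 1, c0 : c + s + 1].any():
            continue
        img[r : r + s, c : c + s] = sp.intensity
        occupied[r : r + s, c : c + s] = True
        placed += 1
    if placed < sp.n:
        warnings.warn(
            f"placed only {placed}/{sp.n} speckles before giving up", stacklevel=2
        )
    return placed


def render(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Rasterise a scene and derive its exact expected topology.

    Deterministic for a given spec (the spec carries the seed).  Raises on
    overlapping primitives, whose ground truth would be ambiguous.
    """
    _validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    img = np.full((spec.height, spec.width), spec.background, dtype=np.int64)
    for p in spec.primitives:
        p.draw(img)
    n_speckles = 0
    if spec.speckle is not None and spec.speckle.n > 0:
        n_speckles = _place_speckles(img, spec, rng)

    bars: dict[tuple[str, int], list[tuple[int, int]]] = {
        ("BW", 0): [],
        ("BW", 1): [],
        ("WB", 0): [],
        ("WB", 1): [],
    }
    bg = spec.background
    for p in spec.primitives:
        for key, bs in p.expected_bars(bg).items():
            bars[key].extend(bs)
    sp = spec.speckle
    for _ in range(n_speckles):
        bars[("BW", 0)].append((sp.intensity, bg))
        bars[("WB", 1)].append((255 - bg, 255 - sp.intensity))

    # essential classes: the darkest object is the elder BW component (capped
    # death); the background is the elder WB component.  A background at 255
    # contributes no positive-persistence BW bar of its own.
    dark_births = sorted(b for (b, _) in bars[("BW", 0)])
    if dark_births:
        bars[("BW", 0)].remove((dark_births[0], bg))
        bars[("BW", 0)].append((dark_births[0], 255))
    else:
        bars[("BW", 0)].append((bg, 255))  # empty scene: constant background
    bars[("WB", 0)].append((255 - bg, 255))

    n_stripes = sum(isinstance(p, FrameStripe) for p in spec.primitives)
    n_objects = len(spec.primitives) + n_speckles
    # unmatched reverse dim-0 bars when matching (dim-1 of D) vs (dim-0 of rev D):
    # every stripe lacks a dual partner; the essential class matches through the
    # duality index correspondence whenever its object is a non-stripe primitive
    unmatched_bw_dim0 = n_stripes if n_objects else 1
    unmatched_wb_dim0 = n_stripes + 1  # background essential never has a dim-1 partner
    truth = GroundTruth(
        bars={k: sorted(v) for k, v in bars.items()},
        n_unmatched={"WB": unmatched_bw_dim0, "BW": unmatched_wb_dim0},
        exact=spec.noise_sigma == 0,
    )

    if spec.noise_sigma > 0:
        img = img + rng.normal(scale=spec.noise_sigma, size=img.shape)
        img = np.clip(np.round(img), 0, 255).astype(np.int64)
    return img, truth


def simulate_fixations(
    fmap: FeatureMap,
    n: int,
    bias: float = 0.0,
    min_duration: float = 100.0,
    max_duration: float = 500.0,
    seed: int | None = None,
    participant: str = "sim",
    image: str = "scene",
) -> list[Fixation]:
    """Draw synthetic fixations with controllable attraction to feature values.

    A window is chosen with probability proportional to ``(1 + value)^bias``
    (``bias = 0``: uniform; large bias: all mass on the argmax window), the
    position is uniform within the window, and the duration uniform in
    ``[min_duration, max_duration]`` ms.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("need at least one fixation")
    if not (0 < min_duration < max_duration):
        raise ValueError("need max_duration > min_duration > 0")
    if bias < 0:
        raise ValueError("bias must be nonnegative")
    rng = np.random.default_rng(seed)
    vals = fmap.grid.ravel()
    if bias > 0 and not (vals > 0).any():
        warnings.warn("all-zero feature map with positive bias; using uniform sampling",
                      stacklevel=2)
        bias = 0.0
    with np.errstate(over="ignore"):
        weights = (1.0 + vals) ** bias
    if not np.isfinite(weights).all():  # huge bias: degenerate to the argmax
        weights = (vals == vals.max()).astype(float)
    probs = weights / weights.sum()
    gh, gw = fmap.grid.shape
    h, w = fmap.image_shape
    win = fmap.window
    cells = rng.choice(gh * gw, size=n, p=probs)
    out = []
    for k, cell in enumerate(cells):
        i, j = divmod(int(cell), gw)
        y0, y1 = i * win, min((i + 1) * win, h)
        x0, x1 = j * win, min((j + 1) * win, w)
        out.append(
            Fixation(
                x=float(rng.uniform(x0, x1 - 1)),
                y=float(rng.uniform(y0, y1 - 1)),
                duration_ms=float(rng.uniform(min_duration, max_duration)),
                participant=participant,
                image=image,
                session="1",
            )
        )
    return out
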