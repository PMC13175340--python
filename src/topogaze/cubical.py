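"""Cubical complexes of greyscale images and their persistent homology.

The complex is the V-construction: one vertex per pixel, edges between
4-neighbours, and a square for every 2x2 pixel block; each cell enters the
filtration at the maximum of its vertices.  The BW filtration uses raw
intensities (dark pixels enter first), the WB filtration uses ``255 - Y``.

Dimension-0 persistence is computed with a union-find sweep (elder rule:
the component with the smaller birth survives a merge).  Dimension-1
persistence uses the planar dual: holes of the sublevel complex are the
bounded complementary regions, tracked by a reverse union-find over squares
and the outer face.  Every dimension-1 class is returned with an explicit
representative: the closed loop of lattice edges bounding the hole at birth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CubicalFiltration",
    "PersistencePair",
    "build_filtration",
    "persistence",
    "pairs_to_frame",
    "frame_to_pairs",
]

ESSENTIAL_DEATH = 255  # capped death level for the essential component


@dataclass(frozen=True)
class PersistencePair:
    """One bar of the barcode.

    ``representative`` holds pixel coordinates: for dimension 0 the birth
    plateau (the connected set of pixels at the birth level), for dimension 1
    the vertices of the closed edge loop bounding the hole at birth.
    ``region`` (dimension 1 only) is the pixel support of the enclosed hole,
    used for duality matching and feature-map window assignment.
    """

    dim: int
    birth: int
    death: int
    essential: bool = False
    direction: str = "BW"
    representative: tuple[tuple[int, int], ...] = field(default=(), compare=False)
    region: tuple[tuple[int, int], ...] = field(default=(), compare=False)

    @property
    def persistence(self) -> int:
        return self.death - self.birth

    @property
    def anchor(self) -> tuple[int, int]:
        """Deterministic spatial anchor: minimal (row, col) of the representative."""
        return min(self.representative) if self.representative else (-1, -1)


@dataclass
class CubicalFiltration:
    """Vertex values of a filtered image grid (WB already stores 255 - Y)."""

    direction: str
    values: np.ndarray  # HxW int

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def edge_values(self) -> tuple[np.ndarray, np.ndarray]:
        """(horizontal, vertical) edge values: the max of the two endpoints."""
        v = self.values
        horiz = np.maximum(v[:, :-1], v[:, 1:])  # H x (W-1)
        vert = np.maximum(v[:-1, :], v[1:, :])  # (H-1) x W
        return horiz, vert

    def square_values(self) -> np.ndarray:
        """(H-1)x(W-1) square values: the max of the four corners."""
        v = self.values
        return np.maximum(
            np.maximum(v[:-1, :-1], v[:-1, 1:]), np.maximum(v[1:, :-1], v[1:, 1:])
        )

    def cell_counts_at(self, level: int) -> tuple[int, int, int]:
        """(#vertices, #edges, #squares) present at a filtration level."""
        horiz, vert = self.edge_values()
        return (
            int((self.values <= level).sum()),
            int((horiz <= level).sum() + (vert <= level).sum()),
            int((self.square_values() <= level).sum()) if min(self.shape) > 1 else 0,
        )


def build_filtration(img: np.ndarray, direction: str = "BW") -> CubicalFiltration:
    """Build the BW (raw) or WB (inverted, 255 - Y) vertex filtration."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D greyscale image, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("image values must lie in [0, 255]")
    arr = arr.astype(np.int64)
    d = direction.upper()
    if d == "BW":
        vals = arr
    elif d == "WB":
        vals = 255 - arr
    else:
        raise ValueError(f"direction must be 'BW' or 'WB', got {direction!r}")
    return CubicalFiltration(direction=d, values=vals)


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:  # path compression
            p[x], x = root, p[x]
        return root


def _dim0_pairs(filt: CubicalFiltration, with_representatives: bool) -> list[PersistencePair]:
    vals = filt.values
    h, w = vals.shape
    flat = vals.ravel()
    n = h * w

    # edges as (value, a, b) with a < b in row-major vertex index
    idx = np.arange(n).reshape(h, w)
    ha, hb = idx[:, :-1].ravel(), idx[:, 1:].ravel()
    va, vb = idx[:-1, :].ravel(), idx[1:, :].ravel()
    ea = np.concatenate([ha, va])
    eb = np.concatenate([hb, vb])
    ev = np.maximum(flat[ea], flat[eb])
    order = np.lexsort((eb, ea, ev))  # by (value, a, b): deterministic
    ea, eb, ev = ea[order], eb[order], ev[order]

    uf = _UnionFind(n)
    birth = flat.copy()  # birth level of the component rooted at each index
    anchor = np.arange(n)  # minimal vertex index among birth-level vertices
    plateau: list[list[int]] | None = None
    if with_representatives:
        plateau = [[i] for i in range(n)]

    pairs: list[PersistencePair] = []
    for a, b, v in zip(ea.tolist(), eb.tolist(), ev.tolist()):
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            continue
        # elder rule: smaller birth survives; ties by smaller anchor
        if (birth[rb], anchor[rb]) < (birth[ra], anchor[ra]):
            ra, rb = rb, ra
        # rb dies (or is absorbed with zero persistence)
        if birth[rb] < v:
            rep: tuple[tuple[int, int], ...] = ()
            if plateau is not None:
                rep = tuple(sorted((i // w, i % w) for i in plateau[rb]))
            pairs.append(
                PersistencePair(
                    dim=0,
                    birth=int(birth[rb]),
                    death=int(v),
                    direction=filt.direction,
                    representative=rep,
                )
            )
            if plateau is not None:
                plateau[rb] = []
        elif plateau is not None:
            if birth[ra] == birth[rb]:
                # equal-birth merge at the birth level: plateaus coalesce
                if len(plateau[ra]) < len(plateau[rb]):
                    plateau[ra], plateau[rb] = plateau[rb], plateau[ra]
                plateau[ra].extend(plateau[rb])
            plateau[rb] = []
        uf.parent[rb] = ra

    # essential classes: one per connected component of the full grid (grid => 1)
    seen: set[int] = set()
    for i in range(n):
        r = uf.find(i)
        if r not in seen:
            seen.add(r)
            rep = ()
            if plateau is not None:
                rep = tuple(sorted((j // w, j % w) for j in plateau[r]))
            pairs.append(
                PersistencePair(
                    dim=0,
                    birth=int(birth[r]),
                    death=ESSENTIAL_DEATH,
                    essential=True,
                    direction=filt.direction,
                    representative=rep,
                )
            )
    return pairs


def _dim1_pairs(filt: CubicalFiltration, with_representatives: bool) -> list[PersistencePair]:
    vals = filt.values
    h, w = vals.shape
    if h < 2 or w < 2:
        return []  # no squares, hence no bounded complementary region
    sq = filt.square_values()  # (h-1) x (w-1)
    nsq = (h - 1) * (w - 1)
    OUTER = nsq
    sq_flat = sq.ravel()

    def sq_id(r: int, c: int) -> int:
        return r * (w - 1) + c

    # dual edges: one per primal edge, connecting the two incident faces
    du_a: list[int] = []
    du_b: list[int] = []
    du_v: list[int] = []
    horiz, vert = filt.edge_values()
    for r in range(h):
        for c in range(w - 1):  # horizontal primal edge (r,c)-(r,c+1)
            above = sq_id(r - 1, c) if r > 0 else OUTER
            below = sq_id(r, c) if r < h - 1 else OUTER
            du_a.append(above)
            du_b.append(below)
            du_v.append(int(horiz[r, c]))
    for r in range(h - 1):
        for c in range(w):  # vertical primal edge (r,c)-(r+1,c)
            left = sq_id(r, c - 1) if c > 0 else OUTER
            right = sq_id(r, c) if c < w - 1 else OUTER
            du_a.append(left)
            du_b.append(right)
            du_v.append(int(vert[r, c]))

    a_arr = np.asarray(du_a)
    b_arr = np.asarray(du_b)
    v_arr = np.asarray(du_v)
    order = np.lexsort((b_arr, a_arr, -v_arr))  # by (-value, a, b): reverse sweep
    a_arr, b_arr, v_arr = a_arr[order], b_arr[order], v_arr[order]

    uf = _UnionFind(nsq + 1)
    # reverse-filtration birth of a complementary region = max square value in it
    rbirth = np.empty(nsq + 1, dtype=np.int64)
    rbirth[:nsq] = sq_flat
    rbirth[OUTER] = np.iinfo(np.int64).max  # the unbounded face never dies
    anchor = np.arange(nsq + 1)
    members: list[list[int]] | None = None
    if with_representatives:
        members = [[i] for i in range(nsq)] + [[]]  # OUTER tracks no squares

    pairs: list[PersistencePair] = []
    for a, b, v in zip(a_arr.tolist(), b_arr.tolist(), v_arr.tolist()):
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            continue
        # elder (survivor): larger reverse birth; ties by smaller anchor
        if (rbirth[rb], -anchor[rb]) > (rbirth[ra], -anchor[ra]):
            ra, rb = rb, ra
        # rb dies: forward bar born at the dual-edge level v, dying at rbirth[rb]
        if v < rbirth[rb]:
            rep: tuple[tuple[int, int], ...] = ()
            region: tuple[tuple[int, int], ...] = ()
            if members is not None:
                region_sq = members[rb]
                rep, region = _hole_boundary(region_sq, w)
            pairs.append(
                PersistencePair(
                    dim=1,
                    birth=int(v),
                    death=int(rbirth[rb]),
                    direction=filt.direction,
                    representative=rep,
                    region=region,
                )
            )
        if members is not None:
            if len(members[ra]) < len(members[rb]):
                members[ra], members[rb] = members[rb], members[ra]
            members[ra].extend(members[rb])
            members[rb] = []
        uf.parent[rb] = ra
    return pairs


def _hole_boundary(region_sq: list[int], w: int):
    """Boundary loop and pixel support of a set of squares (flat ids, width w-1).

    Returns (loop pixels, region pixels): the loop is the set of lattice
    vertices on edges bordered by exactly one region square; the region is
    every corner pixel of the region's squares.
    """
    sq_set = set(region_sq)
    wc = w - 1
    loop: set[tuple[int, int]] = set()
    region_px: set[tuple[int, int]] = set()
    for q in region_sq:
        r, c = divmod(q, wc)
        region_px.update(((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)))
        if r == 0 or (q - wc) not in sq_set:  # top neighbour absent
            loop.update(((r, c), (r, c + 1)))
        if (q + wc) not in sq_set:  # bottom neighbour absent (also past last row)
            loop.update(((r + 1, c), (r + 1, c + 1)))
        if c == 0 or (q - 1) not in sq_set:  # left neighbour absent
            loop.update(((r, c), (r + 1, c)))
        if c == wc - 1 or (q + 1) not in sq_set:  # right neighbour absent
            loop.update(((r, c + 1), (r + 1, c + 1)))
    return tuple(sorted(loop)), tuple(sorted(region_px))


def persistence(
    filt: CubicalFiltration, representatives: bool = True
) -> list[PersistencePair]:
    """Dimension-0 and dimension-1 persistence pairs of a cubical filtration.

    Zero-persistence pairs are dropped.  Output is deterministically ordered
    by (dim, birth, death, anchor).  Set ``representatives=False`` to skip
    representative extraction on large images.
    """
    pairs = _dim0_pairs(filt, representatives) + _dim1_pairs(filt, representatives)
    pairs.sort(key=lambda p: (p.dim, p.birth, p.death, p.anchor))
    return pairs


def pairs_to_frame(pairs: list[PersistencePair]):
    """Persistence pairs as a pandas DataFrame (CSV-friendly)."""
    import pandas as pd

    rows = []
    for p in pairs:
        ar, ac = p.anchor
        rows.append(
            {
                "dim": p.dim,
                "birth": p.birth,
                "death": p.death,
                "essential": p.essential,
                "direction": p.direction,
                "n_rep_pixels": len(p.representative),
                "anchor_row": ar,
                "anchor_col": ac,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "dim",
            "birth",
            "death",
            "essential",
            "direction",
            "n_rep_pixels",
            "anchor_row",
            "anchor_col",
        ],
    )


def frame_to_pairs(df) -> list[PersistencePair]:
    """Rebuild bare pairs (no representatives) from :func:`pairs_to_frame` output."""
    return [
        PersistencePair(
            dim=int(r.dim),
            birth=int(r.birth),
            death=int(r.death),
            essential=bool(r.essential),
            direction=str(r.direction),
        )
        for r in df.itertuples()
    ]
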