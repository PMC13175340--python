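"""Textbook persistence via boundary-matrix reduction over Z/2.

Independent reference implementation for small instances (total cell count
<= ~10^4).  Columns are stored as Python integers used as bitmasks, so column
addition is XOR and the pivot is the highest set bit.  Used by the test suite
to validate the union-find computation in :mod:`topogaze.cubical`; it returns
(dim, birth, death) multisets only, no representatives.
"""

from __future__ import annotations

from .cubical import ESSENTIAL_DEATH, CubicalFiltration

__all__ = ["oracle_persistence", "MAX_CELLS"]

MAX_CELLS = 10_000


def _cells(filt: CubicalFiltration):
    """All cells as (value, dim, tie_index, face_cell_keys)."""
    vals = filt.values
    h, w = vals.shape
    cells = []

    def vkey(r, c):
        return (0, r * w + c)

    def ekey(kind, r, c):  # kind 0: horizontal, 1: vertical
        return (1, kind * h * w + r * w + c)

    for r in range(h):
        for c in range(w):
            cells.append((int(vals[r, c]), 0, vkey(r, c), ()))
    for r in range(h):
        for c in range(w - 1):
            v = max(int(vals[r, c]), int(vals[r, c + 1]))
            cells.append((v, 1, ekey(0, r, c), (vkey(r, c), vkey(r, c + 1))))
    for r in range(h - 1):
        for c in range(w):
            v = max(int(vals[r, c]), int(vals[r + 1, c]))
            cells.append((v, 1, ekey(1, r, c), (vkey(r, c), vkey(r + 1, c))))
    for r in range(h - 1):
        for c in range(w - 1):
            v = max(
                int(vals[r, c]),
                int(vals[r, c + 1]),
                int(vals[r + 1, c]),
                int(vals[r + 1, c + 1]),
            )
            faces = (ekey(0, r, c), ekey(0, r + 1, c), ekey(1, r, c), ekey(1, r, c + 1))
            cells.append((v, 2, (2, r * w + c), faces))
    return cells


def oracle_persistence(filt: CubicalFiltration) -> list[tuple[int, int, int, bool]]:
    """(dim, birth, death, essential) multiset by standard column reduction.

    Faces precede cofaces in the filtration order (a face never has a larger
    value, and at equal value the lower dimension sorts first).  Essential
    classes get the capped death level.  Zero-persistence pairs are dropped,
    matching :func:`topogaze.cubical.persistence`.
    """
    cells = _cells(filt)
    if len(cells) > MAX_CELLS:
        raise ValueError(
            f"instance too large for the reduction oracle: {len(cells)} cells > {MAX_CELLS}"
        )
    cells.sort(key=lambda c: (c[0], c[1], c[2]))
    index = {key: i for i, (_, _, key, _) in enumerate(cells)}

    columns: list[int] = []
    for _, _, _, faces in cells:
        col = 0
        for f in faces:
            col |= 1 << index[f]
        columns.append(col)

    low_to_col: dict[int, int] = {}
    pairs: list[tuple[int, int, int, bool]] = []
    paired: set[int] = set()
    for j in range(len(columns)):
        col = columns[j]
        while col:
            low = col.bit_length() - 1
            other = low_to_col.get(low)
            if other is None:
                break
            col ^= columns[other]
        columns[j] = col
        if col:
            low = col.bit_length() - 1
            low_to_col[low] = j
            paired.add(low)
            paired.add(j)
            birth, death = cells[low][0], cells[j][0]
            if birth != death:
                pairs.append((cells[low][1], birth, death, False))
    for j in range(len(columns)):
        if j not in paired and columns[j] == 0:
            # unpaired creator: essential class of the cell's own dimension
            pairs.append((cells[j][1], cells[j][0], ESSENTIAL_DEATH, True))
    pairs.sort()
    return pairs
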