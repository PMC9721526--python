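"""Persistent homology of super-level-set cubical filtrations.

Every pixel ``(i, j)`` of a field ``S`` is the closed unit square
``[i, i+1] x [j, j+1]`` (voxels analogously).  The super-level set

    B(p) = union of closed pixel cubes with value >= p

grows as the threshold ``p`` is lowered from 1 to 0, and the persistence
barcode of this filtration records the birth/death threshold of every
connected component (dim 0), loop (dim 1) and enclosed cavity (dim 2).

The complex is represented on the "doubled grid": a field of shape
``(N_1, ..., N_d)`` yields cells at integer coordinates ``(a_1, ..., a_d)``
with ``0 <= a_k <= 2 N_k``; the cell dimension is the number of odd
coordinates, and top-dimensional cells (all coordinates odd) are the pixels
themselves.  A lower-dimensional face enters the filtration with its first
cofacing pixel, i.e. carries the *maximum* value over cofacing pixels.
Because closed cubes are used, diagonally adjacent pixels share a vertex and
are therefore connected (8-connectivity in 2D, 26 in 3D).

Each finite bar is created by one cell and killed by another, and each
cell's filtration value equals the value of one specific pixel (ties broken
towards the lexicographically smallest pixel index, which makes barcodes and
critical cells deterministic).  Those two pixels are the bar's *critical
cells*: perturbing them perturbs the bar's endpoints one-to-one, which is
what makes the barcode differentiable with respect to the field.
"""

from __future__ import annotations

import csv
import itertools
import json
import os
from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import validate_field

__all__ = [
    "Bar",
    "Barcode",
    "FilteredCubicalComplex",
    "build_filtration",
    "compute_barcode",
    "betti_at_threshold",
    "reference_barcode_bruteforce",
    "plot_barcode",
]

#: sentinel pixel index for the (truncated) death of the essential component
ESSENTIAL_DEATH_CELL = -1

# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bar:
    """One persistence interval of the super-level filtration.

    ``birth >= death`` because the filtration runs from high thresholds to
    low ones.  ``birth_cell``/``death_cell`` are flat pixel indices whose
    field values equal ``birth``/``death`` exactly; the essential component's
    death is truncated to 0 and its death cell is a sentinel (-1).
    """

    dim: int
    birth: float
    death: float
    birth_cell: int
    death_cell: int
    essential: bool = False

    @property
    def length(self) -> float:
        return self.birth - self.death


@dataclass
class Barcode:
    """Bars grouped by dimension, each group sorted by descending length.

    Rank ``ell`` (1-based position within a dimension) follows the sort
    order: longest bar first, ties broken by higher birth, then by smaller
    birth-cell index.
    """

    bars: list[Bar] = dc_field(default_factory=list)
    shape: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.bars = sorted(
            self.bars, key=lambda b: (b.dim, -b.length, -b.birth, b.birth_cell)
        )

    def of_dim(self, dim: int) -> list[Bar]:
        return [b for b in self.bars if b.dim == dim]

    def n_alive(self, p: float, dim: int) -> int:
        """Number of dim-``dim`` features of B(p): bars with death < p <= birth."""
        return sum(1 for b in self.of_dim(dim) if b.death < p <= b.birth)

    def multiset(self, *, decimals: int = 10) -> list[tuple[int, float, float]]:
        """The (dim, birth, death) multiset, rounded, in sorted order."""
        return sorted(
            (b.dim, round(b.birth, decimals), round(b.death, decimals))
            for b in self.bars
        )

    # -- export ------------------------------------------------------------

    def to_records(self) -> list[dict]:
        recs = []
        ell = {}
        for b in self.bars:
            ell[b.dim] = ell.get(b.dim, 0) + 1
            recs.append(
                {
                    "dim": b.dim,
                    "ell": ell[b.dim],
                    "birth": b.birth,
                    "death": b.death,
                    "birth_cell": b.birth_cell,
                    "death_cell": b.death_cell,
                    "essential": b.essential,
                }
            )
        return recs

    def to_csv(self, path: str | os.PathLike) -> None:
        recs = self.to_records()
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(
                fh,
                fieldnames=[
                    "dim", "ell", "birth", "death",
                    "birth_cell", "death_cell", "essential",
                ],
            )
            w.writeheader()
            w.writerows(recs)

    def to_json(self, path: str | os.PathLike | None = None) -> dict:
        obj = {"shape": list(self.shape), "bars": self.to_records()}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2)
        return obj


# ---------------------------------------------------------------------------
# Filtration construction (doubled-grid arrays)
# ---------------------------------------------------------------------------


class FilteredCubicalComplex:
    """The filtered cubical complex of a field, on the doubled grid.

    Attributes
    ----------
    shape : pixel-grid shape of the underlying field
    dshape : doubled-grid shape, ``2*N_k + 1`` per axis
    cell_values : filtration value of every cell (max over cofacing pixels)
    cell_pixel : flat index of the pixel responsible for each cell's value
    cell_dims : dimension (number of odd coordinates) of every cell
    """

    def __init__(self, field: np.ndarray):
        S = validate_field(field)
        self.field = S
        self.shape = S.shape
        self.ndim = S.ndim
        self.dshape = tuple(2 * n + 1 for n in self.shape)
        vals, pix = _cofacing_max(S)
        self.cell_values = vals
        self.cell_pixel = pix
        parities = sum(np.indices(self.dshape) % 2)
        self.cell_dims = parities.astype(np.int8)

    def n_cells(self, dim: int) -> int:
        return int(np.count_nonzero(self.cell_dims == dim))

    def superlevel_mask(self, p: float) -> np.ndarray:
        """Doubled-grid boolean mask of the closed cubical set B(p)."""
        return self.cell_values >= p


def _cofacing_max(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Max field value over cofacing pixels for every doubled-grid cell.

    Returns (values, responsible-pixel flat indices).  Ties go to the
    lexicographically smallest pixel index.
    """
    d = S.ndim
    shape = S.shape
    dshape = tuple(2 * n + 1 for n in shape)
    Spad = np.full(tuple(n + 2 for n in shape), -np.inf)
    Spad[tuple(slice(1, n + 1) for n in shape)] = S
    # candidate pixel index below/above each doubled coordinate
    ax_lo = [(np.arange(m) - 1) // 2 for m in dshape]
    ax_hi = [np.arange(m) // 2 for m in dshape]
    vals = np.full(dshape, -np.inf)
    pix = np.full(dshape, -1, dtype=np.int64)
    # combos in lexicographically increasing pixel order; strict > keeps the
    # first (smallest) maximiser
    for combo in itertools.product((0, 1), repeat=d):
        idx = [ax_hi[k] if combo[k] else ax_lo[k] for k in range(d)]
        grids = np.meshgrid(*idx, indexing="ij")
        v = Spad[tuple(g + 1 for g in grids)]
        flat = np.zeros(dshape, dtype=np.int64)
        for k, g in enumerate(grids):
            flat = flat * shape[k] + np.clip(g, 0, shape[k] - 1)
        upd = v > vals
        vals[upd] = v[upd]
        pix[upd] = flat[upd]
    return vals, pix


def build_filtration(field: np.ndarray) -> FilteredCubicalComplex:
    """Build the full super-level-set cubical filtration of a field."""
    return FilteredCubicalComplex(field)


# ---------------------------------------------------------------------------
# Persistence via sparse boundary reduction
# ---------------------------------------------------------------------------


def _sym_diff(a: list[int], b: list[int]) -> list[int]:
    """Symmetric difference of two ascending integer lists (GF(2) addition)."""
    out = []
    i = j = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        x, y = a[i], b[j]
        if x < y:
            out.append(x)
            i += 1
        elif y < x:
            out.append(y)
            j += 1
        else:
            i += 1
            j += 1
    out.extend(a[i:])
    out.extend(b[j:])
    return out


def compute_barcode(field: np.ndarray, max_dim: int | None = None) -> Barcode:
    """Persistence barcode of the super-level-set filtration of ``field``.

    Zero-length bars are dropped.  The single essential component is
    reported with its death truncated to filtration value 0 and a sentinel
    death cell; essential classes cannot occur in higher dimensions because
    B(0) is the full (contractible) grid.
    """
    fcc = build_filtration(field)
    d = fcc.ndim
    if max_dim is None:
        max_dim = d - 1
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")

    vals = fcc.cell_values.ravel()
    dims = fcc.cell_dims.ravel()
    pix = fcc.cell_pixel.ravel()
    M = vals.size
    # faces must precede cofaces within a value tie -> sort by dim ascending;
    # flat index last for full determinism
    order = np.lexsort((np.arange(M), dims, -vals))
    rank = np.empty(M, dtype=np.int64)
    rank[order] = np.arange(M)

    dshape = fcc.dshape
    strides = np.array(
        [int(np.prod(dshape[k + 1:])) for k in range(d)], dtype=np.int64
    )
    coords = np.unravel_index(order, dshape)
    odd = [(coords[k] % 2).astype(bool) for k in range(d)]

    pivot_owner: dict[int, int] = {}
    reduced: list[list[int]] = [None] * M  # type: ignore[list-item]
    pairs: list[tuple[int, int]] = []
    rank_l = rank  # local alias
    for j in range(M):
        cell = order[j]
        col: list[int] = []
        for k in range(d):
            if odd[k][j]:
                s = strides[k]
                col.append(rank_l[cell - s])
                col.append(rank_l[cell + s])
        col.sort()
        while col:
            piv = col[-1]
            owner = pivot_owner.get(piv)
            if owner is None:
                break
            col = _sym_diff(col, reduced[owner])
        if col:
            pivot_owner[col[-1]] = j
            reduced[j] = col
            pairs.append((col[-1], j))
        else:
            reduced[j] = col

    bars: list[Bar] = []
    paired_positive = set()
    for i, j in pairs:
        paired_positive.add(i)
        bi, bj = order[i], order[j]
        birth, death = float(vals[bi]), float(vals[bj])
        if birth == death:
            continue
        k = int(dims[bi])
        if k > max_dim:
            continue
        bars.append(Bar(k, birth, death, int(pix[bi]), int(pix[bj])))

    used_as_pivot = set(pivot_owner.values())
    for j in range(M):
        if reduced[j] or j in used_as_pivot or j in paired_positive:
            continue
        # unpaired positive cell: essential class
        bj = order[j]
        k = int(dims[bj])
        if k != 0:
            raise AssertionError(
                "essential class of dimension > 0 in a full-grid filtration"
            )
        birth = float(vals[bj])
        if birth == 0.0:
            continue  # all-zero field: zero-length essential bar is dropped
        bars.append(
            Bar(0, birth, 0.0, int(pix[bj]), ESSENTIAL_DEATH_CELL, essential=True)
        )

    n_ess = sum(1 for b in bars if b.essential)
    if vals.max() > 0 and n_ess != 1:
        raise AssertionError(f"expected exactly one essential bar, got {n_ess}")
    return Barcode(bars, shape=fcc.shape)


# ---------------------------------------------------------------------------
# Betti-number oracles (no persistence involved)
# ---------------------------------------------------------------------------


def _doubled_mask(mask: np.ndarray) -> np.ndarray:
    """Doubled-grid cells of the closed cubical set spanned by ``mask``."""
    return _cofacing_max(mask.astype(np.float64))[0] >= 0.5


def _cell_counts(mask: np.ndarray) -> np.ndarray:
    """Count of k-cells, k = 0..d, of the closed cubical set of ``mask``."""
    dm = _doubled_mask(mask)
    d = mask.ndim
    dims = sum(np.indices(dm.shape) % 2)
    return np.array([np.count_nonzero(dm & (dims == k)) for k in range(d + 1)])


def _gf2_rank(columns: list[int]) -> int:
    """Rank over GF(2) of a matrix given as bitmask columns."""
    pivots: dict[int, int] = {}
    r = 0
    for col in columns:
        while col:
            hi = col.bit_length() - 1
            p = pivots.get(hi)
            if p is None:
                pivots[hi] = col
                r += 1
                break
            col ^= p
    return r


def _betti_gf2(mask: np.ndarray) -> list[int]:
    """All Betti numbers of the closed cubical set via GF(2) boundary ranks."""
    d = mask.ndim
    dm = _doubled_mask(mask)
    dshape = dm.shape
    dims = sum(np.indices(dshape) % 2)
    strides = [int(np.prod(dshape[k + 1:])) for k in range(d)]
    flat_cells = {
        k: np.flatnonzero(dm.ravel() & (dims.ravel() == k)) for k in range(d + 1)
    }
    index_of = {k: {int(c): i for i, c in enumerate(flat_cells[k])} for k in range(d + 1)}
    n = {k: len(flat_cells[k]) for k in range(d + 1)}

    ranks = {0: 0, d + 1: 0}
    for k in range(1, d + 1):
        cols = []
        lower = index_of[k - 1]
        for c in flat_cells[k]:
            c = int(c)
            coord = np.unravel_index(c, dshape)
            bits = 0
            for ax in range(d):
                if coord[ax] % 2:
                    bits ^= 1 << lower[c - strides[ax]]
                    bits ^= 1 << lower[c + strides[ax]]
            cols.append(bits)
        ranks[k] = _gf2_rank(cols)
    return [n[k] - ranks[k] - ranks[k + 1] for k in range(d + 1)]


def _betti_fast(mask: np.ndarray) -> list[int]:
    """Betti numbers via connected components, Euler characteristic and
    (in 3D) cavity counting on the complement.

    Foreground components use vertex adjacency (8/26-connectivity), the
    convention implied by unions of closed cubes.  In 3D the number of
    cavities equals the number of bounded 6-connected components of the
    complement, and beta_1 follows from the Euler characteristic.
    """
    from scipy import ndimage

    d = mask.ndim
    if not mask.any():
        return [0] * (d + 1)
    full = np.ones((3,) * d, dtype=bool)
    b0 = int(ndimage.label(mask, structure=full)[1])
    counts = _cell_counts(mask)
    chi = int(sum((-1) ** k * counts[k] for k in range(d + 1)))
    if d == 2:
        return [b0, b0 - chi, 0]
    comp = np.pad(~mask, 1, constant_values=True)
    face = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    lab, ncomp = ndimage.label(comp, structure=face)
    b2 = int(ncomp) - 1  # all components except the unbounded outside
    return [b0, b0 + b2 - chi, b2]


#: above this many doubled-grid cells the GF(2) route is refused
_GF2_CELL_LIMIT = 20_000


def betti_at_threshold(
    field: np.ndarray, p: float, dim: int, *, method: str = "auto"
) -> int:
    """Betti number ``beta_dim`` of the super-level set B(p), without persistence.

    ``method`` is one of ``"auto"``, ``"fast"`` (union-find + Euler
    characteristic, plus complement-cavity counting in 3D) or ``"gf2"``
    (ranks of GF(2) boundary matrices; small inputs only).  The two routes
    are algorithmically independent and agree exactly.
    """
    arr = validate_field(field)
    d = arr.ndim
    if dim > d - 1 or dim > 2 or dim < 0:
        raise ValueError(f"homology dimension {dim} invalid for a {d}D field")
    mask = arr >= p
    if method == "auto":
        ncells = int(np.prod([2 * n + 1 for n in arr.shape]))
        method = "gf2" if (d == 3 and ncells <= _GF2_CELL_LIMIT) else "fast"
    if method == "gf2":
        ncells = int(np.prod([2 * n + 1 for n in arr.shape]))
        if ncells > _GF2_CELL_LIMIT:
            raise ValueError("field too large for the GF(2) Betti computation")
        return _betti_gf2(mask)[dim]
    if method == "fast":
        return _betti_fast(mask)[dim]
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Brute-force reference barcode (independent oracle)
# ---------------------------------------------------------------------------


def reference_barcode_bruteforce(field: np.ndarray) -> Barcode:
    """Barcode by dense GF(2) boundary-matrix reduction in filtration order.

    An independent oracle for :func:`compute_barcode`: cells are enumerated
    as coordinate tuples, filtration values computed by explicit maxima over
    cofacing pixels, and the full dense boundary matrix is reduced column by
    column.  Tractable only for tiny fields (<= 500 pixels/voxels).
    """
    arr = validate_field(field)
    if arr.size > 500:
        raise ValueError("brute-force oracle limited to fields with <= 500 cells")
    d = arr.ndim
    shape = arr.shape

    cells = list(itertools.product(*(range(2 * n + 1) for n in shape)))

    def cofaces(coord):
        rngs = []
        for k, a in enumerate(coord):
            if a % 2:
                rngs.append([(a - 1) // 2])
            else:
                rngs.append([i for i in (a // 2 - 1, a // 2) if 0 <= i < shape[k]])
        return list(itertools.product(*rngs))

    info = []
    for coord in cells:
        pxs = cofaces(coord)
        vmax = max(arr[q] for q in pxs)
        # lexicographically smallest maximising pixel
        critical = min(q for q in pxs if arr[q] == vmax)
        info.append((coord, float(vmax), sum(a % 2 for a in coord), critical))
    info.sort(key=lambda t: (-t[1], t[2], t[0]))

    M = len(info)
    pos = {t[0]: i for i, t in enumerate(info)}
    mat = np.zeros((M, M), dtype=bool)
    for j, (coord, _, _, _) in enumerate(info):
        for k, a in enumerate(coord):
            if a % 2:
                for delta in (-1, 1):
                    fc = list(coord)
                    fc[k] = a + delta
                    mat[pos[tuple(fc)], j] = True

    lows: dict[int, int] = {}
    pairs = []
    for j in range(M):
        while True:
            nz = np.flatnonzero(mat[:, j])
            if nz.size == 0:
                break
            low = int(nz[-1])
            if low not in lows:
                lows[low] = j
                pairs.append((low, j))
                break
            mat[:, j] ^= mat[:, lows[low]]

    bars = []
    killed = {i for i, _ in pairs}
    creators = set(range(M)) - {j for _, j in pairs}
    for i, j in pairs:
        birth, death = info[i][1], info[j][1]
        if birth == death:
            continue
        k = info[i][2]
        b_px = int(np.ravel_multi_index(info[i][3], shape))
        d_px = int(np.ravel_multi_index(info[j][3], shape))
        bars.append(Bar(k, birth, death, b_px, d_px))
    for i in sorted(creators - killed):
        if info[i][2] != 0:
            raise AssertionError("essential class of dimension > 0")
        birth = info[i][1]
        if birth == 0.0:
            continue
        b_px = int(np.ravel_multi_index(info[i][3], shape))
        bars.append(Bar(0, birth, 0.0, b_px, ESSENTIAL_DEATH_CELL, essential=True))
    return Barcode(bars, shape=shape)


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------


def plot_barcode(barcode: Barcode, path: str | os.PathLike | None = None, ax=None):
    """Horizontal-bar barcode plot, one colour per homology dimension."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    colors = {0: "tab:red", 1: "tab:green", 2: "tab:blue"}
    y = 0
    for k in sorted({b.dim for b in barcode.bars}):
        for b in barcode.of_dim(k):
            ax.hlines(y, b.death, b.birth, color=colors.get(k, "k"), lw=3)
            y += 1
        y += 1
    ax.set_xlim(-0.02, 1.02)
    ax.set_xlabel("filtration value $p$")
    ax.set_yticks([])
    handles = [
        plt.Line2D([], [], color=colors[k], lw=3, label=f"dim {k}")
        for k in sorted({b.dim for b in barcode.bars})
    ]
    if handles:
        ax.legend(handles=handles, loc="lower left", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
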