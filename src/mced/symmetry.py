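"""Laue-group machinery: operator sets, asymmetric-unit reduction, filters.

Diffraction intensities obey the Laue symmetry of the crystal (point group
plus inversion, 11 classes).  Everything downstream — correlating two
datasets on their common reflections, computing completeness against the
set of all symmetry-unique reflections, merging repeated measurements —
needs a canonical representative per symmetry orbit of (h, k, l).  The
canonical index used throughout is the lexicographic maximum over the full
orbit: a single rule for all 11 classes that an exhaustive orbit search can
verify directly.

Conventions: monoclinic unique axis b; rhombohedral lattices in the
hexagonal (obverse) setting with the R centering rule −h+k+l ≡ 0 (mod 3);
trigonal −3m in the −3m1 setting.  Friedel mates are always equivalent
(−I belongs to every Laue class), as appropriate for intensity-only data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import gemmi
import numpy as np
import pandas as pd

from .lattice_cluster import UnitCell

__all__ = [
    "LaueGroup",
    "ReflectionSet",
    "ReindexOperator",
    "LAUE_SYMBOLS",
    "d_spacing",
    "asu_map",
    "merge_within",
    "filter_reflections",
    "apply_reindex",
    "enumerate_unique",
    "centering_mask",
]

log = logging.getLogger(__name__)

# Representative symmorphic primitive space group for each of the 11 Laue
# classes; its rotation parts are exactly the point-group operators.
_LAUE_REPRESENTATIVE = {
    "-1": "P -1",
    "2/m": "P 1 2/m 1",  # unique axis b
    "mmm": "P m m m",
    "4/m": "P 4/m",
    "4/mmm": "P 4/m m m",
    "-3": "P -3",
    "-3m": "P -3 m 1",
    "6/m": "P 6/m",
    "6/mmm": "P 6/m m m",
    "m-3": "P m -3",
    "m-3m": "P m -3 m",
}

LAUE_SYMBOLS = tuple(_LAUE_REPRESENTATIVE)

_LAUE_ORDER = {
    "-1": 2, "2/m": 4, "mmm": 8, "4/m": 8, "4/mmm": 16,
    "-3": 6, "-3m": 12, "6/m": 12, "6/mmm": 24, "m-3": 24, "m-3m": 48,
}

_CENTERINGS = ("P", "A", "B", "C", "I", "F", "R")


@dataclass(frozen=True)
class LaueGroup:
    """One of the 11 Laue classes with its integer operator set.

    Operators act on (h, k, l) as row vectors: hkl' = hkl · M.
    """

    symbol: str
    ops: np.ndarray = field(repr=False)  # (order, 3, 3) int

    @classmethod
    @lru_cache(maxsize=None)
    def from_symbol(cls, symbol: str) -> "LaueGroup":
        if symbol not in _LAUE_REPRESENTATIVE:
            raise ValueError(
                f"unknown Laue symbol {symbol!r}; expected one of {sorted(_LAUE_REPRESENTATIVE)}"
            )
        sg = gemmi.find_spacegroup_by_name(_LAUE_REPRESENTATIVE[symbol])
        mats = {
            tuple(int(x) for x in (np.array(op.rot) // gemmi.Op.DEN).flatten())
            for op in sg.operations()
        }
        ops = np.array(sorted(mats), dtype=np.int64).reshape(-1, 3, 3)
        if len(ops) != _LAUE_ORDER[symbol]:
            raise RuntimeError(f"operator set for {symbol} has wrong order {len(ops)}")
        return cls(symbol, ops)

    @property
    def order(self) -> int:
        return len(self.ops)

    def __eq__(self, other) -> bool:
        return isinstance(other, LaueGroup) and self.symbol == other.symbol

    def __hash__(self) -> int:
        return hash(self.symbol)


def _as_laue(laue: "LaueGroup | str") -> LaueGroup:
    return laue if isinstance(laue, LaueGroup) else LaueGroup.from_symbol(laue)


@dataclass(frozen=True)
class ReindexOperator:
    """Integer 3×3 matrix M with |det M| = 1, acting as hkl' = hkl · M."""

    matrix: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        m = self.as_array()
        if m.shape != (3, 3):
            raise ValueError("reindex operator must be 3×3")
        if abs(round(float(np.linalg.det(m)))) != 1:
            raise ValueError(f"reindex operator must have |det| = 1, got det = {np.linalg.det(m):g}")

    @classmethod
    def from_array(cls, m) -> "ReindexOperator":
        m = np.asarray(m, dtype=int)
        return cls(tuple(tuple(int(x) for x in row) for row in m))

    def as_array(self) -> np.ndarray:
        return np.array(self.matrix, dtype=np.int64)


#: Axis permutation a' = b, b' = c, c' = a (order-3 cycle).
REINDEX_ABC_TO_BCA = ReindexOperator(((0, 0, 1), (1, 0, 0), (0, 1, 0)))
#: Swap of the b and c axes (the classic ambiguity when b ≈ c).
REINDEX_SWAP_BC = ReindexOperator(((1, 0, 0), (0, 0, 1), (0, 1, 0)))


@dataclass
class ReflectionSet:
    """Indexed intensities of one dataset (or one merged cluster).

    ``df`` holds columns h, k, l (int), I, sigma (float) and, once merged,
    n_obs (multiplicity).  σ must be positive for every record.
    """

    dataset_id: str
    cell: UnitCell
    laue: LaueGroup
    centering: str = "P"
    df: pd.DataFrame = None
    merged: bool = False

    def __post_init__(self) -> None:
        self.laue = _as_laue(self.laue)
        if self.centering not in _CENTERINGS:
            raise ValueError(f"unknown centering {self.centering!r}")
        if self.df is None:
            self.df = pd.DataFrame(columns=["h", "k", "l", "I", "sigma"])
        req = {"h", "k", "l", "I", "sigma"}
        if not req.issubset(self.df.columns):
            raise ValueError(f"reflection table must have columns {sorted(req)}")
        if len(self.df):
            if not np.all(np.isfinite(self.df["I"])):
                raise ValueError("non-finite intensity")
            if not np.all(self.df["sigma"] > 0):
                raise ValueError("sigma must be positive")
            if np.any((self.df[["h", "k", "l"]] == 0).all(axis=1)):
                raise ValueError("(0,0,0) is not a reflection")
        if self.merged:
            hkl = self.df[["h", "k", "l"]].to_numpy()
            if len(hkl) != len(np.unique(hkl, axis=0)):
                raise ValueError("merged set has duplicate unique indices")

    @property
    def n_reflections(self) -> int:
        return len(self.df)

    def hkl_array(self) -> np.ndarray:
        return self.df[["h", "k", "l"]].to_numpy(dtype=np.int64)


def d_spacing(cell: UnitCell, hkl) -> np.ndarray | float:
    """Resolution d (Å) of reflections via the reciprocal metric tensor."""
    hkl_arr = np.atleast_2d(np.asarray(hkl, dtype=float))
    if np.any((hkl_arr == 0).all(axis=1)):
        raise ValueError("(0,0,0) has no d-spacing")
    gstar = cell.reciprocal_metric_tensor()
    inv_d2 = np.einsum("ni,ij,nj->n", hkl_arr, gstar, hkl_arr)
    d = 1.0 / np.sqrt(inv_d2)
    return float(d[0]) if np.ndim(hkl) == 1 else d


def _orbit_codes(ops: np.ndarray, hkl: np.ndarray) -> np.ndarray:
    """Encoded orbit of each reflection, shape (n_ops, n)."""
    m = int(np.abs(hkl).max()) + 1 if hkl.size else 1
    base = 2 * m + 1
    orbit = np.einsum("nj,oji->oni", hkl, ops)  # hkl · M for every op
    return ((orbit[..., 0] + m) * base + (orbit[..., 1] + m)) * base + (orbit[..., 2] + m)


def asu_map(laue: LaueGroup | str, hkl) -> np.ndarray:
    """Canonical (asymmetric-unit) representative: lexicographic maximum
    over the orbit {hkl · M : M in the Laue group}.  Idempotent and
    constant on orbits."""
    laue = _as_laue(laue)
    single = np.ndim(hkl) == 1
    hkl_arr = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
    if hkl_arr.size == 0:
        return hkl_arr
    codes = _orbit_codes(laue.ops, hkl_arr)
    best = np.argmax(codes, axis=0)  # lexicographic max == max of the code
    orbit = np.einsum("nj,oji->oni", hkl_arr, laue.ops)
    out = orbit[best, np.arange(hkl_arr.shape[0])]
    return out[0] if single else out


def merge_within(rset: ReflectionSet) -> ReflectionSet:
    """Merge symmetry-equivalent measurements of one dataset.

    Per canonical index: I = unweighted mean, σ = √(Σσᵢ²)/n, multiplicity
    n_obs recorded.  Idempotent on an already-merged set.
    """
    if rset.n_reflections == 0:
        df = rset.df.copy()
        df["n_obs"] = pd.Series(dtype=int)
        return replace(rset, df=df, merged=True)
    can = asu_map(rset.laue, rset.hkl_array())
    df = rset.df.copy()
    df[["h", "k", "l"]] = can
    if "n_obs" not in df.columns:
        df["n_obs"] = 1
    # A merged record with multiplicity n and σ_m = √(Σσᵢ²)/n stands for a
    # sum of squares σ_m²·n²; tracking that sum keeps the rule idempotent.
    df["_s2w"] = df["sigma"] ** 2 * df["n_obs"] ** 2
    g = df.groupby(["h", "k", "l"], sort=True)
    merged = g.agg(I=("I", "mean"), _s2=("_s2w", "sum"), n_obs=("n_obs", "sum")).reset_index()
    merged["sigma"] = np.sqrt(merged["_s2"]) / merged["n_obs"]
    merged = merged[["h", "k", "l", "I", "sigma", "n_obs"]]
    return replace(rset, df=merged, merged=True)


def filter_reflections(
    rset: ReflectionSet,
    d_min: float | None = None,
    d_max: float | None = None,
    min_i_over_sigma: float | None = None,
) -> ReflectionSet:
    """Keep reflections with d_min ≤ d ≤ d_max and I/σ ≥ min_i_over_sigma.

    Both bounds are inclusive.  The number of records removed by each
    criterion is logged.
    """
    if d_min is not None and d_max is not None and d_min > d_max:
        raise ValueError("d_min must not exceed d_max")
    if rset.n_reflections == 0:
        return replace(rset, df=rset.df.copy())
    keep = np.ones(rset.n_reflections, dtype=bool)
    d = d_spacing(rset.cell, rset.hkl_array())
    if d_min is not None:
        bad = d < d_min
        log.debug("%s: %d reflections below d_min", rset.dataset_id, int(bad.sum()))
        keep &= ~bad
    if d_max is not None:
        bad = d > d_max
        log.debug("%s: %d reflections above d_max", rset.dataset_id, int(bad.sum()))
        keep &= ~bad
    if min_i_over_sigma is not None:
        ios = rset.df["I"].to_numpy() / rset.df["sigma"].to_numpy()
        bad = ios < min_i_over_sigma
        log.debug("%s: %d reflections below I/sigma cutoff", rset.dataset_id, int(bad.sum()))
        keep &= ~bad
    return replace(rset, df=rset.df.loc[keep].reset_index(drop=True))


def apply_reindex(rset: ReflectionSet, op: ReindexOperator) -> ReflectionSet:
    """Reindex a dataset: hkl' = hkl · M with the cell transformed consistently.

    The new metric tensor is Mᵀ G M, i.e. the cell axes are permuted/mixed
    the same way as the indices; intensities are untouched.
    """
    m = op.as_array()
    df = rset.df.copy()
    df[["h", "k", "l"]] = rset.hkl_array() @ m
    g = rset.cell.metric_tensor()
    new_cell = UnitCell.from_metric_tensor(m.T @ g @ m)
    return replace(rset, df=df, cell=new_cell)


def centering_mask(hkl: np.ndarray, centering: str) -> np.ndarray:
    """Boolean mask of reflections allowed by the lattice centering."""
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    if centering == "P":
        return np.ones(len(hkl), dtype=bool)
    if centering == "A":
        return (k + l) % 2 == 0
    if centering == "B":
        return (h + l) % 2 == 0
    if centering == "C":
        return (h + k) % 2 == 0
    if centering == "I":
        return (h + k + l) % 2 == 0
    if centering == "F":
        return ((h + k) % 2 == 0) & ((h + l) % 2 == 0)
    if centering == "R":  # hexagonal setting, obverse
        return (-h + k + l) % 3 == 0
    raise ValueError(f"unknown centering {centering!r}")


def enumerate_unique(
    cell: UnitCell,
    laue: LaueGroup | str,
    centering: str = "P",
    d_min: float = 1.0,
    max_grid: int = 30_000_000,
) -> np.ndarray:
    """All symmetry-unique reflections with d ≥ d_min, as canonical indices.

    The index search box is |h| ≤ a/d_min etc. (exact bounds: h = a·s with
    |s| ≤ 1/d_min); centering-forbidden reflections and (0,0,0) are
    excluded before orbit reduction.
    """
    laue = _as_laue(laue)
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    bounds = [int(math.floor(length / d_min)) for length in (cell.a, cell.b, cell.c)]
    grid = (2 * bounds[0] + 1) * (2 * bounds[1] + 1) * (2 * bounds[2] + 1)
    if grid > max_grid:
        raise ValueError(
            f"enumeration grid of {grid} points exceeds the cap; increase d_min"
        )
    h, k, l = np.meshgrid(
        *(np.arange(-b, b + 1, dtype=np.int64) for b in bounds), indexing="ij"
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[~np.all(hkl == 0, axis=1)]
    gstar = cell.reciprocal_metric_tensor()
    inv_d2 = np.einsum("ni,ij,nj->n", hkl.astype(float), gstar, hkl.astype(float))
    hkl = hkl[inv_d2 <= 1.0 / d_min**2 + 1e-12]
    hkl = hkl[centering_mask(hkl, centering)]
    if len(hkl) == 0:
        return np.empty((0, 3), dtype=np.int64)
    can = asu_map(laue, hkl)
    return np.unique(can, axis=0)
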