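"""Stage-1 phase analysis: hierarchical clustering of unit-cell parameters.

Serial electron-diffraction experiments produce one refined unit cell per
crystal.  Cells from one phase scatter around a common mean (the sample
height modulates the effective camera length, so the apparent cell varies
by a few percent), while different phases usually sit far apart in cell
space.  This module clusters the cells with average linkage (UPGMA) on a
plain Euclidean distance, fits Gaussians to windowed per-parameter
histograms to obtain the average cell of a cluster, and ranks candidate
Bravais lattice types by the total number of reflections each one indexed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform

__all__ = [
    "UnitCell",
    "Dendrogram",
    "ClusterAssignment",
    "CellHistogramFit",
    "cell_distance_params",
    "cell_distance_volume",
    "pairwise_cell_distances",
    "average_linkage",
    "cut_dendrogram",
    "suggest_cut",
    "fit_cell_histograms",
    "vote_lattice_type",
    "plot_dendrogram",
    "plot_cell_histograms",
]

CELL_PARAM_NAMES = ("a", "b", "c", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angles must lie in (0, 180): {self}")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        if 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg <= 0.0:
            raise ValueError(f"cell angles do not define a valid lattice: {self}")

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        """Cell volume in Å³, abc·√(1−cos²α−cos²β−cos²γ+2cosαcosβcosγ)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(arg)

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (3×3, Å²)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor())

    def orthogonalization_matrix(self) -> np.ndarray:
        """Columns are the Cartesian basis vectors a, b, c (standard PDB frame)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (a * b * sg)],
            ]
        )

    @classmethod
    def from_metric_tensor(cls, g: np.ndarray) -> "UnitCell":
        g = np.asarray(g, dtype=float)
        a, b, c = (math.sqrt(g[i, i]) for i in range(3))
        alpha = math.degrees(math.acos(g[1, 2] / (b * c)))
        beta = math.degrees(math.acos(g[0, 2] / (a * c)))
        gamma = math.degrees(math.acos(g[0, 1] / (a * b)))
        return cls(a, b, c, alpha, beta, gamma)


def cell_distance_params(c1: UnitCell, c2: UnitCell, scale: Sequence[float] | None = None) -> float:
    """Euclidean distance between the six cell parameters (mixed Å/deg units).

    ``scale`` optionally divides each parameter difference (e.g. by the
    per-parameter standard deviation of the ensemble for a z-scored
    variant); the default is the plain unweighted norm.
    """
    d = np.subtract(c1.parameters, c2.parameters, dtype=float)
    if scale is not None:
        d = d / np.asarray(scale, dtype=float)
    return float(np.linalg.norm(d))


def cell_distance_volume(c1: UnitCell, c2: UnitCell) -> float:
    """Absolute difference of cell volumes in Å³."""
    return abs(c1.volume - c2.volume)


def pairwise_cell_distances(
    cells: Sequence[UnitCell], metric: str = "params", zscore: bool = False
) -> np.ndarray:
    """Condensed distance matrix over ``cells``.

    metric="params" uses the six-parameter Euclidean distance (optionally
    z-scored per parameter when ``zscore`` is set); metric="volume" uses
    |V_i − V_j|.
    """
    n = len(cells)
    if n < 2:
        raise ValueError("need at least two cells")
    if metric == "volume":
        v = np.array([c.volume for c in cells])
        diff = np.abs(v[:, None] - v[None, :])
        return squareform(diff, checks=False)
    if metric != "params":
        raise ValueError(f"unknown metric {metric!r}")
    p = np.array([c.parameters for c in cells], dtype=float)
    if zscore:
        s = p.std(axis=0)
        s[s == 0.0] = 1.0
        p = p / s
    diff = p[:, None, :] - p[None, :, :]
    return squareform(np.sqrt((diff**2).sum(axis=2)), checks=False)


@dataclass
class Dendrogram:
    """Average-linkage merge tree in SciPy linkage-matrix form.

    ``Z`` rows are (node_i, node_j, height, new_size); leaves 0..n−1 map to
    ``ids`` in order, merge m creates node n+m.
    """

    Z: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.ids)
        if self.Z.shape != (n - 1, 4):
            raise ValueError(f"linkage matrix shape {self.Z.shape} does not match {n} leaves")
        h = self.heights
        if np.any(np.diff(h) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")
        if int(self.Z[-1, 3]) != n:
            raise ValueError("final merge must contain all leaves")

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)


@dataclass
class ClusterAssignment:
    """Map dataset id → 1-based cluster label.

    Label 1 is the largest cluster; ties are broken by the smallest member
    id (lexicographic), so reports are deterministic.
    """

    labels: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> list[str]:
        return sorted(k for k, v in self.labels.items() if v == label)

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for v in self.labels.values():
            out[v] = out.get(v, 0) + 1
        return out


def average_linkage(dist, ids: Sequence[str] | None = None) -> Dendrogram:
    """UPGMA merge tree: inter-cluster distance = mean of all cross-pair distances.

    ``dist`` is a condensed (1-D) or square symmetric (2-D) distance matrix.
    """
    dist = np.asarray(dist, dtype=float)
    if np.any(np.isnan(dist)):
        raise ValueError("distance matrix contains NaN")
    if dist.ndim == 2:
        dist = squareform(dist, checks=False)
    m = dist.shape[0]
    n = int(round((1 + math.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m or n < 2:
        raise ValueError("condensed distance matrix has invalid length")
    if ids is None:
        ids = [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("number of ids does not match distance matrix")
    Z = _hier.linkage(dist, method="average")
    return Dendrogram(Z, list(ids))


def cut_dendrogram(dend: Dendrogram, cut: float) -> ClusterAssignment:
    """Clusters = connected components of merges strictly below ``cut``."""
    if cut < 0:
        raise ValueError("cut must be >= 0")
    n = dend.n_leaves
    comp: dict[int, list[int]] = {i: [i] for i in range(n)}
    for m, (i, j, h, _s) in enumerate(dend.Z):
        i, j = int(i), int(j)
        if h < cut and i in comp and j in comp:
            comp[n + m] = comp.pop(i) + comp.pop(j)
    clusters = sorted(
        comp.values(), key=lambda c: (-len(c), min(dend.ids[k] for k in c))
    )
    labels = {dend.ids[k]: lab for lab, c in enumerate(clusters, start=1) for k in c}
    return ClusterAssignment(labels)


def suggest_cut(dend: Dendrogram) -> float:
    """Midpoint of the largest gap between consecutive merge heights.

    A convenient default when phases are well separated: within-phase
    merges pile up at small heights and the between-phase merges tower
    above them.  With a single merge the midpoint of (0, height) is used.
    """
    h = np.sort(dend.heights)
    if h.size == 1:
        return float(h[0] / 2.0)
    gaps = np.diff(h)
    i = int(np.argmax(gaps))
    if gaps[i] <= 0:
        return float(h[-1] + 1.0)
    return float((h[i] + h[i + 1]) / 2.0)


@dataclass
class CellHistogramFit:
    """Windowed Gaussian fit for one cell parameter."""

    param: str
    lo: float
    hi: float
    mean: float
    sigma: float
    n_in_window: int
    counts: np.ndarray = field(repr=False)
    bin_edges: np.ndarray = field(repr=False)


def fit_cell_histograms(
    rows: Iterable,
    windows: Mapping[str, tuple[float, float]] | None = None,
    n_bins: int = 50,
) -> dict[str, CellHistogramFit]:
    """Fit a normal distribution to each cell parameter inside a window.

    The mean and σ are the Gaussian maximum-likelihood estimates (sample
    mean and population standard deviation) of the values falling inside
    the window [lo, hi]; the histogram counts are returned for plotting
    only and do not influence the fit.  ``rows`` may be any objects with
    attributes a, b, c, alpha, beta, gamma (CellTableRow or UnitCell).
    """
    rows = list(rows)
    out: dict[str, CellHistogramFit] = {}
    for name in CELL_PARAM_NAMES:
        vals = np.array([float(getattr(r, name)) for r in rows])
        if windows is not None and name in windows:
            lo, hi = windows[name]
            if not lo < hi:
                raise ValueError(f"window for {name} must have lo < hi")
        else:
            lo, hi = float(vals.min()), float(vals.max())
            if lo == hi:  # degenerate but legal: all values identical
                lo, hi = lo - 0.5, hi + 0.5
        inside = vals[(vals >= lo) & (vals <= hi)]
        if inside.size < 2:
            raise ValueError(f"fewer than 2 values inside the window for parameter {name}")
        counts, edges = np.histogram(inside, bins=n_bins, range=(lo, hi))
        out[name] = CellHistogramFit(
            param=name,
            lo=lo,
            hi=hi,
            mean=float(inside.mean()),
            sigma=float(inside.std(ddof=0)),
            n_in_window=int(inside.size),
            counts=counts,
            bin_edges=edges,
        )
    return out


def average_cell(fits: Mapping[str, CellHistogramFit]) -> UnitCell:
    """Average unit cell from the six histogram fits."""
    return UnitCell(*(fits[name].mean for name in CELL_PARAM_NAMES))


def vote_lattice_type(rows: Iterable) -> list[tuple[str, int]]:
    """Rank Bravais lattice types by total number of indexed reflections.

    Each dataset votes with its ``n_indexed`` count for its ``lattice_type``;
    the type collecting the most indexed reflections is the most likely one.
    Ties are broken alphabetically by symbol.  Rows with an empty lattice
    type abstain; if every row abstains this is an error.
    """
    scores: dict[str, int] = {}
    for r in rows:
        lt = getattr(r, "lattice_type", "") or ""
        if not lt:
            continue
        scores[lt] = scores.get(lt, 0) + int(getattr(r, "n_indexed", 0))
    if not scores:
        raise ValueError("no rows carry a lattice type")
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def plot_dendrogram(dend: Dendrogram, path, cut: float | None = None, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.3 * dend.n_leaves), 4))
    _hier.dendrogram(dend.Z, labels=dend.ids, ax=ax, leaf_rotation=90)
    if cut is not None:
        ax.axhline(cut, color="tab:blue", ls="--", lw=1, label=f"cut = {cut:g}")
        ax.legend()
    ax.set_ylabel("linkage distance")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cell_histograms(fits: Mapping[str, CellHistogramFit], path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(12, 6))
    for ax, name in zip(axes.ravel(), CELL_PARAM_NAMES):
        f = fits[name]
        centers = 0.5 * (f.bin_edges[:-1] + f.bin_edges[1:])
        width = f.bin_edges[1] - f.bin_edges[0]
        ax.bar(centers, f.counts, width=width, color="0.7")
        if f.sigma > 0:
            x = np.linspace(f.lo, f.hi, 200)
            pdf = np.exp(-0.5 * ((x - f.mean) / f.sigma) ** 2)
            pdf *= f.counts.max() if f.counts.max() > 0 else 1.0
            ax.plot(x, pdf, color="tab:red", lw=1)
        ax.set_title(f"{name}: {f.mean:.2f} ({f.sigma:.2f})")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
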