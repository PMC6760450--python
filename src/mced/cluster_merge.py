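"""Stage-2 analysis: reflection-correlation clustering, scaling, merging.

After the unit-cell stage has pinned a phase down, datasets are compared on
the Pearson correlation CC_I of the intensities of their common
symmetry-unique reflections.  The correlation is turned into the distance
d = √(1 − CC_I²), so d = 0.40 corresponds to CC_I ≈ 0.92 and d = 0.20 to
CC_I ≈ 0.98.  Average-linkage clustering on that distance groups crystals
that measured the same structure consistently; each cluster is then scaled
(one multiplicative factor per dataset against a running merged reference)
and merged, and standard crystallographic quality statistics —
completeness, R_meas, CC_1/2, ⟨I/σ⟩, multiplicity — are reported per
cluster so the best one can be picked for structure solution.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lattice_cluster import ClusterAssignment, Dendrogram, UnitCell, average_linkage, cut_dendrogram
from .symmetry import LaueGroup, ReflectionSet, d_spacing, enumerate_unique

log = logging.getLogger(__name__)

__all__ = [
    "PairCorrelation",
    "MergeStats",
    "MultiCrystalMerge",
    "cc_common",
    "cc_to_distance",
    "cluster_reflections",
    "scale_sets",
    "merge_cluster",
    "compute_stats",
    "rank_clusters",
]


@dataclass(frozen=True)
class PairCorrelation:
    """Intensity correlation between two datasets on their common uniques.

    ``cc`` is NaN (and ``defined`` False) when fewer than the required
    number of common reflections exist or the correlation degenerates.
    """

    id_i: str
    id_j: str
    n_common: int
    cc: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.cc)


def cc_common(set_a: ReflectionSet, set_b: ReflectionSet, min_common: int = 10) -> PairCorrelation:
    """Pearson CC_I of intensities over the common canonical indices."""
    if not (set_a.merged and set_b.merged):
        raise ValueError("both reflection sets must be merged before correlating")
    if set_a.laue.symbol != set_b.laue.symbol:
        raise ValueError(
            f"Laue group mismatch: {set_a.laue.symbol} vs {set_b.laue.symbol}"
        )
    common = set_a.df.merge(set_b.df, on=["h", "k", "l"], suffixes=("_a", "_b"))
    n = len(common)
    if n < max(min_common, 2):
        return PairCorrelation(set_a.dataset_id, set_b.dataset_id, n, float("nan"))
    ia = common["I_a"].to_numpy()
    ib = common["I_b"].to_numpy()
    if ia.std() == 0 or ib.std() == 0:
        return PairCorrelation(set_a.dataset_id, set_b.dataset_id, n, float("nan"))
    cc = float(np.corrcoef(ia, ib)[0, 1])
    return PairCorrelation(set_a.dataset_id, set_b.dataset_id, n, cc)


def cc_to_distance(cc: float) -> float:
    """Correlation → clustering distance d = √(1 − cc²).

    Anticorrelated (cc < 0) or undefined pairs are maximally distant
    (d = 1): datasets whose intensities disagree must never cluster.
    """
    if cc is None or math.isnan(cc) or cc < 0.0:
        return 1.0
    cc = min(cc, 1.0)
    return math.sqrt(1.0 - cc * cc)


def distance_to_cc(d: float) -> float:
    """Inverse transform on [0, 1]: the CC_I at a given cut distance."""
    if not 0.0 <= d <= 1.0:
        raise ValueError("distance must lie in [0, 1]")
    return math.sqrt(1.0 - d * d)


def cluster_reflections(
    sets: list[ReflectionSet],
    cut: float = 0.4,
    min_common: int = 10,
) -> tuple[ClusterAssignment, Dendrogram, pd.DataFrame]:
    """Average-linkage clustering of datasets on the √(1−CC_I²) distance.

    Returns the assignment at ``cut``, the dendrogram, and the pairwise
    CC table (NaN where undefined).
    """
    n = len(sets)
    if n < 2:
        raise ValueError("need at least two reflection sets")
    ids = [s.dataset_id for s in sets]
    ccm = np.full((n, n), np.nan)
    np.fill_diagonal(ccm, 1.0)
    dist = np.zeros((n, n))
    any_defined = False
    for i in range(n):
        for j in range(i + 1, n):
            pair = cc_common(sets[i], sets[j], min_common=min_common)
            ccm[i, j] = ccm[j, i] = pair.cc
            if pair.defined:
                any_defined = True
            else:
                log.debug("pair (%s, %s): CC undefined (%d common)", ids[i], ids[j], pair.n_common)
            dist[i, j] = dist[j, i] = cc_to_distance(pair.cc)
    if not any_defined:
        raise ValueError("no dataset pair has enough common reflections for a defined CC")
    dend = average_linkage(dist, ids=ids)
    assignment = cut_dendrogram(dend, cut)
    cc_table = pd.DataFrame(ccm, index=ids, columns=ids)
    return assignment, dend, cc_table


def _common_graph_components(sets: list[ReflectionSet]) -> list[set[str]]:
    parent = {s.dataset_id: s.dataset_id for s in sets}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            common = sets[i].df.merge(sets[j].df, on=["h", "k", "l"])
            if len(common) > 0:
                parent[find(sets[i].dataset_id)] = find(sets[j].dataset_id)
    comps: dict[str, set[str]] = {}
    for s in sets:
        comps.setdefault(find(s.dataset_id), set()).add(s.dataset_id)
    return list(comps.values())


def scale_sets(
    sets: list[ReflectionSet],
    tol: float = 1e-6,
    max_iter: int = 20,
) -> dict[str, float]:
    """Per-dataset multiplicative scale factors within one cluster.

    Least-squares against the running merged reference:
    k_j = Σ(I_ref·I_j) / Σ(I_j²) over the uniques dataset j shares with the
    reference table (the mean of all currently scaled sets), iterated until
    the largest relative change falls below ``tol``.  The dataset with the
    most unique reflections is the reference and is fixed at k = 1.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets to scale")
    if not all(s.merged for s in sets):
        raise ValueError("sets must be merged before scaling")
    comps = _common_graph_components(sets)
    if len(comps) > 1:
        raise ValueError(
            "common-reflection graph is disconnected: "
            + "; ".join(sorted(",".join(sorted(c)) for c in comps))
        )
    ref_id = max(sets, key=lambda s: (s.n_reflections, s.dataset_id)).dataset_id
    k = {s.dataset_id: 1.0 for s in sets}
    tables = {s.dataset_id: s.df.set_index(["h", "k", "l"])["I"] for s in sets}
    for _ in range(max_iter):
        scaled = pd.concat(
            [tables[i] * k[i] for i in tables], axis=1
        )
        reference = scaled.mean(axis=1, skipna=True)
        max_change = 0.0
        for i, tab in tables.items():
            ref_common = reference.reindex(tab.index)
            mask = ref_common.notna()
            ij = tab[mask].to_numpy()
            ir = ref_common[mask].to_numpy()
            denom = float((ij * ij).sum())
            if denom == 0.0:
                continue
            new_k = float((ir * ij).sum()) / denom
            max_change = max(max_change, abs(new_k - k[i]) / max(abs(k[i]), 1e-300))
            k[i] = new_k
        norm = k[ref_id]
        for i in k:
            k[i] /= norm
        if max_change < tol:
            break
    return k


@dataclass
class MultiCrystalMerge:
    """Pooled, scaled measurements of one cluster plus the merged table.

    ``measurements`` keeps every contributing record (canonical h,k,l, the
    scaled I and σ, and dataset_id) so that multiplicity-aware statistics
    (R_meas, CC_1/2) can be computed after merging.
    """

    measurements: pd.DataFrame
    cell: UnitCell
    laue: LaueGroup
    centering: str = "P"
    cluster_id: str = "cluster"

    def merged_table(self) -> pd.DataFrame:
        g = self.measurements.groupby(["h", "k", "l"], sort=True)
        out = g.agg(I=("I", "mean"), _s2=("sigma", lambda s: (s**2).sum()), n_obs=("I", "size"))
        out = out.reset_index()
        out["sigma"] = np.sqrt(out["_s2"]) / out["n_obs"]
        return out[["h", "k", "l", "I", "sigma", "n_obs"]]

    def merged_set(self) -> ReflectionSet:
        return ReflectionSet(
            dataset_id=self.cluster_id,
            cell=self.cell,
            laue=self.laue,
            centering=self.centering,
            df=self.merged_table(),
            merged=True,
        )


def merge_cluster(
    sets: list[ReflectionSet],
    scales: dict[str, float] | None = None,
    cell_tolerance: float = 0.05,
    cluster_id: str = "cluster",
) -> MultiCrystalMerge:
    """Pool the scaled measurements of a cluster per canonical index.

    All sets must share the Laue group and agree on the cell within
    ``cell_tolerance`` (relative per length, absolute fraction of 180° per
    angle); the average cell of the members is attached to the merge.
    """
    if not sets:
        raise ValueError("nothing to merge")
    laue = sets[0].laue
    centering = sets[0].centering
    if any(s.laue.symbol != laue.symbol for s in sets):
        raise ValueError("Laue group mismatch within cluster")
    params = np.array([s.cell.parameters for s in sets])
    mean_p = params.mean(axis=0)
    rel = np.abs(params - mean_p) / np.where(
        np.arange(6) < 3, mean_p, 180.0
    )
    if np.any(rel > cell_tolerance):
        worst = int(np.argmax(rel.max(axis=1)))
        raise ValueError(
            f"cell of dataset {sets[worst].dataset_id!r} deviates more than "
            f"{cell_tolerance:.0%} from the cluster mean"
        )
    if scales is None:
        scales = {s.dataset_id: 1.0 for s in sets}
    frames = []
    for s in sets:
        k = scales[s.dataset_id]
        df = s.df[["h", "k", "l", "I", "sigma"]].copy()
        df["I"] = df["I"] * k
        df["sigma"] = df["sigma"] * abs(k)
        df["dataset_id"] = s.dataset_id
        frames.append(df)
    measurements = pd.concat(frames, ignore_index=True)
    mean_cell = UnitCell(*mean_p)
    return MultiCrystalMerge(
        measurements=measurements,
        cell=mean_cell,
        laue=laue,
        centering=centering,
        cluster_id=cluster_id,
    )


@dataclass
class MergeStats:
    """Quality statistics of a merged multi-crystal dataset.

    completeness is a percentage; R_meas a fraction; cc_half a correlation
    in [−1, 1] (NaN when no unique has multiplicity ≥ 2, like r_meas).
    """

    d_min: float
    n_unique: int
    n_possible: int
    completeness: float
    r_meas: float
    mean_i_over_sigma: float
    cc_half: float
    mean_multiplicity: float
    cc_half_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_unique > self.n_possible:
            raise ValueError("observed uniques exceed the number possible")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError("completeness must lie in [0, 100]")

    def as_dict(self) -> dict:
        return {
            "d_min": self.d_min,
            "n_unique": self.n_unique,
            "n_possible": self.n_possible,
            "completeness": self.completeness,
            "r_meas": None if math.isnan(self.r_meas) else self.r_meas,
            "mean_i_over_sigma": self.mean_i_over_sigma,
            "cc_half": None if math.isnan(self.cc_half) else self.cc_half,
            "mean_multiplicity": self.mean_multiplicity,
            "cc_half_seed": self.cc_half_seed,
        }


def compute_stats(
    merge: MultiCrystalMerge,
    d_min: float,
    seed: int = 0,
) -> MergeStats:
    """Standard merging statistics of a multi-crystal merge at ``d_min``.

    completeness = 100 · n_unique_observed / n_possible (the full
    symmetry-unique enumeration for the cluster cell);
    R_meas = Σ_h √(n_h/(n_h−1)) Σ_i |I_hi − ⟨I_h⟩| / Σ_h Σ_i I_hi over
    uniques measured at least twice, with signed intensities in the
    denominator (negative intensities are legitimate in this data);
    CC_1/2 = Pearson correlation between the means of one seeded random
    half-split of the measurements of each multiply-measured unique.
    """
    meas = merge.measurements
    if len(meas):
        d = d_spacing(merge.cell, meas[["h", "k", "l"]].to_numpy())
        meas = meas.loc[d >= d_min - 1e-12]
    possible = enumerate_unique(merge.cell, merge.laue, merge.centering, d_min)
    n_possible = len(possible)
    groups = meas.groupby(["h", "k", "l"], sort=True)
    n_unique = groups.ngroups
    completeness = 100.0 * n_unique / n_possible if n_possible else 0.0

    merged_i = groups["I"].mean()
    merged_sigma = groups["sigma"].apply(lambda s: np.sqrt((s**2).sum()) / len(s))
    mean_ios = float((merged_i / merged_sigma).mean()) if n_unique else float("nan")
    mean_mult = float(groups.size().mean()) if n_unique else float("nan")

    rng = np.random.default_rng(seed)
    num = 0.0
    den = 0.0
    half_a: list[float] = []
    half_b: list[float] = []
    for _, grp in groups:
        vals = grp["I"].to_numpy()
        n_h = len(vals)
        if n_h < 2:
            continue
        mean = vals.mean()
        num += math.sqrt(n_h / (n_h - 1)) * np.abs(vals - mean).sum()
        den += vals.sum()
        perm = rng.permutation(n_h)
        half = n_h // 2
        half_a.append(vals[perm[:half]].mean())
        half_b.append(vals[perm[half:]].mean())
    if half_a and den != 0.0:
        r_meas = num / den
    else:
        r_meas = float("nan")
    if len(half_a) >= 2 and np.std(half_a) > 0 and np.std(half_b) > 0:
        cc_half = float(np.corrcoef(half_a, half_b)[0, 1])
    elif len(half_a) >= 1 and np.allclose(half_a, half_b):
        cc_half = 1.0
    else:
        cc_half = float("nan")
    if math.isnan(r_meas) or math.isnan(cc_half):
        warnings.warn("no unique reflection measured twice: R_meas/CC_1/2 undefined", stacklevel=2)
    return MergeStats(
        d_min=d_min,
        n_unique=n_unique,
        n_possible=n_possible,
        completeness=completeness,
        r_meas=r_meas,
        mean_i_over_sigma=mean_ios,
        cc_half=cc_half,
        mean_multiplicity=mean_mult,
        cc_half_seed=seed,
    )


def rank_clusters(stats: dict[int, MergeStats]) -> list[tuple[int, MergeStats]]:
    """Order clusters by (completeness desc, CC_1/2 desc, R_meas asc).

    NaN statistics sort last within their tier.
    """
    if not stats:
        raise ValueError("no clusters to rank")

    def key(item):
        _, s = item
        cch = -math.inf if math.isnan(s.cc_half) else s.cc_half
        rm = math.inf if math.isnan(s.r_meas) else s.r_meas
        return (-s.completeness, -cch, rm)

    return sorted(stats.items(), key=key)
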