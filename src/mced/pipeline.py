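"""End-to-end orchestration of the two-stage reduction workflow.

Stage 1 (lattice): collect per-dataset cells (from a CSV table or by
parsing integration logs), cluster them, fit per-cluster cell histograms,
vote the lattice type, and write dendrogram/histogram figures plus a JSON
report.  Stage 2 (reflections): for a selected phase cell, keep the
datasets whose reported cell matches within tolerance (the others "fail",
exactly as a re-integration with a fixed cell would fail on them), filter
and merge each dataset, cluster on the √(1−CC_I²) distance, then scale,
merge and score each cluster.  Stages are independently runnable and all
intermediate artifacts are plain files, so externally produced inputs can
be substituted at any boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import cluster_merge, io_formats, lattice_cluster, symmetry
from .io_formats import CellTableRow
from .lattice_cluster import ClusterAssignment, UnitCell

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_lattice_stage", "run_reflection_stage"]


@dataclass
class PipelineConfig:
    """All knobs of the two-stage pipeline (YAML-serializable)."""

    input_dir: str = "."
    output_dir: str = "mced_out"
    metric: str = "params"  # or "volume"
    cell_cut: float | None = None  # None: cut at the largest height gap
    histogram_windows: dict = field(default_factory=dict)
    laue: str = "mmm"
    centering: str = "P"
    d_min: float = 1.2
    d_max: float | None = None
    min_i_over_sigma: float = 2.0
    cc_cut: float = 0.4
    min_common: int = 10
    cell_tolerance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metric not in ("params", "volume"):
            raise ValueError("metric must be 'params' or 'volume'")
        if not 0.0 <= self.cc_cut <= 1.0:
            raise ValueError("cc_cut must lie in [0, 1]")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _collect_cell_rows(input_dir: Path) -> list[CellTableRow]:
    table = input_dir / "cells.csv"
    if table.exists():
        return io_formats.read_cells_table(table)
    rows = []
    for lp in sorted(input_dir.glob("**/CORRECT.LP")):
        try:
            rows.append(
                io_formats.parse_correct_lp_summary(
                    lp.read_text(), dataset_id=lp.parent.name, source_path=str(lp)
                )
            )
            log.info("%s: indexed", lp.parent.name)
        except io_formats.IndexingFailedError:
            log.info("%s: indexing failed, excluded", lp.parent.name)
    return rows


@dataclass
class LatticeStageResult:
    assignment: ClusterAssignment
    dendrogram: lattice_cluster.Dendrogram
    cut: float
    average_cells: dict[int, UnitCell]
    fits: dict[int, dict]
    vote: list[tuple[str, int]]
    rows: list[CellTableRow]


def run_lattice_stage(config: PipelineConfig) -> LatticeStageResult:
    """Cluster unit cells, fit histograms, vote the lattice type."""
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir) / "lattice"
    out.mkdir(parents=True, exist_ok=True)
    rows = _collect_cell_rows(input_dir)
    if len(rows) < 2:
        raise ValueError(f"need at least 2 indexable datasets, found {len(rows)}")
    cells = [r.cell for r in rows]
    ids = [r.dataset_id for r in rows]
    dist = lattice_cluster.pairwise_cell_distances(cells, metric=config.metric)
    dend = lattice_cluster.average_linkage(dist, ids=ids)
    cut = config.cell_cut if config.cell_cut is not None else lattice_cluster.suggest_cut(dend)
    assignment = lattice_cluster.cut_dendrogram(dend, cut)
    lattice_cluster.plot_dendrogram(dend, out / "dendrogram.png", cut=cut, title="unit-cell clustering")

    by_id = {r.dataset_id: r for r in rows}
    average_cells: dict[int, UnitCell] = {}
    fits: dict[int, dict] = {}
    report_clusters = []
    for label in sorted(set(assignment.labels.values())):
        members = assignment.members(label)
        cluster_rows = [by_id[m] for m in members]
        entry = {"cluster": label, "n_members": len(members), "members": members}
        if len(cluster_rows) >= 2:
            f = lattice_cluster.fit_cell_histograms(
                cluster_rows, windows=config.histogram_windows or None
            )
            fits[label] = f
            average_cells[label] = lattice_cluster.average_cell(f)
            lattice_cluster.plot_cell_histograms(
                f, out / f"histograms_cluster_{label}.png", title=f"cluster {label}"
            )
            entry["average_cell"] = list(average_cells[label].parameters)
            entry["cell_sigmas"] = [f[p].sigma for p in lattice_cluster.CELL_PARAM_NAMES]
        report_clusters.append(entry)
        for m in members:
            log.info("%s: lattice cluster %d", m, label)

    vote = lattice_cluster.vote_lattice_type(rows)
    report = {
        "n_datasets": len(rows),
        "metric": config.metric,
        "cut": cut,
        "clusters": report_clusters,
        "lattice_type_vote": [{"lattice_type": t, "score": s} for t, s in vote],
    }
    (out / "lattice_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return LatticeStageResult(assignment, dend, cut, average_cells, fits, vote, rows)


@dataclass
class ReflectionStageResult:
    assignment: ClusterAssignment
    dendrogram: lattice_cluster.Dendrogram
    stats: dict[int, cluster_merge.MergeStats]
    ranking: list[tuple[int, cluster_merge.MergeStats]]
    merged: dict[int, cluster_merge.MultiCrystalMerge]
    excluded: list[str]


def run_reflection_stage(
    config: PipelineConfig,
    phase_cell: UnitCell,
    lattice_rows: list[CellTableRow] | None = None,
) -> ReflectionStageResult:
    """Filter, cluster on CC_I, scale, merge and score for one phase.

    Reflection files are looked up as ``<dataset_id>.hkl`` in the input
    directory.  Datasets whose reported cell deviates from ``phase_cell``
    by more than the tolerance are excluded up front and logged — the
    stand-in for datasets of other phases failing to index with this cell.
    """
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir) / "reflection"
    out.mkdir(parents=True, exist_ok=True)
    rows = lattice_rows if lattice_rows is not None else _collect_cell_rows(input_dir)
    target = np.asarray(phase_cell.parameters)

    sets = []
    excluded = []
    for row in rows:
        p = np.asarray(row.cell.parameters)
        rel = np.abs(p - target) / np.where(np.arange(6) < 3, target, 180.0)
        if np.any(rel > config.cell_tolerance):
            excluded.append(row.dataset_id)
            log.info("%s: cell mismatch with selected phase, excluded", row.dataset_id)
            continue
        hkl_path = input_dir / f"{row.dataset_id}.hkl"
        if not hkl_path.exists():
            excluded.append(row.dataset_id)
            log.warning("%s: no reflection file, excluded", row.dataset_id)
            continue
        df = io_formats.read_shelx_hkl(hkl_path)
        df = df.loc[df["sigma"] > 0, ["h", "k", "l", "I", "sigma"]].reset_index(drop=True)
        rset = symmetry.ReflectionSet(
            dataset_id=row.dataset_id,
            cell=phase_cell,
            laue=config.laue,
            centering=config.centering,
            df=df,
        )
        rset = symmetry.filter_reflections(
            rset, d_min=config.d_min, d_max=config.d_max,
            min_i_over_sigma=config.min_i_over_sigma,
        )
        sets.append(symmetry.merge_within(rset))
        log.info("%s: %d unique reflections after filtering", row.dataset_id, sets[-1].n_reflections)
    if len(sets) == 0:
        raise ValueError("no dataset matches the selected phase cell")
    if len(sets) < 2:
        raise ValueError("need at least 2 matching datasets for reflection clustering")

    assignment, dend, cc_table = cluster_merge.cluster_reflections(
        sets, cut=config.cc_cut, min_common=config.min_common
    )
    lattice_cluster.plot_dendrogram(
        dend, out / "dendrogram.png", cut=config.cc_cut, title="reflection clustering"
    )
    cc_table.to_csv(out / "cc_matrix.csv", float_format="%.4f")

    by_id = {s.dataset_id: s for s in sets}
    stats: dict[int, cluster_merge.MergeStats] = {}
    merged: dict[int, cluster_merge.MultiCrystalMerge] = {}
    results_for_report: dict[int, dict] = {}
    for label in sorted(set(assignment.labels.values())):
        members = assignment.members(label)
        if len(members) < 2:
            log.warning("cluster %d is a singleton (%s), merge skipped", label, members[0])
            results_for_report[label] = {}
            continue
        cluster_sets = [by_id[m] for m in members]
        scales = cluster_merge.scale_sets(cluster_sets)
        merge = cluster_merge.merge_cluster(
            cluster_sets, scales, cell_tolerance=config.cell_tolerance,
            cluster_id=f"cluster_{label}",
        )
        st = cluster_merge.compute_stats(merge, d_min=config.d_min, seed=config.seed)
        stats[label] = st
        merged[label] = merge
        results_for_report[label] = {"merged": merge, "stats": st, "scales": scales}
        log.info("cluster %d: %d datasets merged, completeness %.1f%%",
                 label, len(members), st.completeness)

    io_formats.write_cluster_report(assignment, results_for_report, out)
    ranking = cluster_merge.rank_clusters(stats) if stats else []
    (out / "ranking.json").write_text(
        json.dumps(
            [{"cluster": lab, **st.as_dict()} for lab, st in ranking],
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    return ReflectionStageResult(assignment, dend, stats, ranking, merged, excluded)
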