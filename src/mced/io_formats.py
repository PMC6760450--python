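"""Readers and writers for the external file dialects the pipeline touches.

Covers: XDS-style CORRECT.LP integration logs (read-only, pattern-based on
labeled lines so that version drift in column layout does not matter),
XSCALE.LP pairwise-correlation blocks (read-only), CSV unit-cell tables
(the canonical internal format), SHELX HKL4 fixed-width reflection files
(3I4 + 2F8.2, terminated by an all-zero record), and per-cluster report
directories.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .cluster_merge import MergeStats, MultiCrystalMerge
    from .lattice_cluster import ClusterAssignment

log = logging.getLogger(__name__)

__all__ = [
    "CellTableRow",
    "CorrelationTableEntry",
    "IndexingFailedError",
    "LogParseError",
    "parse_correct_lp_summary",
    "read_cells_table",
    "write_cells_table",
    "parse_xscale_correlations",
    "read_shelx_hkl",
    "write_shelx_hkl",
    "write_cluster_report",
]

CELLS_TABLE_COLUMNS = (
    "dataset_id", "a", "b", "c", "alpha", "beta", "gamma",
    "lattice_type", "n_indexed", "rotation_range",
)

# Label strings matched in CORRECT.LP-style logs (first hit wins).
CELL_LABELS = ("UNIT CELL PARAMETERS", "UNIT_CELL_CONSTANTS=")
SPACE_GROUP_LABELS = ("SPACE GROUP NUMBER", "SPACE_GROUP_NUMBER=")
N_INDEXED_LABELS = ("NUMBER OF INDEXED REFLECTIONS", "NUMBER OF ACCEPTED OBSERVATIONS")
OSCILLATION_LABELS = ("OSCILLATION_RANGE=",)
DATA_RANGE_LABELS = ("DATA_RANGE=",)

# Crystal-system letter for the two-character Bravais symbol (e.g. "oP").
_SYSTEM_LETTER = {
    "triclinic": "a", "monoclinic": "m", "orthorhombic": "o",
    "tetragonal": "t", "trigonal": "h", "hexagonal": "h", "cubic": "c",
}


class LogParseError(ValueError):
    """The text is not a recognizable integration log."""


class IndexingFailedError(LogParseError):
    """The log is well-formed but reports no indexing solution."""


@dataclass
class CellTableRow:
    """One dataset's cell and indexing summary."""

    dataset_id: str
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    lattice_type: str = ""
    n_indexed: int = 0
    rotation_range: float = 0.0
    source_path: str = ""

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(f"{self.dataset_id}: cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"{self.dataset_id}: cell angles must lie in (0, 180)")
        if self.n_indexed < 0:
            raise ValueError(f"{self.dataset_id}: n_indexed must be >= 0")
        if self.rotation_range < 0:
            raise ValueError(f"{self.dataset_id}: rotation_range must be >= 0")

    @property
    def cell(self):
        from .lattice_cluster import UnitCell

        return UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class CorrelationTableEntry:
    """One pairwise intensity correlation printed by a scaling program."""

    id_i: str
    id_j: str
    n_common: int
    cc: float

    def __post_init__(self) -> None:
        if self.id_i == self.id_j:
            raise ValueError("correlation entry must pair two distinct datasets")
        if self.n_common < 0:
            raise ValueError("n_common must be >= 0")
        if not -1.0 <= self.cc <= 1.0:
            raise ValueError(f"correlation {self.cc} outside [-1, 1]")


def _first_labeled_line(lines: Sequence[str], labels: Sequence[str]) -> str | None:
    for line in lines:
        for lab in labels:
            if lab in line:
                return line.split(lab, 1)[1]
    return None


_NUM = re.compile(r"[-+]?\d+\.?\d*(?:[eE][-+]?\d+)?")


def _numbers(text: str) -> list[float]:
    return [float(m) for m in _NUM.findall(text)]


def parse_correct_lp_summary(
    text: str, dataset_id: str = "", source_path: str = ""
) -> CellTableRow:
    """Extract the unit cell and indexing summary from a CORRECT.LP-style log.

    Matching is by labeled lines (see the module-level ``*_LABELS``
    constants), not by column offsets.  A log that carries none of the
    known labels raises :class:`LogParseError`; a recognizable log without
    a unit-cell line raises :class:`IndexingFailedError` (the program ran
    but found no lattice).
    """
    lines = text.splitlines()
    cell_part = _first_labeled_line(lines, CELL_LABELS)
    any_label = any(
        _first_labeled_line(lines, labs) is not None
        for labs in (SPACE_GROUP_LABELS, N_INDEXED_LABELS, OSCILLATION_LABELS, DATA_RANGE_LABELS)
    )
    if cell_part is None:
        if any_label:
            raise IndexingFailedError(f"{source_path or dataset_id}: no unit-cell line (indexing failed)")
        raise LogParseError(f"{source_path or dataset_id}: not a recognizable integration log")
    cell_nums = _numbers(cell_part)
    if len(cell_nums) < 6:
        raise LogParseError(f"{source_path or dataset_id}: malformed unit-cell line {cell_part!r}")
    a, b, c, alpha, beta, gamma = cell_nums[:6]

    lattice_type = ""
    sg_part = _first_labeled_line(lines, SPACE_GROUP_LABELS)
    if sg_part is not None:
        sg_nums = _numbers(sg_part)
        if sg_nums:
            lattice_type = _bravais_from_space_group(int(sg_nums[0]))

    n_indexed = 0
    n_part = _first_labeled_line(lines, N_INDEXED_LABELS)
    if n_part is not None:
        nums = _numbers(n_part)
        if nums:
            n_indexed = int(nums[0])

    rotation_range = 0.0
    osc_part = _first_labeled_line(lines, OSCILLATION_LABELS)
    rng_part = _first_labeled_line(lines, DATA_RANGE_LABELS)
    if osc_part is not None and rng_part is not None:
        osc = _numbers(osc_part)
        rng = _numbers(rng_part)
        if osc and len(rng) >= 2:
            rotation_range = abs(osc[0]) * (rng[1] - rng[0] + 1)

    return CellTableRow(
        dataset_id=dataset_id or Path(source_path).parent.name or "dataset",
        a=a, b=b, c=c, alpha=alpha, beta=beta, gamma=gamma,
        lattice_type=lattice_type,
        n_indexed=n_indexed,
        rotation_range=rotation_range,
        source_path=source_path,
    )


def _bravais_from_space_group(number: int) -> str:
    import gemmi

    sg = gemmi.find_spacegroup_by_number(number)
    if sg is None:
        return ""
    system = _SYSTEM_LETTER.get(sg.crystal_system_str(), "")
    centring = sg.hm[0] if sg.hm else "P"
    return f"{system}{centring}" if system else ""


def read_cells_table(path) -> list[CellTableRow]:
    """Read a CSV cell table (header per ``CELLS_TABLE_COLUMNS``)."""
    df = pd.read_csv(path, dtype={"dataset_id": str, "lattice_type": str}, keep_default_na=False)
    missing = set(CELLS_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for i, rec in df.iterrows():
        kwargs = {}
        for col in CELLS_TABLE_COLUMNS:
            val = rec[col]
            if col in ("a", "b", "c", "alpha", "beta", "gamma", "rotation_range"):
                try:
                    val = float(val)
                except (TypeError, ValueError) as exc:
                    raise ValueError(f"{path}: row {i + 1}, column {col!r}: bad numeric value {val!r}") from exc
            elif col == "n_indexed":
                try:
                    val = int(val)
                except (TypeError, ValueError) as exc:
                    raise ValueError(f"{path}: row {i + 1}, column {col!r}: bad integer value {val!r}") from exc
            kwargs[col] = val
        if "source_path" in df.columns:
            kwargs["source_path"] = str(rec["source_path"])
        try:
            rows.append(CellTableRow(**kwargs))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 1}: {exc}") from exc
    return rows


def write_cells_table(rows: Iterable[CellTableRow], path) -> None:
    """Write a CSV cell table; lossless round trip with :func:`read_cells_table`."""
    recs = []
    for r in rows:
        d = asdict(r)
        d.pop("source_path", None)
        recs.append(d)
    df = pd.DataFrame(recs, columns=list(CELLS_TABLE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6f")


XSCALE_CORRELATION_HEADER = "CORRELATIONS BETWEEN INPUT DATA SETS"

_CORR_LINE = re.compile(r"^\s*(\d+)\s+(\d+)\s+(\d+)\s+([-+]?\d*\.?\d+)")


def parse_xscale_correlations(text: str) -> list[CorrelationTableEntry]:
    """Parse the pairwise-correlation block of an XSCALE.LP-style log.

    Rows are ``#i #j n_common cc ...``; parsing starts after the header
    line containing ``CORRELATIONS BETWEEN INPUT DATA SETS`` and stops at
    the first non-matching line after data has begun.  An absent block
    yields an empty list (with a warning logged).
    """
    lines = text.splitlines()
    try:
        start = next(i for i, line in enumerate(lines) if XSCALE_CORRELATION_HEADER in line)
    except StopIteration:
        log.warning("no correlation block found in log text")
        return []
    entries: list[CorrelationTableEntry] = []
    started = False
    for line in lines[start + 1:]:
        m = _CORR_LINE.match(line)
        if m:
            started = True
            i, j, n_common, cc = m.group(1), m.group(2), int(m.group(3)), float(m.group(4))
            entries.append(CorrelationTableEntry(id_i=i, id_j=j, n_common=n_common, cc=cc))
        elif started:
            break
    return entries


# SHELX HKL4: 3I4 + 2F8.2, terminated by an all-zero record.
_HKL_LINE_WIDTH = 28
#: Largest |I| (or σ) representable in an F8.2 field without overflow.
HKL4_MAX_VALUE = 99999.99


def read_shelx_hkl(path) -> pd.DataFrame:
    """Read an HKL4 reflection file into a DataFrame (h, k, l, I, sigma).

    The 0 0 0 terminator record (and anything after it) is skipped; a
    non-positive σ raises a warning and the record is flagged in the
    ``suspect_sigma`` column but kept.
    """
    records = []
    suspect = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            body = raw.rstrip("\r\n")
            if not body.strip():
                continue
            if len(body) < 20 or len(body) > _HKL_LINE_WIDTH + 4:
                raise ValueError(f"{path}:{lineno}: line width {len(body)} not a valid HKL4 record")
            body = body.ljust(_HKL_LINE_WIDTH)
            try:
                h = int(body[0:4])
                k = int(body[4:8])
                l = int(body[8:12])
                i_val = float(body[12:20])
                sig = float(body[20:28])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed HKL4 record {body!r}") from exc
            if h == 0 and k == 0 and l == 0:
                break  # terminator
            if sig <= 0:
                warnings.warn(f"{path}:{lineno}: non-positive sigma {sig}", stacklevel=2)
                suspect.append(True)
            else:
                suspect.append(False)
            records.append((h, k, l, i_val, sig))
    df = pd.DataFrame(records, columns=["h", "k", "l", "I", "sigma"])
    df["h"] = df["h"].astype(np.int64)
    df["k"] = df["k"].astype(np.int64)
    df["l"] = df["l"].astype(np.int64)
    df["suspect_sigma"] = pd.Series(suspect, dtype=bool)
    return df


def write_shelx_hkl(reflections, path) -> float:
    """Write reflections (DataFrame with h,k,l,I,sigma) in HKL4 format.

    Emits the fixed 3I4 + 2F8.2 layout and the 0 0 0 terminator.  When any
    intensity or σ would overflow an F8.2 field, all I and σ are rescaled
    by a common factor (returned; 1.0 otherwise) so the layout stays fixed
    width — the factor should be quoted in the accompanying report.
    """
    df = pd.DataFrame(reflections)
    scale = 1.0
    if len(df):
        peak = max(df["I"].abs().max(), df["sigma"].abs().max())
        neg_peak = -df["I"].min() if df["I"].min() < 0 else 0.0
        # negative values lose one character to the sign
        limit_breach = max(peak / HKL4_MAX_VALUE, neg_peak / 9999.99)
        if limit_breach > 1.0:
            scale = 1.0 / limit_breach
    with open(path, "w") as fh:
        for rec in df.itertuples(index=False):
            fh.write(
                f"{int(rec.h):4d}{int(rec.k):4d}{int(rec.l):4d}"
                f"{rec.I * scale:8.2f}{rec.sigma * scale:8.2f}\n"
            )
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")
    return scale


def write_cluster_report(
    assignment: "ClusterAssignment",
    merged_results: dict,
    out_dir,
) -> list[Path]:
    """Write one subdirectory per cluster: merged HKL4, stats JSON, members.

    ``merged_results`` maps cluster label → dict with optional keys
    ``merged`` (a multi-crystal merge carrying a ``merged_set()``),
    ``stats`` (MergeStats), and ``scales``.  Directories are named
    cluster_<label>; labels already order clusters by decreasing size with
    ties broken by the smallest member id.  Output is byte-deterministic
    for identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for label in sorted(set(assignment.labels.values())):
        cdir = out_dir / f"cluster_{label}"
        cdir.mkdir(exist_ok=True)
        members = assignment.members(label)
        (cdir / "members.txt").write_text("".join(f"{m}\n" for m in members))
        result = merged_results.get(label, {})
        stats_doc: dict = {"cluster": label, "n_members": len(members), "members": members}
        merge = result.get("merged")
        hkl_scale = None
        if merge is not None:
            merged_set = merge.merged_set() if hasattr(merge, "merged_set") else merge
            hkl_scale = write_shelx_hkl(
                merged_set.df[["h", "k", "l", "I", "sigma"]], cdir / "merged.hkl"
            )
            stats_doc["hkl_intensity_scale"] = hkl_scale
        stats = result.get("stats")
        if stats is not None:
            stats_doc["stats"] = stats.as_dict() if hasattr(stats, "as_dict") else dict(stats)
        if "scales" in result:
            stats_doc["scales"] = {k: float(v) for k, v in sorted(result["scales"].items())}
        (cdir / "stats.json").write_text(json.dumps(stats_doc, indent=2, sort_keys=True) + "\n")
        written.append(cdir)
    return written
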