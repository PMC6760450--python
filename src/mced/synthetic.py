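"""Ground-truth-known synthetic data for every pipeline stage.

Reflection data: each phase gets a table of true intensities from a
random-point-scatterer model — n random unit scatterers in the cell give
I(hkl) = |Σ_j exp(2πi·hkl·x_j)|² · exp(−B/(2d²)).  This produces the
speckled, heavy-tailed intensity statistics real structures show, strongly
correlated within a phase and essentially uncorrelated between phases with
independent atom positions, which is exactly the structure the
reflection-correlation clustering stage exploits.  Each simulated crystal
observes the subset of reflections whose reciprocal-space azimuth about a
random rotation axis falls in its wedge (a purely geometric stand-in for a
partial rotation range — no excitation-error physics, since clustering and
merging only care about which uniques are sampled), with a per-crystal
scale, multiplicative Gaussian noise, a jittered reported cell, and
optionally scrambled indices to emulate mis-indexed outliers.

Image data: defocused-beam frames are a flat-top bright disc with a soft
edge, a darker disc for the crystal shadow (default 15% of the beam level,
the grey band the segmentation step looks for), low-frequency background
texture, and Gaussian noise.

All generators are pure functions of their spec + seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CellTableRow
from .lattice_cluster import UnitCell
from .symmetry import (
    LaueGroup,
    ReflectionSet,
    ReindexOperator,
    REINDEX_SWAP_BC,
    d_spacing,
    enumerate_unique,
)
from .tracking import Frame

__all__ = [
    "PhaseSpec",
    "CrystalSimSpec",
    "MixtureResult",
    "simulate_phase_intensities",
    "simulate_crystal_dataset",
    "simulate_mixture",
    "simulate_defocused_frame",
    "SCENARIOS",
]


@dataclass(frozen=True)
class PhaseSpec:
    """A crystalline phase for the intensity model."""

    name: str
    cell: UnitCell
    laue: str = "mmm"
    centering: str = "P"
    n_atoms: int = 20
    b_iso: float = 2.0  # Å², overall displacement parameter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.b_iso < 0:
            raise ValueError("b_iso must be >= 0")


@dataclass(frozen=True)
class CrystalSimSpec:
    """One simulated crystal: wedge geometry, scale, noise, cell jitter."""

    phase: str
    wedge_start: float = 0.0  # deg
    wedge_range: float = 30.0  # deg
    scale: float = 1.0
    noise_frac: float = 0.05  # multiplicative Gaussian noise on I
    sigma_floor: float = 0.01  # absolute σ floor
    cell_jitter_length: float = 0.15  # Å, per length
    cell_jitter_angle: float = 0.2  # deg, per angle
    misindexed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wedge_range <= 0:
            raise ValueError("wedge_range must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def simulate_phase_intensities(spec: PhaseSpec, d_min: float = 1.2) -> pd.DataFrame:
    """True intensities on the symmetry-unique reflections of a phase.

    Returns a DataFrame with columns h, k, l (canonical indices) and
    I_true.  Intensities are scaled so their mean is 100.
    """
    uniques = enumerate_unique(spec.cell, spec.laue, spec.centering, d_min)
    rng = np.random.default_rng(spec.seed)
    x = rng.random((spec.n_atoms, 3))
    phase = 2.0 * np.pi * uniques @ x.T  # (n_refl, n_atoms)
    f = np.exp(1j * phase).sum(axis=1)
    intensity = np.abs(f) ** 2
    d = d_spacing(spec.cell, uniques)
    intensity = intensity * np.exp(-spec.b_iso / (2.0 * d**2))
    mean = intensity.mean()
    if mean > 0:
        intensity = intensity * (100.0 / mean)
    return pd.DataFrame(
        {"h": uniques[:, 0], "k": uniques[:, 1], "l": uniques[:, 2], "I_true": intensity}
    )


def _expand_orbits(phase_table: pd.DataFrame, laue: LaueGroup) -> pd.DataFrame:
    """All symmetry-equivalent indices of the canonical table, each carrying
    the canonical intensity (symmetry-consistent by construction)."""
    hkl = phase_table[["h", "k", "l"]].to_numpy(dtype=np.int64)
    i_true = phase_table["I_true"].to_numpy()
    orbit = np.einsum("nj,oji->oni", hkl, laue.ops)  # (order, n, 3)
    n_ops = orbit.shape[0]
    flat = orbit.reshape(-1, 3)
    intens = np.tile(i_true, n_ops)
    # dedupe (hkl) rows, keeping one copy each; intensity is orbit-constant
    _, idx = np.unique(flat, axis=0, return_index=True)
    return pd.DataFrame(
        {"h": flat[idx, 0], "k": flat[idx, 1], "l": flat[idx, 2], "I_true": intens[idx]}
    )


def simulate_crystal_dataset(
    phase_table: pd.DataFrame,
    phase: PhaseSpec,
    spec: CrystalSimSpec,
    dataset_id: str | None = None,
) -> tuple[ReflectionSet, CellTableRow]:
    """One crystal's observed reflections plus its reported cell row.

    A reflection is observed when the azimuth of its reciprocal-lattice
    vector about a random (seeded) rotation axis falls inside
    [wedge_start, wedge_start + wedge_range) mod 360.  Observed
    I = scale · I_true · (1 + ε), ε ~ N(0, noise_frac);
    σ = max(noise_frac·|I|, sigma_floor).  The reported cell is the true
    cell plus Gaussian jitter.  Mis-indexed datasets get their indices
    scrambled by a fixed shear (|det| = 1 but outside the Laue group),
    destroying cross-correlation with correctly indexed data.
    """
    rng = np.random.default_rng(spec.seed)
    dataset_id = dataset_id or f"{spec.phase}_{spec.seed}"
    laue = LaueGroup.from_symbol(phase.laue)
    full = _expand_orbits(phase_table, laue)
    hkl = full[["h", "k", "l"]].to_numpy(dtype=np.int64)

    # reciprocal-space Cartesian coordinates: rows of inv(A) are a*, b*, c*
    a_inv = np.linalg.inv(phase.cell.orthogonalization_matrix())
    s = hkl @ a_inv  # (n, 3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ref = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(ref) < 1e-8:
        ref = np.cross(axis, [0.0, 1.0, 0.0])
    ref /= np.linalg.norm(ref)
    perp = np.cross(axis, ref)
    azimuth = np.degrees(np.arctan2(s @ perp, s @ ref)) % 360.0
    in_wedge = (azimuth - spec.wedge_start) % 360.0 < spec.wedge_range
    obs = full.loc[in_wedge].reset_index(drop=True)
    if len(obs) < 10:
        warnings.warn(
            f"{dataset_id}: wedge of {spec.wedge_range:g} deg sampled only "
            f"{len(obs)} reflections",
            stacklevel=2,
        )

    eps = rng.normal(0.0, spec.noise_frac, size=len(obs)) if spec.noise_frac > 0 else 0.0
    i_obs = spec.scale * obs["I_true"].to_numpy() * (1.0 + eps)
    sigma = np.maximum(spec.noise_frac * np.abs(i_obs), spec.sigma_floor)
    out_hkl = obs[["h", "k", "l"]].to_numpy(dtype=np.int64)
    if spec.misindexed:
        shear = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]], dtype=np.int64)
        out_hkl = out_hkl @ shear

    jitter = np.concatenate(
        [
            rng.normal(0.0, spec.cell_jitter_length, size=3),
            rng.normal(0.0, spec.cell_jitter_angle, size=3),
        ]
    )
    reported = np.asarray(phase.cell.parameters) + jitter
    cell_row = CellTableRow(
        dataset_id=dataset_id,
        a=reported[0], b=reported[1], c=reported[2],
        alpha=reported[3], beta=reported[4], gamma=reported[5],
        lattice_type=_bravais_symbol(phase),
        n_indexed=len(obs),
        rotation_range=spec.wedge_range,
    )
    rset = ReflectionSet(
        dataset_id=dataset_id,
        cell=phase.cell,
        laue=laue,
        centering=phase.centering,
        df=pd.DataFrame(
            {
                "h": out_hkl[:, 0], "k": out_hkl[:, 1], "l": out_hkl[:, 2],
                "I": i_obs, "sigma": sigma,
            }
        ),
    )
    return rset, cell_row


_SYSTEM_OF_LAUE = {
    "-1": "a", "2/m": "m", "mmm": "o", "4/m": "t", "4/mmm": "t",
    "-3": "h", "-3m": "h", "6/m": "h", "6/mmm": "h", "m-3": "c", "m-3m": "c",
}


def _bravais_symbol(phase: PhaseSpec) -> str:
    return f"{_SYSTEM_OF_LAUE[phase.laue]}{phase.centering}"


@dataclass
class MixtureResult:
    """A labeled multi-crystal collection with its generating ground truth."""

    datasets: list[ReflectionSet]
    cell_rows: list[CellTableRow]
    labels: dict[str, str]  # dataset_id -> phase name
    phases: dict[str, PhaseSpec]
    phase_tables: dict[str, pd.DataFrame]
    reindex_op: ReindexOperator | None = None
    swapped_ids: list[str] = field(default_factory=list)


SCENARIOS = ("single", "distinct_cells", "similar_cells", "ambiguity", "with_outliers")

# Default test phases: an MFI-type zeolite cell and a mordenite-like cell,
# the classic pair separable already on lattice parameters.
_CELL_MFI = UnitCell(13.4, 19.9, 20.1, 90, 90, 90)
_CELL_MOR = UnitCell(7.5, 18.3, 20.5, 90, 90, 90)
_CELL_AMBIG = UnitCell(13.4, 20.0, 20.0, 90, 90, 90)  # b = c: indexing ambiguity


def simulate_mixture(
    scenario: str,
    n_per_phase: int = 10,
    seed: int = 0,
    d_min: float = 1.2,
    wedge_range: float = 30.0,
    noise_frac: float = 0.05,
) -> MixtureResult:
    """Labeled multi-crystal collections for the pipeline test scenarios.

    single           one phase;
    distinct_cells   two phases with clearly different cells (separable in
                     stage 1);
    similar_cells    two phases with identical cells but independent
                     intensities (only stage 2 can separate them);
    ambiguity        one phase with b = c; half the datasets are indexed
                     through the b/c axis swap;
    with_outliers    one phase plus two datasets with deviating cells and
                     scrambled indices.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    rng = np.random.default_rng(seed)

    def phase(name, cell, phase_seed):
        return PhaseSpec(name=name, cell=cell, laue="mmm", centering="P", n_atoms=20,
                         b_iso=2.0, seed=phase_seed)

    base = int(rng.integers(0, 2**31 - 1))
    if scenario == "single":
        phases = {"phase_a": phase("phase_a", _CELL_MFI, base)}
    elif scenario == "distinct_cells":
        phases = {
            "phase_a": phase("phase_a", _CELL_MFI, base),
            "phase_b": phase("phase_b", _CELL_MOR, base + 1),
        }
    elif scenario == "similar_cells":
        phases = {
            "phase_a": phase("phase_a", _CELL_MFI, base),
            "phase_b": phase("phase_b", _CELL_MFI, base + 1),
        }
    elif scenario == "ambiguity":
        phases = {"phase_a": phase("phase_a", _CELL_AMBIG, base)}
    else:  # with_outliers
        phases = {"phase_a": phase("phase_a", _CELL_MFI, base)}

    phase_tables = {name: simulate_phase_intensities(p, d_min=d_min) for name, p in phases.items()}

    datasets: list[ReflectionSet] = []
    cell_rows: list[CellTableRow] = []
    labels: dict[str, str] = {}
    swapped: list[str] = []
    counter = 0
    for name, p in phases.items():
        for i in range(n_per_phase):
            counter += 1
            ds_id = f"ds_{counter:03d}"
            spec = CrystalSimSpec(
                phase=name,
                wedge_start=float(rng.uniform(0, 360)),
                wedge_range=wedge_range,
                scale=float(rng.uniform(0.5, 2.0)),
                noise_frac=noise_frac,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rset, row = simulate_crystal_dataset(phase_tables[name], p, spec, dataset_id=ds_id)
            if scenario == "ambiguity" and i >= n_per_phase // 2:
                from .symmetry import apply_reindex

                rset = apply_reindex(rset, REINDEX_SWAP_BC)
                swapped.append(ds_id)
            datasets.append(rset)
            cell_rows.append(row)
            labels[ds_id] = name

    if scenario == "with_outliers":
        for tag, offset in (("out_1", np.array([3.0, -3.5, 3.0, 0, 0, 0])),
                            ("out_2", np.array([-3.2, 3.0, -3.6, 0, 0, 0]))):
            counter += 1
            ds_id = f"ds_{counter:03d}"
            p = phases["phase_a"]
            spec = CrystalSimSpec(
                phase="outlier",
                wedge_start=float(rng.uniform(0, 360)),
                wedge_range=wedge_range,
                scale=1.0,
                noise_frac=noise_frac,
                misindexed=True,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            outlier_cell = UnitCell(*(np.asarray(p.cell.parameters) + offset))
            outlier_phase = PhaseSpec(
                name="outlier", cell=outlier_cell, laue=p.laue, centering=p.centering,
                n_atoms=p.n_atoms, b_iso=p.b_iso, seed=p.seed,
            )
            table = simulate_phase_intensities(outlier_phase, d_min=d_min)
            rset, row = simulate_crystal_dataset(table, outlier_phase, spec, dataset_id=ds_id)
            datasets.append(rset)
            cell_rows.append(row)
            labels[ds_id] = "outlier"

    return MixtureResult(
        datasets=datasets,
        cell_rows=cell_rows,
        labels=labels,
        phases=phases,
        phase_tables=phase_tables,
        reindex_op=REINDEX_SWAP_BC if scenario == "ambiguity" else None,
        swapped_ids=swapped,
    )


def simulate_defocused_frame(
    shape: tuple[int, int] = (256, 256),
    beam_center: tuple[float, float] = (128.0, 128.0),
    beam_radius: float = 40.0,
    particle_offset: tuple[float, float] = (0.0, 0.0),
    particle_radius: float = 10.0,
    contrast: float = 0.85,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[Frame, dict]:
    """A defocused-beam frame with a crystal shadow, plus its ground truth.

    Flat-top bright disc (soft 2-px edge) at ``beam_center``; a darker disc
    of the crystal at beam_center + particle_offset whose interior sits at
    (1 − contrast) of the beam level; faint low-frequency background
    texture; Gaussian noise of ``noise_sigma`` × beam level.
    """
    if float(np.hypot(*particle_offset)) >= beam_radius:
        raise ValueError("particle must lie inside the beam")
    rng = np.random.default_rng(seed)
    beam_level = 1000.0
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r_beam = np.hypot(rr - beam_center[0], cc - beam_center[1])
    soft = 2.0
    beam = beam_level * np.clip((beam_radius - r_beam) / soft + 0.5, 0.0, 1.0)
    pc = (beam_center[0] + particle_offset[0], beam_center[1] + particle_offset[1])
    r_part = np.hypot(rr - pc[0], cc - pc[1])
    shadow = np.clip((particle_radius - r_part) / soft + 0.5, 0.0, 1.0)
    img = beam * (1.0 - contrast * shadow)
    # low-frequency background texture (carbon film)
    from scipy import ndimage

    texture = ndimage.gaussian_filter(rng.normal(size=shape), 8.0)
    img = img + 0.02 * beam_level * texture
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma * beam_level, size=shape)
    truth = {"beam_center": beam_center, "particle_center": pc, "shift_px": particle_offset}
    return Frame(np.clip(img, 0.0, None)), truth
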