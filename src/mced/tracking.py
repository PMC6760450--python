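"""Image algorithms for crystal selection and defocused-beam tracking.

Two pure image-in/vector-out tasks, with no hardware in the loop:

* Overview images: find crystal candidates with an adaptive threshold,
  then keep only "isolated" ones — any pair of crystals closer than a
  threshold distance (1.2 µm by default) disqualifies both, and crystals
  near the edge of view are flagged for re-centering.

* Defocused diffraction frames: the intermediate lens is defocused so the
  primary beam carries a shadow image of the crystal.  The beam's bounding
  box comes from thresholded row/column marginal sums; the crop is
  segmented by an intensity band (10–20% of the range — the grey levels of
  the crystal and of the gradient at the beam edge, ignoring the dark
  background and the bright carbon film); a Gaussian blur suppresses the
  thin beam-edge ring so the argmax of the blurred mask lands on the
  compact crystal; the beam-to-crystal difference vector is the shift to
  apply (optionally mapped to deflector units by a user calibration
  matrix).

Convention: (row, col) indexing, 0-based, origin at the top-left; all
shifts are (Δrow, Δcol) in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "Frame",
    "BeamBox",
    "ParticleFix",
    "CrystalCandidate",
    "NoBeamError",
    "NoParticleError",
    "find_beam_box",
    "crop_beam",
    "segment_particle",
    "locate_particle",
    "compute_shift",
    "track_frame",
    "find_crystals",
    "select_isolated",
]


class NoBeamError(ValueError):
    """No bright region found in the frame."""


class NoParticleError(ValueError):
    """Segmentation produced an empty mask."""


@dataclass
class Frame:
    """Grayscale image with an optional physical pixel size."""

    pixels: np.ndarray
    pixel_size: float = 1.0  # length units per pixel (µm/px for overviews)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("frame must be a 2-D array")
        if min(self.pixels.shape) < 16:
            raise ValueError("frame dimensions must be at least 16 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BeamBox:
    """Half-open pixel bounds of the defocused primary beam."""

    row_lo: int
    row_hi: int
    col_lo: int
    col_hi: int

    def __post_init__(self) -> None:
        if not (self.row_lo < self.row_hi and self.col_lo < self.col_hi):
            raise ValueError("beam box must have lo < hi")

    @property
    def center(self) -> tuple[float, float]:
        """Midpoint in pixel-center coordinates."""
        return ((self.row_lo + self.row_hi - 1) / 2.0, (self.col_lo + self.col_hi - 1) / 2.0)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_hi - self.row_lo, self.col_hi - self.col_lo)


@dataclass(frozen=True)
class ParticleFix:
    """Result of one tracking step: where the crystal sits vs the beam."""

    beam_center: tuple[float, float]
    particle_center: tuple[float, float]
    shift_px: tuple[float, float]
    shift_calibrated: tuple[float, float] | None = None


@dataclass
class CrystalCandidate:
    """A connected component found in an overview image."""

    centroid: tuple[float, float]  # (row, col)
    area: float  # px²
    isolated: bool = False
    reason: str = ""


def find_beam_box(frame: Frame, bright_frac: float = 0.5) -> BeamBox:
    """Bounding box of the beam from thresholded marginal sums.

    The image is summed along rows and along columns; in each marginal the
    threshold is min + bright_frac·(max − min), and the box spans the
    outermost bins above threshold.
    """
    if not 0.0 < bright_frac < 1.0:
        raise ValueError("bright_frac must lie in (0, 1)")
    box = []
    for axis in (1, 0):  # row sums, then column sums
        marg = frame.pixels.sum(axis=axis)
        lo_val, hi_val = marg.min(), marg.max()
        if hi_val == lo_val:
            raise NoBeamError("frame has no intensity variation in its marginals")
        above = np.nonzero(marg > lo_val + bright_frac * (hi_val - lo_val))[0]
        if above.size == 0:
            raise NoBeamError("no marginal bin above the brightness threshold")
        box.append((int(above[0]), int(above[-1]) + 1))
    (row_lo, row_hi), (col_lo, col_hi) = box
    return BeamBox(row_lo, row_hi, col_lo, col_hi)


@dataclass
class CropResult:
    """A padded sub-frame around the beam, with coordinate bookkeeping."""

    pixels: np.ndarray
    origin: tuple[int, int]  # (row, col) of crop pixel (0,0) in the frame
    beam_center: tuple[float, float]  # beam center in crop coordinates

    def to_frame_coords(self, rc: tuple[float, float]) -> tuple[float, float]:
        return (rc[0] + self.origin[0], rc[1] + self.origin[1])


def crop_beam(frame: Frame, box: BeamBox, pad_frac: float = 0.1) -> CropResult:
    """Crop the beam region, expanded by ``pad_frac`` per side and clamped."""
    if pad_frac < 0:
        raise ValueError("pad_frac must be >= 0")
    h, w = box.shape
    pr, pc = int(round(pad_frac * h)), int(round(pad_frac * w))
    r0 = max(box.row_lo - pr, 0)
    r1 = min(box.row_hi + pr, frame.shape[0])
    c0 = max(box.col_lo - pc, 0)
    c1 = min(box.col_hi + pc, frame.shape[1])
    bc = box.center
    return CropResult(
        pixels=frame.pixels[r0:r1, c0:c1],
        origin=(r0, c0),
        beam_center=(bc[0] - r0, bc[1] - c0),
    )


def segment_particle(
    crop: np.ndarray,
    band: tuple[float, float] = (0.10, 0.20),
    denoise_sigma: float = 0.0,
) -> np.ndarray:
    """Binary mask of pixels in an intensity band of the crop's range.

    The default band [10%, 20%) — bins 3 and 4 of a 20-bin equal-width
    histogram over [min, max] — selects the grey levels of the crystal
    shadow and of the gradient at the beam edge, while ignoring the dark
    pixels outside the defocused probe and the bright carbon-film pixels.
    ``denoise_sigma`` optionally smooths the crop first (useful on noisy
    detectors; 0 disables it).
    """
    crop = np.asarray(crop, dtype=float)
    if denoise_sigma > 0:
        crop = ndimage.gaussian_filter(crop, denoise_sigma)
    lo, hi = crop.min(), crop.max()
    if hi == lo:
        raise ValueError("cannot segment a constant image")
    rng = hi - lo
    return (crop >= lo + band[0] * rng) & (crop < lo + band[1] * rng)


def locate_particle(mask: np.ndarray, blur_sigma: float) -> tuple[float, float]:
    """Center of the particle: argmax of the Gaussian-blurred mask.

    The blur integrates the compact crystal blob into a single peak while
    the thin beam-edge ring stays weak, which eliminates the influence of
    the beam edge.  Ties resolve to the smallest (row, col).
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise NoParticleError("empty segmentation mask")
    blurred = ndimage.gaussian_filter(mask.astype(float), blur_sigma)
    idx = np.unravel_index(int(np.argmax(blurred)), blurred.shape)
    return (float(idx[0]), float(idx[1]))


def compute_shift(
    beam_center: tuple[float, float],
    particle_center: tuple[float, float],
    calibration: np.ndarray | None = None,
) -> ParticleFix:
    """Difference vector particle − beam, optionally in deflector units.

    ``calibration`` is a 2×2 matrix mapping a pixel shift to instrument
    units (hardware-specific, supplied by the user).
    """
    shift = (particle_center[0] - beam_center[0], particle_center[1] - beam_center[1])
    calibrated = None
    if calibration is not None:
        m = np.asarray(calibration, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("calibration must be a 2×2 matrix")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("calibration matrix is singular")
        vec = m @ np.asarray(shift)
        calibrated = (float(vec[0]), float(vec[1]))
    return ParticleFix(
        beam_center=tuple(map(float, beam_center)),
        particle_center=tuple(map(float, particle_center)),
        shift_px=tuple(map(float, shift)),
        shift_calibrated=calibrated,
    )


def track_frame(
    frame: Frame,
    bright_frac: float = 0.5,
    pad_frac: float = 0.1,
    blur_sigma: float | None = None,
    denoise_sigma: float = 1.0,
    calibration: np.ndarray | None = None,
) -> ParticleFix:
    """Full tracking chain on one defocused frame.

    find_beam_box → crop_beam → segment_particle → locate_particle →
    compute_shift, all in frame coordinates.  ``blur_sigma`` defaults to
    one fifth of the beam radius estimated from the beam box.
    """
    box = find_beam_box(frame, bright_frac=bright_frac)
    crop = crop_beam(frame, box, pad_frac=pad_frac)
    if blur_sigma is None:
        blur_sigma = (box.shape[0] + box.shape[1]) / 4.0 / 5.0
    mask = segment_particle(crop.pixels, denoise_sigma=denoise_sigma)
    particle_crop = locate_particle(mask, blur_sigma=blur_sigma)
    particle = crop.to_frame_coords(particle_crop)
    return compute_shift(box.center, particle, calibration=calibration)


def find_crystals(
    overview: Frame,
    window_px: int = 31,
    offset_frac: float = 0.05,
    min_area_px: float = 10.0,
    dark_on_light: bool = True,
) -> list[CrystalCandidate]:
    """Crystal candidates from an overview image via adaptive thresholding.

    A pixel is foreground when it deviates from the local mean (box window
    of ``window_px``) by more than ``offset_frac`` of that mean — darker
    for the usual dark-crystal-on-light-support contrast, brighter with
    ``dark_on_light=False``.  Connected components with area ≥
    ``min_area_px`` become candidates.
    """
    img = overview.pixels
    local_mean = ndimage.uniform_filter(img, size=window_px)
    if dark_on_light:
        fg = img < local_mean * (1.0 - offset_frac)
    else:
        fg = img > local_mean * (1.0 + offset_frac)
    labels = measure.label(fg, connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        out.append(CrystalCandidate(centroid=tuple(region.centroid), area=float(region.area)))
    return out


def select_isolated(
    candidates: list[CrystalCandidate],
    pixel_size: float,
    frame_shape: tuple[int, int],
    min_dist: float = 1.2,
    edge_margin_frac: float = 0.05,
) -> list[CrystalCandidate]:
    """Flag candidates as isolated / too close / too near the edge.

    Any pair of candidates whose centroids are closer than ``min_dist``
    (same length units as ``pixel_size``, µm by convention) disqualifies
    BOTH.  Candidates within ``edge_margin_frac`` of a border are flagged
    "edge" — in an acquisition loop they would be re-centered by a stage
    move and re-tested.  Flags are independent of candidate order.
    """
    n = len(candidates)
    too_close = [False] * n
    pts = np.array([c.centroid for c in candidates], dtype=float) * pixel_size
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pts[i] - pts[j]) < min_dist:
                too_close[i] = too_close[j] = True
    out = []
    mr = edge_margin_frac * frame_shape[0]
    mc = edge_margin_frac * frame_shape[1]
    for i, c in enumerate(candidates):
        r, col = c.centroid
        reasons = []
        if too_close[i]:
            reasons.append("too_close")
        if r < mr or r > frame_shape[0] - 1 - mr or col < mc or col > frame_shape[1] - 1 - mc:
            reasons.append("edge")
        out.append(
            CrystalCandidate(
                centroid=c.centroid,
                area=c.area,
                isolated=not reasons,
                reason=",".join(reasons),
            )
        )
    return out
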