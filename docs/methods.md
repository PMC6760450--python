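# Methods

This note documents the models and procedures implemented in `mced`, the
parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Stage 1 — lattice clustering

Each dataset contributes one refined unit cell (a, b, c in Å; α, β, γ in
degrees).  Two distances are offered:

* `params` (default): the unweighted Euclidean norm of the 6-vector of
  parameter differences, mixing Å and degrees.  No weighting between
  lengths and angles is applied; for the few-degree, few-Å spreads
  typical of serial ED cells the two contributions are of comparable
  magnitude, and the unweighted norm keeps cut distances interpretable
  (a cut of ~2 means "cells agreeing to a couple of Å/degrees").  A
  z-scored variant (each parameter divided by its ensemble standard
  deviation) is available behind the `zscore` flag for ensembles where
  one parameter dominates the spread; it is deliberately not the
  default because its scale depends on the ensemble itself.
* `volume`: |V_i − V_j| in Å³, useful as a quick one-dimensional screen
  when axis assignments are unstable.

Clustering is average linkage (UPGMA): the distance between two clusters
is the arithmetic mean of all cross-pair distances.  SciPy's linkage
implementation is used; the test suite checks it merge-for-merge against
a brute-force evaluation of the definition.  Cutting keeps the connected
components of merges strictly below the cut height.  Cluster labels are
1-based, ordered by decreasing size with ties broken by the smallest
member id, so all reports are deterministic.

When no cut is supplied the pipeline cuts at the midpoint of the largest
gap between consecutive merge heights.  This is a heuristic for
well-separated phases only: for a genuinely single-phase ensemble the
largest gap is arbitrary and the heuristic may split the cluster, so
single-phase reductions should pass an explicit cut (a few Å/degrees,
e.g. 2–3 for the cell spreads simulated here).

The average cell of a cluster comes from per-parameter histograms: a
Gaussian is fitted to the values inside a user window by maximum
likelihood (sample mean, population σ).  The histogram (default 50 bins)
is display-only; the fit does not depend on binning, which keeps it
stable at the n ≈ 50 dataset counts typical of one session.  Windows
default to the data range; explicit windows exclude outliers from the
average.

Lattice-type voting: datasets are grouped by their two-letter Bravais
symbol (e.g. `oP`, `mC`) and each group is scored by the summed number
of indexed reflections; the highest score wins, with alphabetical
tie-breaks.  The rationale is that the correct lattice type indexes more
of the observed reflections than a mis-assigned one.

No Niggli reduction or lattice-symmetry idealization is applied before
clustering: cells enter as reported, and idealization happens implicitly
through the averaged cell used downstream.  Angles of exactly 90° are
not special-cased.

## Symmetry machinery

The 11 Laue classes are represented by explicit integer operator sets,
obtained as the rotation parts of the corresponding symmorphic primitive
space groups via `gemmi` (e.g. `P m m m` for mmm); the test suite
verifies closure, the presence of ±identity, and the group orders
exhaustively.  Operators act on (h, k, l) as row vectors.

Conventions: monoclinic unique axis b; trigonal −3m in the −3m1
setting; rhombohedral lattices in the hexagonal obverse setting with the
R centering rule −h + k + l ≡ 0 (mod 3).  Friedel mates are always
merged, as appropriate for intensity-only data.

The canonical (asymmetric-unit) representative of a reflection is the
lexicographic maximum over its full orbit.  This is deliberately not the
per-group "h ≥ k ≥ l"-style rule: one rule covers all 11 classes, it is
idempotent and orbit-invariant by construction, and it is trivially
checkable against a brute-force orbit scan (which the tests and the
acceptance script both do).

d-spacings come from the reciprocal metric tensor of the general
triclinic cell; the sphere enumeration of all unique reflections with
d ≥ d_min uses the exact index bounds |h| ≤ a/d_min (h = a·s with
|s| ≤ 1/d_min), a configurable grid cap, centering filters, and orbit
reduction.

Within-dataset merging: per canonical index, I is the unweighted mean
and σ = √(Σσᵢ²)/n with the multiplicity n recorded.  The unweighted mean
is the default because σ models differ between parsed and simulated
data; a σ-weighted mean would couple the merge result to whichever error
model produced the input.  The σ bookkeeping tracks Σσᵢ² through
multiplicities so that merging is idempotent.

Reindexing operators are integer matrices with |det| = 1 acting as
hkl′ = hkl·M; the cell transforms through its metric tensor
(G′ = MᵀGM), so axis permutations permute the cell axes consistently and
intensities are untouched.

## Stage 2 — reflection clustering, scaling, merging

CC_I between two merged datasets is the Pearson correlation of
intensities over the intersection of their canonical indices, computed
on merged uniques (not raw observations).  A pair with fewer than
`min_common` (default 10) common uniques, or with degenerate variance,
is *undefined*.  The distance transform is

    d = sqrt(1 − CC_I²)        for CC_I ≥ 0
    d = 1                      for CC_I < 0 or undefined

Mapping anticorrelated and undefined pairs to the maximal distance is a
design choice: datasets whose intensities disagree must never cluster,
and the transform's anchor points (d = 0.40 ↔ CC_I ≈ 0.92,
d = 0.20 ↔ CC_I ≈ 0.98) are verified in the acceptance suite.

Default filters before correlating: resolution window d ≥ 1.2 Å and
I/σ ≥ 2, both inclusive and configurable.  Restricting the correlation
to well-measured low-angle reflections makes CC_I a statement about the
structure rather than about noise at the resolution edge.

Scaling within a cluster is a fixed-point iteration of the closed form
k_j = Σ(I_ref·I_j)/Σ(I_j²) over the uniques dataset j shares with the
running merged reference (the mean of all currently scaled sets),
renormalized each round so the reference dataset (largest unique count)
has k = 1; iteration stops at relative change < 1e-6 or 20 rounds.  A
disconnected common-reflection graph is an error that lists the
components.  This is deliberately *not* a Kabsch-style
resolution-and-image-dependent scaling model: one factor per crystal is
what the clustering and merging stages need, and anything finer belongs
to the integration program.

Merging pools every scaled measurement per canonical index (I mean,
σ = √(Σσᵢ²)/n, multiplicity kept).  Member cells must agree within 5%
per length (and the equivalent fraction of 180° per angle) — generous on
purpose, because serial ED cells vary by a few percent with sample
height.  Statistics at resolution d_min:

* completeness = 100 · n_unique_observed / n_possible, with n_possible
  from the full enumeration for the cluster's mean cell;
* R_meas = Σ_h √(n_h/(n_h−1)) Σ_i |I_hi − ⟨I_h⟩| / Σ_h Σ_i I_hi over
  uniques with n_h ≥ 2.  The denominator uses signed intensities as
  summed; negative merged intensities are legitimate in ED data and are
  not clipped;
* CC_1/2: the measurements of each multiply-measured unique are split
  once by a seeded random permutation and the Pearson correlation of the
  two half-set means is reported, with the seed recorded.  One split
  (rather than an average over splits) keeps the statistic exactly
  reproducible;
* ⟨I/σ⟩ on merged values and the mean multiplicity.

Clusters are ranked by completeness, then CC_1/2, then R_meas.  Merging
more wedges can only add uniques, so completeness is weakly monotone in
cluster size — the practical reason multi-crystal merging is worth the
trouble.

## Tracking and crystal selection

All image operations use (row, col) indexing, 0-based, origin top-left.

Defocused-frame chain: (1) the beam's bounding box comes from row/column
marginal sums thresholded at min + 0.5·(max − min); the half-range
default suits a flat-top defocused beam, where the marginal is near-binary,
and is configurable.  (2) The box is cropped with 10% padding.  (3) The
crop is segmented by the intensity band [10%, 20%) of its range — bins 3
and 4 of a 20-bin equal-width histogram over [min, max]; the range is
taken over the crop since only relative grey levels are meaningful.
This selects the crystal's grey shadow and the gradient at the beam
edge while ignoring dark background and bright carbon film.  An optional
pre-smoothing (`denoise_sigma`, default 1 px in the chained
`track_frame`, 0 in the bare `segment_particle`) keeps the band
well-defined on noisy detectors.  (4) The mask is blurred with a
Gaussian of σ = beam radius / 5 by default and the argmax (ties to the
smallest row, col) is the particle centre: the blur integrates the
compact crystal into one peak while the thin beam-edge ring stays weak.
(5) The shift is particle − beam centre, optionally mapped to deflector
units by a user-supplied 2×2 calibration matrix — deflector calibration
is hardware-specific and out of scope, so the library stops at the
pixel/calibrated-vector boundary.

Overview images: adaptive thresholding against a local box mean
(window 31 px, offset 5% of the local mean by default — engineering
choices, as is the connectivity), connected components, and an area
floor give crystal candidates.  Isolation: any pair of centroids closer
than 1.2 µm disqualifies *both*; candidates within 5% of the frame edge
are flagged `edge` (an acquisition loop would re-centre them by a stage
move and re-test; this library only flags).  Flags are order-independent.

## Synthetic data

The generators define the test conditions for the whole package.

Intensities: n = 20 unit point scatterers placed uniformly at random in
the cell (seeded) give I(hkl) = |Σ_j exp(2πi·hkl·x_j)|² · exp(−B/(2d²))
with B = 2 Å², evaluated on the canonical unique set and normalized to
mean 100.  A point-scatterer |F|² — rather than, say, independent
log-normal draws — produces the speckled Wilson-like statistics real
structures show: intensities are strongly correlated between crystals of
the same phase and essentially uncorrelated between phases with
independent atom positions, which is precisely the contrast the CC_I
stage exploits.  Intensities are evaluated on canonical indices only and
copied to the whole orbit, so Laue consistency holds by construction.

Sampling: a crystal observes the orbit-expanded reflections whose
reciprocal-space azimuth about a random rotation axis falls in its
wedge.  Default wedge 30°, matching the middle of the rotation-range
distribution of automated serial collections (means of roughly 12–16°
with tails to 70–80°).  The model is purely geometric — no excitation
error, curvature, or partiality — because clustering and merging consume
only *which* uniques are sampled and with what multiplicity.

Noise and errors: observed I = scale · I_true · (1 + ε) with
ε ~ N(0, 5%) by default; σ = max(0.05·|I|, 0.01); per-crystal scales
drawn from [0.5, 2]; reported cells jittered by N(0, 0.15 Å) per length
and N(0, 0.2°) per angle, emulating the sample-height effect.
Mis-indexed outliers get their indices scrambled by a fixed unimodular
shear outside the Laue group.

Scenarios: `single`; `distinct_cells` (13.4/19.9/20.1 Å vs
7.5/18.3/20.5 Å orthorhombic cells — an MFI-like and a mordenite-like
lattice, separable in stage 1 since the cell separation is ≥ 10× the
jitter); `similar_cells` (identical cells, independent intensity seeds —
only stage 2 separates them); `ambiguity` (b = c = 20.0 Å, half the
datasets indexed through the b/c swap); `with_outliers` (two datasets
with cells offset by ~3 Å, 20× the jitter, plus scrambled indices).

Defocused frames: flat-top beam disc (soft 2-px edge) at level 1000, a
crystal shadow disc whose interior sits at 15% of the beam level (inside
the segmentation band), 2% low-frequency background texture, Gaussian
noise up to 10% of the beam level in the tests.

What the generators do **not** emulate — and therefore what passing
tests do not certify for real data: dynamical diffraction and
excitation-error effects on intensities, beam-damage decay within a
wedge, detector point spread and hot pixels, genuinely non-Gaussian
error models, rod-shaped crystals and agglomerates in overview images,
and the coupling between goniometer mechanics and wedge geometry.  The
tests certify the *reduction logic* (clustering, scaling, merging,
statistics, geometry of the image chain), not the physics upstream of it.

## Problem sizes and determinism

Default test and acceptance problem sizes were chosen to exercise each
stage at realistic scale while keeping a full run in tens of seconds:
~1000–1100 reflections per 30° dataset at d_min = 1.2 Å (~13 000 in the
full sphere), 10 datasets per phase, 5 generator seeds per scenario, 200
random instances for the UPGMA oracle, and 60 tracking frames across
beam radii 20/40/80 px.  Every stochastic step takes an explicit seed:
generators are pure functions of spec + seed, CC_1/2 records its split
seed, and re-running the pipeline with the same config and seeds
reproduces stats files byte for byte.

## Known limitations

* The largest-gap auto-cut is unreliable for single-phase ensembles
  (see above); pass an explicit cut.
* CC_I is computed on merged uniques; computing it on unmerged common
  observations would differ at second order in the noise.
* HKL4 output rescales intensities by a common factor when a value would
  overflow an F8.2 field (the factor is recorded in the cluster report);
  the nominal 10⁶ SHELX limit already exceeds the 8-character field for
  values ≥ 10⁵, so the writer guards the field width, not the nominal
  limit.
* `scale_sets` assumes one multiplicative factor per crystal; no
  resolution-dependent decay correction is applied at merge time (the
  generator's B-factor is shared by all crystals of a phase, so this is
  exact for the synthetic data and an approximation for real data).
* Space-group determination from systematic absences is out of scope;
  the package stops at Laue class + centering.
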