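# mced — multi-crystal electron-diffraction data reduction

Serial rotation electron diffraction collects continuous-rotation
diffraction datasets from hundreds of sub-micrometre crystals on a single
TEM grid.  Each crystal yields only a partial wedge of reciprocal space,
crystals diffract unequally well, multi-phase powders mix datasets from
different structures, and near-equal cell axes create indexing
ambiguities.  `mced` is the desk-side data-reduction toolbox for that
situation: it groups the datasets, picks the ones worth merging, merges
them, and reports standard crystallographic quality statistics — plus the
image algorithms needed to find isolated crystals in overview images and
to keep a crystal centred in a defocused beam during rotation.

The pipeline works in two stages of hierarchical cluster analysis
(average linkage / UPGMA in both):

1. **Lattice clustering.**  Datasets are clustered on the Euclidean
   distance between their six unit-cell parameters (a, b, c, α, β, γ) or
   on |V_i − V_j|.  Cutting the dendrogram separates phases with distinct
   cells and exposes outliers.  Windowed Gaussian fits to the
   per-parameter histograms give the average cell of each cluster, and
   candidate Bravais lattice types are ranked by the total number of
   reflections each type indexed.

2. **Reflection clustering.**  Within one phase, datasets i and j are
   compared through the Pearson correlation CC_I of the intensities of
   their common symmetry-unique reflections, converted to the distance

       d_ij = sqrt(1 − CC_I²)

   so a cut at d = 0.40 corresponds to CC_I ≈ 0.92 and d = 0.20 to
   CC_I ≈ 0.98.  Each resulting cluster is scaled (one multiplicative
   factor per dataset, least squares against the running merged
   reference), merged, and scored by completeness, R_meas, CC_1/2 and
   ⟨I/σ⟩, so the best cluster for structure solution is simply the top of
   the ranking.  Reindexing operators (integer 3×3 matrices with
   |det| = 1) resolve indexing ambiguities such as a b/c axis swap.

Everything is testable without a microscope: `mced.synthetic` generates
multi-crystal reflection collections with known ground truth (per-phase
point-scatterer intensities, wedge sampling, per-crystal scales, noise,
cell jitter, mis-indexed outliers, phase mixtures, axis-swap ambiguity)
and defocused-beam frames with a planted crystal offset.

## Worked example

Two phases with *identical* unit cells but different structures cannot be
separated by lattice clustering; reflection clustering separates them
exactly:

```python
from mced.synthetic import simulate_mixture
from mced.symmetry import merge_within, filter_reflections
from mced.cluster_merge import (cluster_reflections, scale_sets,
                                merge_cluster, compute_stats)

mix = simulate_mixture("similar_cells", n_per_phase=5, seed=42)
sets = [merge_within(filter_reflections(d, d_min=1.2, min_i_over_sigma=2.0))
        for d in mix.datasets]
assignment, dendrogram, cc = cluster_reflections(sets, cut=0.4)
print("clusters:", assignment.n_clusters)
for label in sorted(set(assignment.labels.values())):
    members = assignment.members(label)
    cluster_sets = [s for s in sets if s.dataset_id in members]
    scales = scale_sets(cluster_sets)
    merge = merge_cluster(cluster_sets, scales)
    stats = compute_stats(merge, d_min=1.2, seed=0)
    print(f"cluster {label}: {len(members)} datasets, "
          f"completeness {stats.completeness:.1f}%, R_meas {stats.r_meas:.3f}, "
          f"CC1/2 {stats.cc_half:.3f}, <I/sigma> {stats.mean_i_over_sigma:.2f}")
```

prints

```
clusters: 2
cluster 1: 5 datasets, completeness 95.5%, R_meas 0.035, CC1/2 0.996, <I/sigma> 32.52
cluster 2: 5 datasets, completeness 89.2%, R_meas 0.037, CC1/2 0.997, <I/sigma> 33.79
```

Every dataset lands in the cluster of its true phase (the generator knows
the labels), merging 5 wedges of 30° each lifts completeness to ~90–95%
at 1.2 Å, R_meas ≈ 3.5% reflects the simulated 5% intensity noise beaten
down by multiplicity, and CC_1/2 ≈ 1 confirms internal consistency.

The same workflow is available from the shell:

```
mced simulate --scenario distinct_cells --n 10 --seed 1 --out sim
mced cluster-cells --cells sim/cells.csv --out lattice_out
mced run --config config.yaml           # both stages, with figures + reports
mced track --frame frame.tiff           # crystal shift from a defocused frame
mced find-crystals --overview o.tiff --pixel-size 0.04
```

File formats: SHELX HKL4 reflection files (3I4 + 2F8.2) are read and
written bit-exactly; XDS CORRECT.LP-style logs and XSCALE.LP correlation
blocks are parsed; cell tables are plain CSV; per-cluster results are
written one folder per cluster (merged HKL4 + stats JSON + member list).

## Layout

```
src/mced/io_formats.py       file dialects (HKL4, CORRECT.LP, XSCALE.LP, CSV, reports)
src/mced/lattice_cluster.py  stage 1: cells, distances, UPGMA, histograms, lattice vote
src/mced/symmetry.py         Laue groups, asymmetric unit, d-spacings, filters, reindexing
src/mced/cluster_merge.py    stage 2: CC_I distance, scaling, merging, quality statistics
src/mced/tracking.py         beam-box / segmentation / particle location / isolation
src/mced/synthetic.py        ground-truth-known generators (reflections + images)
src/mced/pipeline.py         two-stage orchestration with figures and JSON reports
src/mced/cli.py              `mced` command-line entry points
docs/methods.md              models, assumptions, parameter choices, limitations
```
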