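import math

import numpy as np
import pandas as pd
import pytest

from mced.cluster_merge import (
    cc_common,
    cc_to_distance,
    cluster_reflections,
    compute_stats,
    distance_to_cc,
    merge_cluster,
    rank_clusters,
    scale_sets,
    MergeStats,
)
from mced.lattice_cluster import UnitCell
from mced.symmetry import LaueGroup, ReflectionSet, merge_within

CELL = UnitCell(10, 10, 10)
MMM = LaueGroup.from_symbol("mmm")


def make_merged(ds, hkl, intensities, sigma=1.0, cell=CELL, laue=MMM):
    hkl = np.asarray(hkl)
    df = pd.DataFrame(
        {
            "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
            "I": np.asarray(intensities, dtype=float),
            "sigma": np.full(len(hkl), sigma),
            "n_obs": np.ones(len(hkl), dtype=int),
        }
    )
    return ReflectionSet(ds, cell, laue, "P", df, merged=True)


HKL3 = [(1, 0, 0), (2, 1, 0), (3, 2, 1)]
HKL6 = HKL3 + [(4, 1, 0), (5, 2, 1), (6, 3, 2)]


class TestCcCommon:
    def test_self_correlation_is_one(self):
        a = make_merged("a", HKL6, [1, 5, 2, 8, 3, 9])
        pair = cc_common(a, a, min_common=2)
        assert pair.cc == pytest.approx(1.0)
        assert pair.n_common == 6

    def test_scale_invariance(self):
        a = make_merged("a", HKL6, [1, 5, 2, 8, 3, 9])
        b = make_merged("b", HKL6, [2.5 * x for x in [1, 5, 2, 8, 3, 9]])
        assert cc_common(a, b, min_common=2).cc == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = make_merged("a", HKL3, [1, 2, 3])
        b = make_merged("b", HKL3, [3, 2, 1])
        assert cc_common(a, b, min_common=2).cc == pytest.approx(-1.0)

    def test_too_few_common_is_undefined(self):
        a = make_merged("a", HKL3, [1, 2, 3])
        b = make_merged("b", HKL3, [3, 2, 1])
        assert not cc_common(a, b, min_common=10).defined

    def test_laue_mismatch_rejected(self):
        a = make_merged("a", HKL3, [1, 2, 3])
        b = make_merged("b", HKL3, [1, 2, 3], laue=LaueGroup.from_symbol("4/mmm"))
        with pytest.raises(ValueError, match="Laue"):
            cc_common(a, b)


class TestCcToDistance:
    def test_perfect_correlation_distance_zero(self):
        assert cc_to_distance(1.0) == 0.0

    def test_printed_cut_cc_pairs(self):
        # the published cut distances correspond to these CC_I values
        assert round(distance_to_cc(0.40), 2) == 0.92
        assert round(distance_to_cc(0.38), 2) == 0.92
        assert round(distance_to_cc(0.20), 2) == 0.98

    def test_negative_or_undefined_is_maximal(self):
        assert cc_to_distance(-0.3) == 1.0
        assert cc_to_distance(float("nan")) == 1.0

    def test_strictly_decreasing_with_bounded_slope(self):
        grid = np.linspace(0.0, 0.99, 200)
        d = np.array([cc_to_distance(c) for c in grid])
        assert np.all(np.diff(d) < 0)
        max_slope = 0.99 / math.sqrt(1 - 0.99**2)  # |d'| = cc/sqrt(1-cc²)
        assert np.all(np.abs(np.diff(d)) <= np.diff(grid) * max_slope + 1e-12)
        assert cc_to_distance(0.0) == 1.0


class TestClusterReflections:
    def test_identical_sets_form_one_cluster(self):
        a = make_merged("a", HKL6, [1, 5, 2, 8, 3, 9])
        b = make_merged("b", HKL6, [1, 5, 2, 8, 3, 9])
        assignment, _, _ = cluster_reflections([a, b], cut=0.1, min_common=2)
        assert assignment.n_clusters == 1

    def test_cut_zero_gives_singletons(self):
        a = make_merged("a", HKL6, [1, 5, 2, 8, 3, 9])
        b = make_merged("b", HKL6, [1, 5, 2, 8, 3, 9])
        assignment, _, _ = cluster_reflections([a, b], cut=0.0, min_common=2)
        assert assignment.n_clusters == 2

    def test_all_pairs_undefined_is_error(self):
        a = make_merged("a", HKL3, [1, 2, 3])
        b = make_merged("b", [(7, 0, 0), (8, 1, 0), (9, 2, 1)], [1, 2, 3])
        with pytest.raises(ValueError, match="common"):
            cluster_reflections([a, b], cut=0.4, min_common=2)

    def test_two_uncorrelated_phases_recovered(self):
        from mced.symmetry import filter_reflections
        from mced.synthetic import simulate_mixture

        for seed in range(2):
            result = simulate_mixture("similar_cells", n_per_phase=5, seed=seed)
            sets = [
                merge_within(filter_reflections(d, d_min=1.2, min_i_over_sigma=2.0))
                for d in result.datasets
            ]
            assignment, _, _ = cluster_reflections(sets, cut=0.4)
            phase_of_label = {}
            for ds, lab in assignment.labels.items():
                phase_of_label.setdefault(lab, set()).add(result.labels[ds])
            assert len(phase_of_label) == 2
            assert all(len(p) == 1 for p in phase_of_label.values())


class TestScaleSets:
    def test_duplicates_scale_to_unity(self):
        sets = [make_merged(f"d{i}", HKL6, [1, 5, 2, 8, 3, 9]) for i in range(3)]
        k = scale_sets(sets)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in k.values())

    def test_half_intensity_set_gets_factor_two(self):
        base = [10.0, 50.0, 20.0, 80.0, 30.0, 90.0]
        a = make_merged("a", HKL6, base)
        b = make_merged("b", HKL3, [x / 2 for x in base[:3]])
        k = scale_sets([a, b])
        assert k["a"] == pytest.approx(1.0)
        assert k["b"] == pytest.approx(2.0, abs=1e-6)

    def test_disconnected_graph_reports_components(self):
        a = make_merged("a", HKL3, [1, 2, 3])
        b = make_merged("b", [(7, 0, 0), (8, 1, 0)], [1, 2])
        with pytest.raises(ValueError, match="disconnected"):
            scale_sets([a, b])

    def test_recovers_planted_scales_noiseless(self):
        from mced.symmetry import merge_within
        from mced.synthetic import (
            CrystalSimSpec,
            PhaseSpec,
            simulate_crystal_dataset,
            simulate_phase_intensities,
        )

        phase = PhaseSpec("p", UnitCell(13.4, 19.9, 20.1), seed=3)
        table = simulate_phase_intensities(phase, d_min=1.2)
        true_scales = [0.5, 0.8, 1.0, 1.5, 2.0]
        sets = []
        for i, s in enumerate(true_scales):
            spec = CrystalSimSpec(
                "p", wedge_start=i * 70.0, wedge_range=60.0, scale=s,
                noise_frac=0.0, seed=10 + i,
            )
            dset, _ = simulate_crystal_dataset(table, phase, spec, dataset_id=f"d{i}")
            sets.append(merge_within(dset))
        k = scale_sets(sets)
        ref = max(sets, key=lambda s: (s.n_reflections, s.dataset_id)).dataset_id
        s_ref = true_scales[int(ref[1])]
        for i, s in enumerate(true_scales):
            assert k[f"d{i}"] * s / s_ref == pytest.approx(1.0, abs=1e-4)


class TestMergeCluster:
    def test_self_merge_doubles_multiplicity(self):
        a = make_merged("a", HKL3, [1, 2, 3])
        merge = merge_cluster([a, a])
        table = merge.merged_table()
        assert np.allclose(table["I"], [1, 2, 3])
        assert table["n_obs"].tolist() == [2, 2, 2]

    def test_measurement_conservation(self):
        a = make_merged("a", HKL6, [1, 5, 2, 8, 3, 9])
        b = make_merged("b", HKL3, [1, 5, 2])
        merge = merge_cluster([a, b])
        assert merge.merged_table()["n_obs"].sum() == 9

    def test_cell_mismatch_rejected(self):
        a = make_merged("a", HKL3, [1, 2, 3])
        b = make_merged("b", HKL3, [1, 2, 3], cell=UnitCell(12, 10, 10))
        with pytest.raises(ValueError, match="deviates"):
            merge_cluster([a, b])

    def test_noiseless_halves_reproduce_truth(self):
        from mced.symmetry import merge_within
        from mced.synthetic import (
            CrystalSimSpec,
            PhaseSpec,
            simulate_crystal_dataset,
            simulate_phase_intensities,
        )

        phase = PhaseSpec("p", UnitCell(13.4, 19.9, 20.1), seed=11)
        table = simulate_phase_intensities(phase, d_min=1.5)
        sets = []
        for i, (start, scale) in enumerate([(0.0, 1.0), (180.0, 0.25)]):
            spec = CrystalSimSpec(
                "p", wedge_start=start, wedge_range=180.0, scale=scale,
                noise_frac=0.0, seed=20 + i,
            )
            dset, _ = simulate_crystal_dataset(table, phase, spec, dataset_id=f"d{i}")
            sets.append(merge_within(dset))
        scales = scale_sets(sets)
        merged = merge_cluster(sets, scales).merged_table()
        truth = table.set_index(["h", "k", "l"])["I_true"]
        got = merged.set_index(["h", "k", "l"])["I"]
        common = truth.index.intersection(got.index)
        assert len(common) > 100
        ratio = (got.loc[common] / truth.loc[common]).to_numpy()
        assert np.allclose(ratio, ratio[0], atol=1e-9)


class TestComputeStats:
    def test_duplicated_dataset_has_zero_rmeas_and_unit_cchalf(self):
        a = make_merged("a", HKL6, [1, 5, 2, 8, 3, 9])
        merge = merge_cluster([a, a])
        stats = compute_stats(merge, d_min=1.5, seed=1)
        assert stats.r_meas == pytest.approx(0.0, abs=1e-12)
        assert stats.cc_half == pytest.approx(1.0)

    def test_full_enumeration_is_complete(self):
        from mced.symmetry import enumerate_unique

        uniques = enumerate_unique(CELL, MMM, "P", d_min=2.5)
        a = make_merged("a", uniques, np.arange(1, len(uniques) + 1, dtype=float))
        stats = compute_stats(merge_cluster([a, a]), d_min=2.5, seed=0)
        assert stats.completeness == pytest.approx(100.0)

    def test_half_the_uniques_is_fifty_percent(self):
        from mced.symmetry import enumerate_unique

        uniques = enumerate_unique(CELL, MMM, "P", d_min=2.5)
        half = uniques[: len(uniques) // 2]
        a = make_merged("a", half, np.arange(1, len(half) + 1, dtype=float))
        stats = compute_stats(merge_cluster([a, a]), d_min=2.5, seed=0)
        assert stats.completeness == pytest.approx(100.0 * len(half) / len(uniques))
        if len(uniques) % 2 == 0:
            assert stats.completeness == pytest.approx(50.0)

    def test_no_repeats_leaves_rmeas_undefined(self):
        a = make_merged("a", HKL3, [1, 2, 3])
        merge = merge_cluster([a])
        with pytest.warns(UserWarning, match="undefined"):
            stats = compute_stats(merge, d_min=2.5, seed=0)
        assert math.isnan(stats.r_meas)
        assert math.isnan(stats.cc_half)

    def test_global_rescale_leaves_statistics_unchanged(self):
        a = make_merged("a", HKL6, [1, 5, 2, 8, 3, 9])
        b = make_merged("b", HKL6, [1.1, 5.2, 1.9, 8.3, 2.8, 9.4])
        s1 = compute_stats(merge_cluster([a, b]), d_min=1.5, seed=3)
        a2 = make_merged("a", HKL6, [10, 50, 20, 80, 30, 90], sigma=10.0)
        b2 = make_merged("b", HKL6, [11, 52, 19, 83, 28, 94], sigma=10.0)
        s2 = compute_stats(merge_cluster([a2, b2]), d_min=1.5, seed=3)
        assert s1.r_meas == pytest.approx(s2.r_meas)
        assert s1.cc_half == pytest.approx(s2.cc_half)
        assert s1.completeness == s2.completeness
        assert s1.mean_i_over_sigma == pytest.approx(s2.mean_i_over_sigma)


class TestRankClusters:
    @staticmethod
    def _stats(completeness, cc_half=0.9, r_meas=0.2):
        return MergeStats(
            d_min=1.0, n_unique=10, n_possible=20, completeness=completeness,
            r_meas=r_meas, mean_i_over_sigma=3.0, cc_half=cc_half, mean_multiplicity=2.0,
        )

    def test_single_cluster(self):
        ranked = rank_clusters({1: self._stats(50.0)})
        assert [lab for lab, _ in ranked] == [1]

    def test_completeness_decides(self):
        ranked = rank_clusters({1: self._stats(91.0), 2: self._stats(96.6)})
        assert [lab for lab, _ in ranked] == [2, 1]

    def test_cc_half_breaks_completeness_ties(self):
        ranked = rank_clusters({1: self._stats(90.0, cc_half=0.8), 2: self._stats(90.0, cc_half=0.95)})
        assert [lab for lab, _ in ranked] == [2, 1]

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            rank_clusters({})
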