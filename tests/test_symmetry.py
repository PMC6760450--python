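import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mced.lattice_cluster import UnitCell
from mced.symmetry import (
    LAUE_SYMBOLS,
    LaueGroup,
    REINDEX_ABC_TO_BCA,
    REINDEX_SWAP_BC,
    ReflectionSet,
    ReindexOperator,
    apply_reindex,
    asu_map,
    centering_mask,
    d_spacing,
    enumerate_unique,
    filter_reflections,
    merge_within,
)

from oracles import brute_force_unique, orbit_canonical

CUBIC10 = UnitCell(10, 10, 10)

hkl_strategy = st.tuples(*(st.integers(-8, 8) for _ in range(3))).filter(lambda t: t != (0, 0, 0))


class TestLaueGroups:
    @pytest.mark.parametrize("symbol", LAUE_SYMBOLS)
    def test_closure_identity_inversion_and_order(self, symbol):
        group = LaueGroup.from_symbol(symbol)
        ops = {tuple(m.flatten()) for m in group.ops}
        eye = tuple(np.eye(3, dtype=int).flatten())
        assert eye in ops
        assert tuple((-np.eye(3, dtype=int)).flatten()) in ops
        for m1, m2 in itertools.product(group.ops, repeat=2):
            assert tuple((m1 @ m2).flatten()) in ops
        expected_order = {"-1": 2, "2/m": 4, "mmm": 8, "4/m": 8, "4/mmm": 16, "-3": 6,
                          "-3m": 12, "6/m": 12, "6/mmm": 24, "m-3": 24, "m-3m": 48}
        assert group.order == expected_order[symbol]

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="Laue"):
            LaueGroup.from_symbol("432")


class TestDSpacing:
    def test_cubic_closed_forms(self):
        assert d_spacing(CUBIC10, (1, 0, 0)) == pytest.approx(10.0)
        assert d_spacing(CUBIC10, (1, 1, 1)) == pytest.approx(10 / math.sqrt(3))

    def test_zero_index_rejected(self):
        with pytest.raises(ValueError):
            d_spacing(CUBIC10, (0, 0, 0))

    def test_matches_gemmi_on_random_triclinic(self, rng):
        import gemmi

        cell = UnitCell(8.3, 11.7, 14.2, 83.0, 95.5, 102.0)
        gcell = gemmi.UnitCell(*cell.parameters)
        hkl = rng.integers(-8, 9, size=(20, 3))
        hkl = hkl[~np.all(hkl == 0, axis=1)]
        ours = d_spacing(cell, hkl)
        for row, d in zip(hkl, ours):
            assert d == pytest.approx(gcell.calculate_d([int(x) for x in row]), abs=1e-9)

    def test_invariant_under_matching_laue_group(self, rng):
        group = LaueGroup.from_symbol("m-3m")
        hkl = rng.integers(-6, 7, size=(30, 3))
        hkl = hkl[~np.all(hkl == 0, axis=1)]
        d0 = d_spacing(CUBIC10, hkl)
        for m in group.ops:
            assert np.allclose(d_spacing(CUBIC10, hkl @ m), d0, atol=1e-9)


class TestAsuMap:
    def test_mmm_sign_flips(self):
        assert tuple(asu_map("mmm", (-1, 2, -3))) == (1, 2, 3)

    @given(hkl=hkl_strategy, symbol=st.sampled_from(LAUE_SYMBOLS))
    def test_idempotent(self, hkl, symbol):
        once = asu_map(symbol, hkl)
        assert tuple(asu_map(symbol, once)) == tuple(once)

    @given(hkl=hkl_strategy, symbol=st.sampled_from(LAUE_SYMBOLS))
    def test_orbit_invariant(self, hkl, symbol):
        group = LaueGroup.from_symbol(symbol)
        canon = tuple(asu_map(group, hkl))
        for m in group.ops:
            assert tuple(asu_map(group, np.asarray(hkl) @ m)) == canon

    def test_matches_brute_force_orbit_max(self, rng):
        group = LaueGroup.from_symbol("m-3m")
        hkl = rng.integers(-10, 11, size=(100, 3))
        hkl = hkl[~np.all(hkl == 0, axis=1)]
        ours = asu_map(group, hkl)
        for row, canon in zip(hkl, ours):
            assert tuple(canon) == orbit_canonical(group.ops, tuple(row))


def _make_set(records, cell=CUBIC10, laue="m-3m", merged=False, ds="d"):
    df = pd.DataFrame(records, columns=["h", "k", "l", "I", "sigma"])
    return ReflectionSet(ds, cell, LaueGroup.from_symbol(laue), "P", df, merged=merged)


class TestMergeWithin:
    def test_mean_and_sigma_formula(self):
        rset = _make_set([(1, 0, 0, 10.0, 1.0), (0, 1, 0, 20.0, 1.0)])
        merged = merge_within(rset)
        assert merged.n_reflections == 1
        rec = merged.df.iloc[0]
        assert rec.I == pytest.approx(15.0)
        assert rec.sigma == pytest.approx(math.sqrt(2) / 2)
        assert rec.n_obs == 2

    def test_idempotent(self):
        rset = _make_set([(1, 0, 0, 10.0, 1.0), (0, 1, 0, 20.0, 1.0), (1, 1, 1, 5.0, 0.5)])
        once = merge_within(rset)
        twice = merge_within(once)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_measurement_count_conserved(self, rng):
        n = 200
        hkl = rng.integers(-4, 5, size=(n, 3))
        hkl = hkl[~np.all(hkl == 0, axis=1)]
        records = [(h, k, l, float(rng.uniform(1, 100)), 1.0) for h, k, l in hkl]
        merged = merge_within(_make_set(records))
        assert merged.df["n_obs"].sum() == len(records)


class TestFilterReflections:
    def test_i_over_sigma_boundary_inclusive(self):
        rset = _make_set([(1, 0, 0, 1.9, 1.0), (0, 1, 0, 2.0, 1.0), (1, 1, 0, 5.0, 1.0)])
        kept = filter_reflections(rset, min_i_over_sigma=2.0)
        assert kept.n_reflections == 2

    def test_no_criteria_is_identity(self):
        rset = _make_set([(1, 0, 0, 1.0, 1.0), (3, 2, 1, 4.0, 2.0)])
        kept = filter_reflections(rset, d_min=0.001, min_i_over_sigma=0.0)
        pd.testing.assert_frame_equal(kept.df, rset.df)

    def test_resolution_cut_matches_enumeration(self):
        records = []
        for h in range(-3, 4):
            for k in range(-3, 4):
                for l in range(-3, 4):
                    if (h, k, l) != (0, 0, 0) and h * h + k * k + l * l <= 9:
                        records.append((h, k, l, 10.0, 1.0))
        kept = filter_reflections(_make_set(records), d_min=5.0)
        got = {tuple(r) for r in kept.hkl_array()}
        expected = {
            (h, k, l)
            for h, k, l, *_ in records
            if h * h + k * k + l * l <= 4  # d = 10/sqrt(h²+k²+l²) >= 5
        }
        assert got == expected

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            filter_reflections(_make_set([(1, 0, 0, 1.0, 1.0)]), d_min=5.0, d_max=2.0)


class TestReindex:
    def test_identity_leaves_set_unchanged(self):
        rset = _make_set([(1, 2, 3, 10.0, 1.0)], cell=UnitCell(10, 11, 12))
        out = apply_reindex(rset, ReindexOperator.from_array(np.eye(3, dtype=int)))
        pd.testing.assert_frame_equal(out.df, rset.df)
        assert out.cell.parameters == pytest.approx(rset.cell.parameters)

    def test_cyclic_axis_permutation_has_order_three(self):
        rset = _make_set([(1, 2, 3, 10.0, 1.0), (2, 0, 1, 5.0, 0.5)], cell=UnitCell(10, 11, 12))
        out = rset
        for _ in range(3):
            out = apply_reindex(out, REINDEX_ABC_TO_BCA)
        np.testing.assert_array_equal(out.hkl_array(), rset.hkl_array())
        assert out.cell.parameters == pytest.approx(rset.cell.parameters)

    def test_swap_permutes_cell_axes(self):
        rset = _make_set([(1, 2, 3, 10.0, 1.0)], cell=UnitCell(10, 11, 12))
        out = apply_reindex(rset, REINDEX_SWAP_BC)
        assert out.cell.parameters == pytest.approx((10, 12, 11, 90, 90, 90))

    def test_non_unimodular_operator_rejected(self):
        with pytest.raises(ValueError, match="det"):
            ReindexOperator.from_array([[2, 0, 0], [0, 1, 0], [0, 0, 1]])


class TestEnumerateUnique:
    def test_cubic_m3m_example(self):
        got = {tuple(r) for r in enumerate_unique(CUBIC10, "m-3m", "P", d_min=5.0)}
        assert got == {(1, 0, 0), (1, 1, 0), (1, 1, 1), (2, 0, 0)}

    def test_nothing_beyond_the_cell_edge(self):
        assert len(enumerate_unique(CUBIC10, "m-3m", "P", d_min=11.0)) == 0

    def test_body_centering_removes_odd_sums(self):
        all_p = enumerate_unique(CUBIC10, "-1", "P", d_min=3.0)
        all_i = enumerate_unique(CUBIC10, "-1", "I", d_min=3.0)
        even = all_p[(all_p.sum(axis=1) % 2) == 0]
        assert {tuple(r) for r in all_i} == {tuple(r) for r in even}

    @pytest.mark.parametrize("symbol", ["2/m", "mmm", "4/mmm", "-3m", "6/m", "m-3m"])
    def test_matches_brute_force_enumeration(self, symbol):
        cell = {
            "2/m": UnitCell(6, 7, 8, 90, 100, 90),
            "mmm": UnitCell(6, 7, 8),
            "4/mmm": UnitCell(6, 6, 9),
            "-3m": UnitCell(6, 6, 9, 90, 90, 120),
            "6/m": UnitCell(6, 6, 9, 90, 90, 120),
            "m-3m": UnitCell(7, 7, 7),
        }[symbol]
        group = LaueGroup.from_symbol(symbol)
        got = {tuple(r) for r in enumerate_unique(cell, group, "P", d_min=2.0)}
        expected = brute_force_unique(
            cell, group.ops, lambda hkl: True, lambda hkl: d_spacing(cell, hkl), 2.0
        )
        assert got == expected

    def test_orbit_size_conservation(self):
        cell = UnitCell(6, 7, 8)
        group = LaueGroup.from_symbol("mmm")
        uniques = enumerate_unique(cell, group, "P", d_min=2.0)
        total = 0
        for u in uniques:
            orbit = {tuple(int(x) for x in u @ m) for m in group.ops}
            total += len(orbit)
        # every allowed reflection in the sphere is in exactly one orbit
        all_p = enumerate_unique(cell, "-1", "P", d_min=2.0)
        n_sphere = sum(
            len({tuple(int(x) for x in u @ m) for m in LaueGroup.from_symbol("-1").ops})
            for u in all_p
        )
        assert total == n_sphere

    def test_grid_cap_advises_larger_dmin(self):
        with pytest.raises(ValueError, match="d_min"):
            enumerate_unique(UnitCell(100, 100, 100), "-1", "P", d_min=0.2, max_grid=1000)


class TestCenteringMask:
    @pytest.mark.parametrize(
        "centering,allowed,forbidden",
        [
            ("P", (1, 1, 1), None),
            ("A", (1, 1, 1), (1, 1, 2)),
            ("B", (1, 1, 1), (1, 2, 2)),
            ("C", (1, 1, 2), (1, 2, 2)),
            ("I", (1, 1, 2), (1, 1, 1)),
            ("F", (1, 1, 1), (1, 1, 2)),
            ("R", (1, 1, 0), (1, 0, 0)),
        ],
    )
    def test_reflection_conditions(self, centering, allowed, forbidden):
        assert centering_mask(np.array([allowed]), centering)[0]
        if forbidden is not None:
            assert not centering_mask(np.array([forbidden]), centering)[0]


class TestReflectionSetInvariants:
    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            _make_set([(1, 0, 0, 1.0, 0.0)])

    def test_zero_index_rejected(self):
        with pytest.raises(ValueError):
            _make_set([(0, 0, 0, 1.0, 1.0)])

    def test_merged_set_must_be_unique(self):
        with pytest.raises(ValueError, match="duplicate"):
            _make_set([(1, 0, 0, 1.0, 1.0), (1, 0, 0, 2.0, 1.0)], merged=True)
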