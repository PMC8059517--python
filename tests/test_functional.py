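"""Trait space construction and convex-hull functional beta-diversity."""

import numpy as np
import pandas as pd
import pytest

from elevbeta import (
    CommunityMatrix,
    TraitSpace,
    TraitTable,
    ValidationError,
    beta_matrix_functional,
    build_trait_space,
    hull_area,
    hull_intersection_area,
)
from elevbeta.functional import DegenerateHullError

from conftest import ccw_hull, monte_carlo_intersection

UNIT_SQUARE = [(0, 0), (1, 0), (1, 1), (0, 1)]
SHIFTED_SQUARE = [(0.5, 0), (1.5, 0), (1.5, 1), (0.5, 1)]
INNER_SQUARE = [(0.25, 0.25), (0.75, 0.25), (0.75, 0.75), (0.25, 0.75)]


class TestTraitSpace:
    def test_two_traits_fill_the_plane(self):
        rng = np.random.default_rng(1)
        tt = TraitTable(
            pd.DataFrame(
                np.exp(rng.normal(1.0, 0.4, size=(10, 2))),
                index=[f"sp{i}" for i in range(10)],
                columns=["max_length", "min_length"],
            )
        )
        ts = build_trait_space(tt)
        assert ts.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_non_increasing(self, rodent_like_traits):
        ts = build_trait_space(rodent_like_traits)
        v = ts.explained_variance_ratio
        assert (np.diff(v) <= 1e-12).all()
        assert ((v >= 0) & (v <= 1)).all()

    def test_sign_convention_largest_loading_positive(self, rodent_like_traits):
        ts = build_trait_space(rodent_like_traits)
        for ax in ts.loadings.columns:
            col = ts.loadings[ax].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_duplicate_species_get_identical_coordinates(self):
        data = pd.DataFrame(
            {"w": [2.0, 2.0, 5.0, 7.0], "l": [3.0, 3.0, 4.0, 9.0]},
            index=["sp1", "sp2", "sp3", "sp4"],
        )
        ts = build_trait_space(TraitTable(data))
        np.testing.assert_allclose(
            ts.coordinates.loc["sp1"], ts.coordinates.loc["sp2"], atol=1e-12
        )

    def test_constant_column_named_in_error(self):
        data = pd.DataFrame(
            {"w": [2.0, 2.0, 2.0, 2.0], "l": [3.0, 4.0, 5.0, 9.0]},
            index=[f"sp{i}" for i in range(4)],
        )
        with pytest.raises(ValidationError, match="'w'"):
            build_trait_space(TraitTable(data))

    def test_uncorrelated_traits_align_with_axes(self):
        # after log + z-score the two columns are exactly uncorrelated
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        data = pd.DataFrame(
            {"w": np.exp(a), "l": np.exp(2.0 * b)}, index=[f"sp{i}" for i in range(4)]
        )
        ts = build_trait_space(TraitTable(data))
        load = np.abs(ts.loadings.to_numpy())
        assert np.allclose(np.sort(load.ravel())[:2], 0, atol=1e-9)


class TestHullGeometry:
    def test_unit_square(self):
        assert hull_area(UNIT_SQUARE) == pytest.approx(1.0, abs=1e-12)

    def test_triangle_shoelace(self):
        assert hull_area([(0, 0), (2, 0), (0, 2)]) == pytest.approx(2.0, abs=1e-12)

    def test_collinear_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert hull_area([(0, 0), (1, 1), (2, 2)]) == 0.0

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(DegenerateHullError):
            hull_area([(0, 0), (1, 1)])

    @pytest.mark.parametrize(
        "pts_b, expected",
        [
            (SHIFTED_SQUARE, 0.5),
            ([(5, 5), (6, 5), (6, 6), (5, 6)], 0.0),
            (INNER_SQUARE, 0.25),
        ],
    )
    def test_intersection_hand_cases(self, pts_b, expected):
        assert hull_intersection_area(UNIT_SQUARE, pts_b) == pytest.approx(
            expected, abs=1e-12
        )

    def test_degenerate_hull_rejected_in_intersection(self):
        with pytest.raises(DegenerateHullError):
            hull_intersection_area(UNIT_SQUARE, [(0, 0), (1, 1), (2, 2)])

    def test_intersection_bounded_by_smaller_hull(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = rng.random((6, 2)) * 2
            B = rng.random((6, 2)) * 2 + rng.normal(0, 0.5, 2)
            inter = hull_intersection_area(A, B)
            assert inter <= min(hull_area(A), hull_area(B)) + 1e-12

    def test_monte_carlo_oracle_small(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            A = rng.random((7, 2)) * 2
            B = rng.random((7, 2)) * 2 + 0.3
            inter = hull_intersection_area(A, B)
            est, se = monte_carlo_intersection(ccw_hull(A), ccw_hull(B), 40_000, rng)
            assert abs(inter - est) <= max(3 * se, 1e-3)


def _space_from_points(mapping: dict) -> TraitSpace:
    coords = pd.DataFrame(
        [(x, y) for pts in mapping.values() for (x, y) in [pts]],
        index=list(mapping),
        columns=["pc1", "pc2"],
    )
    return TraitSpace(
        coordinates=coords,
        loadings=pd.DataFrame(np.eye(2), index=["t1", "t2"], columns=["pc1", "pc2"]),
        explained_variance_ratio=np.array([0.7, 0.3]),
    )


class TestFunctionalBetaMatrix:
    def test_identical_communities_are_zero(self, square_trait_space):
        cm = CommunityMatrix(
            ["s1", "s2"],
            [f"sp{i}" for i in range(12)],
            np.array([[1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
                      [1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0]]),
        )
        t = beta_matrix_functional(cm, square_trait_space)
        row = t.iloc[0]
        assert (row.beta_sim, row.beta_sne, row.beta_sor) == (0.0, 0.0, 0.0)

    def test_shifted_square_pure_turnover(self, square_trait_space):
        # unit square vs +0.5-shifted square: a = b = c = 0.5
        cm = CommunityMatrix(
            ["s1", "s2"],
            [f"sp{i}" for i in range(12)],
            np.array([[1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
                      [0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0]]),
        )
        row = beta_matrix_functional(cm, square_trait_space).iloc[0]
        assert row.a_area == pytest.approx(0.5, abs=1e-12)
        assert row.beta_sor == pytest.approx(0.5, abs=1e-12)
        assert row.beta_sim == pytest.approx(0.5, abs=1e-12)
        assert row.beta_sne == pytest.approx(0.0, abs=1e-12)

    def test_nested_square_pure_nestedness(self, square_trait_space):
        # V1 = 1, V2 = 0.25, a = 0.25 -> sor = sne = 0.6, sim = 0
        cm = CommunityMatrix(
            ["s1", "s2"],
            [f"sp{i}" for i in range(12)],
            np.array([[1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
                      [0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1]]),
        )
        row = beta_matrix_functional(cm, square_trait_space).iloc[0]
        assert row.beta_sim == pytest.approx(0.0, abs=1e-12)
        assert row.beta_sne == pytest.approx(0.6, abs=1e-12)
        assert row.beta_sor == pytest.approx(0.6, abs=1e-12)

    def test_small_communities_excluded(self, square_trait_space):
        cm = CommunityMatrix(
            ["s1", "s2"],
            [f"sp{i}" for i in range(12)],
            np.array([[1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
                      [0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0]]),
        )
        row = beta_matrix_functional(cm, square_trait_space).iloc[0]
        assert row.excluded
        assert row.reason == "below min_richness"
        assert np.isnan(row.beta_sor)

    def test_collinear_hull_excluded_not_jittered(self):
        ts = _space_from_points(
            {"a": (0, 0), "b": (1, 1), "c": (2, 2), "d": (0, 1), "e": (1, 0), "f": (0.2, 0.4)}
        )
        cm = CommunityMatrix(
            ["s1", "s2"], list("abcdef"),
            np.array([[1, 1, 1, 0, 0, 0], [0, 0, 1, 1, 1, 1]]),
        )
        t = beta_matrix_functional(cm, ts)
        assert t.iloc[0].excluded
        assert t.iloc[0].reason == "degenerate hull"

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.random((10, 2)) * 3
        names = [f"sp{i}" for i in range(10)]
        inc = np.array([[1] * 5 + [0] * 5, [0] * 3 + [1] * 7])
        cm = CommunityMatrix(["s1", "s2"], names, inc)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + np.array([10.0, -4.0])
        t1 = beta_matrix_functional(cm, _space_from_points(dict(zip(names, map(tuple, pts)))))
        t2 = beta_matrix_functional(cm, _space_from_points(dict(zip(names, map(tuple, moved)))))
        for col in ("beta_sim", "beta_sne", "beta_sor"):
            np.testing.assert_allclose(t1[col], t2[col], atol=1e-9)

    def test_containment_forces_zero_turnover(self):
        rng = np.random.default_rng(8)
        outer = rng.random((6, 2)) * 4
        inner = outer.mean(axis=0) + (outer[:4] - outer.mean(axis=0)) * 0.3
        names = [f"o{i}" for i in range(6)] + [f"i{i}" for i in range(4)]
        ts = _space_from_points(dict(zip(names, map(tuple, np.vstack([outer, inner])))))
        inc = np.array([[1] * 6 + [0] * 4, [0] * 6 + [1] * 4])
        cm = CommunityMatrix(["s1", "s2"], names, inc)
        row = beta_matrix_functional(cm, ts).iloc[0]
        assert row.beta_sim == pytest.approx(0.0, abs=1e-9)

    def test_additivity_on_computable_pairs(self, square_trait_space):
        rng = np.random.default_rng(2)
        inc = (rng.random((6, 12)) < 0.5).astype(int)
        cm = CommunityMatrix([f"s{i}" for i in range(6)], [f"sp{i}" for i in range(12)], inc)
        t = beta_matrix_functional(cm, square_trait_space)
        ok = ~t["excluded"]
        resid = t.loc[ok, "beta_sor"] - (t.loc[ok, "beta_sim"] + t.loc[ok, "beta_sne"])
        assert np.abs(resid).max() <= 1e-12


class TestDropUnmatchedTraits:
    def test_missing_coordinates_error_then_pruned(self, square_trait_space):
        names = [f"sp{i}" for i in range(12)] + ["ghost"]
        inc = np.zeros((2, 13), dtype=int)
        inc[0, [0, 1, 2, 3, 12]] = 1
        inc[1, [4, 5, 6, 7]] = 1
        cm = CommunityMatrix(["s1", "s2"], names, inc)
        with pytest.raises(ValidationError, match="ghost"):
            beta_matrix_functional(cm, square_trait_space)
        with pytest.warns(UserWarning, match="ghost"):
            t = beta_matrix_functional(cm, square_trait_space, drop_unmatched=True)
        # without the ghost species the pair is the shifted-square case
        assert t.iloc[0].beta_sor == pytest.approx(0.5, abs=1e-12)
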