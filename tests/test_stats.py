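"""Wilcoxon engine, distance-decay fits, slope comparison, forward AIC,
and station-based climate interpolation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from elevbeta import (
    SiteTable,
    StationRecords,
    ValidationError,
    compare_slopes,
    distance_decay,
    forward_aic,
    interpolate_station_climate,
    wilcoxon_z,
)
from elevbeta.stats import RegressionFit, significance_label

from conftest import exact_ranksum_p


class TestWilcoxon:
    def test_separated_samples_hand_value(self):
        # x = {1,2,3}, y = {4,5,6}: W = 6, mu = 10.5, sigma = sqrt(5.25)
        res = wilcoxon_z([1, 2, 3], [4, 5, 6])
        assert res.abs_z == pytest.approx(4.5 / np.sqrt(5.25), abs=1e-9)
        assert res.abs_z == pytest.approx(1.9640, abs=5e-4)
        assert not res.tie_correction_applied

    def test_identical_multisets_give_zero(self):
        res = wilcoxon_z([1, 2, 3], [1, 2, 3])
        assert res.z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetric_under_sample_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(1.0, 1.0, size=5)
        a = wilcoxon_z(x, y)
        b = wilcoxon_z(y, x)
        assert a.z == pytest.approx(-b.z, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(7) + 0.1, rng.random(9) + 0.1
        a = wilcoxon_z(x, y)
        b = wilcoxon_z(np.log(x), np.log(y))
        assert a.z == pytest.approx(b.z, abs=1e-12)

    def test_tie_corrected_sigma_matches_scipy(self):
        x = [1, 2, 2, 3, 5, 5, 5]
        y = [2, 3, 3, 4, 5, 6]
        res = wilcoxon_z(x, y)
        assert res.tie_correction_applied
        # scipy's asymptotic Mann-Whitney U without continuity correction
        # uses the same tie-corrected normal approximation
        sp = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert res.p == pytest.approx(sp.pvalue, abs=1e-10)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            res = wilcoxon_z(x, y, method="exact")
            assert res.p == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_normal_tracks_exact_in_decision_tail(self):
        """The normal approximation agrees with exhaustive enumeration to
        within 0.02 wherever decisions are made: whenever the exact
        two-sided p is <= 0.05 (any split with n1+n2 <= 12), and throughout
        the p <= 0.1 band once both samples have at least 4 values. (In the
        non-significant mid-range the discrete rank-sum distribution puts
        visibly more mass on large |W - mu| than the normal curve, so no
        global 0.02 agreement exists at these sizes.)"""
        from itertools import combinations

        worst_sig = 0.0
        worst_band = 0.0
        for n1 in range(2, 11):
            for n2 in range(2, 13 - n1):
                n = n1 + n2
                base = np.arange(1.0, n + 1.0)
                for comb in combinations(range(n), n1):
                    x = base[list(comb)]
                    y = np.delete(base, list(comb))
                    p_norm = wilcoxon_z(x, y).p
                    p_ex = exact_ranksum_p(x, y)
                    if p_ex <= 0.05:
                        worst_sig = max(worst_sig, abs(p_norm - p_ex))
                    if p_ex <= 0.1 and min(n1, n2) >= 4:
                        worst_band = max(worst_band, abs(p_norm - p_ex))
        assert worst_sig <= 0.02
        assert worst_band <= 0.02

    def test_degenerate_all_tied_rejected(self):
        with pytest.raises(ValidationError, match="tied"):
            wilcoxon_z([2, 2, 2], [2, 2, 2])


class TestDistanceDecay:
    def _beta(self, d, values):
        n = len(values)
        return pd.DataFrame(
            {
                "site_i": [f"s{i}" for i in range(n)],
                "site_j": [f"t{i}" for i in range(n)],
                "beta_sor": values,
                "excluded": [False] * n,
            }
        ), SiteTable(
            pd.DataFrame(
                {"elevation": np.concatenate([np.zeros(n), d])},
                index=[f"s{i}" for i in range(n)] + [f"t{i}" for i in range(n)],
            )
        )

    def test_exact_linear_input_recovered(self):
        d = np.array([100.0, 400.0, 900.0, 1600.0, 2100.0])
        beta, sites = self._beta(d, 2e-4 * d)
        fit = distance_decay(beta, sites, "beta_sor")
        assert fit.slope == pytest.approx(2e-4, rel=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_gives_zero_slope(self):
        d = np.array([100.0, 400.0, 900.0, 1600.0])
        beta, sites = self._beta(d, np.full(4, 0.3))
        fit = distance_decay(beta, sites, "beta_sor")
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            d = rng.random(12) * 2500
            y = 0.2 + 1e-4 * d + rng.normal(0, 0.05, 12)
            beta, sites = self._beta(d, y)
            fit = distance_decay(beta, sites, "beta_sor")
            slope = ((d - d.mean()) * (y - y.mean())).sum() / ((d - d.mean()) ** 2).sum()
            intercept = y.mean() - slope * d.mean()
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_invariant_to_elevation_offset(self):
        rng = np.random.default_rng(9)
        d = rng.random(8) * 2000
        y = 1e-4 * d + rng.normal(0, 0.01, 8)
        beta, sites = self._beta(d, y)
        shifted = SiteTable(sites.data.assign(elevation=sites.data["elevation"] + 500.0))
        f1 = distance_decay(beta, sites, "beta_sor")
        f2 = distance_decay(beta, shifted, "beta_sor")
        assert f1.slope == pytest.approx(f2.slope, abs=1e-12)

    def test_zero_distance_variance_rejected(self):
        beta, sites = self._beta(np.full(4, 500.0), np.random.rand(4))
        with pytest.raises(ValidationError, match="variance"):
            distance_decay(beta, sites, "beta_sor")


class TestCompareSlopes:
    def test_cross_group_ranking(self):
        fits = {
            "passerines": RegressionFit(2.05e-4, 0, 1e-5, 0.5, 136),
            "rodents": RegressionFit(4.66e-4, 0, 1e-4, 0.6, 36),
            "ants": RegressionFit(2.00e-4, 0, 1e-3, 0.4, 55),
        }
        r = compare_slopes(fits)
        assert [n for n, _ in r.ranked] == ["rodents", "passerines", "ants"]

    def test_non_significant_fit_not_ranked(self):
        fits = {
            "a": RegressionFit(5e-4, 0, 0.2, 0.1, 30),
            "b": RegressionFit(1e-4, 0, 0.01, 0.4, 30),
        }
        r = compare_slopes(fits)
        assert [n for n, _ in r.ranked] == ["b"]
        assert r.not_compared == ["a"]

    def test_ties_keep_input_order(self):
        fits = {
            "first": RegressionFit(2e-4, 0, 0.01, 0.4, 30),
            "second": RegressionFit(2e-4, 0, 0.01, 0.4, 30),
        }
        r = compare_slopes(fits)
        assert [n for n, _ in r.ranked] == ["first", "second"]


class TestForwardAIC:
    def _predictors(self, rng, n=60):
        return pd.DataFrame(
            {f"d_{v}": rng.random(n) * 10 for v in ("AMT", "AP", "AMH", "NPP", "PET")}
        )

    def test_planted_signal_is_selected(self):
        rng = np.random.default_rng(0)
        X = self._predictors(rng)
        y = 3.0 * X["d_AMT"] + rng.normal(0, 0.1, len(X))
        sel = forward_aic(y, X)
        assert sel.predictors[0] == "d_AMT"
        assert "d_AMT" in sel.coefficients
        assert sel.coefficients["d_AMT"] == pytest.approx(3.0, abs=0.05)

    def test_pure_noise_mostly_selects_nothing(self):
        """One spurious candidate survives AIC's +2 penalty only ~16% of
        the time, so intercept-only is the clear majority outcome."""
        empty = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"d_AMT": rng.random(40) * 10})
            y = rng.normal(size=40)
            if not forward_aic(y, X).predictors:
                empty += 1
        assert empty >= int(0.6 * reps)

    def test_aic_trajectory_strictly_decreases(self):
        rng = np.random.default_rng(5)
        X = self._predictors(rng)
        y = 2.0 * X["d_NPP"] - 1.0 * X["d_AP"] + rng.normal(0, 0.2, len(X))
        sel = forward_aic(y, X)
        assert (np.diff(sel.aic_trajectory) < 0).all()

    def test_single_useless_candidate_gives_empty_selection(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"d_AMT": rng.random(30)})
        y = rng.normal(size=30)
        sel = forward_aic(y, X)
        assert sel.predictors == []
        assert len(sel.aic_trajectory) == 1

    def test_collinear_candidate_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        a = rng.random(30)
        X = pd.DataFrame({"d_AMT": a, "d_PET": 2.0 * a + 1.0})
        y = a * 1.5 + rng.normal(0, 0.1, 30)
        with pytest.warns(UserWarning, match="collinear"):
            sel = forward_aic(y, X)
        assert sel.dropped_collinear == ["d_PET"]
        assert sel.predictors == ["d_AMT"]


class TestClimateInterpolation:
    @pytest.fixture
    def stations(self):
        return StationRecords(
            pd.DataFrame(
                {
                    "elevation": [2000.0, 3000.0, 4200.0],
                    "AMT": [10.0, 4.0, -2.0],
                    "AP": [600.0, 800.0, 900.0],
                    "AMH": [40.0, 55.0, 60.0],
                },
                index=["valley", "forest", "summit"],
            )
        )

    def test_midpoint_interpolation(self, stations):
        est = interpolate_station_climate(stations, 2500.0)
        assert est.AMT == pytest.approx(7.0)
        assert est.AP == pytest.approx(700.0)
        assert not est.extrapolated

    def test_site_at_station_elevation(self, stations):
        est = interpolate_station_climate(stations, 3000.0)
        assert est.AMT == pytest.approx(4.0)
        assert est.AMH == pytest.approx(55.0)

    def test_extrapolation_flagged(self):
        two = StationRecords(
            pd.DataFrame(
                {"elevation": [2000.0, 3000.0], "AMT": [10.0, 4.0],
                 "AP": [1.0, 2.0], "AMH": [3.0, 4.0]},
                index=["lo", "hi"],
            )
        )
        est = interpolate_station_climate(two, 3500.0)
        assert est.AMT == pytest.approx(1.0)
        assert est.extrapolated


class TestSignificanceLabels:
    @pytest.mark.parametrize(
        "p, label",
        [
            (0.01, "significant"),
            (0.05, "significant"),
            (0.059, "nearly significant"),
            (0.1, "nearly significant"),
            (0.2, "not significant"),
        ],
    )
    def test_bands(self, p, label):
        assert significance_label(p) == label


class TestMantelAndPredictorForms:
    def test_mantel_permutation_p_reported_and_deterministic(self):
        rng = np.random.default_rng(2)
        n_sites = 8
        elev = np.linspace(2000, 4500, n_sites)
        sites = SiteTable(
            pd.DataFrame({"elevation": elev}, index=[f"s{i}" for i in range(n_sites)])
        )
        ii, jj = np.triu_indices(n_sites, k=1)
        d = np.abs(elev[ii] - elev[jj])
        beta = pd.DataFrame(
            {
                "site_i": [f"s{i}" for i in ii],
                "site_j": [f"s{j}" for j in jj],
                "beta_sor": 2e-4 * d + rng.normal(0, 0.02, len(d)),
                "excluded": False,
            }
        )
        from elevbeta import distance_decay

        fit = distance_decay(beta, sites, "beta_sor", mantel_permutations=499)
        again = distance_decay(beta, sites, "beta_sor", mantel_permutations=499)
        assert fit.p_mantel is not None
        assert fit.p_mantel == again.p_mantel
        assert fit.p_mantel < 0.05  # strong planted signal survives permutation
        plain = distance_decay(beta, sites, "beta_sor")
        assert plain.p_mantel is None

    def test_midpoint_predictor_form(self):
        from elevbeta.stats import pairwise_distance_table

        sites = SiteTable(
            pd.DataFrame(
                {"elevation": [2000.0, 3000.0, 4000.0], "AMT": [10.0, 4.0, -2.0]},
                index=["a", "b", "c"],
            )
        )
        diff = pairwise_distance_table(sites, ["a", "b", "c"], ("AMT",))
        assert list(diff["d_AMT"]) == [6.0, 12.0, 6.0]
        mid = pairwise_distance_table(sites, ["a", "b", "c"], ("AMT",), form="midpoint")
        assert list(mid["m_AMT"]) == [7.0, 4.0, 1.0]
        with pytest.raises(ValidationError, match="form"):
            pairwise_distance_table(sites, ["a"], ("AMT",), form="ratio")
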