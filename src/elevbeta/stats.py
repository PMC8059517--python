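"""Comparative statistics along the elevational gradient.

Three levels of comparison drive the analysis: turnover vs nestedness
within a dimension (Wilcoxon rank-sum), the same index across dimensions
(Wilcoxon), and the rate of increase of dissimilarity with elevational
distance across species groups (slopes of significant linear fits).
Environmental dependence is assessed by forward AIC selection over
pairwise environmental distances, and site climate is interpolated from
the two elevation-nearest weather stations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from .datatypes import SiteTable, StationRecords, ValidationError
from .taxonomic import pair_index

__all__ = [
    "WilcoxonResult",
    "wilcoxon_z",
    "RegressionFit",
    "distance_decay",
    "SlopeRanking",
    "compare_slopes",
    "SelectedModel",
    "forward_aic",
    "ClimateEstimate",
    "interpolate_station_climate",
    "pairwise_distance_table",
    "significance_label",
]

ALPHA = 0.05
NEARLY_SIGNIFICANT = 0.1  # the 0.05 < p <= 0.1 band reported alongside


def significance_label(p: float, alpha: float = ALPHA) -> str:
    if p <= alpha:
        return "significant"
    if p <= NEARLY_SIGNIFICANT:
        return "nearly significant"
    return "not significant"


@dataclass(frozen=True)
class WilcoxonResult:
    z: float
    abs_z: float
    p: float
    n1: int
    n2: int
    tie_correction_applied: bool
    method: str = "normal"


def _exact_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exhaustive-enumeration p: P(|W − μ| ≥ |w_obs − μ|) over
    every way of assigning n1 of the pooled (tie-averaged) ranks to the
    first sample."""
    n = len(ranks)
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-9
    hits = 0
    total = 0
    for comb in combinations(range(n), n1):
        w = ranks[list(comb)].sum()
        hits += abs(w - mu) >= dev
        total += 1
    return hits / total


def wilcoxon_z(x, y, alternative: str = "two-sided", *, method: str = "normal") -> WilcoxonResult:
    """Two-sample Wilcoxon rank-sum test via the normal approximation.

    W is the rank sum of the first sample with average ranks for ties;
    z = (W − μ_W)/σ_W with the tie-corrected σ_W and no continuity
    correction. ``method='exact'`` enumerates all rank assignments
    (feasible cross-check for n1 + n2 ≤ ~14).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each sample needs at least 2 values")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValidationError("all values tied across both samples")
    ranks = rankdata(pooled)
    n = n1 + n2
    W = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    has_ties = bool((counts > 1).any())
    if sigma2 <= 0:
        raise ValidationError("zero variance after tie correction")
    z = (W - mu) / np.sqrt(sigma2)
    if method == "exact":
        if n > 14:
            raise ValidationError("exact enumeration is limited to n1+n2 <= 14")
        p2 = _exact_p(ranks, n1, W)
        if alternative == "two-sided":
            p = p2
        else:
            sign = 1.0 if alternative == "greater" else -1.0
            mu_dev = W - mu
            # one-sided exact tail in the requested direction
            hits = 0
            total = 0
            for comb in combinations(range(n), n1):
                w = ranks[list(comb)].sum()
                hits += sign * (w - mu) >= sign * mu_dev - 1e-9
                total += 1
            p = hits / total
    else:
        if alternative == "two-sided":
            p = 2.0 * norm.sf(abs(z))
        elif alternative == "greater":
            p = float(norm.sf(z))
        else:
            p = float(norm.cdf(z))
        p = min(float(p), 1.0)
    return WilcoxonResult(float(z), float(abs(z)), float(p), n1, n2, has_ties, method)


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    p_slope: float
    r2: float
    n_pairs: int
    p_mantel: float | None = None  # permutation p; only set when requested


def pairwise_distance_table(
    sites: SiteTable, site_order, variables=("elevation",), form: str = "difference"
) -> pd.DataFrame:
    """Per-pair environmental predictors in canonical pair order.

    ``form="difference"`` (default) takes the absolute difference of each
    site-level variable; ``form="midpoint"`` takes the pair mean instead
    (predictors then describe where along the gradient a pair sits rather
    than how far apart it is).
    """
    if form not in ("difference", "midpoint"):
        raise ValidationError("form must be 'difference' or 'midpoint'")
    site_order = [str(s).strip() for s in site_order]
    missing = set(site_order) - set(sites.data.index)
    if missing:
        raise ValidationError(f"site table is missing sites: {sorted(missing)}")
    ii, jj = pair_index(len(site_order))
    out = {"site_i": np.asarray(site_order, dtype=object)[ii],
           "site_j": np.asarray(site_order, dtype=object)[jj]}
    prefix = "d_" if form == "difference" else "m_"
    for var in variables:
        v = sites.data.loc[site_order, var].to_numpy(dtype=float)
        if form == "difference":
            out[f"{prefix}{var}"] = np.abs(v[ii] - v[jj])
        else:
            out[f"{prefix}{var}"] = (v[ii] + v[jj]) / 2.0
    return pd.DataFrame(out)


def distance_decay(
    beta: pd.DataFrame,
    sites: SiteTable,
    index: str = "beta_sor",
    *,
    mantel_permutations: int | None = None,
    mantel_seed: int = 0,
) -> RegressionFit:
    """OLS of one beta index on pairwise elevational distance (metres).

    The slope's t-test p treats pairs as independent, which pairwise
    distances are not; ``mantel_permutations`` additionally reports a
    Mantel-style permutation p (site elevations permuted, slope
    recomputed), left off by default.
    """
    if index not in beta.columns:
        raise ValidationError(f"no column {index!r} in the beta table")
    elev = sites.data["elevation"]
    missing = (set(beta["site_i"]) | set(beta["site_j"])) - set(elev.index)
    if missing:
        raise ValidationError(f"site table is missing sites: {sorted(missing)}")
    d = np.abs(
        elev.loc[beta["site_i"]].to_numpy() - elev.loc[beta["site_j"]].to_numpy()
    )
    y = beta[index].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    if "excluded" in beta.columns:
        keep &= ~beta["excluded"].to_numpy(dtype=bool)
    d, y = d[keep], y[keep]
    if len(y) < 3:
        raise ValidationError("need at least 3 computable pairs")
    if np.ptp(d) == 0:
        raise ValidationError("zero variance in elevational distances")
    X = sm.add_constant(d)
    fit = sm.OLS(y, X).fit()
    p_mantel = None
    if mantel_permutations:
        # permute site identities (elevations), rebuild pair distances
        keep_pairs = beta.loc[keep, ["site_i", "site_j"]]
        site_ids = sorted(set(keep_pairs["site_i"]) | set(keep_pairs["site_j"]))
        elev_map = elev.loc[site_ids].to_numpy()
        pos = {s: k for k, s in enumerate(site_ids)}
        pi = keep_pairs["site_i"].map(pos).to_numpy()
        pj = keep_pairs["site_j"].map(pos).to_numpy()
        obs_slope = abs(float(fit.params[1]))
        rng = np.random.default_rng(mantel_seed)
        hits = 1
        for _ in range(mantel_permutations):
            perm = rng.permutation(elev_map)
            dp = np.abs(perm[pi] - perm[pj])
            dc = dp - dp.mean()
            denom = (dc**2).sum()
            slope_p = (dc * (y - y.mean())).sum() / denom if denom > 0 else 0.0
            hits += abs(slope_p) >= obs_slope - 1e-15
        p_mantel = hits / (mantel_permutations + 1)
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_slope=float(fit.pvalues[1]),
        r2=float(fit.rsquared),
        n_pairs=int(len(y)),
        p_mantel=p_mantel,
    )


@dataclass(frozen=True)
class SlopeRanking:
    ranked: list  # (name, slope) pairs, steepest first, input order on ties
    not_compared: list  # names whose slope was not significant
    alpha: float


def compare_slopes(fits: dict[str, RegressionFit], alpha: float = ALPHA) -> SlopeRanking:
    """Rank groups by the slope of their *significant* distance-decay fits.

    Groups whose slope p-value exceeds alpha are listed separately and not
    ranked. Ties keep the input order (stable sort).
    """
    if len(fits) < 2:
        raise ValidationError("need at least 2 fits to compare")
    sig = [(name, f.slope) for name, f in fits.items() if f.p_slope <= alpha]
    ranked = sorted(sig, key=lambda t: -t[1])
    not_compared = [name for name, f in fits.items() if f.p_slope > alpha]
    return SlopeRanking(ranked, not_compared, alpha)


@dataclass
class SelectedModel:
    predictors: list[str]
    aic_trajectory: list[float]  # starts at the intercept-only AIC
    coefficients: dict[str, float] = field(default_factory=dict)
    dropped_collinear: list[str] = field(default_factory=list)

    @property
    def final_aic(self) -> float:
        return self.aic_trajectory[-1]


def _aic(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    n = len(y)
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta_hat) ** 2).sum())
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * X.shape[1], beta_hat


def forward_aic(response, predictors: pd.DataFrame) -> SelectedModel:
    """Greedy forward selection minimizing AIC = n·ln(RSS/n) + 2k.

    Starts from the intercept-only model, at each step adds the candidate
    lowering AIC the most (ties broken by column order), and stops when no
    addition lowers AIC. Perfectly collinear (|r| = 1) candidates are
    dropped, keeping the earlier column, with a warning.
    """
    y = np.asarray(response, dtype=float)
    cols = list(predictors.columns)
    if not cols:
        raise ValidationError("need at least one candidate predictor")
    P = predictors.to_numpy(dtype=float)
    keep = ~np.isnan(y) & ~np.isnan(P).any(axis=1)
    y, P = y[keep], P[keep]
    n = len(y)
    if n < 3:
        raise ValidationError("need at least 3 complete observations")
    dropped = []
    active: list[int] = []
    for j in range(len(cols)):
        collinear = False
        for i in active:
            vi, vj = P[:, i], P[:, j]
            if np.std(vi) == 0 or np.std(vj) == 0:
                continue
            r = np.corrcoef(vi, vj)[0, 1]
            if abs(abs(r) - 1.0) < 1e-12:
                collinear = True
                warnings.warn(
                    f"dropping predictor {cols[j]!r}: perfectly collinear with {cols[i]!r}",
                    stacklevel=2,
                )
                break
        if collinear:
            dropped.append(cols[j])
        else:
            active.append(j)

    selected: list[int] = []
    X = np.ones((n, 1))
    current_aic, beta_hat = _aic(y, X)
    trajectory = [current_aic]
    remaining = list(active)
    while remaining:
        best = None
        for j in remaining:  # column order breaks ties (strict improvement)
            cand_X = np.column_stack([X, P[:, j]])
            aic, bh = _aic(y, cand_X)
            if aic < current_aic - 1e-12 and (best is None or aic < best[0] - 1e-12):
                best = (aic, j, cand_X, bh)
        if best is None:
            break
        current_aic, j, X, beta_hat = best
        selected.append(j)
        remaining.remove(j)
        trajectory.append(current_aic)
    names = [cols[j] for j in selected]
    coeffs = {"intercept": float(beta_hat[0])}
    for k, name in enumerate(names):
        coeffs[name] = float(beta_hat[k + 1])
    return SelectedModel(names, trajectory, coeffs, dropped)


@dataclass(frozen=True)
class ClimateEstimate:
    AMT: float
    AP: float
    AMH: float
    stations_used: tuple[str, str]
    extrapolated: bool


def interpolate_station_climate(stations: StationRecords, site_elevation: float) -> ClimateEstimate:
    """Linear climate estimate from the two elevation-nearest stations.

    Sites outside the two stations' elevation bracket are linearly
    extrapolated and flagged.
    """
    df = stations.data
    elev = df["elevation"].to_numpy(dtype=float)
    order = np.argsort(np.abs(elev - float(site_elevation)), kind="stable")
    i1, i2 = order[0], order[1]
    e1, e2 = elev[i1], elev[i2]
    if e1 == e2:
        raise ValidationError("two nearest stations share the same elevation")
    t = (float(site_elevation) - e1) / (e2 - e1)
    values = {}
    for var in ("AMT", "AP", "AMH"):
        if var not in df.columns:
            raise ValidationError(f"station records lack column {var!r}")
        v1, v2 = float(df[var].iloc[i1]), float(df[var].iloc[i2])
        values[var] = v1 + t * (v2 - v1)
    lo, hi = min(e1, e2), max(e1, e2)
    extrapolated = not (lo <= float(site_elevation) <= hi)
    return ClimateEstimate(
        values["AMT"], values["AP"], values["AMH"],
        (str(df.index[i1]), str(df.index[i2])), extrapolated,
    )
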