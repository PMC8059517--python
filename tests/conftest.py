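"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive every quantity from first
principles (set algebra, exhaustive enumeration, Monte-Carlo sampling)
without touching the library code paths they are used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from elevbeta import CommunityMatrix, SiteTable, TraitTable
from elevbeta.io import parse_newick

# ---------------------------------------------------------------- oracles


def oracle_triplet(s1: set, s2: set) -> tuple[float, float, float]:
    """Brute-force (sim, sne, sor) straight from the defining formulas."""
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    sor = (b + c) / (2 * a + b + c)
    sim = min(b, c) / (a + min(b, c))
    return sim, sor - sim, sor


def oracle_branch_components(tree, s1: set, s2: set):
    """Per-branch classification via dendropy's own leaf enumeration.

    Walks every non-root edge and asks dendropy which leaves descend from
    it — an API-level route independent of the package's postorder bitset
    accumulation.
    """
    dtree = tree.dendropy_tree
    a = b = c = 0.0
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        tips = {leaf.taxon.label.strip() for leaf in node.leaf_iter()}
        in1 = bool(tips & s1)
        in2 = bool(tips & s2)
        length = node.edge.length or 0.0
        if in1 and in2:
            a += length
        elif in1:
            b += length
        elif in2:
            c += length
    return a, b, c


def point_in_convex_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Vectorized half-plane test against a CCW convex polygon."""
    inside = np.ones(len(points), dtype=bool)
    n = len(polygon)
    for i in range(n):
        p0 = polygon[i]
        p1 = polygon[(i + 1) % n]
        edge = p1 - p0
        rel = points - p0
        inside &= edge[0] * rel[:, 1] - edge[1] * rel[:, 0] >= -1e-12
    return inside


def ccw_hull(points: np.ndarray) -> np.ndarray:
    """Andrew monotone-chain convex hull (oracle-side, CCW order)."""
    pts = sorted(map(tuple, points))
    if len(pts) <= 2:
        return np.asarray(pts)

    def half(seq):
        out = []
        for p in seq:
            while len(out) >= 2 and (
                (out[-1][0] - out[-2][0]) * (p[1] - out[-2][1])
                - (out[-1][1] - out[-2][1]) * (p[0] - out[-2][0])
            ) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = half(pts)
    upper = half(reversed(pts))
    return np.asarray(lower[:-1] + upper[:-1])


def monte_carlo_intersection(poly_a: np.ndarray, poly_b: np.ndarray,
                             n: int, rng: np.random.Generator):
    """MC estimate (and standard error) of the area inside both polygons.

    Samples the overlap of the two bounding boxes — the only region where
    the intersection can live — which keeps the binomial variance low; if
    the boxes are disjoint the intersection is exactly zero.
    """
    lo = np.maximum(poly_a.min(axis=0), poly_b.min(axis=0))
    hi = np.minimum(poly_a.max(axis=0), poly_b.max(axis=0))
    if (hi <= lo).any():
        return 0.0, 0.0
    box = np.prod(hi - lo)
    sample = lo + rng.random((n, 2)) * (hi - lo)
    hits = point_in_convex_polygon(sample, poly_a) & point_in_convex_polygon(sample, poly_b)
    p = hits.mean()
    return box * p, box * math.sqrt(max(p * (1 - p), 1e-12) / n)


def exact_ranksum_p(x, y) -> float:
    """Exhaustive two-sided rank-sum p: P(|W − μ| ≥ |w_obs − μ|)."""
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="stable")
    ranks = np.empty(len(pooled))
    # average ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n1 = len(x)
    n = len(pooled)
    mu = n1 * (n + 1) / 2.0
    w_obs = ranks[:n1].sum()
    dev = abs(w_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        w = ranks[list(comb)].sum()
        hits += abs(w - mu) >= dev - 1e-9
        total += 1
    return hits / total


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def small_cm() -> CommunityMatrix:
    return CommunityMatrix(
        ["low", "mid", "high"],
        ["A", "B", "C", "D", "E"],
        np.array([[1, 1, 1, 0, 0], [0, 1, 1, 1, 1], [1, 1, 1, 0, 0]]),
    )


@pytest.fixture
def nested_cm() -> CommunityMatrix:
    """Ordered subsets: low ⊃ mid ⊃ high."""
    return CommunityMatrix(
        ["low", "mid", "high"],
        ["A", "B", "C", "D"],
        np.array([[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0]]),
    )


@pytest.fixture
def star_tree():
    return parse_newick("(A:1,B:1,C:1,D:1,E:1);", allow_basal_polytomy=True)


@pytest.fixture
def balanced_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def simple_sites() -> SiteTable:
    return SiteTable(
        pd.DataFrame(
            {"elevation": [2000.0, 3000.0, 4000.0]},
            index=["low", "mid", "high"],
        )
    )


@pytest.fixture
def square_trait_space():
    """Hand-built 2-D trait space: unit square, shifted square, inner square."""
    from elevbeta import TraitSpace

    coords = pd.DataFrame(
        {
            "pc1": [0, 1, 1, 0, 0.5, 1.5, 1.5, 0.5, 0.25, 0.75, 0.75, 0.25],
            "pc2": [0, 0, 1, 1, 0.0, 0.0, 1.0, 1.0, 0.25, 0.25, 0.75, 0.75],
        },
        index=[f"sp{i}" for i in range(12)],
    )
    return TraitSpace(
        coordinates=coords,
        loadings=pd.DataFrame(np.eye(2), index=["t1", "t2"], columns=["pc1", "pc2"]),
        explained_variance_ratio=np.array([0.6, 0.4]),
    )


@pytest.fixture
def rodent_like_traits() -> TraitTable:
    rng = np.random.default_rng(7)
    data = np.exp(rng.normal(3.0, 0.5, size=(8, 5)))
    return TraitTable(
        pd.DataFrame(
            data,
            index=[f"sp{i}" for i in range(8)],
            columns=["weight", "head_body", "tail", "ear", "hind_foot"],
        )
    )
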