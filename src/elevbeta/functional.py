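"""Functional (trait-based) beta-diversity in a 2-D morphological space.

Traits are natural-log transformed, z-scored, and projected onto the first
two principal components (so the PCA is correlation-based). Each
assemblage occupies the convex hull of its species' scores; the matching
components a, b, c are the hull-intersection area and the two unique
areas, decomposed exactly like species counts. Hulls need at least three
non-collinear species, so assemblages below that are flagged and excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

from .datatypes import CommunityMatrix, TraitTable, ValidationError
from .decompose import decompose_arrays
from .taxonomic import pair_index

__all__ = [
    "TraitSpace",
    "DegenerateHullError",
    "build_trait_space",
    "hull_area",
    "hull_intersection_area",
    "beta_matrix_functional",
]

#: numerical tolerance below zero allowed for the unique-area components
#: (floating-point seepage from polygon clipping) before an error is raised
CLAMP_TOL = 1e-9


class DegenerateHullError(ValueError):
    """Fewer than 3 points, or all points collinear: no 2-D hull."""


@dataclass
class TraitSpace:
    """Species scores on the first PCA axes of the transformed trait table."""

    coordinates: pd.DataFrame  # species × (pc1, pc2, ...)
    loadings: pd.DataFrame  # traits × axes
    explained_variance_ratio: np.ndarray

    @property
    def species(self) -> list[str]:
        return list(self.coordinates.index)

    def points(self, species) -> np.ndarray:
        return self.coordinates.loc[list(species)].to_numpy(dtype=float)


def build_trait_space(traits: TraitTable, n_axes: int = 2) -> TraitSpace:
    """PCA trait space from log-transformed, z-scored measurements.

    Uses the SVD of the centred transformed matrix; each axis's sign is
    fixed so its largest-magnitude loading is positive. A constant trait
    column has no information after scaling and is refused by name.
    """
    df = traits.data
    if df.shape[1] < n_axes:
        raise ValidationError(
            f"need at least {n_axes} trait columns for {n_axes} axes"
        )
    X = np.log(df.to_numpy(dtype=float))
    sd = X.std(axis=0, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValidationError(
            f"constant trait column(s) after log transform: "
            f"{[df.columns[i] for i in zero]}"
        )
    Z = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive on every axis
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S
    axes = [f"pc{k + 1}" for k in range(n_axes)]
    var_ratio = (S**2) / (S**2).sum()
    return TraitSpace(
        coordinates=pd.DataFrame(scores[:, :n_axes], index=df.index, columns=axes),
        loadings=pd.DataFrame(Vt[:n_axes].T, index=df.columns, columns=axes),
        explained_variance_ratio=var_ratio[:n_axes],
    )


def _hull(points: np.ndarray) -> Polygon | None:
    """Convex hull polygon of 2-D points, or None when degenerate."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise DegenerateHullError("need at least 3 points for a hull")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0.0:
        return None
    return hull


def hull_area(points) -> float:
    """Convex-hull area of ≥3 points; collinear sets give 0 with a warning."""
    hull = _hull(np.asarray(points, dtype=float))
    if hull is None:
        warnings.warn("degenerate (collinear) hull: area 0", stacklevel=2)
        return 0.0
    return float(hull.area)


def hull_intersection_area(pts_a, pts_b) -> float:
    """Area shared by the convex hulls of two point sets.

    Both hulls must be non-degenerate; disjoint hulls give 0.
    """
    ha = _hull(np.asarray(pts_a, dtype=float))
    hb = _hull(np.asarray(pts_b, dtype=float))
    if ha is None or hb is None:
        raise DegenerateHullError("degenerate hull has no intersection area")
    return float(ha.intersection(hb).area)


def _clamp(x: float) -> float:
    if x < -CLAMP_TOL:
        raise ValueError(f"unique hull area fell below tolerance: {x}")
    return max(x, 0.0)


def beta_matrix_functional(
    cm: CommunityMatrix, ts: TraitSpace, min_richness: int = 3,
    *, drop_unmatched: bool = False,
) -> pd.DataFrame:
    """Pairwise functional beta table over trait-hull areas.

    Pairs where either assemblage holds fewer than ``min_richness`` species,
    or has a zero-area (collinear) hull, are flagged excluded. Species
    without trait coordinates are a hard error unless ``drop_unmatched``
    prunes them (with a warning listing every dropped name).
    """
    missing = set(sp for sp in cm.occurring_species()) - set(ts.species)
    dropped: set[str] = set()
    if missing:
        if not drop_unmatched:
            raise ValidationError(
                f"no trait coordinates for species: {sorted(missing)}"
            )
        warnings.warn(
            f"dropping species without trait coordinates: {sorted(missing)}",
            stacklevel=2,
        )
        dropped = missing
    hulls: list[Polygon | None] = []
    reasons: list[str] = []
    for i in range(cm.n_sites):
        comm = sorted(cm.species_set(i) - dropped)
        if len(comm) < min_richness:
            hulls.append(None)
            reasons.append("below min_richness")
            continue
        hull = _hull(ts.points(comm))
        hulls.append(hull)
        reasons.append("" if hull is not None else "degenerate hull")
    ii, jj = pair_index(cm.n_sites)
    n_pairs = len(ii)
    a = np.full(n_pairs, np.nan)
    b = np.full(n_pairs, np.nan)
    c = np.full(n_pairs, np.nan)
    excluded = np.zeros(n_pairs, dtype=bool)
    reason = np.empty(n_pairs, dtype=object)
    reason[:] = ""
    for k, (i, j) in enumerate(zip(ii, jj)):
        if hulls[i] is None or hulls[j] is None:
            excluded[k] = True
            reason[k] = reasons[i] if hulls[i] is None else reasons[j]
            continue
        inter = hulls[i].intersection(hulls[j]).area
        a[k] = inter
        b[k] = _clamp(hulls[i].area - inter)
        c[k] = _clamp(hulls[j].area - inter)
    sim, sne, sor = decompose_arrays(a, b, c)
    # identical hulls: a > 0, b = c = 0 is a defined (0, 0, 0) triplet
    return pd.DataFrame(
        {
            "site_i": np.asarray(cm.sites, dtype=object)[ii],
            "site_j": np.asarray(cm.sites, dtype=object)[jj],
            "a_area": a,
            "b_area": b,
            "c_area": c,
            "beta_sim": np.where(excluded, np.nan, sim),
            "beta_sne": np.where(excluded, np.nan, sne),
            "beta_sor": np.where(excluded, np.nan, sor),
            "dimension": "functional",
            "excluded": excluded,
            "reason": reason,
        }
    )
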