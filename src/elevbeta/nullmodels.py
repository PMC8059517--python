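"""Null-model randomizations and standardized effect sizes (SES).

SES = (observed − null mean) / null sd per site pair and per index.
Negative values flag less dissimilarity than expected under the null
(an environmental-filtering signature), positive values more (limiting
similarity). Three schemes:

``richness_preserving_draw``
    each site keeps its richness; species are drawn equiprobably without
    replacement from the pool.
``fixed_fixed_swap``
    sequential 2×2 checkerboard swaps preserving both row (richness) and
    column (occupancy) sums; a burn-in then thinning chain.
``label_shuffle``
    the community matrix is untouched; the species → tip or species →
    trait-coordinate assignment is permuted (isolates tree / trait
    structure from composition).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix, PhyloTree, ValidationError
from .decompose import decompose_arrays
from .functional import TraitSpace, _hull
from .phylo import BranchIncidence
from .taxonomic import pair_component_arrays, pair_index

__all__ = ["randomize", "ses_beta", "SCHEMES", "DEFAULT_SCHEMES"]

SCHEMES = ("richness_preserving_draw", "fixed_fixed_swap", "label_shuffle")

#: field-standard defaults per dimension: a margin-conserving community
#: null for species identity; tree/trait label shuffles for structure
DEFAULT_SCHEMES = {
    "taxonomic": "fixed_fixed_swap",
    "phylogenetic": "label_shuffle",
    "functional": "label_shuffle",
}


def _draw_matrix(incidence: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Richness-preserving equiprobable draw from the species pool."""
    n_sites, n_species = incidence.shape
    rich = incidence.sum(axis=1)
    keys = rng.random((n_sites, n_species))
    order = np.argsort(keys, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(n_sites)[:, None]
    ranks[rows, order] = np.arange(n_species)[None, :]
    return (ranks < rich[:, None]).astype(np.int8)


def _swap_step(M: np.ndarray, rng: np.random.Generator, n_attempts: int) -> int:
    """Attempt ``n_attempts`` checkerboard swaps in place; returns successes."""
    n_sites, n_species = M.shape
    r = rng.integers(0, n_sites, size=(n_attempts, 2))
    c = rng.integers(0, n_species, size=(n_attempts, 2))
    done = 0
    for (i1, i2), (j1, j2) in zip(r, c):
        if i1 == i2 or j1 == j2:
            continue
        a, b = M[i1, j1], M[i1, j2]
        c2, d = M[i2, j1], M[i2, j2]
        if a == d and b == c2 and a != b:  # checkerboard unit
            M[i1, j1], M[i1, j2] = b, a
            M[i2, j1], M[i2, j2] = d, c2
            done += 1
    return done


def _has_checkerboard(M: np.ndarray) -> bool:
    S = M @ (1 - M).T
    return bool((np.triu(S, 1) * np.triu(S.T, 1)).any())


def randomize(
    cm: CommunityMatrix,
    scheme: str,
    seed=None,
    *,
    burn_in: int = 10_000,
    rng: np.random.Generator | None = None,
):
    """One randomization of a community matrix (or a label permutation).

    For ``label_shuffle`` the return value is a permuted copy of the
    species list (the mapping position k: cm.species[k] → permuted[k]),
    to be applied to tip labels or trait coordinates; the matrix itself is
    left untouched. The other schemes return a new :class:`CommunityMatrix`.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if scheme == "label_shuffle":
        return [cm.species[k] for k in rng.permutation(cm.n_species)]
    if scheme == "richness_preserving_draw":
        return CommunityMatrix(cm.sites, cm.species, _draw_matrix(cm.incidence, rng))
    # fixed_fixed_swap
    M = cm.incidence.astype(np.int8).copy()
    if not _has_checkerboard(M):
        raise ValidationError("matrix has no swappable 2×2 checkerboard submatrix")
    _swap_step(M, rng, burn_in)
    out = CommunityMatrix(cm.sites, cm.species, M)
    assert (out.incidence.sum(axis=1) == cm.incidence.sum(axis=1)).all()
    assert (out.incidence.sum(axis=0) == cm.incidence.sum(axis=0)).all()
    return out


class _TaxonomicEngine:
    index_names = ("beta_sim", "beta_sne", "beta_sor")

    def __init__(self, cm: CommunityMatrix):
        self.cm = cm

    def observed(self):
        return decompose_arrays(*pair_component_arrays(self.cm.incidence))

    def null(self, incidence: np.ndarray):
        return decompose_arrays(*pair_component_arrays(incidence))


class _PhyloEngine(_TaxonomicEngine):
    def __init__(self, cm: CommunityMatrix, tree: PhyloTree):
        super().__init__(cm)
        pool = cm.occurring_species()
        self.cols = np.asarray([cm.species.index(s) for s in pool])
        self.bi = BranchIncidence(tree, pool)

    def observed(self):
        return decompose_arrays(
            *self.bi.component_arrays(self.cm.incidence[:, self.cols])
        )

    def null(self, incidence: np.ndarray):
        return decompose_arrays(*self.bi.component_arrays(incidence[:, self.cols]))


class _FunctionalEngine:
    index_names = ("beta_sim", "beta_sne", "beta_sor")

    def __init__(self, cm: CommunityMatrix, ts: TraitSpace, min_richness: int = 3):
        self.cm = cm
        self.min_richness = min_richness
        # coordinate rows aligned with matrix species order; shuffling the
        # species→coordinate assignment is a row permutation of this array
        self.coords = ts.coordinates.loc[
            [s for s in cm.species], :
        ].to_numpy(dtype=float)

    def _triplets(self, coords: np.ndarray):
        n = self.cm.n_sites
        hulls = []
        for i in range(n):
            mask = self.cm.incidence[i].astype(bool)
            if mask.sum() < self.min_richness:
                hulls.append(None)
                continue
            try:
                hulls.append(_hull(coords[mask]))
            except Exception:
                hulls.append(None)
        ii, jj = pair_index(n)
        a = np.full(len(ii), np.nan)
        b = np.full(len(ii), np.nan)
        c = np.full(len(ii), np.nan)
        for k, (i, j) in enumerate(zip(ii, jj)):
            hi, hj = hulls[i], hulls[j]
            if hi is None or hj is None:
                continue
            inter = hi.intersection(hj).area
            a[k] = inter
            b[k] = max(hi.area - inter, 0.0)
            c[k] = max(hj.area - inter, 0.0)
        return decompose_arrays(a, b, c)

    def observed(self):
        return self._triplets(self.coords)

    def null_permutation(self, perm: np.ndarray):
        return self._triplets(self.coords[perm])


def ses_beta(
    cm: CommunityMatrix,
    dimension: str,
    *,
    tree: PhyloTree | None = None,
    trait_space: TraitSpace | None = None,
    n_rand: int = 999,
    scheme: str | None = None,
    seed=None,
    min_richness: int = 3,
    burn_in: int = 10_000,
    thin: int = 1_000,
) -> pd.DataFrame:
    """Standardized effect sizes for every beta index of one dimension.

    Fully reproducible from ``(scheme, seed, n_rand)``. Pairs whose null
    standard deviation is zero are flagged (``degenerate_null``) and carry
    NaN SES. The swap scheme runs one sequential chain: ``burn_in``
    attempted swaps, then ``thin`` between successive null samples.
    """
    if dimension not in DEFAULT_SCHEMES:
        raise ValidationError(f"unknown dimension {dimension!r}")
    if seed is None:
        raise ValidationError("a seed is mandatory for SES computation")
    if n_rand < 99:
        raise ValidationError("n_rand must be at least 99")
    scheme = scheme or DEFAULT_SCHEMES[dimension]
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    if dimension == "taxonomic" and scheme == "label_shuffle":
        raise ValidationError("label_shuffle leaves taxonomic indices unchanged")
    if dimension == "phylogenetic" and tree is None:
        raise ValidationError("phylogenetic SES needs a tree")
    if dimension == "functional" and trait_space is None:
        raise ValidationError("functional SES needs a trait space")

    rng = np.random.default_rng(seed)
    if dimension == "taxonomic":
        engine = _TaxonomicEngine(cm)
    elif dimension == "phylogenetic":
        engine = _PhyloEngine(cm, tree)
    else:
        engine = _FunctionalEngine(cm, trait_space, min_richness)

    obs = np.stack(engine.observed())  # (3, n_pairs)
    n_pairs = obs.shape[1]
    nulls = np.empty((n_rand, 3, n_pairs))

    if scheme == "label_shuffle":
        if dimension == "phylogenetic":
            # permuting the species→tip assignment == permuting matrix columns
            for r in range(n_rand):
                perm = rng.permutation(cm.n_species)
                nulls[r] = np.stack(engine.null(cm.incidence[:, perm]))
        else:
            pool = np.arange(cm.n_species)
            for r in range(n_rand):
                nulls[r] = np.stack(engine.null_permutation(rng.permutation(pool)))
    elif scheme == "richness_preserving_draw":
        for r in range(n_rand):
            nulls[r] = np.stack(engine.null(_draw_matrix(cm.incidence, rng)))
    else:  # fixed_fixed_swap chain
        M = cm.incidence.astype(np.int8).copy()
        if not _has_checkerboard(M):
            raise ValidationError("matrix has no swappable 2×2 checkerboard submatrix")
        _swap_step(M, rng, burn_in)
        for r in range(n_rand):
            _swap_step(M, rng, thin)
            assert (M.sum(axis=1) == cm.incidence.sum(axis=1)).all()
            assert (M.sum(axis=0) == cm.incidence.sum(axis=0)).all()
            nulls[r] = np.stack(engine.null(M))

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN excluded pairs
        null_mean = np.nanmean(nulls, axis=0)
        null_sd = np.nanstd(nulls, axis=0, ddof=1)
        n_valid = np.sum(~np.isnan(nulls), axis=0)
        # sd indistinguishable from float noise counts as degenerate
        degenerate = ~(null_sd > 1e-12 * np.maximum(1.0, np.abs(null_mean)))
        ses = np.where(~degenerate, (obs - null_mean) / np.where(~degenerate, null_sd, 1.0), np.nan)

    if bool(np.all(degenerate | np.isnan(null_mean))):
        raise ValidationError(
            "degenerate null: the randomization left every index identical "
            "across all pairs and draws"
        )

    ii, jj = pair_index(cm.n_sites)
    sites = np.asarray(cm.sites, dtype=object)
    frames = []
    for k, name in enumerate(engine.index_names):
        frames.append(
            pd.DataFrame(
                {
                    "site_i": sites[ii],
                    "site_j": sites[jj],
                    "index": name,
                    "observed": obs[k],
                    "null_mean": null_mean[k],
                    "null_sd": null_sd[k],
                    "ses": ses[k],
                    "n_null_valid": n_valid[k],
                    "degenerate_null": degenerate[k],
                    "n_rand": n_rand,
                    "scheme": scheme,
                    "seed": seed,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    # drop rows for pairs with no observed value (excluded pairs)
    table.loc[np.isnan(table["observed"]), "ses"] = np.nan
    return table
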