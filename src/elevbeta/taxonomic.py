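"""Taxonomic (species-identity) pairwise beta-diversity.

Matching components per unordered site pair: a = shared species,
b / c = species unique to either site, fed through the shared turnover /
nestedness decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix, ValidationError
from .decompose import decompose_arrays

__all__ = ["PairComponents", "pair_counts", "beta_matrix_taxonomic",
           "pair_component_arrays", "pair_index"]


@dataclass(frozen=True)
class PairComponents:
    a: int
    b: int
    c: int


def pair_counts(comm1, comm2) -> PairComponents:
    """Matching components of two assemblages (species sets)."""
    s1, s2 = set(comm1), set(comm2)
    inter = len(s1 & s2)
    return PairComponents(inter, len(s1) - inter, len(s2) - inter)


def pair_index(n_sites: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the n(n-1)/2 unordered pairs in canonical order
    (site_i before site_j in matrix order)."""
    iu = np.triu_indices(n_sites, k=1)
    return iu[0], iu[1]


def pair_component_arrays(incidence: np.ndarray):
    """Condensed (a, b, c) arrays over all unordered site pairs.

    Vectorized core shared with the null-model loop: a = M Mᵀ off-diagonal,
    b and c from row richness.
    """
    M = np.asarray(incidence, dtype=np.int64)
    shared = M @ M.T
    rich = M.sum(axis=1)
    ii, jj = pair_index(M.shape[0])
    a = shared[ii, jj]
    b = rich[ii] - a
    c = rich[jj] - a
    return a, b, c


def beta_matrix_taxonomic(cm: CommunityMatrix, *, empty_pair: str = "exclude") -> pd.DataFrame:
    """Pairwise taxonomic beta table: one row per unordered site pair.

    Pairs involving an empty assemblage have an undefined turnover ratio
    (0/0). Under the default ``empty_pair="exclude"`` policy they are
    flagged excluded with NaN indices; ``empty_pair="as_one"`` instead
    records total dissimilarity 1 for one-empty pairs while keeping the
    turnover/nestedness split undefined, so such pairs still enter
    whole-index analyses but stay out of component comparisons.
    """
    if cm.n_sites < 2:
        raise ValidationError("need at least 2 sites")
    if empty_pair not in ("exclude", "as_one"):
        raise ValidationError("empty_pair must be 'exclude' or 'as_one'")
    a, b, c = pair_component_arrays(cm.incidence)
    sim, sne, sor = decompose_arrays(a, b, c)
    ii, jj = pair_index(cm.n_sites)
    rich = cm.richness()
    empty_i = rich[ii] == 0
    empty_j = rich[jj] == 0
    both_empty = empty_i & empty_j
    one_empty = (empty_i | empty_j) & ~both_empty
    excluded = empty_i | empty_j
    reason = np.where(
        both_empty, "both assemblages empty",
        np.where(one_empty, "empty assemblage", ""),
    )
    sor_out = np.where(excluded, np.nan, sor)
    if empty_pair == "as_one":
        sor_out = np.where(one_empty, 1.0, sor_out)
        excluded = both_empty
        reason = np.where(
            one_empty, "empty assemblage (beta_sor recorded as 1)", reason
        )
    df = pd.DataFrame(
        {
            "site_i": np.asarray(cm.sites, dtype=object)[ii],
            "site_j": np.asarray(cm.sites, dtype=object)[jj],
            "a": a,
            "b": b,
            "c": c,
            "beta_sim": np.where(empty_i | empty_j, np.nan, sim),
            "beta_sne": np.where(empty_i | empty_j, np.nan, sne),
            "beta_sor": sor_out,
            "dimension": "taxonomic",
            "excluded": excluded,
            "reason": reason,
        }
    )
    return df


def all_pairs(cm: CommunityMatrix):
    """Iterate (site_i, site_j, assemblage_i, assemblage_j) in canonical order."""
    sets = [cm.species_set(i) for i in range(cm.n_sites)]
    for i, j in combinations(range(cm.n_sites), 2):
        yield cm.sites[i], cm.sites[j], sets[i], sets[j]
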