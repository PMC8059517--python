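"""Additive decomposition of pairwise Sørensen-family dissimilarity.

For matching components a (shared), b and c (unique to either assemblage):

    beta_sor = (b + c) / (2a + b + c)        total dissimilarity
    beta_sim = min(b, c) / (a + min(b, c))   turnover
    beta_sne = beta_sor - beta_sim           nestedness-resultant

The same three formulas apply whether a, b, c are species counts,
shared/unique branch lengths on a phylogeny, or shared/unique convex-hull
areas in trait space. Integer components are evaluated in exact rational
arithmetic and converted to float once, so the additivity identity holds
to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = ["BetaTriplet", "UndefinedPairError", "EmptyAssemblageError", "decompose_pair",
           "decompose_arrays"]


class UndefinedPairError(ValueError):
    """Both assemblages empty: no dissimilarity is defined."""


class EmptyAssemblageError(ValueError):
    """Exactly one assemblage empty: the turnover ratio is 0/0."""


@dataclass(frozen=True)
class BetaTriplet:
    beta_sim: float
    beta_sne: float
    beta_sor: float

    def __iter__(self):
        return iter((self.beta_sim, self.beta_sne, self.beta_sor))


def decompose_pair(a, b, c) -> BetaTriplet:
    """Decompose one pair's matching components into (sim, sne, sor).

    Raises :class:`UndefinedPairError` when a = b = c = 0 and
    :class:`EmptyAssemblageError` when exactly one assemblage is empty
    (a = 0 and min(b, c) = 0 with max(b, c) > 0); callers building pair
    tables turn the latter into flagged exclusions.
    """
    if a < 0 or b < 0 or c < 0:
        raise ValueError("components must be non-negative")
    if a == 0 and b == 0 and c == 0:
        raise UndefinedPairError("both assemblages are empty")
    if a == 0 and min(b, c) == 0:
        raise EmptyAssemblageError("one assemblage is empty; turnover is 0/0")
    exact = all(isinstance(x, (int, np.integer)) for x in (a, b, c))
    if exact:
        a, b, c = int(a), int(b), int(c)
        sor = Fraction(b + c, 2 * a + b + c)
        sim = Fraction(min(b, c), a + min(b, c))
        sne = sor - sim
        return BetaTriplet(float(sim), float(sne), float(sor))
    sor = (b + c) / (2.0 * a + b + c)
    m = min(b, c)
    sim = m / (a + m)
    return BetaTriplet(float(sim), float(sor - sim), float(sor))


def decompose_arrays(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Vectorized decomposition; undefined pairs yield NaN in all three.

    Used by the matrix builders and the null-model loop. NaN marks pairs
    where at least one assemblage is empty (or both are).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    m = np.minimum(b, c)
    denom_sor = 2.0 * a + b + c
    denom_sim = a + m
    ok = (denom_sor > 0) & (denom_sim > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sor = np.where(ok, (b + c) / np.where(denom_sor > 0, denom_sor, 1.0), np.nan)
        sim = np.where(ok, m / np.where(denom_sim > 0, denom_sim, 1.0), np.nan)
    sne = sor - sim
    return sim, sne, sor
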