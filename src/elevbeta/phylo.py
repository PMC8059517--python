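"""Phylogenetic beta-diversity (shared-branch-length family) and Blomberg's K.

The matching components a, b, c are sums of branch lengths on the
root-to-tip paths of both / only the first / only the second assemblage,
measured on the tree pruned to the regional species pool (the union of all
surveyed assemblages). The root stem is dropped. Components feed through
the same turnover / nestedness decomposition as species counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix, PhyloTree, ValidationError
from .decompose import decompose_arrays
from .taxonomic import pair_index

__all__ = [
    "BranchComponents",
    "BranchIncidence",
    "branch_components",
    "beta_matrix_phylo",
    "multi_tree_summary",
    "KResult",
    "blomberg_k",
]


@dataclass(frozen=True)
class BranchComponents:
    a: float  # shared branch length
    b: float  # unique to community 1
    c: float  # unique to community 2


class BranchIncidence:
    """Branch × species presence structure of a pruned tree.

    ``membership`` is a (n_branches × n_species) boolean matrix: branch e is
    on the root-to-tip path of species s. Lets a whole community matrix (or
    a null randomization of it) be converted to branch components with two
    matrix products.
    """

    def __init__(self, tree: PhyloTree, species: list[str]):
        self.species = [str(s).strip() for s in species]
        idx = {s: k for k, s in enumerate(self.species)}
        missing = set(self.species) - set(tree.tip_labels)
        if missing:
            raise ValidationError(f"species not on tree: {sorted(missing)}")
        pruned = tree.pruned_to(self.species)
        dtree = pruned.dendropy_tree
        rows: list[np.ndarray] = []
        lengths: list[float] = []
        tipset: dict = {}
        for node in dtree.postorder_node_iter():
            mask = np.zeros(len(self.species), dtype=bool)
            if node.is_leaf():
                mask[idx[node.taxon.label.strip()]] = True
            else:
                for child in node.child_nodes():
                    mask |= tipset[child]
            tipset[node] = mask
            if node is not dtree.seed_node:  # root stem dropped
                rows.append(mask)
                lengths.append(float(node.edge.length or 0.0))
        self.membership = np.asarray(rows, dtype=bool)
        self.lengths = np.asarray(lengths, dtype=float)
        self.tree = pruned

    def community_branch_presence(self, incidence: np.ndarray) -> np.ndarray:
        """(n_sites × n_branches) boolean: branch on some path of the site."""
        M = np.asarray(incidence, dtype=np.int64)
        return (M @ self.membership.T.astype(np.int64)) > 0

    def component_arrays(self, incidence: np.ndarray):
        """Condensed (a, b, c) branch-length arrays over all site pairs."""
        B = self.community_branch_presence(incidence).astype(float)
        Bw = B * self.lengths
        shared = Bw @ B.T
        totals = Bw.sum(axis=1)
        ii, jj = pair_index(B.shape[0])
        a = shared[ii, jj]
        b = totals[ii] - a
        c = totals[jj] - a
        return a, b, c


def branch_components(tree: PhyloTree, comm1, comm2, *, pool=None) -> BranchComponents:
    """Branch-length matching components for one pair of assemblages.

    ``pool`` is the regional species pool the tree is pruned to before
    classifying branches; it defaults to the union of the two assemblages
    but should be the union over ALL sites when pairs come from a matrix
    (the matrix builder does this).
    """
    s1 = {str(x).strip() for x in comm1}
    s2 = {str(x).strip() for x in comm2}
    pool_list = sorted(pool) if pool is not None else sorted(s1 | s2)
    if not (s1 | s2) <= set(pool_list):
        raise ValidationError("assemblages must be drawn from the pool")
    bi = BranchIncidence(tree, pool_list)
    inc = np.array(
        [[sp in s1 for sp in pool_list], [sp in s2 for sp in pool_list]], dtype=int
    )
    a, b, c = bi.component_arrays(inc)
    return BranchComponents(float(a[0]), float(b[0]), float(c[0]))


def _phylo_pair_table(cm: CommunityMatrix, a, b, c) -> pd.DataFrame:
    sim, sne, sor = decompose_arrays(a, b, c)
    ii, jj = pair_index(cm.n_sites)
    rich = cm.richness()
    excluded = (rich[ii] == 0) | (rich[jj] == 0)
    reason = np.where(
        (rich[ii] == 0) & (rich[jj] == 0), "both assemblages empty",
        np.where(excluded, "empty assemblage", ""),
    )
    return pd.DataFrame(
        {
            "site_i": np.asarray(cm.sites, dtype=object)[ii],
            "site_j": np.asarray(cm.sites, dtype=object)[jj],
            "a_bl": a,
            "b_bl": b,
            "c_bl": c,
            "beta_sim": np.where(excluded, np.nan, sim),
            "beta_sne": np.where(excluded, np.nan, sne),
            "beta_sor": np.where(excluded, np.nan, sor),
            "dimension": "phylogenetic",
            "excluded": excluded,
            "reason": reason,
        }
    )


def beta_matrix_phylo(
    cm: CommunityMatrix, tree: PhyloTree, *, drop_unmatched: bool = False
) -> pd.DataFrame:
    """Pairwise phylogenetic beta table on the pool-pruned tree.

    Species missing from the tree are a hard error by default;
    ``drop_unmatched=True`` prunes them from the analysis with a warning
    listing every dropped name (never silently).
    """
    pool = cm.occurring_species()
    if not pool:
        raise ValidationError("no species occurs in any site")
    missing = sorted(set(pool) - set(tree.tip_labels))
    if missing:
        if not drop_unmatched:
            raise ValidationError(f"species not on tree: {missing}")
        warnings.warn(f"dropping species absent from tree: {missing}", stacklevel=2)
        pool = [s for s in pool if s not in set(missing)]
        if not pool:
            raise ValidationError("no species left after dropping unmatched")
    bi = BranchIncidence(tree, pool)
    cols = [cm.species.index(s) for s in pool]
    a, b, c = bi.component_arrays(cm.incidence[:, cols])
    return _phylo_pair_table(cm, a, b, c)


def consensus_tree(trees: list[PhyloTree], min_freq: float = 0.5) -> PhyloTree:
    """Majority-rule consensus with mean split branch lengths."""
    if not trees:
        raise ValidationError("need at least one tree")
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(
        [
            dendropy.Tree.get(
                data=t.dendropy_tree.as_string("newick"),
                schema="newick",
                taxon_namespace=tns,
                preserve_underscores=True,
            )
            for t in trees
        ],
        taxon_namespace=tns,
    )
    cons = tl.consensus(min_freq=min_freq, summarize_splits=True,
                        set_edge_lengths="mean-length")
    for edge in cons.preorder_edge_iter():
        if edge.head_node is not cons.seed_node and edge.length is None:
            edge.length = 0.0
    return PhyloTree(cons)


def multi_tree_summary(
    cm: CommunityMatrix, trees: list[PhyloTree], *, aggregation: str = "mean"
) -> pd.DataFrame:
    """Phylogenetic indices over a tree distribution (e.g. posterior sample).

    ``aggregation="mean"`` (default) computes each index per tree and
    returns the per-pair arithmetic mean plus across-tree sd columns;
    ``"consensus"`` collapses the distribution to a majority-rule
    consensus tree first and computes indices once. All trees must share
    the same tip set.
    """
    if not trees:
        raise ValidationError("need at least one tree")
    tipsets = {frozenset(t.tip_labels) for t in trees}
    if len(tipsets) != 1:
        raise ValidationError("all trees must share an identical tip set")
    if aggregation not in ("mean", "consensus"):
        raise ValidationError("aggregation must be 'mean' or 'consensus'")
    if aggregation == "consensus":
        out = beta_matrix_phylo(cm, consensus_tree(trees))
        out["n_trees"] = len(trees)
        return out
    tables = [beta_matrix_phylo(cm, t) for t in trees]
    base = tables[0].copy()
    idx_cols = ["beta_sim", "beta_sne", "beta_sor"]
    comp_cols = ["a_bl", "b_bl", "c_bl"]
    stacked = {c: np.stack([t[c].to_numpy() for t in tables]) for c in idx_cols + comp_cols}
    for c in idx_cols + comp_cols:
        base[c] = stacked[c].mean(axis=0)
    for c in idx_cols:
        base[f"{c}_sd"] = stacked[c].std(axis=0, ddof=0)
    base["n_trees"] = len(trees)
    return base


@dataclass(frozen=True)
class KResult:
    K: float
    p: float
    n_perm: int


def _k_ratio(x: np.ndarray, Vinv: np.ndarray, ones: np.ndarray) -> float:
    """Observed MSE0/MSE for a trait vector given V⁻¹ (shared across perms)."""
    denom = ones @ Vinv @ ones
    ahat = (ones @ Vinv @ x) / denom
    resid = x - ahat
    mse0 = resid @ resid
    mse = resid @ Vinv @ resid
    return float(mse0 / mse)


def blomberg_k(tree: PhyloTree, trait, *, n_perm: int = 999, seed=None) -> KResult:
    """Blomberg's K phylogenetic signal of a tip trait.

    K = (MSE0/MSE) / E[MSE0/MSE] with the phylogenetically corrected mean
    â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1), MSE0 the ordinary mean square about â, MSE the
    V-weighted mean square, and the Brownian expectation
    E[MSE0/MSE] = (tr V − n/(1ᵀV⁻¹1)) / (n − 1). K = 1 matches Brownian
    motion on the given tree; K < 1 indicates weaker signal.

    ``trait`` maps tip label → value (dict or pandas Series). The p-value
    is the proportion of tip permutations (observed included) whose
    MSE0/MSE is at least the observed ratio; ``n_perm = 0`` skips it.
    """
    series = pd.Series(trait)
    series.index = [str(i).strip() for i in series.index]
    tips = [t for t in tree.tip_labels]
    missing = set(tips) - set(series.index)
    if missing:
        raise ValidationError(f"trait missing for tips: {sorted(missing)}")
    n = len(tips)
    if n < 4:
        raise ValidationError("Blomberg's K needs at least 4 tips")
    x = series.loc[tips].to_numpy(dtype=float)
    V, _ = tree.vcv(tips)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular phylogenetic covariance (zero-length cherry?); "
            "collapse or perturb zero-length internal branches"
        ) from exc
    ones = np.ones(n)
    denom = ones @ Vinv @ ones
    expected = (np.trace(V) - n / denom) / (n - 1)
    observed = _k_ratio(x, Vinv, ones)
    K = observed / expected
    if n_perm <= 0:
        return KResult(K, float("nan"), 0)
    rng = np.random.default_rng(seed)
    hits = 1  # observed counts as one permutation
    for _ in range(n_perm):
        ratio = _k_ratio(rng.permutation(x), Vinv, ones)
        if ratio >= observed - 1e-12:
            hits += 1
    return KResult(K, hits / (n_perm + 1), n_perm)
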