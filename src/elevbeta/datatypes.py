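"""Core domain objects shared by every analysis stage.

The central container is :class:`CommunityMatrix`, a binary site × species
incidence table. Site metadata (:class:`SiteTable`), morphological traits
(:class:`TraitTable`), weather-station summaries (:class:`StationRecords`)
and phylogenies (:class:`PhyloTree`, a thin wrapper over a rooted dendropy
tree) all cross-reference it through shared site / species identifiers.
Identifiers are compared case-sensitively after whitespace trimming.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CommunityMatrix",
    "SiteTable",
    "TraitTable",
    "StationRecords",
    "PhyloTree",
    "ENV_COLUMNS",
]

#: Site-level environmental columns recognised throughout the pipeline:
#: annual mean temperature (°C), annual precipitation (mm), annual mean
#: humidity (%), net primary production and potential evapotranspiration.
ENV_COLUMNS = ("AMT", "AP", "AMH", "NPP", "PET")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


def _clean_ids(ids: Iterable, what: str) -> list[str]:
    out = [str(x).strip() for x in ids]
    if len(set(out)) != len(out):
        dupes = sorted({x for x in out if out.count(x) > 1})
        raise ValidationError(f"duplicate {what} identifier(s): {dupes}")
    return out


@dataclass
class CommunityMatrix:
    """Binary site × species incidence matrix (rows = sites)."""

    sites: list[str]
    species: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        self.sites = _clean_ids(self.sites, "site")
        self.species = _clean_ids(self.species, "species")
        inc = np.asarray(self.incidence)
        if inc.ndim != 2 or inc.shape != (len(self.sites), len(self.species)):
            raise ValidationError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.sites)} sites × {len(self.species)} species"
            )
        if len(self.sites) < 2:
            raise ValidationError("a community matrix needs at least 2 sites")
        if len(self.species) < 1:
            raise ValidationError("a community matrix needs at least 1 species")
        if not np.isin(inc, (0, 1)).all():
            bad = np.argwhere(~np.isin(inc, (0, 1)))[0]
            raise ValidationError(
                f"incidence entries must be 0/1; first offender at "
                f"site {self.sites[bad[0]]!r}, species {self.species[bad[1]]!r}"
            )
        self.incidence = inc.astype(np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def richness(self) -> np.ndarray:
        """Species count per site, in site order."""
        return self.incidence.sum(axis=1)

    def species_set(self, site) -> frozenset[str]:
        """Assemblage of a site, by id or positional index."""
        i = site if isinstance(site, (int, np.integer)) else self.sites.index(str(site).strip())
        row = self.incidence[i]
        return frozenset(sp for sp, v in zip(self.species, row) if v)

    def occurring_species(self) -> list[str]:
        """Regional species pool: species present in at least one site."""
        present = self.incidence.any(axis=0)
        return [sp for sp, p in zip(self.species, present) if p]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=self.sites, columns=self.species)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class SiteTable:
    """Per-site metadata: elevation (m) plus optional environmental columns."""

    data: pd.DataFrame  # indexed by site id; must contain 'elevation'

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = _clean_ids(df.index, "site")
        if "elevation" not in df.columns:
            raise ValidationError("site table must contain an 'elevation' column")
        elev = pd.to_numeric(df["elevation"], errors="coerce")
        if not np.isfinite(elev.to_numpy(dtype=float)).all():
            raise ValidationError("every site needs a finite elevation")
        df["elevation"] = elev.astype(float)
        self.data = df

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    def elevation(self, site: str) -> float:
        return float(self.data.loc[str(site).strip(), "elevation"])

    def env_columns(self) -> list[str]:
        return [c for c in ENV_COLUMNS if c in self.data.columns]

    def check_covers(self, cm: CommunityMatrix) -> None:
        missing = set(cm.sites) - set(self.data.index)
        if missing:
            raise ValidationError(f"site table is missing matrix site(s): {sorted(missing)}")


@dataclass
class TraitTable:
    """Species × trait table of strictly positive size measurements."""

    data: pd.DataFrame  # indexed by species id

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = _clean_ids(df.index, "species")
        if df.shape[1] < 2:
            raise ValidationError("a trait table needs at least 2 trait columns")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all() or (values <= 0).any():
            r, c = np.argwhere(~(np.isfinite(values) & (values > 0)))[0]
            raise ValidationError(
                f"trait values must be positive and finite (log transform): "
                f"offending species {df.index[r]!r}, trait {df.columns[c]!r}"
            )
        self.data = df.astype(float)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def check_covers(self, species: Sequence[str]) -> None:
        missing = set(species) - set(self.data.index)
        if missing:
            raise ValidationError(f"trait table is missing species: {sorted(missing)}")


@dataclass
class StationRecords:
    """Weather-station annual summaries used for site climate interpolation."""

    data: pd.DataFrame  # indexed by station id; elevation + AMT/AP/AMH

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = _clean_ids(df.index, "station")
        if len(df) < 2:
            raise ValidationError("need at least 2 weather stations")
        if "elevation" not in df.columns:
            raise ValidationError("station records need an 'elevation' column")
        elev = df["elevation"].to_numpy(dtype=float)
        if len(np.unique(elev)) != len(elev):
            raise ValidationError("station elevations must be distinct")
        self.data = df


class PhyloTree:
    """Rooted phylogeny with branch lengths, tips keyed by species id.

    Wraps a :class:`dendropy.Tree`. The root stem (an edge above the root
    node, if the source newick carried one) is ignored by every analysis.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise ValidationError("every tip must be labelled")
            labels.append(leaf.taxon.label.strip())
        if len(set(labels)) != len(labels):
            raise ValidationError("tip labels must be unique")
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue  # root stem may legitimately lack a length
            if edge.length is None:
                raise ValidationError("every branch must carry a length")
            if edge.length < 0:
                raise ValidationError("branch lengths must be >= 0")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label.strip() for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def total_length(self) -> float:
        """Sum of branch lengths, root stem excluded."""
        return float(
            sum(
                e.length or 0.0
                for e in self._tree.preorder_edge_iter()
                if e.head_node is not self._tree.seed_node
            )
        )

    def pruned_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Copy of the tree retaining only the given tips."""
        keep = {str(x).strip() for x in labels}
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValidationError(f"species not on tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label.strip() in keep]
        clone.retain_taxa(taxa)
        # collapse a unifurcate root left behind by pruning
        seed = clone.seed_node
        while len(seed.child_nodes()) == 1:
            child = seed.child_nodes()[0]
            clone.seed_node = child
            child.parent_node = None
            seed = child
        return PhyloTree(clone)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip (root stem excluded)."""
        depths: dict[str, float] = {}
        node_depth = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label.strip()] = node_depth[node]
        return depths

    def vcv(self, order: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Brownian-motion variance–covariance matrix among tips.

        ``V[i, j]`` is the shared root-to-MRCA path length of tips i and j;
        the diagonal holds root-to-tip depths.
        """
        tips = [str(x).strip() for x in (order or self.tip_labels)]
        idx = {t: i for i, t in enumerate(tips)}
        n = len(tips)
        V = np.zeros((n, n))
        node_depth: dict = {self._tree.seed_node: 0.0}
        tipsets: dict = {}
        for node in self._tree.preorder_node_iter():
            if node is not self._tree.seed_node:
                node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label.strip()
                if label not in idx:
                    raise ValidationError(f"tip {label!r} not in requested order")
                tipsets[node] = [idx[label]]
                V[idx[label], idx[label]] = node_depth[node]
            else:
                children = [tipsets[c] for c in node.child_nodes()]
                h = node_depth[node]
                for i in range(len(children)):
                    for j in range(i + 1, len(children)):
                        ii = np.asarray(children[i])
                        jj = np.asarray(children[j])
                        V[np.ix_(ii, jj)] = h
                        V[np.ix_(jj, ii)] = h
                tipsets[node] = [t for c in children for t in c]
        return V, tips

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_tips} tips, total length {self.total_length():.4g})"
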