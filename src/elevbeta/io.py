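"""Readers and writers for the plain-text formats the pipeline touches.

CSV for incidence matrices, site metadata, traits and station records;
newick for phylogenies. All outputs are UTF-8 tidy CSVs with deterministic
row order plus a generated data dictionary.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd

from .datatypes import (
    CommunityMatrix,
    PhyloTree,
    SiteTable,
    StationRecords,
    TraitTable,
    ValidationError,
)

__all__ = [
    "read_community_matrix",
    "read_newick",
    "parse_newick",
    "read_trait_table",
    "read_site_table",
    "read_station_records",
    "write_results",
]


def read_community_matrix(path, *, transpose: bool = False) -> CommunityMatrix:
    """Read a binary site × species CSV (header = species, first column = site ids).

    Any nonzero numeric cell is coerced to 1 with a warning. Set
    ``transpose=True`` when the file stores species in rows; orientation is
    never guessed silently.
    """
    # pandas mangles duplicate headers (A, A.1): check the raw header row
    with open(path, encoding="utf-8") as fh:
        header = next(csv.reader(fh))[1:]
    if len(set(h.strip() for h in header)) != len(header):
        raise ValidationError(
            f"duplicate species column name(s) in {path}"
        )
    df = pd.read_csv(path, index_col=0)
    if transpose:
        df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna().to_numpy().argmax()]
                raise ValidationError(
                    f"non-numeric incidence cell at row {row!r}, column {col!r}"
                ) from exc
        raise
    nonbinary = (values != 0) & (values != 1)
    if nonbinary.any():
        warnings.warn(
            f"{int(nonbinary.sum())} nonzero cell(s) coerced to presence (1)",
            stacklevel=2,
        )
        values = (values != 0).astype(int)
    return CommunityMatrix(list(df.index), list(df.columns), values.astype(int))


def parse_newick(newick: str, *, allow_basal_polytomy: bool = False) -> PhyloTree:
    """Parse a single rooted newick string with branch lengths.

    A basal polytomy (more than two children at the root) usually signals
    an unrooted tree and is refused unless ``allow_basal_polytomy`` is set,
    in which case the polytomy is interpreted as the root.
    """
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    n_basal = len(tree.seed_node.child_nodes())
    if n_basal > 2 and not allow_basal_polytomy:
        raise ValidationError(
            f"basal polytomy with {n_basal} children looks unrooted; "
            "pass allow_basal_polytomy=True to interpret it as the root"
        )
    return PhyloTree(tree)


def read_newick(path, *, allow_basal_polytomy: bool = False) -> PhyloTree:
    """Read a rooted, branch-length-bearing newick file."""
    text = Path(path).read_text(encoding="utf-8").strip()
    return parse_newick(text, allow_basal_polytomy=allow_basal_polytomy)


def read_trait_table(path, *, columns: Mapping[str, str] | None = None) -> TraitTable:
    """Read a species × trait CSV of positive measurements."""
    df = pd.read_csv(path, index_col=0)
    if columns:
        df = df.rename(columns=dict(columns))
    return TraitTable(df)


def read_site_table(path, *, columns: Mapping[str, str] | None = None) -> SiteTable:
    """Read per-site metadata. ``columns`` maps file headers onto the
    canonical names (elevation, AMT, AP, AMH, NPP, PET) when the source
    layout differs."""
    df = pd.read_csv(path, index_col=0)
    if columns:
        df = df.rename(columns=dict(columns))
    return SiteTable(df)


def read_station_records(path, *, columns: Mapping[str, str] | None = None) -> StationRecords:
    df = pd.read_csv(path, index_col=0)
    if columns:
        df = df.rename(columns=dict(columns))
    return StationRecords(df)


_DICTIONARY = {
    "site_i": "first site of the unordered pair (matrix order)",
    "site_j": "second site of the unordered pair",
    "a": "shared species count",
    "b": "species unique to site_i",
    "c": "species unique to site_j",
    "a_bl": "shared branch length",
    "b_bl": "branch length unique to site_i's subtree",
    "c_bl": "branch length unique to site_j's subtree",
    "a_area": "trait-hull intersection area",
    "b_area": "hull area unique to site_i",
    "c_area": "hull area unique to site_j",
    "beta_sim": "turnover component of Sørensen dissimilarity",
    "beta_sne": "nestedness-resultant component",
    "beta_sor": "total Sørensen dissimilarity (= beta_sim + beta_sne)",
    "dimension": "taxonomic | phylogenetic | functional",
    "excluded": "True when the pair carries no dissimilarity value",
    "reason": "why the pair was excluded (empty string otherwise)",
    "index": "which beta measure the row standardizes",
    "observed": "observed value of the index",
    "null_mean": "mean of the index over null randomizations",
    "null_sd": "standard deviation over null randomizations",
    "ses": "(observed - null_mean) / null_sd",
    "n_rand": "number of null randomizations",
    "scheme": "null randomization scheme",
    "seed": "RNG seed of the randomization stream",
}


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write tidy result CSVs plus a generated data dictionary.

    Row order is made deterministic: tables carrying site_i/site_j keep
    their (already canonical) pair order; anything else keeps input order.
    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    seen_cols: set[str] = set()
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.12g")
        written.append(path)
        seen_cols.update(map(str, df.columns))
    lines = ["column,description"]
    for col in sorted(seen_cols):
        if col in _DICTIONARY:
            lines.append(f'{col},"{_DICTIONARY[col]}"')
    dict_path = out / "data_dictionary.csv"
    dict_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.append(dict_path)
    return written
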