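"""End-to-end orchestration of the comparative beta-diversity workflow.

Per species group: observed pairwise dissimilarity in up to three
dimensions, turnover/nestedness decomposition, within-dimension and
cross-dimension Wilcoxon comparisons, distance-decay regressions for
observed and standardized indices, forward-AIC environmental selection;
then the cross-group slope ranking. Everything lands in tidy tables plus
a run manifest (config hash + seed) and a human-readable summary whose
every number is traceable to a table cell.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata as _metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ebio
from .datatypes import CommunityMatrix, PhyloTree, SiteTable, TraitTable, ValidationError
from .functional import TraitSpace, beta_matrix_functional, build_trait_space
from .nullmodels import DEFAULT_SCHEMES, ses_beta
from .phylo import beta_matrix_phylo, blomberg_k, multi_tree_summary
from .stats import (
    RegressionFit,
    compare_slopes,
    distance_decay,
    forward_aic,
    pairwise_distance_table,
    significance_label,
    wilcoxon_z,
)
from .taxonomic import beta_matrix_taxonomic

__all__ = ["GroupData", "PipelineConfig", "ReportBundle", "run_pipeline", "load_config"]

logger = logging.getLogger("elevbeta.pipeline")

DIMENSIONS = ("taxonomic", "phylogenetic", "functional")
INDEX_COLS = ("beta_sim", "beta_sne", "beta_sor")


@dataclass
class GroupData:
    """All inputs of one species group, already loaded and cross-checked."""

    name: str
    community: CommunityMatrix
    sites: SiteTable
    trees: list[PhyloTree] = field(default_factory=list)
    traits: TraitTable | None = None

    def __post_init__(self) -> None:
        self.sites.check_covers(self.community)
        if self.traits is not None:
            self.traits.check_covers(self.community.occurring_species())


@dataclass
class PipelineConfig:
    groups: dict[str, GroupData]
    seed: int
    dimensions: tuple[str, ...] = DIMENSIONS
    min_richness: int = 3
    n_rand: int = 999
    alpha: float = 0.05
    schemes: dict = field(default_factory=dict)
    shared_subset: bool = True
    run_ses: bool = True

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("no groups configured")
        unknown = set(self.dimensions) - set(DIMENSIONS)
        if unknown:
            raise ValidationError(f"unknown dimension(s): {sorted(unknown)}")
        if self.run_ses and self.seed is None:
            raise ValidationError("a seed is mandatory when SES is enabled")
        for g in self.groups.values():
            if "phylogenetic" in self.dimensions and not g.trees:
                raise ValidationError(f"group {g.name!r}: phylogenetic dimension "
                                      "enabled but no tree given")
            if "functional" in self.dimensions and g.traits is None:
                raise ValidationError(f"group {g.name!r}: functional dimension "
                                      "enabled but no trait table given")


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    summary: str
    manifest: dict
    errors: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir) -> list[Path]:
        out = Path(out_dir)
        written = ebio.write_results(self.tables, out)
        (out / "summary.txt").write_text(self.summary, encoding="utf-8")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str) + "\n",
            encoding="utf-8",
        )
        return written + [out / "summary.txt", out / "manifest.json"]


def _config_hash(cfg: PipelineConfig) -> str:
    payload = {
        "seed": cfg.seed,
        "dimensions": list(cfg.dimensions),
        "min_richness": cfg.min_richness,
        "n_rand": cfg.n_rand,
        "alpha": cfg.alpha,
        "schemes": dict(cfg.schemes),
        "shared_subset": cfg.shared_subset,
        "run_ses": cfg.run_ses,
        "groups": {
            name: {
                "sites": g.community.sites,
                "species": g.community.species,
                "incidence": g.community.incidence.tolist(),
                "n_trees": len(g.trees),
            }
            for name, g in cfg.groups.items()
        },
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode("utf-8")
    ).hexdigest()


def _observed_tables(g: GroupData, cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    if "taxonomic" in cfg.dimensions:
        out["taxonomic"] = beta_matrix_taxonomic(g.community)
    if "phylogenetic" in cfg.dimensions:
        if len(g.trees) > 1:
            out["phylogenetic"] = multi_tree_summary(g.community, g.trees)
        else:
            out["phylogenetic"] = beta_matrix_phylo(g.community, g.trees[0])
    if "functional" in cfg.dimensions:
        ts = build_trait_space(g.traits)
        out["functional"] = beta_matrix_functional(
            g.community, ts, min_richness=cfg.min_richness
        )
        out["_trait_space"] = ts  # stashed for SES; stripped before reporting
    return out


def _computable(table: pd.DataFrame) -> np.ndarray:
    return ~table["excluded"].to_numpy(dtype=bool) & ~np.isnan(
        table["beta_sor"].to_numpy(dtype=float)
    )


def _comparison_rows(group: str, betas: dict[str, pd.DataFrame], cfg: PipelineConfig):
    rows = []
    dims = [d for d in cfg.dimensions if d in betas]
    # level 1: turnover vs nestedness within each dimension
    for dim in dims:
        t = betas[dim]
        keep = _computable(t)
        if keep.sum() >= 2:
            try:
                res = wilcoxon_z(t.loc[keep, "beta_sim"], t.loc[keep, "beta_sne"])
            except ValidationError:
                continue  # every value tied: nothing to compare
            rows.append(
                dict(group=group, level="component", dimension=dim,
                     comparison="beta_sim vs beta_sne", z=res.z, abs_z=res.abs_z,
                     p=res.p, n1=res.n1, n2=res.n2,
                     decision=significance_label(res.p, cfg.alpha),
                     subset="computable pairs"))
    # level 2: same component across dimensions
    if len(dims) >= 2:
        if cfg.shared_subset:
            shared = np.logical_and.reduce([_computable(betas[d]) for d in dims])
        for comp in INDEX_COLS:
            for i in range(len(dims)):
                for j in range(i + 1, len(dims)):
                    d1, d2 = dims[i], dims[j]
                    if cfg.shared_subset:
                        k1 = k2 = shared
                        subset = "shared computable pairs"
                    else:
                        k1, k2 = _computable(betas[d1]), _computable(betas[d2])
                        subset = "per-dimension pairs"
                    if k1.sum() < 2 or k2.sum() < 2:
                        continue
                    try:
                        res = wilcoxon_z(
                            betas[d1].loc[k1, comp], betas[d2].loc[k2, comp]
                        )
                    except ValidationError:
                        continue
                    rows.append(
                        dict(group=group, level="dimension", dimension=f"{d1} vs {d2}",
                             comparison=comp, z=res.z, abs_z=res.abs_z, p=res.p,
                             n1=res.n1, n2=res.n2,
                             decision=significance_label(res.p, cfg.alpha),
                             subset=subset))
    return rows


def _regression_rows(group: str, betas, ses_tables, g: GroupData, cfg: PipelineConfig):
    rows = []
    fits: dict[tuple, RegressionFit] = {}
    for dim, t in betas.items():
        for idx in INDEX_COLS:
            try:
                fit = distance_decay(t, g.sites, idx)
            except ValidationError:
                continue
            fits[(dim, idx, "observed")] = fit
            rows.append(dict(group=group, dimension=dim, index=idx, kind="observed",
                             slope=fit.slope, intercept=fit.intercept,
                             p_slope=fit.p_slope, r2=fit.r2, n_pairs=fit.n_pairs,
                             decision=significance_label(fit.p_slope, cfg.alpha)))
    for dim, st in ses_tables.items():
        for idx in INDEX_COLS:
            sub = st[st["index"] == idx].rename(columns={"ses": f"ses_{idx}"})
            sub = sub.assign(excluded=np.isnan(sub[f"ses_{idx}"]))
            try:
                fit = distance_decay(sub, g.sites, f"ses_{idx}")
            except ValidationError:
                continue
            fits[(dim, idx, "ses")] = fit
            rows.append(dict(group=group, dimension=dim, index=idx, kind="ses",
                             slope=fit.slope, intercept=fit.intercept,
                             p_slope=fit.p_slope, r2=fit.r2, n_pairs=fit.n_pairs,
                             decision=significance_label(fit.p_slope, cfg.alpha)))
    return rows, fits


def _aic_rows(group: str, betas, g: GroupData, cfg: PipelineConfig):
    env_vars = g.sites.env_columns()
    if not env_vars:
        return []
    dist = pairwise_distance_table(g.sites, g.community.sites, variables=env_vars)
    rows = []
    for dim, t in betas.items():
        keep = _computable(t)
        for idx in INDEX_COLS:
            y = t[idx].to_numpy(dtype=float)
            sel = forward_aic(
                pd.Series(np.where(keep, y, np.nan)),
                dist[[f"d_{v}" for v in env_vars]],
            )
            rows.append(dict(
                group=group, dimension=dim, index=idx,
                selected="+".join(p.removeprefix("d_") for p in sel.predictors) or "(intercept only)",
                aic_start=sel.aic_trajectory[0], aic_final=sel.final_aic,
                n_steps=len(sel.predictors)))
    return rows


def _phylo_signal_rows(group: str, g: GroupData, cfg: PipelineConfig, seed: int):
    """Blomberg's K of each log size attribute on the group's (first) tree."""
    if not g.trees or g.traits is None:
        return []
    pool = [s for s in g.community.occurring_species() if s in set(g.traits.species)]
    if len(pool) < 4:
        return []
    tree = g.trees[0].pruned_to(pool)
    rows = []
    for k, col in enumerate(g.traits.data.columns):
        trait = np.log(g.traits.data.loc[pool, col])
        try:
            res = blomberg_k(tree, trait, n_perm=999, seed=seed + k)
        except ValidationError:
            continue
        rows.append(dict(group=group, trait=col, K=res.K, p=res.p, n_perm=res.n_perm,
                         n_species=len(pool)))
    return rows


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run the full comparative workflow; identical config + seed gives
    byte-identical tables. Group failures are isolated: the run fails only
    when every group fails."""
    beta_frames, comp_rows, reg_rows, aic_rows_all, ses_frames = [], [], [], [], []
    signal_rows = []
    slope_fits: dict[str, dict] = {}
    errors: dict[str, str] = {}
    summary_lines: list[str] = []
    for name, g in cfg.groups.items():
        try:
            betas = _observed_tables(g, cfg)
            ts: TraitSpace | None = betas.pop("_trait_space", None)
            for dim, t in betas.items():
                beta_frames.append(t.assign(group=name))
            comp_rows.extend(_comparison_rows(name, betas, cfg))
            ses_tables: dict[str, pd.DataFrame] = {}
            if cfg.run_ses:
                for k, dim in enumerate(d for d in cfg.dimensions if d in betas):
                    scheme = cfg.schemes.get(dim, DEFAULT_SCHEMES[dim])
                    # one deterministic sub-seed per (group, dimension)
                    name_key = int.from_bytes(
                        hashlib.sha256(name.encode("utf-8")).digest()[:4], "big"
                    )
                    sub_seed = int(
                        np.random.SeedSequence(
                            [cfg.seed, name_key, k]
                        ).generate_state(1)[0] % (2**31)
                    )
                    logger.info(
                        "SES %s/%s: scheme=%s seed=%d n_rand=%d",
                        name, dim, scheme, sub_seed, cfg.n_rand,
                    )
                    st = ses_beta(
                        g.community, dim,
                        tree=g.trees[0] if g.trees else None,
                        trait_space=ts,
                        n_rand=cfg.n_rand, scheme=scheme, seed=sub_seed,
                        min_richness=cfg.min_richness,
                    )
                    ses_tables[dim] = st
                    ses_frames.append(st.assign(group=name, dimension=dim))
            rows, fits = _regression_rows(name, betas, ses_tables, g, cfg)
            reg_rows.extend(rows)
            slope_fits[name] = fits
            aic_rows_all.extend(_aic_rows(name, betas, g, cfg))
            signal_rows.extend(_phylo_signal_rows(name, g, cfg, cfg.seed or 0))
            summary_lines.append(f"group {name}: {len(betas)} dimension(s), "
                                 f"{g.community.n_sites} sites, "
                                 f"{g.community.n_species} species")
        except Exception as exc:  # noqa: BLE001 — group isolation is the contract
            errors[name] = f"{type(exc).__name__}: {exc}"
    if len(errors) == len(cfg.groups):
        raise ValidationError(f"every group failed: {errors}")

    # level 3: cross-group slope ranking on observed indices
    ranking_rows = []
    for dim in cfg.dimensions:
        for idx in INDEX_COLS:
            fits = {
                name: f[(dim, idx, "observed")]
                for name, f in slope_fits.items()
                if (dim, idx, "observed") in f
            }
            if len(fits) >= 2:
                ranking = compare_slopes(fits, cfg.alpha)
                ranking_rows.append(dict(
                    dimension=dim, index=idx,
                    ranking=" > ".join(f"{n} ({s:.3g})" for n, s in ranking.ranked),
                    not_compared=", ".join(ranking.not_compared)))

    tables = {
        "pairwise_beta": pd.concat(beta_frames, ignore_index=True) if beta_frames else pd.DataFrame(),
        "comparisons": pd.DataFrame(comp_rows),
        "regressions": pd.DataFrame(reg_rows),
        "slope_ranking": pd.DataFrame(ranking_rows),
        "forward_aic": pd.DataFrame(aic_rows_all),
        "phylo_signal": pd.DataFrame(signal_rows),
    }
    if ses_frames:
        tables["ses"] = pd.concat(ses_frames, ignore_index=True)

    for row in comp_rows:
        if row["level"] == "component":
            summary_lines.append(
                f"{row['group']} / {row['dimension']}: beta_sim vs beta_sne "
                f"|z| = {row['abs_z']:.3f}, p = {row['p']:.3g} ({row['decision']})"
            )
    for row in ranking_rows:
        if row["ranking"]:
            summary_lines.append(f"slopes [{row['dimension']} {row['index']}]: {row['ranking']}")
    for name, msg in errors.items():
        summary_lines.append(f"group {name} FAILED: {msg}")

    try:
        version = _metadata.version("elevbeta")
    except _metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_rand": cfg.n_rand,
        "dimensions": list(cfg.dimensions),
        "elevbeta_version": version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "groups": sorted(cfg.groups),
        "failed_groups": errors,
    }
    return ReportBundle(tables, "\n".join(summary_lines) + "\n", manifest, errors)


def load_config(path, *, seed: int | None = None, run_ses: bool = True) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file of input paths."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    base = Path(path).parent
    groups = {}
    for name, spec in raw.get("groups", {}).items():
        trees = []
        tree_paths = spec.get("trees") or ([spec["tree"]] if "tree" in spec else [])
        for tp in tree_paths:
            trees.append(ebio.read_newick(base / tp))
        groups[name] = GroupData(
            name=name,
            community=ebio.read_community_matrix(base / spec["community"]),
            sites=ebio.read_site_table(base / spec["sites"]),
            trees=trees,
            traits=ebio.read_trait_table(base / spec["traits"]) if "traits" in spec else None,
        )
    dims = tuple(raw.get("dimensions", DIMENSIONS))
    return PipelineConfig(
        groups=groups,
        seed=seed if seed is not None else raw.get("seed"),
        dimensions=dims,
        min_richness=int(raw.get("min_richness", 3)),
        n_rand=int(raw.get("n_rand", 999)),
        alpha=float(raw.get("alpha", 0.05)),
        schemes=dict(raw.get("schemes", {})),
        shared_subset=bool(raw.get("shared_subset", True)),
        run_ses=run_ses and bool(raw.get("run_ses", True)),
    )
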