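"""End-to-end orchestration: traits -> units -> descriptors -> statistics.

:func:`run_full_analysis` executes the whole comparative workflow on either
a synthetic scenario or a directory of input files, repeats every
tree-dependent statistic over a posterior sample of chronograms, and writes
five report artifacts into the output directory:

* ``signal_table.csv``   — Blomberg's K per trait, mean ± dispersion across
  trees, with the count of significant iterations;
* ``pgls_anova.csv``     — the WPI-on-DM PGLS ANOVA table;
* ``pairwise_pgls.csv``  — coefficients of each trait on each of the 21
  range descriptors with significance flags;
* ``pls_loadings.csv``   — vector loadings, r and p of the six PLS analyses
  (naive and phylogenetic x both-traits / WPI-only / DM-only);
* ``per_tree_stats.csv`` — the long-format per-tree archive from which the
  summary tables can be re-rendered without recomputation.

Descriptor and trait blocks are standardized (column z-scores) before PLS so
that descriptors measured on very different scales contribute comparably.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pcm import (
    PGLS,
    PhylogeneticSignal,
    TwoBlockPLS,
    multi_tree_run,
    spawn_seeds,
)
from .rangeenv import (
    DESCRIPTOR_NAMES,
    RangeMask,
    RasterStack,
    range_descriptor_table,
    read_masks_csv,
)
from .synth import SyntheticScenario, generate_dataset
from .traits import lineage_trait_table, read_specimens, write_trait_table
from .treeops import (
    Chronogram,
    cut_at_age,
    phylo_covariance,
    read_trees,
    retain_tips,
    sample_posterior,
)

__all__ = ["RunConfig", "ReportBundle", "run_full_analysis", "render_report"]

log = logging.getLogger("viperpcm")

TRAITS = ("wpi", "dm")
PLS_MODES = ("both", "wpi", "dm")


@dataclass
class RunConfig:
    """All run constants; defaults are the study's stated choices."""

    scenario: str | SyntheticScenario | None = None
    input_dir: str | None = None
    out_dir: str = "run"
    cut_age: float = 2.5
    n_posterior_trees: int = 1000
    n_perm: int = 999
    alpha: float = 0.05
    q_trim: float = 0.05
    min_cells: int = 20
    max_specimens_per_lineage: int = 10
    drop_units: list = field(default_factory=list)
    seed: int = 0
    se_mode: str = "sd"  # dispersion column: "sd" across trees or "sem"
    holm: bool = False

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        if isinstance(self.scenario, SyntheticScenario):
            data["scenario"] = dataclasses.asdict(self.scenario)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if isinstance(data.get("scenario"), dict):
            data["scenario"] = SyntheticScenario(**data["scenario"])
        return cls(**data)


@dataclass
class ReportBundle:
    trait_table: pd.DataFrame
    descriptor_table: pd.DataFrame
    signal_table: pd.DataFrame
    pgls_anova: pd.DataFrame
    pairwise: pd.DataFrame
    pls_loadings: pd.DataFrame
    per_tree: pd.DataFrame
    out_dir: Path


# ---------------------------------------------------------------------------
# input resolution


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        scenario = (
            config.scenario
            if isinstance(config.scenario, SyntheticScenario)
            else SyntheticScenario.from_yaml(config.scenario)
        )
        ds = generate_dataset(scenario)
        return ds.specimens, ds.tree, ds.posterior, ds.stack, ds.masks
    if config.input_dir is None:
        raise ValueError("config needs either a scenario or an input_dir")
    d = Path(config.input_dir)
    specimens = read_specimens(d / "specimens.csv")
    tree = read_trees(str(d / "tree.nwk"), schema="newick")[0]
    posterior = read_trees(str(d / "posterior.nex"), schema="nexus")
    stack = RasterStack.read_dir(d / "rasters")
    masks = read_masks_csv(d / "masks.csv", stack.grid)
    return specimens, tree, posterior, stack, masks


def _merge_masks(masks: dict[str, RangeMask], membership: dict[str, str]) -> dict[str, RangeMask]:
    """Union member-lineage masks into per-unit masks keyed by representative."""
    merged: dict[str, set] = {}
    for lid, mask in masks.items():
        rep = membership.get(lid)
        if rep is None:
            continue
        merged.setdefault(rep, set()).update(mask.cells)
    return {rep: RangeMask(rep, frozenset(cells)) for rep, cells in merged.items()}


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1).replace(0.0, 1.0)
    return (df - df.mean()) / sd


# ---------------------------------------------------------------------------
# per-tree analysis


def _analyze_one_tree(
    tree: Chronogram,
    seed,
    traits_df: pd.DataFrame,
    desc_z: pd.DataFrame,
    n_perm: int,
    holm: bool,
) -> dict[str, float]:
    labels = list(traits_df.index)
    cov = phylo_covariance(tree).reorder(labels)
    seeds = spawn_seeds(seed, 3 + len(PLS_MODES) + 2 * len(DESCRIPTOR_NAMES))
    stats: dict[str, float] = {}

    for i, trait in enumerate(TRAITS):
        sig = PhylogeneticSignal(
            cov=cov, n_perm=n_perm, random_state=np.random.default_rng(seeds[i])
        ).fit(traits_df[f"mean_{trait}"])
        stats[f"k_{trait}"] = sig.k_
        stats[f"p_k_{trait}"] = sig.p_value_

    pgls = PGLS(
        cov=cov, n_perm=n_perm, random_state=np.random.default_rng(seeds[2])
    ).fit(traits_df[["mean_dm"]], traits_df["mean_wpi"])
    stats["pgls_slope"] = float(pgls.coef_[0])
    stats["pgls_r2"] = pgls.r2_
    stats["pgls_f"] = pgls.f_
    stats["pgls_z"] = pgls.z_
    stats["p_pgls"] = pgls.p_value_

    trait_z = _zscore(traits_df[["mean_wpi", "mean_dm"]]).rename(
        columns={"mean_wpi": "WPI", "mean_dm": "DM"}
    )
    blocks = {"both": trait_z, "wpi": trait_z[["WPI"]], "dm": trait_z[["DM"]]}
    for j, mode in enumerate(PLS_MODES):
        pls = TwoBlockPLS(
            cov=cov, n_perm=n_perm,
            random_state=np.random.default_rng(seeds[3 + j]),
        ).fit(blocks[mode], desc_z)
        stats[f"pls_r_{mode}"] = pls.r_
        stats[f"p_pls_{mode}"] = pls.p_value_
        for t, col in enumerate(blocks[mode].columns):
            stats[f"load_{mode}_{col}"] = float(pls.x_loadings_[t])
        for t, name in enumerate(DESCRIPTOR_NAMES):
            stats[f"load_{mode}_{name}"] = float(pls.y_loadings_[t])

    k = 3 + len(PLS_MODES)
    for trait in TRAITS:
        for name in DESCRIPTOR_NAMES:
            est = PGLS(
                cov=cov, n_perm=n_perm,
                random_state=np.random.default_rng(seeds[k]),
            ).fit(desc_z[[name]], traits_df[f"mean_{trait}"])
            stats[f"coef_{trait}_{name}"] = float(est.coef_[0])
            stats[f"p_{trait}_{name}"] = est.p_value_
            k += 1
    return stats


def _naive_pls_tables(
    traits_df: pd.DataFrame, desc_z: pd.DataFrame, n_perm: int, seed
) -> dict[str, dict[str, float]]:
    trait_z = _zscore(traits_df[["mean_wpi", "mean_dm"]]).rename(
        columns={"mean_wpi": "WPI", "mean_dm": "DM"}
    )
    blocks = {"both": trait_z, "wpi": trait_z[["WPI"]], "dm": trait_z[["DM"]]}
    seeds = spawn_seeds(seed, len(PLS_MODES))
    out: dict[str, dict[str, float]] = {}
    for j, mode in enumerate(PLS_MODES):
        pls = TwoBlockPLS(
            cov=None, n_perm=n_perm, random_state=np.random.default_rng(seeds[j])
        ).fit(blocks[mode], desc_z)
        entry = {"r": pls.r_, "p": pls.p_value_}
        for t, col in enumerate(blocks[mode].columns):
            entry[col] = float(pls.x_loadings_[t])
        for t, name in enumerate(DESCRIPTOR_NAMES):
            entry[name] = float(pls.y_loadings_[t])
        out[mode] = entry
    return out


# ---------------------------------------------------------------------------
# summaries


def _disp(summary_per_tree: pd.DataFrame, col: str, se_mode: str) -> float:
    sd = float(summary_per_tree[col].std(ddof=1)) if len(summary_per_tree) > 1 else 0.0
    return sd / np.sqrt(len(summary_per_tree)) if se_mode == "sem" else sd


def _build_reports(
    per_tree: pd.DataFrame,
    naive: dict[str, dict[str, float]],
    n_labels: int,
    alpha: float,
    se_mode: str,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    n_trees = len(per_tree)

    signal_rows = []
    for trait in TRAITS:
        signal_rows.append(
            {
                "trait": trait.upper(),
                "K_mean": per_tree[f"k_{trait}"].mean(),
                "K_disp": _disp(per_tree, f"k_{trait}", se_mode),
                "p_mean": per_tree[f"p_k_{trait}"].mean(),
                "p_disp": _disp(per_tree, f"p_k_{trait}", se_mode),
                "n_significant": int((per_tree[f"p_k_{trait}"] < alpha).sum()),
                "n_trees": n_trees,
            }
        )
    signal_table = pd.DataFrame(signal_rows)

    n = n_labels
    anova = pd.DataFrame(
        [
            {
                "term": "DM",
                "df": 1,
                "R2_mean": per_tree["pgls_r2"].mean(),
                "R2_disp": _disp(per_tree, "pgls_r2", se_mode),
                "F_mean": per_tree["pgls_f"].mean(),
                "F_disp": _disp(per_tree, "pgls_f", se_mode),
                "Z_mean": per_tree["pgls_z"].mean(),
                "Z_disp": _disp(per_tree, "pgls_z", se_mode),
                "pval_mean": per_tree["p_pgls"].mean(),
                "pval_disp": _disp(per_tree, "p_pgls", se_mode),
                "n_significant": int((per_tree["p_pgls"] < alpha).sum()),
            },
            {
                "term": "Residuals",
                "df": n - 2,
                "R2_mean": 1.0 - per_tree["pgls_r2"].mean(),
                "R2_disp": _disp(per_tree, "pgls_r2", se_mode),
            },
            {"term": "Total", "df": n - 1},
        ]
    )

    pair_rows = []
    for trait in TRAITS:
        for name in DESCRIPTOR_NAMES:
            pcol = f"p_{trait}_{name}"
            n_sig = int((per_tree[pcol] < alpha).sum())
            pair_rows.append(
                {
                    "trait": trait.upper(),
                    "descriptor": name,
                    "coef_mean": per_tree[f"coef_{trait}_{name}"].mean(),
                    "coef_disp": _disp(per_tree, f"coef_{trait}_{name}", se_mode),
                    "p_mean": per_tree[pcol].mean(),
                    "n_significant": n_sig,
                    "significant": n_sig > n_trees / 2,
                }
            )
    pairwise = pd.DataFrame(pair_rows)

    row_order = ["WPI", "DM", *DESCRIPTOR_NAMES, "r", "p"]
    loadings = pd.DataFrame(index=row_order)
    for mode in PLS_MODES:
        col = {}
        for name in row_order[:-2]:
            col[name] = naive[mode].get(name, np.nan)
        col["r"] = naive[mode]["r"]
        col["p"] = naive[mode]["p"]
        loadings[f"naive_{mode}"] = pd.Series(col)
        pcol = {}
        for name in row_order[:-2]:
            key = f"load_{mode}_{name}"
            pcol[name] = per_tree[key].mean() if key in per_tree else np.nan
        pcol["r"] = per_tree[f"pls_r_{mode}"].mean()
        pcol["p"] = per_tree[f"p_pls_{mode}"].mean()
        loadings[f"phylo_{mode}"] = pd.Series(pcol)
        loadings[f"phylo_{mode}_disp"] = pd.Series(
            {
                "r": _disp(per_tree, f"pls_r_{mode}", se_mode),
                "p": _disp(per_tree, f"p_pls_{mode}", se_mode),
            }
        )
    loadings.index.name = "variable"
    return signal_table, anova, pairwise, loadings


# ---------------------------------------------------------------------------
# the run


def run_full_analysis(config: RunConfig) -> ReportBundle:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path) -> ReportBundle:
    from . import __version__

    log.info("viperpcm %s starting run (seed=%s)", __version__, config.seed)
    config.to_yaml(out_dir / "run_config.yml")
    seeds = spawn_seeds(config.seed, 4)

    specimens, tree, posterior, stack, masks = _load_inputs(config)
    log.info(
        "inputs: %d specimens, %d-tip tree, %d posterior trees",
        len(specimens), tree.n_tips, len(posterior),
    )

    # delimit units on the summary tree and re-key everything to units
    delim = cut_at_age(tree, config.cut_age)
    pruned = retain_tips(
        tree,
        [r for u, r in delim.representatives.items() if u not in config.drop_units],
    )
    membership = {
        tip: delim.representatives[uid]
        for tip, uid in delim.membership().items()
        if uid not in config.drop_units
    }
    log.info("cut at %.3g My: %d units", config.cut_age, delim.n_units)
    unit_masks = _merge_masks(masks, membership)

    offenders = sorted(
        set(specimens["lineage_id"]) - {""} - set(delim.membership())
    )
    if offenders:
        raise ValueError(
            f"specimen lineage ids absent from the tree: {offenders}"
        )
    sp = specimens.copy()
    known = sp["lineage_id"] != ""
    sp.loc[known, "lineage_id"] = sp.loc[known, "lineage_id"].map(
        lambda lid: membership.get(lid, "")
    )
    trait_table = lineage_trait_table(
        sp, masks=unit_masks, grid=stack.grid,
        max_n=config.max_specimens_per_lineage,
    )
    labels = sorted(set(pruned.tips) & set(trait_table["lineage_id"]))
    missing_traits = sorted(set(pruned.tips) - set(labels))
    if missing_traits:
        log.warning("units with no usable specimens dropped: %s", missing_traits)
        pruned = retain_tips(pruned, labels)
    traits_df = trait_table.set_index("lineage_id").loc[labels]
    write_trait_table(trait_table, out_dir / "trait_table.csv")

    descriptors = range_descriptor_table(
        stack, {k: v for k, v in unit_masks.items() if k in labels},
        q=config.q_trim, min_cells=config.min_cells,
    ).loc[labels]
    descriptors.to_csv(out_dir / "descriptor_table.csv")
    desc_z = _zscore(descriptors)

    # posterior trees pruned to the same representative tips
    post = sample_posterior(
        posterior, min(config.n_posterior_trees, len(posterior)),
        seed=np.random.default_rng(seeds[0]),
    )
    post_pruned = []
    for p in post:
        extra = set(p.tips) - set(labels)
        post_pruned.append(retain_tips(p, set(labels)) if extra else p)

    naive = _naive_pls_tables(traits_df, desc_z, config.n_perm, seeds[1])

    summary = multi_tree_run(
        lambda t, s: _analyze_one_tree(
            t, s, traits_df, desc_z, config.n_perm, config.holm
        ),
        post_pruned,
        seed=seeds[2],
        alpha=config.alpha,
        p_key="p_pgls",
    )
    log.info(
        "multi-tree run: %d trees analyzed, %d failed", summary.n_trees, summary.n_failed
    )

    signal_table, anova, pairwise, loadings = _build_reports(
        summary.per_tree, naive, len(labels), config.alpha, config.se_mode
    )

    signal_table.to_csv(out_dir / "signal_table.csv", index=False)
    anova.to_csv(out_dir / "pgls_anova.csv", index=False)
    pairwise.to_csv(out_dir / "pairwise_pgls.csv", index=False)
    loadings.to_csv(out_dir / "pls_loadings.csv")
    long = summary.per_tree.reset_index().melt(
        id_vars="tree_index", var_name="statistic", value_name="value"
    )
    long.to_csv(out_dir / "per_tree_stats.csv", index=False)
    pd.DataFrame(naive).to_csv(out_dir / "naive_pls.csv")
    log.info("report bundle written to %s", out_dir)

    return ReportBundle(
        trait_table=trait_table,
        descriptor_table=descriptors,
        signal_table=signal_table,
        pgls_anova=anova,
        pairwise=pairwise,
        pls_loadings=loadings,
        per_tree=summary.per_tree,
        out_dir=out_dir,
    )


def render_report(run_dir, alpha: float = 0.05, se_mode: str = "sd") -> None:
    """Re-render the summary tables from a finished run's per-tree archive."""
    run_dir = Path(run_dir)
    long = pd.read_csv(run_dir / "per_tree_stats.csv")
    per_tree = long.pivot(index="tree_index", columns="statistic", values="value")
    naive = pd.read_csv(run_dir / "naive_pls.csv", index_col=0).to_dict()
    n_labels = len(pd.read_csv(run_dir / "descriptor_table.csv"))
    signal_table, anova, pairwise, loadings = _build_reports(
        per_tree, naive, n_labels, alpha, se_mode
    )
    signal_table.to_csv(run_dir / "signal_table.csv", index=False)
    anova.to_csv(run_dir / "pgls_anova.csv", index=False)
    pairwise.to_csv(run_dir / "pairwise_pgls.csv", index=False)
    loadings.to_csv(run_dir / "pls_loadings.csv")
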