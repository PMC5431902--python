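"""End-to-end orchestration: per-species tests, cross-tabulation,
phylogenetically controlled suite, and the command-line interface.

The pipeline takes individual-level morphometric records (or the packaged
species-level reference table), runs the colony-structured guard-vs-forager
tests with table-wide false-discovery control, derives the species flags
("guards of increased size", negative allometry), cross-tabulates them
against robber-bee target status, and runs the comparative analyses (PGLS,
Pagel's correlated-evolution test, stochastic mapping with Fitch and Mk1
reconstructions). Every stochastic step is seeded from one master seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import warnings
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import click
import numpy as np
import pandas as pd
import yaml

from . import comparative, morpho, phylo, synth
from .morpho import bh_adjust, cv_corrected, differentiation_index
from .phylo import BinaryStateVector, PhyloTree
from .synth import StudyFixture, build_study_fixture, derive_seed, tip_label

logger = logging.getLogger("beecastes")


@dataclasses.dataclass
class AnalysisConfig:
    """Run configuration with the defaults used throughout the study."""

    morph_csv: Optional[str] = None
    trait_csv: Optional[str] = None
    tree_file: Optional[str] = None
    alpha: float = 0.05
    n_sim: int = 1000
    master_seed: int = 1
    branch_length_floor: float = phylo.BRANCH_LENGTH_FLOOR
    within_genus_divergence: float = 2.0
    output_dir: str = "beecastes_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def tree_hash(tree: PhyloTree) -> str:
    return hashlib.sha256(tree.to_newick().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Species-level tests on individual records
# ---------------------------------------------------------------------------

def run_species_tests(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-species guard-vs-forager statistics with table-wide FDR control.

    For every species: random-intercept LME of head width on role (t-test
    fallback for single-colony species, flagged), corrected CV (per colony,
    averaged), DI, signed size difference relative to foragers, model-II
    allometry where wet weight exists, and melanization LME/DI where gray
    levels exist. Benjamini-Hochberg adjustment is applied across the
    guard tests as one family and across the allometry tests as a second;
    melanization p-values are reported raw and Bonferroni-adjusted within
    their own small family. Head width, never wet weight, enters the
    guard-vs-forager comparison.
    """
    rows = []
    for species, grp in records.groupby("species", sort=True):
        row: Dict[str, object] = {"species": species}
        roles = set(grp["role"].unique())
        if roles != {"guard", "forager"}:
            warnings.warn(f"{species}: missing a role; skipped")
            continue
        hw = grp["head_width_mm"].astype(float)
        row["n_workers"] = len(grp)
        row["n_colonies"] = grp["colony"].nunique()
        row["mean_head_width_mm"] = hw.mean()
        row["sd_head_width_mm"] = hw.std(ddof=1)
        mg = grp.loc[grp["role"] == "guard", "head_width_mm"].mean()
        mf = grp.loc[grp["role"] == "forager", "head_width_mm"].mean()
        row["size_difference_pct"] = 100.0 * (mg - mf) / mf
        cvs = [cv_corrected(c["head_width_mm"])
               for _, c in grp.groupby("colony") if len(c) >= 2]
        row["cv_headwidth"] = float(np.mean(cvs))
        try:
            row["di_headwidth"] = differentiation_index(grp, "head_width")
        except ValueError:
            row["di_headwidth"] = np.nan
        fit = morpho.lme_random_intercept(grp, response="head_width")
        row["t_guards"] = fit.t_value
        row["p_guards_raw"] = fit.p_value
        row["df_guards"] = fit.df
        row["single_colony_fallback"] = fit.fallback_ttest
        # allometry from all workers with weight (pooled roles)
        w = grp["wet_weight_mg"].astype(float)
        if w.notna().sum() >= 3:
            rma = morpho.rma_allometry(hw[w.notna()], w.dropna())
            row["allometry_slope"] = rma.slope
            row["t_allometry"] = rma.t_value
            row["p_allometry_raw"] = rma.p_value
            row["mean_weight_mg"] = w.mean()
            row["sd_weight_mg"] = w.std(ddof=1)
            wcv = [cv_corrected(c["wet_weight_mg"].dropna()) for _, c in
                   grp.groupby("colony") if c["wet_weight_mg"].notna().sum() >= 2]
            row["cv_weight"] = float(np.mean(wcv)) if wcv else np.nan
        else:
            row["allometry_slope"] = np.nan
            row["t_allometry"] = np.nan
            row["p_allometry_raw"] = np.nan
        if grp["gray_level"].notna().sum() >= 4:
            mel = morpho.lme_random_intercept(grp, response="melanization")
            row["t_melanization"] = mel.t_value
            row["p_melanization_raw"] = mel.p_value
            try:
                row["di_melanization"] = differentiation_index(grp, "melanization")
            except ValueError:
                row["di_melanization"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no species with both roles present")
    out["p_guards_adj"] = bh_adjust(out["p_guards_raw"])
    has_allom = out["p_allometry_raw"].notna()
    out["p_allometry_adj"] = np.nan
    if has_allom.any():
        out.loc[has_allom, "p_allometry_adj"] = bh_adjust(
            out.loc[has_allom, "p_allometry_raw"])
    if "p_melanization_raw" in out:
        has_mel = out["p_melanization_raw"].notna()
        m = int(has_mel.sum())
        out.loc[has_mel, "p_melanization_bonf"] = np.minimum(
            out.loc[has_mel, "p_melanization_raw"] * m, 1.0)
    out["larger_guards"] = ((out["p_guards_adj"] <= alpha)
                            & (out["size_difference_pct"] > 0))
    out["negative_allometry"] = ((out["p_allometry_adj"] <= alpha)
                                 & (out["allometry_slope"] < 1))
    return out


# ---------------------------------------------------------------------------
# Flags and counts from the species-level reference table
# ---------------------------------------------------------------------------

def flags_from_reference(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the significance rules to an already-adjusted species table.

    ``larger_guards``: adjusted guard-test p <= alpha and guards larger
    than foragers. ``negative_allometry``: slope < 1 and adjusted
    allometry p <= alpha (species without weight data stay unflagged/NaN).
    """
    df = table.copy()
    if "p_guards_num" not in df:
        df["p_guards_num"] = df["p_guards_adj"].astype(str).str.lstrip("<").astype(float)
    df["larger_guards"] = ((df["p_guards_num"] <= alpha)
                           & (df["size_difference_pct"] > 0))
    has = df["p_allometry_adj"].notna()
    df["negative_allometry"] = pd.NA
    df.loc[has, "negative_allometry"] = ((df.loc[has, "p_allometry_adj"] <= alpha)
                                         & (df.loc[has, "allometry_slope"] < 1))
    if "genus" not in df:
        df["genus"] = df["species"].str.split().str[0]
    return df


def genus_count(flagged: pd.DataFrame, column: str = "larger_guards") -> int:
    """Number of genera containing at least one flagged species."""
    return int(flagged.loc[flagged[column].eq(True), "genus"].nunique())


def colony_size_index(traffic: pd.DataFrame) -> pd.Series:
    """Species-level relative colony size from entrance-traffic counts.

    ``traffic`` columns: species, colony, count (bees entering per minute;
    typically two observations per colony, morning and afternoon). Counts
    are averaged per colony, then colony means per species.
    """
    need = {"species", "colony", "count"}
    if not need <= set(traffic.columns):
        raise ValueError(f"traffic table needs columns {sorted(need)}")
    per_colony = traffic.groupby(["species", "colony"])["count"].mean()
    return per_colony.groupby("species").mean()


@dataclasses.dataclass
class CrossTab:
    """2x2 table of robber-bee target status against the larger-guards flag."""

    counts: pd.DataFrame          # rows: target yes/no; cols: larger yes/no
    row_percent: pd.DataFrame     # row proportions as percentages, 1 decimal
    n: int


def crosstab_targets(summary: pd.DataFrame) -> CrossTab:
    """Cross-tabulate lestrimelitta_target x larger_guards with row percentages."""
    df = summary.dropna(subset=["larger_guards", "lestrimelitta_target"])
    dropped = len(summary) - len(df)
    if dropped:
        logger.info("crosstab: %d species without both flags excluded", dropped)
    t = df["lestrimelitta_target"].astype(bool)
    g = df["larger_guards"].astype(bool)
    counts = pd.crosstab(t, g).reindex(index=[True, False],
                                       columns=[True, False], fill_value=0)
    counts.index.name = "lestrimelitta_target"
    counts.columns.name = "larger_guards"
    sums = counts.sum(axis=1)
    pct = counts.div(sums.replace(0, np.nan), axis=0) * 100.0
    pct = pct.round(1)
    return CrossTab(counts, pct, int(counts.to_numpy().sum()))


# ---------------------------------------------------------------------------
# Comparative suite
# ---------------------------------------------------------------------------

def run_comparative_suite(summary: pd.DataFrame, tree: PhyloTree,
                          config: Optional[AnalysisConfig] = None,
                          trait_table: Optional[pd.DataFrame] = None) -> dict:
    """Run the phylogenetically controlled analyses and return a JSON-able report.

    Sections (skipped with a note when the needed columns are absent):
    (a) PGLS of log worker-size diversity on log queen-worker dimorphism;
    (b) PGLS of worker diversity on log colony size;
    (c) PGLS of the head-width CV on the larger-guards flag;
    (d) Pagel's test of negative allometry x larger guards;
    (e) Pagel's test of robber-bee target x larger guards;
    (f) stochastic mapping of larger guards (with Fitch and ML-Mk1
        reconstructions and the origin-count posterior).
    Continuous traits are natural-log transformed before PGLS.
    """
    cfg = config or AnalysisConfig()
    report: dict = {"tree_hash": tree_hash(tree), "alpha": cfg.alpha,
                    "master_seed": cfg.master_seed, "sections": {}}
    df = summary.set_index("species", drop=False)
    tips = {tip_label(s): s for s in df["species"]}
    missing = [t for t in tree.tip_labels if t not in tips]
    if missing:
        raise ValueError(f"tree tips without trait rows: {missing}")

    def series(col, log=False, source=None):
        src = source if source is not None else df
        if col not in src.columns or src[col].isna().any():
            return None
        vals = src[col].astype(float)
        if log:
            if (vals <= 0).any():
                return None
            vals = np.log(vals)
        return {tip_label(s): float(v) for s, v in zip(src["species"], vals)}

    src_traits = trait_table if trait_table is not None else df
    diversity = series("cv_headwidth", log=True)

    # (a) queen-worker dimorphism
    qw = series("qw_dimorphism", log=True, source=src_traits) \
        if trait_table is not None else None
    if qw and diversity:
        fit = comparative.pgls_fit(tree, diversity, qw)
        report["sections"]["pgls_diversity_vs_qw_dimorphism"] = _pgls_dict(fit)
    else:
        report["sections"]["pgls_diversity_vs_qw_dimorphism"] = {
            "skipped": "queen-worker dimorphism values not provided"}
    # (b) colony size
    cs = series("colony_size_index", log=True, source=src_traits) \
        if trait_table is not None else None
    if cs and diversity:
        fit = comparative.pgls_fit(tree, diversity, cs)
        report["sections"]["pgls_diversity_vs_colony_size"] = _pgls_dict(fit)
    else:
        report["sections"]["pgls_diversity_vs_colony_size"] = {
            "skipped": "colony size index not provided"}
    # (c) CV ~ larger guards
    lg_map = {tip_label(s): int(bool(v)) for s, v in
              zip(df["species"], df["larger_guards"])}
    if diversity and len(set(lg_map.values())) == 2:
        fit = comparative.pgls_fit(tree, diversity, lg_map)
        report["sections"]["pgls_cv_vs_larger_guards"] = _pgls_dict(fit)
    else:
        report["sections"]["pgls_cv_vs_larger_guards"] = {
            "skipped": "larger-guards flag constant across species"}

    lg = BinaryStateVector(lg_map, "guards of increased size")
    # (d) negative allometry x larger guards
    na = df["negative_allometry"]
    sub = df.loc[na.notna()]
    if len(sub) >= 4 and sub["negative_allometry"].astype(bool).nunique() == 2:
        kept = [tip_label(s) for s in sub["species"]]
        subtree = prune_tree(tree, kept)
        pa = BinaryStateVector({tip_label(s): int(bool(v)) for s, v in
                                zip(sub["species"], sub["negative_allometry"])},
                               "negative allometry")
        lg_sub = BinaryStateVector({k: lg_map[k] for k in kept},
                                   "guards of increased size")
        fit = comparative.pagel_fit(subtree, pa, lg_sub,
                                    seed=derive_seed(cfg.master_seed, "pagel"))
        report["sections"]["pagel_allometry_x_guards"] = _pagel_dict(fit)
    else:
        report["sections"]["pagel_allometry_x_guards"] = {
            "skipped": "negative-allometry flag constant or too sparse"}
    # (e) target x larger guards
    if "lestrimelitta_target" in df and df["lestrimelitta_target"].notna().all():
        tg = BinaryStateVector({tip_label(s): int(bool(v)) for s, v in
                                zip(df["species"], df["lestrimelitta_target"])},
                               "target of Lestrimelitta")
        fit = comparative.pagel_fit(tree, tg, lg,
                                    seed=derive_seed(cfg.master_seed, "pagel"))
        d = _pagel_dict(fit)
        d["guard_gain_rate_in_targets"] = fit.rates_dependent["qB01_A1"]
        d["guard_gain_rate_in_nontargets"] = fit.rates_dependent["qB01_A0"]
        d["gain_rate_ordering_positive"] = bool(
            fit.rates_dependent["qB01_A1"] > fit.rates_dependent["qB01_A0"])
        report["sections"]["pagel_target_x_guards"] = d
    # (f) reconstruction of larger guards
    smap = phylo.stochastic_map(tree, lg, n_sim=cfg.n_sim,
                                seed=derive_seed(cfg.master_seed, "mapping"))
    mk1 = phylo.mk1_fit(tree, lg)
    report["sections"]["reconstruction_larger_guards"] = {
        "fitch_min_changes": phylo.fitch_count(tree, lg),
        "mk1_rate": mk1.rate,
        "mk1_log_likelihood": mk1.log_likelihood,
        "mk1_root_p1": mk1.marginal_node_probabilities[tree.root],
        "stochastic_map": smap.to_json_dict(),
    }
    return report


def _pgls_dict(fit: comparative.PGLSFit) -> dict:
    return {"coefficients": dict(zip(fit.names, fit.coefficients.tolist())),
            "standard_errors": dict(zip(fit.names, fit.standard_errors.tolist())),
            "t_values": dict(zip(fit.names, fit.t_values.tolist())),
            "p_values": dict(zip(fit.names, fit.p_values.tolist())),
            "df": fit.df, "r_squared": fit.r_squared}


def _pagel_dict(fit: comparative.PagelFit) -> dict:
    return {"logL_independent": fit.logL_independent,
            "logL_dependent": fit.logL_dependent,
            "likelihood_ratio": fit.likelihood_ratio,
            "df": fit.df, "p_value": fit.p_value,
            "rates_dependent": fit.rates_dependent}


def prune_tree(tree: PhyloTree, keep: List[str]) -> PhyloTree:
    """Subtree induced by a tip subset (degree-2 nodes collapsed, lengths summed)."""
    keep_set = set(keep)
    missing = keep_set - set(tree.tip_labels)
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)}")
    keep_node = np.zeros(tree.n_nodes, bool)
    for v in tree.postorder:
        if tree.is_tip(v):
            keep_node[v] = tree.label[v] in keep_set
        else:
            keep_node[v] = any(keep_node[c] for c in tree.children[v])
    # rebuild, collapsing internal nodes with a single kept child
    parent_map: Dict[int, int] = {}
    new_parent: List[int] = []
    new_len: List[float] = []
    new_label: List[Optional[str]] = []

    def build(v: int, plen: float, new_p: int) -> None:
        kept_kids = [c for c in tree.children[v]] if not tree.is_tip(v) else []
        kept_kids = [c for c in kept_kids if keep_node[c]]
        if tree.is_tip(v) or len(kept_kids) >= 2:
            idx = len(new_parent)
            new_parent.append(new_p)
            new_len.append(plen)
            new_label.append(tree.label[v])
            for c in kept_kids:
                build(c, float(tree.length[c]), idx)
        else:  # single kept child: splice through
            c = kept_kids[0]
            build(c, plen + float(tree.length[c]), new_p)

    root_kids = [c for c in tree.children[tree.root] if keep_node[c]]
    if len(root_kids) >= 2:
        build(tree.root, 0.0, -1)
    else:
        v = root_kids[0]
        while True:
            kids = [c for c in tree.children[v] if keep_node[c]]
            if tree.is_tip(v) or len(kids) >= 2:
                break
            v = kids[0]
        build(v, 0.0, -1)
    return PhyloTree(np.array(new_parent), np.array(new_len), new_label)


# ---------------------------------------------------------------------------
# Full run + CLI
# ---------------------------------------------------------------------------

def run_full(config: AnalysisConfig) -> dict:
    """Fixture-or-file full pipeline; returns the written report as a dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=out / "beecastes.log", level=logging.INFO,
                        format="%(asctime)s %(levelname)s %(message)s")
    if config.morph_csv:
        records = morpho.read_morph_csv(config.morph_csv)
        summary = run_species_tests(records, config.alpha)
        summary["lestrimelitta_target"] = pd.NA
    else:
        fx = build_study_fixture(config.within_genus_divergence, config.alpha)
        summary = flags_from_reference(fx.table, config.alpha)
    if config.tree_file:
        tree = phylo.parse_newick(Path(config.tree_file).read_text())
    else:
        tree = synth.fixture_tree(config.within_genus_divergence)
    trait_table = pd.read_csv(config.trait_csv) if config.trait_csv else None
    logger.info("run_full: seed=%d alpha=%s tree=%s", config.master_seed,
                config.alpha, tree_hash(tree))
    ct = crosstab_targets(summary) if summary["lestrimelitta_target"].notna().all() \
        else None
    report = {
        "config": dataclasses.asdict(config),
        "species_summary_counts": {
            "n_species": int(len(summary)),
            "larger_guards": int(summary["larger_guards"].sum()),
            "genera_with_larger_guards": genus_count(flags_from_reference(summary)
                                                     if "genus" not in summary
                                                     else summary),
            "negative_allometry": int(summary["negative_allometry"].eq(True).sum()),
        },
        "crosstab": None if ct is None else {
            "counts": ct.counts.to_numpy().tolist(),
            "row_percent": ct.row_percent.to_numpy().tolist(),
            "n": ct.n},
        "comparative": run_comparative_suite(summary, tree, config, trait_table),
    }
    summary.to_csv(out / "species_summary.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    return report


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


@click.group()
def main() -> None:
    """Comparative morphometrics of stingless-bee soldier sub-castes."""


@main.command("simulate")
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--n-species", type=int, default=4, show_default=True)
@click.option("--di", type=float, default=1.0, show_default=True)
@click.option("--out", type=click.Path(), default="synthetic_morph.csv",
              show_default=True)
def cli_simulate(seed: int, n_species: int, di: float, out: str) -> None:
    """Write a synthetic individual-level morphometric CSV."""
    frames = []
    for i in range(n_species):
        spec = synth.SpeciesGeneratorSpec(species=f"Synthetica sp{i + 1}", di=di)
        frames.append(synth.generate_colony_dataset(
            spec, seed=derive_seed(seed, "colonies") + i))
    morpho.write_morph_csv(pd.concat(frames, ignore_index=True), out)
    synth.write_manifest(Path(out).with_suffix(".manifest.json"),
                         {"seed": seed, "n_species": n_species, "di": di})
    click.echo(f"wrote {out}")


@main.command("species-tests")
@click.argument("morph_csv", type=click.Path(exists=True))
@click.option("--alpha", type=float, default=0.05, show_default=True)
@click.option("--out", type=click.Path(), default="species_summary.csv",
              show_default=True)
def cli_species_tests(morph_csv: str, alpha: float, out: str) -> None:
    """Guard-vs-forager tests from an individual-level CSV."""
    summary = run_species_tests(morpho.read_morph_csv(morph_csv), alpha)
    summary.to_csv(out, index=False)
    click.echo(f"wrote {out} ({int(summary['larger_guards'].sum())} species "
               "with larger guards)")


@main.command("comparative")
@click.argument("summary_csv", type=click.Path(exists=True))
@click.option("--tree", "tree_file", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--nsim", type=int, default=1000, show_default=True)
@click.option("--out", type=click.Path(), default="comparative_report.json",
              show_default=True)
def cli_comparative(summary_csv: str, tree_file: str, seed: int, nsim: int,
                    out: str) -> None:
    """Phylogenetically controlled suite from a species summary CSV."""
    summary = pd.read_csv(summary_csv)
    tree = phylo.parse_newick(Path(tree_file).read_text())
    cfg = AnalysisConfig(master_seed=seed, n_sim=nsim)
    report = run_comparative_suite(summary, tree, cfg)
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    click.echo(f"wrote {out}")


@main.command("full")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--alpha", type=float, default=None)
@click.option("--nsim", type=int, default=None)
@click.option("--tree-variant", type=click.Choice(["default", "near-zero"]),
              default="default", show_default=True)
@click.option("--out", "output_dir", type=click.Path(), default=None)
def cli_full(config_path, seed, alpha, nsim, tree_variant, output_dir) -> None:
    """Full fixture (or configured) analysis; writes CSV + JSON reports."""
    cfg = AnalysisConfig.from_yaml(config_path) if config_path else AnalysisConfig()
    if seed is not None:
        cfg.master_seed = seed
    if alpha is not None:
        cfg.alpha = alpha
    if nsim is not None:
        cfg.n_sim = nsim
    if output_dir is not None:
        cfg.output_dir = output_dir
    if tree_variant == "near-zero":
        cfg.within_genus_divergence = phylo.BRANCH_LENGTH_FLOOR
    try:
        report = run_full(cfg)
    except FileNotFoundError as exc:
        raise click.ClickException(str(exc))
    c = report["species_summary_counts"]
    click.echo(f"{c['larger_guards']} of {c['n_species']} species with larger "
               f"guards ({c['genera_with_larger_guards']} genera); "
               f"{c['negative_allometry']} with negative allometry")


@main.command("fixture")
@click.option("--out-dir", type=click.Path(), default="fixture", show_default=True)
@click.option("--within-genus-divergence", type=float, default=2.0,
              show_default=True)
def cli_fixture(out_dir: str, within_genus_divergence: float) -> None:
    """Export the packaged reference table, tree and binary state vectors."""
    fx = build_study_fixture(within_genus_divergence)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx.table.to_csv(out / "species_summary_reference.csv", index=False)
    (out / "fixture_tree.nwk").write_text(fx.tree.to_newick() + "\n")
    pd.DataFrame({"species": list(fx.larger_guards.states),
                  "state": list(fx.larger_guards.states.values())}
                 ).to_csv(out / "larger_guards.csv", index=False)
    pd.DataFrame({"species": list(fx.lestrimelitta_target.states),
                  "state": list(fx.lestrimelitta_target.states.values())}
                 ).to_csv(out / "lestrimelitta_target.csv", index=False)
    click.echo(f"wrote fixture files to {out}")


def cli_main(argv: Optional[List[str]] = None) -> int:
    """Programmatic CLI entry point returning an exit code."""
    try:
        main.main(args=argv, standalone_mode=False)
        return 0
    except click.ClickException as exc:
        exc.show()
        return exc.exit_code or 1
    except SystemExit as exc:  # click --help etc.
        return int(exc.code or 0)
    except FileNotFoundError as exc:
        click.echo(str(exc), err=True)
        return 1


if __name__ == "__main__":
    sys.exit(cli_main())
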