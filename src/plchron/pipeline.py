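"""Configuration-driven command-line orchestration.

Subcommands tie the library stages into complete dating analyses:

- ``date``       cross-validate the smoothing parameter, date at the
                 optimum, run diagnostics, optionally bootstrap.
- ``pergene``    the same per gene over a directory of alignments, with
                 aggregate age percentiles.
- ``subsample``  fixed-length column subsamples, each dated in full.
- ``simulate``   write a synthetic scenario (tree, alignment, calibrations).
- ``diagnose``   smoothing sweep + stem/crown rate-ratio sweep + QQ table.
- ``ortho-filter`` run the 1:1 orthogroup cascade over gene trees.
- ``aln-stats``  site-class and completeness summary of an alignment.

Configs are YAML; all tables are TSV with a header comment carrying a hash
of the config so outputs are traceable; trees are written as nexus with
ages and rates as node comments. Everything is deterministic given the
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment_stats import read_fasta, site_classes, completeness, \
    subsample_columns
from .branch_lengths import SubstitutionModel, fit_branch_lengths
from .diagnostics import (
    clade_path_ratio,
    crown_to_stem_length_ratio,
    lognormal_qq,
    rate_ratio_table,
    stem_crown_ratio_sweep,
)
from .orthology import (
    extract_one_to_one,
    filter_orthogroups,
    midpoint_root_if_unrooted,
    monophyly_filter,
    prune_monospecific_clades,
)
from .phylo_core import CalibrationSet, leaf_labels, read_tree, write_tree
from .pl_dating import (
    PLError,
    bootstrap_dates,
    cross_validate,
    default_lambda_grid,
    fit_pl,
    gradient_check,
    smoothing_sweep,
)
from .synthetic_data import (
    apply_rates,
    paper_scenario,
    simulate_alignment,
    to_phylogram,
)

logger = logging.getLogger("plchron")


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise click.ClickException("config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def calibrations_from_config(cfg: dict) -> CalibrationSet:
    cals = CalibrationSet()
    for entry in cfg.get("calibrations", []):
        cals.add(entry["taxa"], entry.get("min"), entry.get("max"))
    if not len(cals):
        raise click.ClickException("config defines no calibrations")
    return cals


def lambda_grid_from_config(cfg: dict) -> np.ndarray:
    spec = cfg.get("lambda_grid")
    if spec is None:
        return default_lambda_grid()
    lo, hi = float(spec.get("min_exp", -2)), float(spec.get("max_exp", 6))
    step = float(spec.get("step", 0.5))
    return 10.0 ** np.arange(lo, hi + step / 2, step)


def write_tsv(df: pd.DataFrame, path: Path, chash: str):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# plchron {__version__} config={chash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _setup_logging(level: str, out_dir: Path | None):
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(message)s",
        stream=sys.stderr,
        force=True,
    )
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_dir / "run.log", mode="w")
        fh.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logging.getLogger().addHandler(fh)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("--seed", default=1, show_default=True, type=int)
@click.option("--threads", default=1, show_default=True, type=int,
              help="Accepted for interface stability; execution is serial.")
@click.option("--out", default="plchron_out", show_default=True,
              type=click.Path())
@click.option("--log-level", default="INFO", show_default=True)
@click.pass_context
def main(ctx, seed, threads, out, log_level):
    """Penalized-likelihood dating pipeline."""
    ctx.ensure_object(dict)
    ctx.obj["seed"] = seed
    ctx.obj["out"] = Path(out)
    _setup_logging(log_level, Path(out))
    logger.info("plchron %s seed=%d", __version__, seed)


def _load_dating_inputs(cfg):
    tree = read_tree(Path(cfg["tree"]).read_text(), require_lengths=True)
    aln = None
    if cfg.get("alignment"):
        aln = read_fasta(Path(cfg["alignment"]).read_text())
        tree_taxa = set(leaf_labels(tree))
        if set(aln.taxa) != tree_taxa:
            raise click.ClickException(
                "alignment taxa do not match tree leaves"
            )
    L = cfg.get("L") or (aln.length if aln is not None else None)
    if L is None:
        raise click.ClickException("need an alignment or an explicit L")
    cals = calibrations_from_config(cfg)
    clade = cfg.get("clade")
    if not clade:
        raise click.ClickException("config must name the target clade taxa")
    return tree, aln, float(L), cals, list(clade)


def run_date(cfg: dict, out_dir: Path, seed: int) -> dict:
    """cross_validate -> fit at optimum -> diagnostics -> optional bootstrap."""
    chash = config_hash(cfg)
    tree, aln, L, cals, clade = _load_dating_inputs(cfg)
    grid = lambda_grid_from_config(cfg)
    cv = cross_validate(tree, cals, L, lambdas=grid, seed=seed)
    write_tsv(cv.table(), out_dir / "cv.tsv", chash)
    fit = fit_pl(tree, cals, cv.optimum, L, seed=seed)
    diag = rate_ratio_table(tree, fit)
    write_tsv(diag, out_dir / "diagnostics.tsv", chash)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "dated.nex").write_text(write_tree(fit.chronogram, "nexus"))
    report = {
        "config_hash": chash,
        "optimum_lambda": cv.optimum,
        "crown_age": fit.node_age(clade),
        "gradient_check": bool(gradient_check(fit)),
        "objective": fit.objective,
    }
    boot = cfg.get("bootstrap")
    if boot and aln is not None:
        policy = boot.get("policy", "reuse")
        lam = cv.optimum if policy == "reuse" else "cv"
        bd = bootstrap_dates(
            aln, tree, cals, clade, lam, n=int(boot.get("n", 100)),
            seed=seed, optimize_model=bool(boot.get("optimize_model", True)),
            point_fit=fit,
        )
        write_tsv(
            pd.DataFrame({"replicate_age": bd.ages}),
            out_dir / "bootstrap.tsv", chash,
        )
        report["bootstrap"] = bd.summary()
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def run_pergene(cfg: dict, out_dir: Path, seed: int) -> dict:
    """Per-gene cross-validated dating with aggregate percentiles."""
    chash = config_hash(cfg)
    topo = read_tree(Path(cfg["tree"]).read_text())
    cals = calibrations_from_config(cfg)
    clade = list(cfg["clade"])
    grid = lambda_grid_from_config(cfg)
    gene_dir = Path(cfg["alignment_dir"])
    rows, failures = [], []
    for path in sorted(gene_dir.glob("*.fasta")):
        try:
            aln = read_fasta(path.read_text())
            gt = topo.clone(depth=1)
            gt.retain_taxa_with_labels(aln.taxa)
            bres = fit_branch_lengths(aln, gt)
            pcals = CalibrationSet()
            present = set(aln.taxa)
            for cal in cals:
                kept = set(cal.taxa) & present
                if kept:
                    pcals.add(kept, cal.min_age, cal.max_age)
            cv = cross_validate(bres.tree, pcals, aln.length,
                                lambdas=grid, seed=seed)
            fit = fit_pl(bres.tree, pcals, cv.optimum, aln.length, seed=seed)
            rows.append({
                "gene": path.stem,
                "optimum_lambda": cv.optimum,
                "crown_age": fit.node_age(set(clade) & present),
                "gradient_check": bool(gradient_check(fit)),
            })
        except (PLError, Exception) as exc:  # degrade gracefully per gene
            logger.warning("gene %s failed: %s", path.stem, exc)
            failures.append({"gene": path.stem, "error": str(exc)})
    table = pd.DataFrame(rows)
    write_tsv(table, out_dir / "pergene.tsv", chash)
    passing = table[table["gradient_check"]] if len(table) else table
    ages = passing["crown_age"].to_numpy() if len(passing) else np.array([])
    report = {
        "config_hash": chash,
        "n_genes": len(rows),
        "n_failed": len(failures),
        "n_passing_gradient": int(len(passing)),
        "failures": failures,
    }
    if len(ages):
        q = np.percentile(ages, [2.5, 25, 50, 75, 97.5])
        report["age_percentiles"] = {
            "p2.5": q[0], "p25": q[1], "median": q[2],
            "p75": q[3], "p97.5": q[4],
        }
        hist = passing["optimum_lambda"].value_counts().sort_index()
        write_tsv(
            hist.rename_axis("lambda").reset_index(name="n_genes"),
            out_dir / "lambda_histogram.tsv", chash,
        )
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def run_subsample(cfg: dict, out_dir: Path, seed: int) -> dict:
    """Date fixed-length column subsamples and summarize the spread."""
    chash = config_hash(cfg)
    tree, aln, _, cals, clade = _load_dating_inputs(cfg)
    sub = cfg.get("subsample", {})
    length = int(sub.get("length", aln.length))
    count = int(sub.get("count", 1))
    if count < 1:
        raise click.ClickException("need at least one subsample")
    grid = lambda_grid_from_config(cfg)
    rows = []
    for i in range(count):
        saln = subsample_columns(aln, length, seed * 1009 + i)
        bres = fit_branch_lengths(saln, tree)
        cv = cross_validate(bres.tree, cals, saln.length,
                            lambdas=grid, seed=seed)
        fit = fit_pl(bres.tree, cals, cv.optimum, saln.length, seed=seed)
        rows.append({
            "subsample": i,
            "optimum_lambda": cv.optimum,
            "crown_age": fit.node_age(clade),
        })
    table = pd.DataFrame(rows)
    write_tsv(table, out_dir / "subsamples.tsv", chash)
    report = {
        "config_hash": chash,
        "n_subsamples": count,
        "subsample_length": length,
        "mean_age": float(table["crown_age"].mean()),
        "sd_age": float(table["crown_age"].std(ddof=1))
        if count > 1 else 0.0,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


@main.command("date")
@click.argument("config", type=click.Path(exists=True))
@click.pass_context
def cmd_date(ctx, config):
    """Full dating run from a YAML config."""
    report = run_date(load_config(config), ctx.obj["out"], ctx.obj["seed"])
    click.echo(json.dumps(report, indent=2))


@main.command("pergene")
@click.argument("config", type=click.Path(exists=True))
@click.pass_context
def cmd_pergene(ctx, config):
    """Per-gene dating over a directory of alignments."""
    report = run_pergene(load_config(config), ctx.obj["out"], ctx.obj["seed"])
    click.echo(json.dumps(report, indent=2))


@main.command("subsample")
@click.argument("config", type=click.Path(exists=True))
@click.pass_context
def cmd_subsample(ctx, config):
    """Dating of fixed-length column subsamples."""
    report = run_subsample(
        load_config(config), ctx.obj["out"], ctx.obj["seed"]
    )
    click.echo(json.dumps(report, indent=2))


@main.command("simulate")
@click.option("--scenario", default="chloroplast-like", show_default=True,
              type=click.Choice(["chloroplast-like", "nuclear-like"]))
@click.option("--mode", default="poisson", show_default=True,
              type=click.Choice(["expectation", "poisson"]))
@click.option("--length", default=None, type=int,
              help="Override the scenario alignment length.")
@click.option("--with-alignment", is_flag=True,
              help="Also simulate a nucleotide alignment (same length).")
@click.pass_context
def cmd_simulate(ctx, scenario, mode, length, with_alignment):
    """Write a synthetic dating problem (tree, calibrations, optional
    alignment)."""
    seed, out_dir = ctx.obj["seed"], ctx.obj["out"]
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = paper_scenario(scenario, L=length)
    rated = apply_rates(bundle.chronogram, bundle.scenario, seed=seed)
    phylo = to_phylogram(rated, bundle.L, mode=mode, seed=seed)
    (out_dir / "phylogram.nwk").write_text(write_tree(phylo))
    (out_dir / "true_chronogram.nex").write_text(write_tree(rated, "nexus"))
    cal_doc = [
        {"taxa": sorted(c.taxa), "min": c.min_age, "max": c.max_age}
        for c in bundle.calibrations
    ]
    config = {
        "tree": str(out_dir / "phylogram.nwk"),
        "L": bundle.L,
        "calibrations": cal_doc,
        "clade": sorted(bundle.ingroup),
    }
    if with_alignment:
        model = SubstitutionModel(alpha=1.0)
        aln = simulate_alignment(phylo, model, bundle.L, seed=seed)
        from .alignment_stats import write_fasta

        (out_dir / "alignment.fasta").write_text(write_fasta(aln))
        config["alignment"] = str(out_dir / "alignment.fasta")
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config))
    click.echo(json.dumps({"out": str(out_dir), "L": bundle.L}))


@main.command("diagnose")
@click.argument("config", type=click.Path(exists=True))
@click.pass_context
def cmd_diagnose(ctx, config):
    """Smoothing sweep, stem/crown rate-ratio sweep and rate QQ tables."""
    cfg = load_config(config)
    seed, out_dir = ctx.obj["seed"], ctx.obj["out"]
    chash = config_hash(cfg)
    tree, _, L, cals, clade = _load_dating_inputs(cfg)
    grid = lambda_grid_from_config(cfg)
    sweep = smoothing_sweep(tree, cals, L, clade, lambdas=grid, seed=seed)
    write_tsv(sweep, out_dir / "age_sweep.tsv", chash)
    ratios = stem_crown_ratio_sweep(tree, cals, L, clade, grid, seed=seed)
    write_tsv(ratios, out_dir / "rho_sweep.tsv", chash)
    fit = fit_pl(tree, cals, grid[-1], L, seed=seed)
    rates = [nd.rate for nd in fit.chronogram.preorder_node_iter()
             if nd.parent_node is not None]
    qq = lognormal_qq(rates)
    write_tsv(qq.table(), out_dir / "rate_qq.tsv", chash)
    click.echo(json.dumps({"qq_r_squared": qq.r_squared}, indent=2))


@main.command("ortho-filter")
@click.argument("config", type=click.Path(exists=True))
@click.pass_context
def cmd_ortho_filter(ctx, config):
    """1:1 orthogroup extraction cascade over a directory of gene trees."""
    cfg = load_config(config)
    out_dir = ctx.obj["out"]
    chash = config_hash(cfg)
    tree_dir = Path(cfg["genetree_dir"])
    min_species = int(cfg.get("min_species", 0))
    required_all = cfg.get("required_all", [])
    required_any = cfg.get("required_any", [])
    constraints = [set(c) for c in cfg.get("monophyly_constraints", [])]
    rows = []
    for path in sorted(tree_dir.glob("*.nwk")):
        gt = read_tree(path.read_text())
        midpoint_root_if_unrooted(gt)
        pruned = prune_monospecific_clades(gt)
        groups = extract_one_to_one(pruned)
        kept = filter_orthogroups(groups, min_species,
                                  required_all, required_any)
        verdicts = monophyly_filter(gt, constraints) if constraints else []
        rows.append({
            "gene_tree": path.stem,
            "n_orthogroups": len(groups),
            "n_kept": len(kept),
            "monophyly_pass": all(verdicts) if verdicts else True,
        })
    table = pd.DataFrame(rows)
    write_tsv(table, out_dir / "orthogroups.tsv", chash)
    click.echo(table.to_string(index=False))


@main.command("aln-stats")
@click.argument("fasta", type=click.Path(exists=True))
@click.option("--ambiguity", default="missing", show_default=True,
              type=click.Choice(["missing", "state"]))
@click.pass_context
def cmd_aln_stats(ctx, fasta, ambiguity):
    """Site-class and completeness summary of an alignment."""
    aln = read_fasta(Path(fasta).read_text())
    stats = site_classes(aln, ambiguity=ambiguity)
    stats["completeness"] = completeness(aln)
    stats["n_taxa"] = aln.n_taxa
    click.echo(json.dumps(stats, indent=2))


if __name__ == "__main__":
    main()
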