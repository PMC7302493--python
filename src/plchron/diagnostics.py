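"""Relaxed-clock goodness-of-fit diagnostics.

The central quantity is the effective/assigned rate ratio of a branch,

    rho_k = (b_k / t_hat_k) / r_hat_k

the observed branch length divided by the fitted duration (the "effective"
rate), over the rate the dating model assigned. rho = 1 means the model
reproduces the branch exactly; rho well below 1 flags a branch the model
predicts to be much longer than observed — the signature of a lineage-
specific slowdown forced onto a smoothed-rate solution.

Also here: lognormal QQ summaries of branch-rate sets, and the raw
phylogram contrasts (path-length ratios between sister clades, crown/stem
length ratios) that motivate the rate-heterogeneity story.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phylo_core import TreeError, clade_leaves, mrca, root_to_tip_lengths
from .pl_dating import CalibrationSet, PLFit, fit_pl

__all__ = [
    "effective_rate_ratio",
    "rate_ratio_table",
    "stem_crown_ratio_sweep",
    "QQReport",
    "lognormal_qq",
    "clade_path_ratio",
    "crown_to_stem_length_ratio",
]


def _edge_map(tree):
    """clade leaf-set -> node, for matching edges across tree copies."""
    out = {}
    for nd in tree.preorder_node_iter():
        out[frozenset(clade_leaves(nd))] = nd
    return out


def effective_rate_ratio(phylogram, fit: PLFit, branch_taxa) -> float:
    """rho for the edge subtending the MRCA of ``branch_taxa``.

    ``phylogram`` supplies the observed length b; ``fit`` (a dated solution
    on the same topology) supplies the fitted duration and assigned rate.
    """
    obs_node = mrca(phylogram, branch_taxa)
    if obs_node.parent_node is None:
        raise TreeError("the root has no subtending branch")
    fit_node = mrca(fit.chronogram, set(clade_leaves(obs_node)))
    if fit_node.parent_node is None:
        raise TreeError("branch not present in the fitted chronogram")
    t_hat = fit_node.parent_node.age - fit_node.age
    if t_hat <= 0:
        raise TreeError("fitted duration is zero; rho undefined")
    b = obs_node.edge.length
    return float((b / t_hat) / fit_node.rate)


def rate_ratio_table(phylogram, fit: PLFit) -> pd.DataFrame:
    """rho for every non-root branch, keyed by the clade it subtends."""
    fit_edges = _edge_map(fit.chronogram)
    rows = []
    for nd in phylogram.preorder_node_iter():
        if nd.parent_node is None:
            continue
        key = frozenset(clade_leaves(nd))
        fnode = fit_edges[key]
        t_hat = fnode.parent_node.age - fnode.age
        # collapsed branches (duration at the numerical floor) have no
        # meaningful effective rate
        rho = np.nan
        if t_hat > 1e-6:
            rho = (nd.edge.length / t_hat) / fnode.rate
        rows.append(
            {
                "clade": "|".join(sorted(key)),
                "n_taxa": len(key),
                "b_observed": nd.edge.length,
                "t_fitted": t_hat,
                "rate_assigned": fnode.rate,
                "rho": rho,
            }
        )
    return pd.DataFrame(rows)


def _crown_edge_keys(phylogram, clade_taxa, crown_edges: str = "all"):
    clade_taxa = set(clade_taxa)
    node = mrca(phylogram, clade_taxa)
    if set(clade_leaves(node)) != clade_taxa:
        raise TreeError("clade is not monophyletic in this phylogram")
    keys = []
    for nd in node.preorder_iter():
        if nd is node:
            continue
        if crown_edges == "terminal" and not nd.is_leaf():
            continue
        keys.append(frozenset(clade_leaves(nd)))
    return node, keys


def stem_crown_ratio_sweep(
    phylogram,
    calibrations: CalibrationSet,
    L: float,
    clade_taxa,
    lambdas,
    restarts: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Stem rho and mean crown rho across a smoothing grid.

    The crown mean is the arithmetic mean of rho over every edge whose child
    node lies inside the clade's crown group.
    """
    node, crown_keys = _crown_edge_keys(phylogram, clade_taxa)
    rows = []
    for lam in np.asarray(lambdas, float):
        fit = fit_pl(phylogram, calibrations, lam, L,
                     restarts=restarts, seed=seed)
        table = rate_ratio_table(phylogram, fit)
        by_key = {
            frozenset(c.split("|")): r for c, r in
            zip(table["clade"], table["rho"])
        }
        stem = by_key[frozenset(clade_taxa)]
        crown = float(np.nanmean([by_key[k] for k in crown_keys]))
        rows.append({"lambda": lam, "stem_rho": stem, "crown_mean_rho": crown})
    return pd.DataFrame(rows)


@dataclass
class QQReport:
    theoretical: np.ndarray
    empirical: np.ndarray  # ordered log10 rates
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool
    flagged: dict

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"normal_quantile": self.theoretical,
             "log10_rate": self.empirical}
        )


def lognormal_qq(rates, flag: dict | None = None) -> QQReport:
    """QQ comparison of log10 branch rates against a normal distribution.

    Plotting positions are Blom's ((i - 3/8)/(n + 1/4)). ``flag`` maps
    display names to rate values whose quantile positions are reported
    (e.g. the stem branch). A straight QQ line (high R^2) is the signature
    of lognormally distributed rates.
    """
    rates = np.asarray(rates, float)
    if len(rates) < 3:
        raise ValueError("need at least 3 rates")
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    logr = np.sort(np.log10(rates))
    n = len(logr)
    positions = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = stats.norm.ppf(positions)
    if np.allclose(logr, logr[0]):
        return QQReport(theo, logr, 0.0, float(logr[0]), 1.0, True,
                        flagged={})
    slope, intercept, r, _, _ = stats.linregress(theo, logr)
    flagged = {}
    if flag:
        for name, value in flag.items():
            rank = int(np.searchsorted(logr, np.log10(value)))
            rank = min(rank, n - 1)
            flagged[name] = {
                "log10_rate": float(np.log10(value)),
                "normal_quantile": float(theo[rank]),
                "rank": rank,
            }
    return QQReport(theo, logr, float(slope), float(intercept),
                    float(r ** 2), False, flagged)


def clade_path_ratio(phylogram, cladeA_taxa, cladeB_taxa) -> float:
    """Mean root-to-tip path length of clade A over clade B, both measured
    from their joint MRCA (substitutions accumulated since divergence)."""
    a, b = set(cladeA_taxa), set(cladeB_taxa)
    if a & b:
        raise TreeError("clades overlap")
    joint = mrca(phylogram, a | b)
    paths = root_to_tip_lengths(phylogram, joint)
    mean_a = float(np.mean([paths[t] for t in a]))
    mean_b = float(np.mean([paths[t] for t in b]))
    if mean_b == 0:
        raise TreeError("zero path length in denominator clade")
    return mean_a / mean_b


def crown_to_stem_length_ratio(
    phylogram, clade_taxa, crown_edges: str = "all"
) -> float:
    """Mean crown branch length over stem branch length for a clade.

    ``crown_edges`` selects the averaging set: "all" (default; every edge
    whose child node is inside the crown group) or "terminal" (tip edges
    only).
    """
    clade_taxa = set(clade_taxa)
    if len(clade_taxa) < 2:
        raise TreeError("a single-tip clade has no crown")
    node, keys = _crown_edge_keys(phylogram, clade_taxa, crown_edges)
    if node.parent_node is None:
        raise TreeError("clade is the whole tree; no stem branch")
    stem = node.edge.length
    if not stem:
        raise TreeError("zero-length stem branch")
    lengths = []
    for nd in node.preorder_iter():
        if nd is node:
            continue
        if crown_edges == "terminal" and not nd.is_leaf():
            continue
        lengths.append(nd.edge.length)
    return float(np.mean(lengths) / stem)
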