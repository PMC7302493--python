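"""Penalized-likelihood divergence dating with cross-validated smoothing.

Given a rooted phylogram with branch lengths b_k (expected substitutions per
site), an alignment length L, and fossil calibrations, the method estimates
node ages t and per-branch absolute rates r by maximizing

    sum_k [ x_k * ln(r_k * t_k) - r_k * t_k ]  -  lambda * Phi(r)

where x_k = b_k * L is the (real-valued) expected substitution count on
branch k, t_k is the branch duration implied by the ages, and Phi is the
additive roughness penalty: the squared rate difference between every edge
and its parent edge, plus the sample variance of the rates of the root's
child edges. Large lambda forces a near-clock; small lambda lets every
branch take its own rate.

Inside the objective the rates r_k are on the substitution-count scale
(counts per Myr, so the unpenalized optimum is r_k = x_k / t_k); this is
the scale on which half-decade smoothing grids spanning 10^-2..10^6
interpolate between free rates and a clock, and it makes the fit invariant
to trading branch-length scale against alignment length (b -> c*b,
L -> L/c). Reported chronogram rates are converted to
substitutions/site/Myr.

The ordered-age constraint is handled by construction: each internal node's
age is encoded as a proportion of its feasible window (bounded above by its
parent's age and any calibration maximum, below by the oldest calibration
minimum in its subtree), turning the problem into a box-constrained one
solved with L-BFGS-B from multiple perturbed starts.

The smoothing parameter is chosen by leave-one-terminal-out cross
validation: each terminal branch is pruned, the model is refit, and the
pruned branch's substitution count is predicted from the refit rate and
duration at its attachment point; the chi-squared-style prediction error
summed over terminals scores each lambda.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .alignment_stats import AlignmentMatrix, bootstrap_columns
from .branch_lengths import SubstitutionModel, fit_branch_lengths
from .phylo_core import (
    CalibrationSet,
    TreeError,
    clade_leaves,
    leaf_labels,
    mrca,
)

logger = logging.getLogger("plchron")

__all__ = [
    "PLError",
    "PLFit",
    "CVResult",
    "BootstrapDates",
    "default_lambda_grid",
    "pl_objective",
    "fit_pl",
    "gradient_check",
    "cross_validate",
    "smoothing_sweep",
    "bootstrap_dates",
]

DEFAULT_T_FLOOR = 1e-6  # Myr; avoids log singularities on collapsed branches


class PLError(RuntimeError):
    pass


try:  # JIT the hot objective/gradient kernel when numba is available
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@_njit(cache=False)
def _pl_kernel(params, lam, n, root, parent, internals, floor, cal_max,
               edges, x, t_floor, scale, root_children, pen_j, pen_k):
    """Negative normalized PL objective and gradient wrt (p, log-rates)."""
    n_int = internals.shape[0]
    n_edge = edges.shape[0]
    p = params[:n_int]
    ages = np.zeros(n)
    for k in range(n_int):
        i = internals[k]
        lo = floor[i]
        if i == root:
            hi = cal_max[i]
        else:
            hi = ages[parent[i]]
            if cal_max[i] < hi:
                hi = cal_max[i]
        width = hi - lo
        if width < 0.0:
            width = 0.0
        ages[i] = lo + p[k] * width
    rates = np.zeros(n)
    for k in range(n_edge):
        rates[edges[k]] = np.exp(params[n_int + k])

    ll = 0.0
    g_age = np.zeros(n)
    dll_dr = np.zeros(n)
    for k in range(n_edge):
        e = edges[k]
        t = ages[parent[e]] - ages[e]
        teff = t if t > t_floor else t_floor
        r = rates[e]
        rt = r * teff
        if x[e] > 0.0:
            ll += x[e] * np.log(rt)
        ll -= rt
        dll_dr[e] = (x[e] / r if x[e] > 0.0 else 0.0) - teff
        if t > t_floor:
            d = (x[e] / teff if x[e] > 0.0 else 0.0) - r
            g_age[parent[e]] += d
            g_age[e] -= d

    phi = 0.0
    dphi = np.zeros(n)
    for m in range(pen_j.shape[0]):
        j = pen_j[m]
        k = pen_k[m]
        dr = rates[j] - rates[k]
        phi += dr * dr
        dphi[j] += 2.0 * dr
        dphi[k] -= 2.0 * dr
    nc = root_children.shape[0]
    if nc >= 2:
        mean = 0.0
        for m in range(nc):
            mean += rates[root_children[m]]
        mean /= nc
        var = 0.0
        for m in range(nc):
            d = rates[root_children[m]] - mean
            var += d * d
        phi += var / (nc - 1)
        for m in range(nc):
            c = root_children[m]
            dphi[c] += 2.0 * (rates[c] - mean) / (nc - 1)

    f = ll - lam * phi
    grad = np.zeros(n_int + n_edge)
    for k in range(n_edge):
        e = edges[k]
        grad[n_int + k] = (dll_dr[e] - lam * dphi[e]) * rates[e]
    for k in range(n_int - 1, -1, -1):
        i = internals[k]
        lo = floor[i]
        if i == root:
            grad[k] = g_age[i] * (cal_max[i] - lo)
        else:
            par = parent[i]
            hi = ages[par]
            if cal_max[i] < hi:
                hi = cal_max[i]
            width = hi - lo
            if width < 0.0:
                width = 0.0
            grad[k] = g_age[i] * width
            if ages[par] <= cal_max[i]:
                g_age[par] += g_age[i] * p[k]
    return -f / scale, -grad / scale


def default_lambda_grid() -> np.ndarray:
    """10^-2 ... 10^6 in half-decade steps (17 values, endpoints included)."""
    return 10.0 ** np.arange(-2.0, 6.25, 0.5)


# ---------------------------------------------------------------------------
# Indexed problem
# ---------------------------------------------------------------------------

class _PLProblem:
    """Flat-array view of a phylogram plus calibrations.

    Node order is dendropy postorder; the root is the last index. Every
    non-root node indexes the edge to its parent. Parameters are
    ``[p_internal..., u_edges...]`` with p the age proportions (root first)
    and u = log rate.
    """

    def __init__(self, phylogram, calibrations: CalibrationSet | None,
                 L: float, t_floor: float = DEFAULT_T_FLOOR,
                 require_bounded_root: bool = True):
        if L <= 0:
            raise PLError("alignment length L must be positive")
        self.tree = phylogram.clone(depth=1)
        self.L = float(L)
        self.t_floor = float(t_floor)
        self.nodes = list(self.tree.postorder_node_iter())
        self.n = len(self.nodes)
        self.root = self.n - 1
        index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.parent = np.array(
            [index[id(nd.parent_node)] if nd.parent_node else -1
             for nd in self.nodes]
        )
        self.is_tip = np.array([nd.is_leaf() for nd in self.nodes])
        self.b = np.zeros(self.n)
        for i, nd in enumerate(self.nodes):
            if i != self.root:
                if nd.edge.length is None:
                    raise TreeError("phylogram edge without length")
                self.b[i] = nd.edge.length
        self.edges = np.array([i for i in range(self.n) if i != self.root])
        self.x = self.b * self.L  # expected substitution counts
        self.scale = 1.0 + float(self.x.sum())
        # internals in parent-before-child order (reverse postorder)
        self.internals = np.array(
            [i for i in range(self.n - 1, -1, -1) if not self.is_tip[i]]
        )
        self.n_internal = len(self.internals)
        self.n_edges = len(self.edges)
        self.root_children = [i for i in range(self.n)
                              if self.parent[i] == self.root]
        self._apply_calibrations(calibrations or CalibrationSet(),
                                 require_bounded_root)
        # flat arrays for the JIT kernel
        pe = self.parent[self.edges]
        mask = pe != self.root
        self._pen_j = pe[mask].astype(np.int64)
        self._pen_k = self.edges[mask].astype(np.int64)
        self._root_children = np.asarray(self.root_children, dtype=np.int64)
        self._edges64 = self.edges.astype(np.int64)
        self._internals64 = self.internals.astype(np.int64)
        self._parent64 = self.parent.astype(np.int64)

    # -- calibrations -------------------------------------------------------

    def _apply_calibrations(self, calibrations: CalibrationSet,
                            require_bounded_root: bool = True):
        cal_min = np.zeros(self.n)
        cal_max = np.full(self.n, np.inf)
        labels = set(leaf_labels(self.tree))
        index = {id(nd): i for i, nd in enumerate(self.nodes)}
        for cal in calibrations:
            missing = set(cal.taxa) - labels
            if missing:
                raise TreeError(
                    f"calibration taxa absent from tree: {sorted(missing)}"
                )
            node = mrca(self.tree, cal.taxa)
            i = index[id(node)]
            if self.is_tip[i]:
                raise PLError(
                    "calibration resolves to a terminal node; extant tips "
                    "are fixed at age 0"
                )
            if cal.min_age is not None:
                cal_min[i] = max(cal_min[i], cal.min_age)
            if cal.max_age is not None:
                cal_max[i] = min(cal_max[i], cal.max_age)
        # propagate minimum ages rootward
        floor = cal_min.copy()
        for i in range(self.n):  # postorder: children first
            p = self.parent[i]
            if p >= 0:
                floor[p] = max(floor[p], floor[i])
        if np.any(floor > cal_max + 1e-12):
            raise PLError("infeasible calibrations: a minimum age exceeds "
                          "a maximum age on the same lineage")
        if require_bounded_root and not np.isfinite(cal_max[self.root]):
            raise PLError(
                "the root age is unbounded above; add a maximum-age "
                "calibration on the root or an ancestor of every tip"
            )
        self.floor = floor
        self.cal_max = cal_max

    # -- parameter <-> age mapping -----------------------------------------

    def ages_from_p(self, p: np.ndarray) -> np.ndarray:
        ages = np.zeros(self.n)
        for k, i in enumerate(self.internals):
            lo = self.floor[i]
            hi = self.cal_max[i] if i == self.root else min(
                ages[self.parent[i]], self.cal_max[i]
            )
            width = max(hi - lo, 0.0)
            ages[i] = lo + p[k] * width
        return ages

    def p_from_ages(self, ages: np.ndarray) -> np.ndarray:
        p = np.full(self.n_internal, 0.5)
        for k, i in enumerate(self.internals):
            lo = self.floor[i]
            hi = self.cal_max[i] if i == self.root else min(
                ages[self.parent[i]], self.cal_max[i]
            )
            width = hi - lo
            if width > 0:
                p[k] = np.clip((ages[i] - lo) / width, 1e-6, 1 - 1e-6)
        return p

    # -- objective ----------------------------------------------------------

    def objective_parts(self, ages: np.ndarray, rates_by_node: np.ndarray,
                        lam: float):
        """(log-likelihood, penalty) for edge rates indexed by child node."""
        e = self.edges
        t = ages[self.parent[e]] - ages[e]
        if np.any(t < -1e-9):
            raise PLError("negative branch duration")
        teff = np.maximum(t, self.t_floor)
        r = rates_by_node[e]
        rt = r * teff
        ll = float(np.sum(np.where(self.x[e] > 0,
                                   self.x[e] * np.log(rt), 0.0) - rt))
        phi = 0.0
        pe = self.parent[e]
        has_parent_edge = pe != self.root
        dr = rates_by_node[pe[has_parent_edge]] - r[has_parent_edge]
        phi += float(np.sum(dr * dr))
        rc = rates_by_node[self.root_children]
        if len(rc) >= 2:
            phi += float(np.var(rc, ddof=1))
        return ll, phi

    def neg_objective_and_grad(self, params: np.ndarray, lam: float):
        """Normalized negative objective and its gradient wrt (p, u)."""
        if _HAVE_NUMBA:
            return _pl_kernel(
                np.asarray(params, float), float(lam), self.n, self.root,
                self._parent64, self._internals64, self.floor, self.cal_max,
                self._edges64, self.x, self.t_floor, self.scale,
                self._root_children, self._pen_j, self._pen_k,
            )
        return self._neg_objective_and_grad_numpy(params, lam)

    def _neg_objective_and_grad_numpy(self, params: np.ndarray, lam: float):
        p = params[: self.n_internal]
        u = params[self.n_internal:]
        ages = self.ages_from_p(p)
        rates = np.zeros(self.n)
        rates[self.edges] = np.exp(u)

        e = self.edges
        t = ages[self.parent[e]] - ages[e]
        teff = np.maximum(t, self.t_floor)
        r = rates[e]
        x = self.x[e]
        rt = r * teff
        ll = np.sum(np.where(x > 0, x * np.log(rt), 0.0) - rt)

        # gradient of LL wrt rates and durations
        dll_dr = np.where(x > 0, x / r, 0.0) - teff
        dll_dt = np.where(t > self.t_floor, np.where(x > 0, x / teff, 0.0) - r,
                          0.0)

        # penalty
        pe = self.parent[e]
        mask = pe != self.root
        j = pe[mask]  # parent-edge node index
        k = e[mask]
        dr = rates[j] - rates[k]
        phi = np.sum(dr * dr)
        dphi = np.zeros(self.n)
        np.add.at(dphi, j, 2.0 * dr)
        np.add.at(dphi, k, -2.0 * dr)
        rc = np.asarray(self.root_children)
        if len(rc) >= 2:
            m = rates[rc].mean()
            phi += np.var(rates[rc], ddof=1)
            dphi[rc] += 2.0 * (rates[rc] - m) / (len(rc) - 1)

        f = ll - lam * phi

        # assemble gradient wrt u = log r
        df_dr = np.zeros(self.n)
        df_dr[e] = dll_dr
        df_dr -= lam * dphi
        grad_u = df_dr[e] * r

        # backprop durations -> ages -> p
        g_age = np.zeros(self.n)
        np.add.at(g_age, self.parent[e], dll_dt)
        np.add.at(g_age, e, -dll_dt)
        grad_p = np.zeros(self.n_internal)
        for k in range(self.n_internal - 1, -1, -1):  # children before parents
            i = self.internals[k]
            lo = self.floor[i]
            if i == self.root:
                width = self.cal_max[i] - lo
                grad_p[k] = g_age[i] * width
            else:
                par = self.parent[i]
                hi = min(ages[par], self.cal_max[i])
                width = max(hi - lo, 0.0)
                grad_p[k] = g_age[i] * width
                if ages[par] <= self.cal_max[i]:
                    g_age[par] += g_age[i] * p[k]
        s = self.scale
        grad = np.concatenate([grad_p, grad_u])
        return -f / s, -grad / s

    # -- initialization -----------------------------------------------------

    def initial_params(self) -> np.ndarray:
        # mean distances: root->node and node->descendant tips
        d_root = np.zeros(self.n)
        for i in range(self.n - 1, -1, -1):
            p = self.parent[i]
            if p >= 0:
                d_root[i] = d_root[p] + self.b[i]
        m_tip = np.zeros(self.n)
        n_tip = np.zeros(self.n)
        for i in range(self.n):
            if self.is_tip[i]:
                n_tip[i] = 1.0
            p = self.parent[i]
            if p >= 0:
                m_tip[p] += m_tip[i] + self.b[i] * n_tip[i]
                n_tip[p] += n_tip[i]
        mean_below = np.where(n_tip > 0, m_tip / np.maximum(n_tip, 1), 0.0)

        root_lo = self.floor[self.root]
        root_hi = self.cal_max[self.root]
        a_root = 0.5 * (root_lo + root_hi)
        ages = np.zeros(self.n)
        for i in self.internals:
            if i == self.root:
                ages[i] = a_root
                continue
            denom = d_root[i] + mean_below[i]
            frac = mean_below[i] / denom if denom > 0 else 0.5
            target = ages[self.parent[i]] * frac
            lo = self.floor[i]
            hi = min(ages[self.parent[i]], self.cal_max[i])
            width = hi - lo
            if width > 0:
                target = np.clip(target, lo + 0.02 * width, hi - 0.02 * width)
            else:
                target = lo
            ages[i] = target
        p0 = self.p_from_ages(ages)
        e = self.edges
        t = np.maximum(ages[self.parent[e]] - ages[e], self.t_floor)
        # count-scale clock rate: total expected substitutions over total time
        r0 = max(self.x.sum() / max(t.sum(), self.t_floor), 1e-12)
        u0 = np.full(self.n_edges, np.log(r0))
        return np.concatenate([p0, u0])


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class PLFit:
    """A penalized-likelihood dating solution."""

    chronogram: dendropy.Tree
    lam: float
    L: float
    objective: float          # maximized (unnormalized) objective
    gradient_norm: float      # projected-gradient inf-norm, normalized scale
    converged: bool
    n_restarts: int
    restart_objectives: list = field(default_factory=list)
    restart_ages: list = field(default_factory=list)
    ages: np.ndarray | None = None
    rates: np.ndarray | None = None
    problem: object = field(default=None, repr=False)

    def node_age(self, taxa) -> float:
        return float(mrca(self.chronogram, taxa).age)

    def rate_of_edge(self, taxa) -> float:
        """Rate on the edge subtending the MRCA of ``taxa``."""
        node = mrca(self.chronogram, taxa)
        if node.parent_node is None:
            rates = [c.rate for c in node.child_nodes()]
            return float(np.mean(rates))
        return float(node.rate)


def pl_objective(phylogram, ages, rates, lam: float, L: float,
                 t_floor: float = DEFAULT_T_FLOOR) -> float:
    """Penalized log-likelihood at explicit ages and rates.

    ``ages`` and ``rates`` are per-node arrays in the tree's postorder
    indexing (root last; a non-root node's entry in ``rates`` is the rate of
    the edge to its parent, its entry in ``ages`` the node age in Ma; tip
    ages must be 0). Calibrations play no role in the score itself.
    """
    prob = _PLProblem(phylogram, None, L, t_floor,
                      require_bounded_root=False)
    ll, phi = prob.objective_parts(np.asarray(ages, float),
                                   np.asarray(rates, float), lam)
    return ll - lam * phi


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _projected_gradient_norm(params, grad, bounds) -> float:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    g = grad.copy()
    at_lo = (params <= lo + 1e-12) & (g > 0)
    at_hi = (params >= hi - 1e-12) & (g < 0)
    g[at_lo | at_hi] = 0.0
    return float(np.max(np.abs(g))) if len(g) else 0.0


def fit_pl(
    phylogram,
    calibrations: CalibrationSet | None,
    lam: float,
    L: float,
    restarts: int = 5,
    seed: int = 0,
    t_floor: float = DEFAULT_T_FLOOR,
    ftol: float = 1e-10,
    maxiter: int = 10000,
    warm_start: np.ndarray | None = None,
    _problem: _PLProblem | None = None,
) -> PLFit:
    """Maximize the penalized likelihood subject to calibrations.

    Runs ``restarts`` L-BFGS-B optimizations from the deterministic
    initialization plus seed-perturbed variants (and ``warm_start`` if
    given) and keeps the best. Extant tips are fixed at age 0.
    """
    prob = _problem or _PLProblem(phylogram, calibrations, L, t_floor)
    rng = np.random.default_rng(seed)
    x0 = prob.initial_params()
    starts = []
    if warm_start is not None and len(warm_start) == len(x0):
        starts.append(np.asarray(warm_start, float))
    if len(starts) < max(restarts, 1):
        starts.append(x0)
    # rate perturbations shrink with the penalty stiffness: at large lambda
    # the optimum rates differ by O(1/lambda), and large random rate offsets
    # put restarts on top of enormous penalty barriers they cannot descend
    # within the iteration budget
    sigma_u = 0.5 / (1.0 + lam) ** 0.25
    while len(starts) < max(restarts, 1):
        pert = x0.copy()
        npar = prob.n_internal
        pert[:npar] = np.clip(
            pert[:npar] + rng.uniform(-0.25, 0.25, npar), 1e-6, 1 - 1e-6
        )
        pert[npar:] = pert[npar:] + rng.normal(0.0, sigma_u, prob.n_edges)
        starts.append(pert)

    bounds = [(0.0, 1.0)] * prob.n_internal + [(-35.0, 8.0)] * prob.n_edges
    opts = {"maxiter": maxiter, "ftol": ftol, "gtol": 1e-10, "maxcor": 25}
    lo_b = np.array([b[0] for b in bounds])
    hi_b = np.array([b[1] for b in bounds])
    results = []
    for s in starts:
        res = minimize(
            prob.neg_objective_and_grad, np.clip(s, lo_b, hi_b),
            args=(lam,), method="L-BFGS-B", jac=True, bounds=bounds,
            options=opts,
        )
        # polish: fresh runs from the endpoint reset the Hessian
        # approximation and tighten the attainable precision (on which the
        # multi-restart agreement diagnostic and fine lambda-sweep
        # comparisons depend); repeat while it still helps
        for _ in range(3):
            res2 = minimize(
                prob.neg_objective_and_grad, res.x, args=(lam,),
                method="L-BFGS-B", jac=True, bounds=bounds, options=opts,
            )
            if res2.fun >= res.fun:
                break
            res = res2
        results.append(res)
    best = min(results, key=lambda r: r.fun)
    converged = any(r.success for r in results)
    if not converged:
        logger.warning("fit_pl: no restart reported convergence; "
                       "returning best point")

    p = best.x[: prob.n_internal]
    ages = prob.ages_from_p(p)
    rates = np.zeros(prob.n)
    rates[prob.edges] = np.exp(best.x[prob.n_internal:])
    f, g = prob.neg_objective_and_grad(best.x, lam)
    pgnorm = _projected_gradient_norm(best.x, g, bounds)

    chrono = prob.tree
    for i, nd in enumerate(prob.nodes):
        nd.age = float(ages[i])
        if i != prob.root:
            # internal rates are counts/Myr; report substitutions/site/Myr
            nd.rate = float(rates[i]) / prob.L
            nd.edge.length = float(ages[prob.parent[i]] - ages[i])
    restart_ages = []
    for r in results:
        restart_ages.append(prob.ages_from_p(r.x[: prob.n_internal]))
    return PLFit(
        chronogram=chrono,
        lam=lam,
        L=L,
        objective=float(-best.fun * prob.scale),
        gradient_norm=pgnorm,
        converged=converged,
        n_restarts=len(starts),
        restart_objectives=[float(-r.fun * prob.scale) for r in results],
        restart_ages=restart_ages,
        ages=ages,
        rates=rates,
        problem=prob,
    )


def gradient_check(
    fit: PLFit,
    grad_tol: float = 3e-4,
    obj_rtol: float = 1e-6,
    age_rtol: float = 1e-2,
) -> bool:
    """Single-optimum diagnostic.

    Passes when (a) the projected gradient at the solution is numerically
    zero and (b) no restart reaches an objective comparable to the best
    while ending at a different age vector. Flat rate/age ridges (typical
    at very low smoothing) produce exactly that signature — near-equal
    objectives at ages tens of Myr apart — and fail. Restarts trapped in
    clearly inferior local optima do not contradict the best solution and
    are ignored.

    The gradient tolerance scales with sqrt(1 + lambda): the curvature of
    the penalty grows with the smoothing weight, which bounds the gradient
    precision attainable at a fixed relative-objective stopping rule.
    """
    if fit.gradient_norm > grad_tol * math.sqrt(1.0 + fit.lam):
        return False
    objs = np.asarray(fit.restart_objectives)
    if len(objs) < 2:
        return False
    best = objs.max()
    best_idx = int(objs.argmax())
    ref_ages = fit.restart_ages[best_idx]
    scale = max(abs(ref_ages).max(), 1.0)
    for obj, ages in zip(objs, fit.restart_ages):
        near_best = abs(obj - best) <= obj_rtol * (1.0 + abs(best))
        same_ages = np.max(np.abs(ages - ref_ages)) <= age_rtol * scale
        if near_best and not same_ages:
            return False
    return True


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    lambdas: np.ndarray
    scores: np.ndarray
    gradient_ok: np.ndarray
    optimum: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "cv_score": self.scores,
                "gradient_check": self.gradient_ok,
            }
        )


def _prune_tip(tree, label):
    """Remove one leaf, suppressing the resulting unifurcation (edge lengths
    add).

    Returns ``(pruned tree, anchor_labels, below_labels, frac)``:
    ``anchor_labels`` identify the clade under the shallowest surviving
    ancestor of the pruned tip; when the tip's parent was suppressed into a
    merged edge, ``below_labels`` identify the clade below that edge and
    ``frac`` locates the attachment point on it (fraction of the merged
    branch length measured up from the child end), so the attachment age
    can be interpolated from the refit ages. Otherwise ``below_labels`` is
    None and the attachment age is the anchor node's age itself.
    """
    pruned = tree.clone(depth=1)
    leaf = next(nd for nd in pruned.leaf_node_iter()
                if nd.taxon.label == label)
    parent = leaf.parent_node
    parent.remove_child(leaf)
    anchor_parent = parent
    below_labels, frac = None, 0.0
    if len(parent.child_nodes()) == 1:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        if grand is None:
            # parent was the root: the remaining child becomes the new root
            parent.remove_child(only)
            pruned.seed_node = only
            only.parent_node = None
            below = only.edge.length or 0.0
            only.edge.length = None
            anchor_parent = None
            below_labels = [nd.taxon.label for nd in only.leaf_iter()]
            frac = 1.0  # attachment at the old root end
        else:
            extra = parent.edge.length or 0.0
            below = only.edge.length or 0.0
            grand.remove_child(parent)
            grand.add_child(only)
            only.edge.length = below + extra
            anchor_parent = grand
            below_labels = [nd.taxon.label for nd in only.leaf_iter()]
            total = below + extra
            frac = below / total if total > 0 else 0.5
    if anchor_parent is None:
        anchor_labels = [nd.taxon.label for nd in pruned.leaf_node_iter()]
    else:
        anchor_labels = [nd.taxon.label for nd in anchor_parent.leaf_iter()]
    return pruned, anchor_labels, below_labels, frac


def _filter_calibrations(calibrations, labels_present):
    kept = CalibrationSet()
    present = set(labels_present)
    for cal in calibrations:
        taxa = set(cal.taxa) & present
        if taxa:
            kept.add(taxa, cal.min_age, cal.max_age)
    return kept


def cross_validate(
    phylogram,
    calibrations: CalibrationSet,
    L: float,
    lambdas: np.ndarray | None = None,
    restarts: int = 3,
    cv_restarts: int = 1,
    seed: int = 0,
    t_floor: float = DEFAULT_T_FLOOR,
) -> CVResult:
    """Leave-one-terminal-out cross validation over the smoothing grid.

    For each lambda the full tree is fit (with a gradient check), then each
    terminal branch j is pruned and refit; the pruned branch's substitution
    count is predicted as r-hat (rate on the edge above the attachment node)
    times the attachment node's refit age times L, and scored as
    ``(x_j - xhat_j)^2 / xhat_j``. The optimum is the minimum-score lambda
    among those passing gradient checks.
    """
    if lambdas is None:
        lambdas = default_lambda_grid()
    lambdas = np.asarray(lambdas, float)
    tips = leaf_labels(phylogram)
    if len(tips) < 4:
        raise PLError("cross validation needs at least 4 terminal branches")

    # per-tip pruned problems, shared across lambdas
    pruned = {}
    for label in tips:
        ptree, anchor, below, frac = _prune_tip(phylogram, label)
        pcals = _filter_calibrations(calibrations, leaf_labels(ptree))
        prob = _PLProblem(ptree, pcals, L, t_floor)
        pruned[label] = (prob, anchor, below, frac)
    full_problem = _PLProblem(phylogram, calibrations, L, t_floor)
    x_by_label = {}
    for nd in phylogram.leaf_node_iter():
        x_by_label[nd.taxon.label] = nd.edge.length * L

    scores = np.zeros(len(lambdas))
    grad_ok = np.zeros(len(lambdas), dtype=bool)
    warm_full = None
    warm_tip = {label: None for label in tips}
    for li, lam in enumerate(lambdas):
        full_fit = fit_pl(
            phylogram, calibrations, lam, L, restarts=restarts, seed=seed,
            t_floor=t_floor, warm_start=warm_full, _problem=full_problem,
        )
        warm_full = np.concatenate([
            full_fit.problem.p_from_ages(full_fit.ages),
            np.log(np.maximum(full_fit.rates[full_fit.problem.edges], 1e-300)),
        ])
        grad_ok[li] = gradient_check(full_fit)
        total = 0.0
        for label in tips:
            prob, anchor, below, frac = pruned[label]
            pfit = fit_pl(
                prob.tree, None, lam, L, restarts=cv_restarts,
                seed=seed + 1, t_floor=t_floor,
                warm_start=warm_tip[label], _problem=prob,
            )
            warm_tip[label] = np.concatenate([
                prob.p_from_ages(pfit.ages),
                np.log(np.maximum(pfit.rates[prob.edges], 1e-300)),
            ])
            anchor_age = pfit.node_age(anchor)
            if below is None:
                t_hat = anchor_age
                r_hat = pfit.rate_of_edge(anchor)
            else:
                # attachment interpolated on the merged edge using the
                # observed branch lengths; rate of the merged edge
                below_age = pfit.node_age(below)
                t_hat = below_age + frac * (anchor_age - below_age)
                r_hat = pfit.rate_of_edge(below)
            x_hat = max(r_hat * t_hat * L, 1e-12)
            x_obs = x_by_label[label]
            total += (x_obs - x_hat) ** 2 / x_hat
        scores[li] = total
        logger.info("CV lambda=%g score=%.6g gradient_ok=%s",
                    lam, total, grad_ok[li])

    if not grad_ok.any():
        raise PLError("all smoothing values failed gradient checks")
    masked = np.where(grad_ok, scores, np.inf)
    optimum = float(lambdas[int(np.argmin(masked))])
    return CVResult(lambdas, scores, grad_ok, optimum)


def smoothing_sweep(
    phylogram,
    calibrations: CalibrationSet,
    L: float,
    node_taxa,
    lambdas: np.ndarray | None = None,
    restarts: int = 3,
    seed: int = 0,
    t_floor: float = DEFAULT_T_FLOOR,
) -> pd.DataFrame:
    """Fitted age of the MRCA of ``node_taxa`` across the smoothing grid."""
    if lambdas is None:
        lambdas = default_lambda_grid()
    lambdas = np.asarray(lambdas, float)
    problem = _PLProblem(phylogram, calibrations, L, t_floor)
    rows = []
    warm = None
    for lam in lambdas:
        fit = fit_pl(phylogram, calibrations, lam, L, restarts=restarts,
                     seed=seed, t_floor=t_floor, warm_start=warm,
                     _problem=problem)
        warm = np.concatenate([
            problem.p_from_ages(fit.ages),
            np.log(np.maximum(fit.rates[problem.edges], 1e-300)),
        ])
        rows.append(
            {
                "lambda": lam,
                "age": fit.node_age(node_taxa),
                "converged": fit.converged,
                "gradient_check": gradient_check(fit),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals
# ---------------------------------------------------------------------------

@dataclass
class BootstrapDates:
    node_taxa: tuple
    ages: np.ndarray
    point_estimate: float
    interval: tuple
    n_failed: int

    def summary(self) -> dict:
        return {
            "point": self.point_estimate,
            "ci_low": self.interval[0],
            "ci_high": self.interval[1],
            "n_replicates": len(self.ages),
            "n_failed": self.n_failed,
        }


def bootstrap_dates(
    aln: AlignmentMatrix,
    topology,
    calibrations: CalibrationSet,
    node_taxa,
    lam: float | str,
    n: int = 100,
    seed: int = 0,
    model: SubstitutionModel | None = None,
    optimize_model: bool = True,
    restarts: int = 2,
    L: float | None = None,
    point_fit: PLFit | None = None,
) -> BootstrapDates:
    """Nonparametric bootstrap CI on a node age.

    Each replicate resamples alignment columns, re-estimates branch lengths
    on the fixed topology, and re-dates. ``lam`` may be a number (reuse the
    original cross-validated optimum, the default policy) or ``"cv"`` to
    re-cross-validate inside every replicate. The 95% interval is the
    empirical 2.5/97.5 percentile pair.
    """
    if L is None:
        L = aln.length
    if point_fit is None:
        base = fit_branch_lengths(aln, topology, model=model,
                                  optimize_model=optimize_model)
        lam0 = lam if isinstance(lam, (int, float)) else cross_validate(
            base.tree, calibrations, L, seed=seed).optimum
        point_fit = fit_pl(base.tree, calibrations, lam0, L,
                           restarts=restarts, seed=seed)
    ages = []
    n_failed = 0
    for rep in range(n):
        rep_seed = seed * 100003 + rep
        try:
            baln = bootstrap_columns(aln, rep_seed)
            bres = fit_branch_lengths(baln, topology, model=model,
                                      optimize_model=optimize_model)
            if lam == "cv":
                lam_rep = cross_validate(bres.tree, calibrations, L,
                                         seed=rep_seed).optimum
            else:
                lam_rep = float(lam)
            bfit = fit_pl(bres.tree, calibrations, lam_rep, L,
                          restarts=restarts, seed=rep_seed)
            ages.append(bfit.node_age(node_taxa))
        except (PLError, TreeError, ValueError) as exc:
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
    if not ages:
        raise PLError("every bootstrap replicate failed")
    ages = np.asarray(ages)
    lo, hi = np.percentile(ages, [2.5, 97.5])
    return BootstrapDates(
        node_taxa=tuple(node_taxa),
        ages=ages,
        point_estimate=point_fit.node_age(node_taxa),
        interval=(float(lo), float(hi)),
        n_failed=n_failed,
    )
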