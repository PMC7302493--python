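"""Fixed-topology GTR+G+I likelihood and branch-length estimation.

Implements Felsenstein pruning with four discrete gamma rate categories
(equal-probability classes represented by their means) and a proportion of
invariant sites, plus a coordinate-wise optimizer that re-estimates branch
lengths on a constrained topology. Topology is never searched: the engine
exists to turn bootstrap pseudo-replicates and simulated alignments into
phylograms on a fixed tree.

Branch lengths are in expected substitutions per site for a site evolving at
the mean gamma rate; the rate matrix is normalized to mean rate 1 at the
stationary frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .alignment_stats import AlignmentMatrix
from .phylo_core import TreeError, leaf_labels

__all__ = [
    "SubstitutionModel",
    "log_likelihood",
    "fit_branch_lengths",
    "BranchFitResult",
]

MAX_BRANCH_LENGTH = 10.0
MIN_BRANCH_LENGTH = 1e-9

# IUPAC nucleotide codes -> allowed states over (A, C, G, T)
_CODE_STATES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", "X": "ACGT",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _leaf_partial_table() -> np.ndarray:
    """256 x 4 indicator table mapping a byte code to allowed states."""
    table = np.zeros((256, 4))
    for code, states in _CODE_STATES.items():
        row = np.zeros(4)
        for s in states:
            row[_BASE_INDEX[s]] = 1.0
        table[ord(code)] = row
        table[ord(code.lower())] = row
    return table

_LEAF_TABLE = _leaf_partial_table()


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR+G+I parameterization.

    exchangeabilities: 6 symmetric rates in the order AC, AG, AT, CG, CT, GT
    (GT conventionally fixed to 1); frequencies sum to 1; ``alpha`` is the
    gamma shape over ``ncat`` equal-probability categories; ``p_inv`` the
    proportion of invariant sites.
    """

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    frequencies: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: float = np.inf  # inf = no rate variation
    p_inv: float = 0.0
    ncat: int = 4

    def __post_init__(self):
        if len(self.exchangeabilities) != 6 or min(self.exchangeabilities) <= 0:
            raise ValueError("need 6 positive exchangeabilities")
        f = np.asarray(self.frequencies, float)
        if len(f) != 4 or abs(f.sum() - 1) > 1e-8 or f.min() <= 0:
            raise ValueError("frequencies must be 4 positive values summing to 1")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @classmethod
    def jc(cls, alpha: float = np.inf, p_inv: float = 0.0) -> "SubstitutionModel":
        return cls(alpha=alpha, p_inv=p_inv)

    def q_matrix(self) -> np.ndarray:
        """GTR rate matrix scaled to mean rate 1."""
        s = self.exchangeabilities
        pi = np.asarray(self.frequencies, float)
        ex = np.zeros((4, 4))
        ex[0, 1] = ex[1, 0] = s[0]
        ex[0, 2] = ex[2, 0] = s[1]
        ex[0, 3] = ex[3, 0] = s[2]
        ex[1, 2] = ex[2, 1] = s[3]
        ex[1, 3] = ex[3, 1] = s[4]
        ex[2, 3] = ex[3, 2] = s[5]
        q = ex * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def category_rates(self) -> np.ndarray:
        """Mean rates of the equal-probability gamma categories (mean 1)."""
        if not np.isfinite(self.alpha):
            return np.ones(1)
        a, k = self.alpha, self.ncat
        edges = _gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
        upper = np.concatenate([gammainc(a + 1, a * edges), [1.0]])
        lower = np.concatenate([[0.0], gammainc(a + 1, a * edges)])
        return k * (upper - lower)

    def eigensystem(self):
        """Symmetric-form eigendecomposition of Q for fast expm."""
        pi = np.asarray(self.frequencies, float)
        sq = np.sqrt(pi)
        b = (sq[:, None] / sq[None, :]) * self.q_matrix()
        b = (b + b.T) / 2.0
        w, v = np.linalg.eigh(b)
        left = v.T * sq[None, :]      # rows: V^T D^{1/2}
        right = v / sq[:, None]       # D^{-1/2} V
        return w, right, left


def transition_matrices(model: SubstitutionModel, lengths: np.ndarray) -> np.ndarray:
    """P(t * c) for every branch length and gamma category.

    Returns array of shape (n_edges, ncat, 4, 4).
    """
    w, right, left = model.eigensystem()
    rates = model.category_rates()
    t = np.asarray(lengths, float)[:, None, None] * rates[None, :, None]
    ew = np.exp(t * w[None, None, :])  # (edges, ncat, 4)
    p = np.einsum("il,ecl,lj->ecij", right, ew, left)
    return np.clip(p, 0.0, None)


# ---------------------------------------------------------------------------
# Pattern compression and likelihood
# ---------------------------------------------------------------------------

def _compress(aln: AlignmentMatrix, taxa_order):
    rows = np.stack([aln.row(t).view(np.uint8) for t in taxa_order])
    patterns, counts = np.unique(rows, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class _TreeIndex:
    """Flat postorder arrays for a fixed topology."""

    def __init__(self, tree):
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.parent = np.array(
            [
                self.index[id(nd.parent_node)] if nd.parent_node else -1
                for nd in self.nodes
            ]
        )
        self.is_leaf = np.array([nd.is_leaf() for nd in self.nodes])
        self.leaf_labels = [
            nd.taxon.label for nd in self.nodes if nd.is_leaf()
        ]
        self.children = [[] for _ in self.nodes]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.root = len(self.nodes) - 1
        self.edges = [i for i in range(len(self.nodes)) if i != self.root]

    def lengths(self):
        return np.array(
            [
                nd.edge.length if nd.edge.length is not None else 0.0
                for nd in self.nodes
            ]
        )


class _Pruner:
    """Holds compressed data and evaluates the pruning likelihood."""

    def __init__(self, aln: AlignmentMatrix, tree):
        tree_taxa = set(leaf_labels(tree))
        if tree_taxa != set(aln.taxa):
            raise TreeError(
                "alignment taxa do not match tree leaves: "
                f"{sorted(tree_taxa ^ set(aln.taxa))}"
            )
        self.ti = _TreeIndex(tree)
        order = [
            nd.taxon.label for nd in self.ti.nodes if nd.is_leaf()
        ]
        self.patterns, self.counts = _compress(aln, order)
        self.leaf_partials = {}
        row = 0
        for i, nd in enumerate(self.ti.nodes):
            if self.ti.is_leaf[i]:
                self.leaf_partials[i] = _LEAF_TABLE[self.patterns[row]]
                row += 1
        # intersection of allowed states per pattern, for the invariant class
        inter = np.ones((self.patterns.shape[1], 4))
        for part in self.leaf_partials.values():
            inter *= part
        self.invariant_mask = inter  # (npat, 4) 0/1

    @property
    def n_sites(self):
        return self.counts.sum()

    def _down_partials(self, pmats):
        """Conditional likelihoods below each node: dict i -> (ncat,npat,4)."""
        down = {}
        for i in range(len(self.ti.nodes)):
            if self.ti.is_leaf[i]:
                continue
            prod = None
            for c in self.ti.children[i]:
                if self.ti.is_leaf[c]:
                    child = self.leaf_partials[c][None, :, :]  # (1,npat,4)
                else:
                    child = down[c]
                msg = np.einsum("cij,cpj->cpi", pmats[c], child)
                prod = msg if prod is None else prod * msg
            down[i] = prod
        return down

    def site_likelihoods(self, model, pmats):
        pi = np.asarray(model.frequencies, float)
        down = self._down_partials(pmats)
        root = down[self.ti.root]  # (ncat, npat, 4)
        var_part = np.einsum("cpj,j->p", root, pi) / root.shape[0]
        inv_part = self.invariant_mask @ pi
        p_inv = model.p_inv
        return (1.0 - p_inv) * var_part + p_inv * inv_part

    def log_likelihood(self, model, lengths=None):
        if lengths is None:
            lengths = self.ti.lengths()
        pmats = transition_matrices(model, lengths)
        site_l = self.site_likelihoods(model, pmats)
        if np.any(site_l <= 0):
            return -np.inf
        return float(self.counts @ np.log(site_l))

    # -- per-edge machinery (outer partials) --------------------------------

    def _edge_messages(self, pmats, down):
        """msg[i] = P_i @ down_i for every non-root node i."""
        msg = {}
        for i in self.ti.edges:
            child = (
                self.leaf_partials[i][None, :, :]
                if self.ti.is_leaf[i]
                else down[i]
            )
            msg[i] = np.einsum("cij,cpj->cpi", pmats[i], child)
        return msg

    def _outer_partials(self, model, pmats, down, msg):
        """out[i]: likelihood of all data outside i's subtree, as a function
        of the state at i's parent (includes root frequencies)."""
        pi = np.asarray(model.frequencies, float)
        out = {}
        for i in reversed(range(len(self.ti.nodes))):  # preorder
            if i == self.ti.root:
                continue
            p = self.ti.parent[i]
            sib = np.ones_like(msg[i])
            for s in self.ti.children[p]:
                if s != i:
                    sib = sib * msg[s]
            if p == self.ti.root:
                out[i] = pi[None, None, :] * sib
            else:
                above = np.einsum("cpj,cji->cpi", out[p], pmats[p])
                out[i] = above * sib
        return out

    def edge_site_likelihoods(self, model, edge, length, out_e, down_e):
        pmat = transition_matrices(model, np.array([length]))[0]
        var = np.einsum("cpi,cij,cpj->p", out_e, pmat, down_e) / pmat.shape[0]
        inv = self.invariant_mask @ np.asarray(model.frequencies, float)
        return (1.0 - model.p_inv) * var + model.p_inv * inv


def log_likelihood(
    aln: AlignmentMatrix, phylogram, model: SubstitutionModel
) -> float:
    """GTR+G+I log-likelihood of an alignment on a fixed phylogram."""
    return _Pruner(aln, phylogram).log_likelihood(model)


# ---------------------------------------------------------------------------
# Branch-length fitting
# ---------------------------------------------------------------------------

@dataclass
class BranchFitResult:
    tree: object  # phylogram with fitted lengths
    model: SubstitutionModel
    log_likelihood: float
    converged: bool
    n_rounds: int


def empirical_frequencies(aln: AlignmentMatrix) -> tuple:
    counts = np.array(
        [(aln.data == b).sum() for b in (b"A", b"C", b"G", b"T")], float
    )
    counts += 1.0  # avoid zero frequencies on tiny alignments
    return tuple(counts / counts.sum())


def _optimize_model_params(pruner, model, lengths):
    """Bounded quasi-Newton on (log exchangeabilities, log alpha, logit p_inv);
    base frequencies stay empirical."""

    def unpack(theta):
        ex = tuple(np.exp(theta[:5])) + (1.0,)
        alpha = float(np.exp(theta[5]))
        p_inv = float(1.0 / (1.0 + np.exp(-theta[6])))
        return replace(model, exchangeabilities=ex, alpha=alpha,
                       p_inv=min(p_inv, 0.999))

    def negll(theta):
        try:
            return -pruner.log_likelihood(unpack(theta), lengths)
        except (ValueError, FloatingPointError):
            return np.inf

    ex0 = np.log(np.asarray(model.exchangeabilities[:5], float))
    a0 = np.log(model.alpha if np.isfinite(model.alpha) else 100.0)
    p0 = np.log(max(model.p_inv, 1e-4) / (1 - max(model.p_inv, 1e-4)))
    theta0 = np.concatenate([ex0, [a0, p0]])
    bounds = [(-7, 7)] * 5 + [(np.log(0.02), np.log(100.0)), (-9, 5)]
    res = minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 60, "ftol": 1e-9})
    return unpack(res.x)


def fit_branch_lengths(
    aln: AlignmentMatrix,
    topology,
    model: SubstitutionModel | None = None,
    optimize_model: bool = True,
    max_rounds: int = 20,
    rel_tol: float = 1e-6,
) -> BranchFitResult:
    """Estimate branch lengths (and optionally GTR+G+I parameters) on a
    fixed topology by coordinate-wise Brent sweeps interleaved with bounded
    quasi-Newton steps on the model parameters.

    The topology tree is not modified; a clone with fitted lengths is
    returned. Lengths are bounded in [0, 10] substitutions/site.
    """
    import dendropy

    tree = topology.clone(depth=1)
    pruner = _Pruner(aln, tree)
    if model is None:
        model = SubstitutionModel(
            frequencies=empirical_frequencies(aln), alpha=0.5, p_inv=0.1
        )
    lengths = pruner.ti.lengths()
    missing = lengths <= 0
    lengths[missing] = 0.05  # neutral starting point for unset edges
    lengths = np.clip(lengths, MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH)

    ll = pruner.log_likelihood(model, lengths)
    converged = False
    n_rounds = 0
    for rnd in range(max_rounds):
        n_rounds = rnd + 1
        # one full sweep over branches using outer/inner partial caching
        pmats = transition_matrices(model, lengths)
        down = pruner._down_partials(pmats)
        msg = pruner._edge_messages(pmats, down)
        out = pruner._outer_partials(model, pmats, down, msg)
        for e in pruner.ti.edges:
            down_e = (
                pruner.leaf_partials[e][None, :, :]
                if pruner.ti.is_leaf[e]
                else down[e]
            )

            def neg(t, _e=e, _d=down_e):
                site_l = pruner.edge_site_likelihoods(model, _e, t, out[_e], _d)
                if np.any(site_l <= 0):
                    return np.inf
                return -float(pruner.counts @ np.log(site_l))

            res = minimize_scalar(
                neg,
                bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                method="bounded",
                options={"xatol": 1e-8},
            )
            if res.fun < neg(lengths[e]):
                lengths[e] = res.x
            # refresh caches that depend on this edge
            pmats[e] = transition_matrices(model, lengths[[e]])[0]
            down = pruner._down_partials(pmats)
            msg = pruner._edge_messages(pmats, down)
            out = pruner._outer_partials(model, pmats, down, msg)
        if optimize_model:
            model = _optimize_model_params(pruner, model, lengths)
        new_ll = pruner.log_likelihood(model, lengths)
        if new_ll - ll <= rel_tol * (abs(ll) + 1.0):
            ll = max(new_ll, ll)
            converged = True
            break
        ll = new_ll

    # snap numerically-zero lengths back to zero
    fitted = np.where(lengths <= 2 * MIN_BRANCH_LENGTH, 0.0, lengths)
    for i, nd in enumerate(pruner.ti.nodes):
        if i != pruner.ti.root:
            nd.edge.length = float(fitted[i])
    _rebalance_root_edges(tree, topology)
    return BranchFitResult(tree, model, ll, converged, n_rounds)


def _rebalance_root_edges(tree, reference):
    """Split the fitted root-adjacent length sum as in the reference tree.

    Under a reversible model only the sum of the two root-adjacent branch
    lengths is identifiable (pulley principle); the optimizer's split is
    arbitrary. Re-apportioning the fitted sum in the reference topology's
    proportions is likelihood-neutral and keeps the root split stable
    across bootstrap replicates.
    """
    kids = tree.seed_node.child_nodes()
    ref_kids = reference.seed_node.child_nodes()
    if len(kids) != 2 or len(ref_kids) != 2:
        return
    ref = [nd.edge.length for nd in ref_kids]
    if any(v is None for v in ref) or sum(ref) <= 0:
        return
    # match reference children to fitted children by leaf sets
    def key(nd):
        return frozenset(lf.taxon.label for lf in nd.leaf_iter())

    ref_by_key = {key(nd): nd.edge.length for nd in ref_kids}
    total = sum(nd.edge.length for nd in kids)
    ref_total = sum(ref)
    for nd in kids:
        k = key(nd)
        if k not in ref_by_key:
            return  # different rooting; leave untouched
        nd.edge.length = total * ref_by_key[k] / ref_total
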