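"""Rooted-tree data model and arithmetic shared by every analysis stage.

Trees are :class:`dendropy.Tree` objects, always treated as rooted. Two
optional node attributes extend the dendropy model:

``node.age``
    Absolute age in Ma (millions of years before present); extant tips are 0.
``node.rate``
    Absolute substitution rate (substitutions/site/Myr) on the edge leading
    to the node from its parent.

A *phylogram* carries edge lengths in expected substitutions per site; a
*chronogram* carries ages on every node and rates on every non-root edge.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

logger = logging.getLogger("plchron")

__all__ = [
    "TreeError",
    "Calibration",
    "CalibrationSet",
    "read_tree",
    "write_tree",
    "mrca",
    "root_to_tip_lengths",
    "reroot_on_edge",
    "leaf_labels",
    "set_ages_from_lengths",
    "ages_from_tree",
    "check_chronogram",
]


class TreeError(ValueError):
    """Malformed tree input or an invalid tree query."""


# ---------------------------------------------------------------------------
# Calibrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Min/max age bound (Ma) on the MRCA of ``taxa``.

    Either bound may be None (one-sided constraint). ``min_age == max_age``
    fixes the node age exactly.
    """

    taxa: frozenset
    min_age: float | None = None
    max_age: float | None = None

    def __post_init__(self):
        if not self.taxa:
            raise ValueError("calibration needs a non-empty taxon set")
        if (
            self.min_age is not None
            and self.max_age is not None
            and self.min_age > self.max_age
        ):
            raise ValueError(
                f"calibration min_age {self.min_age} > max_age {self.max_age}"
            )


class CalibrationSet:
    """Ordered collection of :class:`Calibration` constraints."""

    def __init__(self, calibrations: Iterable[Calibration] = ()):
        self.calibrations = list(calibrations)

    def __iter__(self):
        return iter(self.calibrations)

    def __len__(self):
        return len(self.calibrations)

    def add(self, taxa: Iterable[str], min_age=None, max_age=None):
        self.calibrations.append(
            Calibration(frozenset(taxa), min_age, max_age)
        )
        return self

    def validate_against(self, tree: dendropy.Tree):
        labels = set(leaf_labels(tree))
        for cal in self.calibrations:
            missing = set(cal.taxa) - labels
            if missing:
                raise TreeError(
                    f"calibration taxa not in tree: {sorted(missing)}"
                )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _looks_like_nexus(text: str) -> bool:
    return text.lstrip().lower().startswith("#nexus")


def read_tree(text: str, require_lengths: bool = False) -> dendropy.Tree:
    """Parse a newick or nexus TREES-block string into a rooted tree.

    Explicitly unrooted trees (``[&U]``) are rejected: rooting is the
    caller's job (see :func:`reroot_on_edge`). Duplicate leaf labels are an
    error. With ``require_lengths``, every non-root edge must carry a length.
    """
    text = text.strip()
    if not text:
        raise TreeError("empty tree input")
    schema = "nexus" if _looks_like_nexus(text) else "newick"
    if "[&U]" in text or "[&u]" in text:
        raise TreeError("unrooted tree rejected; reroot explicitly first")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"could not parse {schema} tree: {exc}") from exc
    tree.is_rooted = True
    labels = leaf_labels(tree)
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")
    if require_lengths:
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                raise TreeError(
                    f"missing branch length on edge to {node_label(nd)!r}"
                )
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None and nd.edge.length < 0:
            raise TreeError("negative branch length")
    return tree


def write_tree(tree: dendropy.Tree, schema: str = "newick") -> str:
    """Serialize a tree; node ``age`` attributes go out as nexus comments."""
    if schema == "newick":
        return tree.as_string(
            schema="newick", unquoted_underscores=True
        ).strip() + "\n"
    if schema == "nexus":
        for nd in tree.preorder_node_iter():
            parts = []
            if getattr(nd, "age", None) is not None:
                parts.append(f"age={nd.age:.6g}")
            if getattr(nd, "rate", None) is not None:
                parts.append(f"rate={nd.rate:.6g}")
            nd.annotations.drop()
            for part in parts:
                k, v = part.split("=")
                nd.annotations.add_new(k, v)
        return tree.as_string(schema="nexus", unquoted_underscores=True)
    raise ValueError(f"unknown schema {schema!r}")


def node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def leaf_labels(tree: dendropy.Tree) -> list:
    return [nd.taxon.label for nd in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def mrca(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of a set of leaf labels.

    The MRCA of a single taxon is the leaf itself.
    """
    taxa = set(taxa)
    if not taxa:
        raise TreeError("empty taxon set")
    by_label = {nd.taxon.label: nd for nd in tree.leaf_node_iter()}
    unknown = taxa - set(by_label)
    if unknown:
        raise TreeError(f"unknown leaf labels: {sorted(unknown)}")
    if len(taxa) == 1:
        return by_label[taxa.pop()]
    paths = []
    for label in taxa:
        path = []
        nd = by_label[label]
        while nd is not None:
            path.append(nd)
            nd = nd.parent_node
        paths.append(path[::-1])  # root ... leaf
    deepest = None
    for level in zip(*paths):
        first = level[0]
        if all(nd is first for nd in level):
            deepest = first
        else:
            break
    return deepest


def clade_leaves(node: dendropy.Node) -> list:
    return [lf.taxon.label for lf in node.leaf_iter()]


def is_monophyletic(tree: dendropy.Tree, taxa: Iterable[str]) -> bool:
    taxa = set(taxa)
    anc = mrca(tree, taxa)
    return set(clade_leaves(anc)) == taxa


def root_to_tip_lengths(
    tree: dendropy.Tree, from_node: dendropy.Node | None = None
) -> Mapping[str, float]:
    """Sum of branch lengths from ``from_node`` (default: root) to each
    descendant leaf."""
    if from_node is None:
        from_node = tree.seed_node
    found = any(nd is from_node for nd in tree.preorder_node_iter())
    if not found:
        raise TreeError("from_node is not part of this tree")
    out = {}

    def _walk(nd, acc):
        if nd.is_leaf():
            out[nd.taxon.label] = acc
            return
        for ch in nd.child_nodes():
            if ch.edge.length is None:
                raise TreeError("branch length missing on path")
            _walk(ch, acc + ch.edge.length)

    if from_node.is_leaf():
        out[from_node.taxon.label] = 0.0
    else:
        _walk(from_node, 0.0)
    return out


def reroot_on_edge(tree: dendropy.Tree, leaf_label: str, fraction: float = 0.5):
    """Reroot on the edge above the named leaf, splitting it at ``fraction``."""
    leaf = next(
        nd for nd in tree.leaf_node_iter() if nd.taxon.label == leaf_label
    )
    edge = leaf.edge
    if edge.length is None:
        tree.reroot_at_edge(edge, update_bipartitions=False)
    else:
        left = edge.length * fraction
        tree.reroot_at_edge(
            edge,
            length1=edge.length - left,
            length2=left,
            update_bipartitions=False,
        )
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Ages
# ---------------------------------------------------------------------------

def set_ages_from_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Interpret edge lengths as durations (Myr) on an ultrametric tree and
    assign node ages; tips get age 0."""
    depths = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            if nd.edge.length is None:
                raise TreeError("duration missing")
            depths[nd] = depths[nd.parent_node] + nd.edge.length
    tip_depths = [depths[nd] for nd in tree.leaf_node_iter()]
    height = max(tip_depths)
    if max(tip_depths) - min(tip_depths) > 1e-6 * max(height, 1.0):
        raise TreeError("tree is not ultrametric; cannot assign ages")
    for nd in tree.preorder_node_iter():
        nd.age = height - depths[nd]
    for nd in tree.leaf_node_iter():
        nd.age = 0.0
    return tree


def ages_from_tree(tree: dendropy.Tree) -> Mapping[dendropy.Node, float]:
    ages = {}
    for nd in tree.preorder_node_iter():
        age = getattr(nd, "age", None)
        if age is None:
            raise TreeError("node without age; not a chronogram")
        ages[nd] = age
    return ages


def check_chronogram(tree: dendropy.Tree, allow_zero: bool = True):
    """Validate chronogram invariants: parent older than child, rates > 0."""
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            dt = nd.parent_node.age - nd.age
            if dt < 0 or (dt == 0 and not allow_zero):
                raise TreeError(
                    f"age inversion at {node_label(nd)!r}: "
                    f"{nd.parent_node.age} -> {nd.age}"
                )
            rate = getattr(nd, "rate", None)
            if rate is not None and rate <= 0:
                raise TreeError("non-positive branch rate")
    return True
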