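"""Tree-based 1:1 ortholog extraction and gene-tree filtering.

Gene families arrive as rooted gene trees whose leaves carry a species, a
sequence id and a sequence length, encoded in the leaf label as
``species|seq_id|length``. The cascade mirrors the usual transcriptome
marker-selection pipeline:

1. collapse every maximal single-species ("monospecific") clade to its
   longest sequence, removing redundant transcripts and post-speciation
   duplicates;
2. extract maximal clades containing exactly one sequence per species
   (1:1 orthogroups);
3. filter orthogroups on species occupancy and required taxa;
4. reject gene trees that fail clade-monophyly constraints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy

from .phylo_core import TreeError, clade_leaves, mrca

logger = logging.getLogger("plchron")

__all__ = [
    "GeneLeaf",
    "Orthogroup",
    "tag_gene_tree",
    "midpoint_root_if_unrooted",
    "prune_monospecific_clades",
    "extract_one_to_one",
    "filter_orthogroups",
    "monophyly_filter",
]


@dataclass(frozen=True)
class GeneLeaf:
    species: str
    seq_id: str
    length: float

    @property
    def label(self) -> str:
        return f"{self.species}|{self.seq_id}|{self.length:g}"


@dataclass(frozen=True)
class Orthogroup:
    """A 1:1 set of sequences: exactly one per species present."""

    members: frozenset  # of (species, seq_id)

    @property
    def species(self) -> frozenset:
        return frozenset(s for s, _ in self.members)

    def __post_init__(self):
        species = [s for s, _ in self.members]
        if len(species) != len(set(species)):
            raise ValueError("orthogroup with duplicated species")


def _parse_leaf(label: str) -> GeneLeaf:
    parts = label.split("|")
    if len(parts) != 3:
        raise TreeError(
            f"gene-tree leaf {label!r} is not 'species|seq_id|length'"
        )
    species, seq_id, length = parts
    length = float(length)
    if length <= 0:
        raise TreeError(f"non-positive sequence length on {label!r}")
    return GeneLeaf(species, seq_id, length)


def tag_gene_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Attach parsed ``GeneLeaf`` tags to every leaf (in place)."""
    for nd in tree.leaf_node_iter():
        nd.gene = _parse_leaf(nd.taxon.label)
    return tree


def midpoint_root_if_unrooted(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root trees with a basal polytomy (the usual unrooted
    convention); rooted binary-basal trees pass through unchanged."""
    if len(tree.seed_node.child_nodes()) > 2:
        logger.info("gene tree looks unrooted; applying midpoint rooting")
        tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def _species_counts(node) -> dict:
    counts = {}
    for lf in node.leaf_iter():
        sp = lf.gene.species
        counts[sp] = counts.get(sp, 0) + 1
    return counts


def prune_monospecific_clades(gt: dendropy.Tree) -> dendropy.Tree:
    """Collapse each maximal single-species clade to its longest sequence.

    Length ties break by lexicographically smallest seq_id, so the result
    is deterministic. Returns a new tree.
    """
    tree = gt.clone(depth=1)
    tag_gene_tree(tree)
    # species set per node, postorder
    spset = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            spset[id(nd)] = {nd.gene.species}
        else:
            s = set()
            for c in nd.child_nodes():
                s |= spset[id(c)]
            spset[id(nd)] = s
    # maximal monospecific internal nodes, preorder
    targets = []
    stack = [tree.seed_node]
    while stack:
        nd = stack.pop()
        if len(spset[id(nd)]) == 1:
            if not nd.is_leaf():
                targets.append(nd)
            continue  # maximal: do not descend
        stack.extend(nd.child_nodes())
    for nd in targets:
        leaves = list(nd.leaf_iter())
        best = min(leaves, key=lambda lf: (-lf.gene.length, lf.gene.seq_id))
        nd.set_child_nodes([])
        nd.taxon = best.taxon
        nd.gene = best.gene
    return tree


def extract_one_to_one(
    gt: dendropy.Tree, species_universe=None
) -> list:
    """Maximal clades with exactly one sequence per species present.

    No returned clade is nested inside another. Singleton leaves qualify
    trivially; occupancy filtering happens downstream. If
    ``species_universe`` is given, sequences from other species are an
    error.
    """
    tag_gene_tree(gt)
    if species_universe is not None:
        universe = set(species_universe)
        for lf in gt.leaf_node_iter():
            if lf.gene.species not in universe:
                raise TreeError(
                    f"species {lf.gene.species!r} outside the universe"
                )
    groups = []
    stack = [gt.seed_node]
    while stack:
        nd = stack.pop()
        counts = _species_counts(nd)
        if counts and max(counts.values()) == 1:
            members = frozenset(
                (lf.gene.species, lf.gene.seq_id) for lf in nd.leaf_iter()
            )
            groups.append(Orthogroup(members))
            continue
        stack.extend(nd.child_nodes())
    return groups


def filter_orthogroups(
    groups,
    min_species: int = 0,
    required_all=(),
    required_any=(),
) -> list:
    """Occupancy/required-taxon filter.

    Keeps groups with strictly more than ``min_species`` species that
    contain every species in ``required_all`` and at least one of
    ``required_any`` (vacuously true when the sets are empty).
    """
    required_all = set(required_all)
    required_any = set(required_any)
    kept = []
    for g in groups:
        sp = g.species
        if len(sp) <= min_species:
            continue
        if required_all - sp:
            continue
        if required_any and not (required_any & sp):
            continue
        kept.append(g)
    return kept


def monophyly_filter(tree: dendropy.Tree, constraint_clades) -> list:
    """Per-constraint monophyly verdicts on a (species-labelled) tree.

    A constraint passes iff the MRCA of its taxa present in the tree
    contains no other leaves. Constraints with fewer than two taxa present
    pass vacuously; absent taxa are skipped with a logged note.
    """
    present = {nd.taxon.label for nd in tree.leaf_node_iter()}
    verdicts = []
    for taxa in constraint_clades:
        taxa = set(taxa)
        absent = taxa - present
        if absent:
            logger.info("monophyly constraint: skipping absent taxa %s",
                        sorted(absent))
        taxa &= present
        if len(taxa) < 2:
            verdicts.append(True)
            continue
        anc = mrca(tree, taxa)
        verdicts.append(set(clade_leaves(anc)) == taxa)
    return verdicts
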