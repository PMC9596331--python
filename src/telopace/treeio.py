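"""Newick tree input, majority-rule consensus, and phylogenetic covariance.

Trees are held as :class:`dendropy.Tree` objects. The covariance matrix
built here is the standard Brownian-motion "A matrix" of the animal model:
entry (i, j) is the branch length shared on the root-to-tip paths of species
i and j (the depth of their most recent common ancestor), rescaled so the
maximum diagonal entry is 1. Under Brownian motion on the tree this matrix
is proportional to the expected among-species trait covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "parse_newick_trees",
    "majority_consensus",
    "tree_to_phylo_covariance",
    "PhyloCovariance",
    "normalize_species_name",
]


def normalize_species_name(name: str) -> str:
    """Canonical species label: stripped, underscores for spaces, case-folded.

    Makes ``"Parus major"`` and ``"parus_major"`` compare equal when matching
    tree tips against trait-table rows.
    """
    return "_".join(name.strip().split()).casefold()


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or violates tree invariants."""


def _validate_tree(tree: dendropy.Tree, index: int) -> None:
    labels = [leaf.taxon.label if leaf.taxon else "" for leaf in tree.leaf_node_iter()]
    if any(not lab for lab in labels):
        raise NewickParseError(f"tree {index}: empty or missing tip label")
    seen: set[str] = set()
    dups = {lab for lab in labels if lab in seen or seen.add(lab)}
    if dups:
        raise NewickParseError(f"tree {index}: duplicate tip labels {sorted(dups)}")
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            if edge.head_node is not tree.seed_node:
                n_missing += 1
            edge.length = 0.0
        elif edge.length < 0:
            raise NewickParseError(
                f"tree {index}: negative branch length {edge.length}"
            )
    if n_missing:
        logger.warning(
            "tree %d: %d missing branch length(s) read as 0", index, n_missing
        )


def parse_newick_trees(source) -> list[dendropy.Tree]:
    """Read one or more Newick trees from a path, string, or text stream.

    Trees may be separated by newlines or simply by their terminating
    semicolons. Returns one rooted :class:`dendropy.Tree` per statement.
    Missing branch lengths are read as 0 with a logged warning; malformed
    statements raise :class:`NewickParseError` naming the offending tree
    index (0-based).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "(" not in text and ";" not in text:
            with open(text) as fh:
                text = fh.read()

    statements = [s.strip() for s in text.split(";") if s.strip()]
    if not statements:
        raise NewickParseError("no Newick statements found in source")

    trees: list[dendropy.Tree] = []
    for i, stmt in enumerate(statements):
        try:
            tree = dendropy.Tree.get(
                data=stmt + ";",
                schema="newick",
                preserve_underscores=True,
                taxon_namespace=dendropy.TaxonNamespace(),
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"tree {i}: malformed Newick ({exc})") from exc
        tree.is_rooted = True
        _validate_tree(tree, i)
        trees.append(tree)
    return trees


def _tip_set(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _clade_lengths(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    """Map each clade (as a frozenset of tip labels) to its subtending branch length."""
    out: dict[frozenset[str], float] = {}
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        out[below[node]] = float(node.edge.length or 0.0)
    return out


def majority_consensus(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Strict majority-rule (>50%) consensus of rooted trees on one tip set.

    A clade is retained if it appears in more than half of the input trees;
    its branch length is the arithmetic mean of the subtending branch length
    over the trees that contain it. Incompatible minority clades are dropped,
    leaving multifurcations where the sample disagrees.
    """
    if not trees:
        raise ValueError("majority_consensus requires a non-empty tree list")
    tip_sets = [_tip_set(t) for t in trees]
    ref = tip_sets[0]
    for i, ts in enumerate(tip_sets[1:], start=1):
        if ts != ref:
            diff = sorted(ts.symmetric_difference(ref))
            raise ValueError(
                f"tree {i} tip set differs from tree 0; symmetric difference: {diff}"
            )

    counts: dict[frozenset[str], int] = {}
    length_sums: dict[frozenset[str], float] = {}
    for tree in trees:
        for clade, length in _clade_lengths(tree).items():
            counts[clade] = counts.get(clade, 0) + 1
            length_sums[clade] = length_sums.get(clade, 0.0) + length

    n = len(trees)
    kept = {c for c, k in counts.items() if 2 * k > n}
    kept.add(ref)  # root clade always present
    mean_len = {c: length_sums[c] / counts[c] for c in kept}

    # Majority clades are pairwise compatible, so nesting by set inclusion
    # reconstructs a unique rooted tree.
    taxon_ns = dendropy.TaxonNamespace(sorted(ref))
    nodes: dict[frozenset[str], dendropy.Node] = {}
    for clade in kept:
        node = dendropy.Node()
        node.edge.length = mean_len[clade]
        if len(clade) == 1:
            (label,) = clade
            node.taxon = taxon_ns.get_taxon(label)
        nodes[clade] = node

    for clade in sorted(kept, key=len):
        if clade == ref:
            continue
        parent = min(
            (c for c in kept if len(c) > len(clade) and clade < c), key=len
        )
        nodes[parent].add_child(nodes[clade])

    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = nodes[ref]
    tree.is_rooted = True
    if counts.get(ref, 0) < n or nodes[ref].edge.length is None:
        nodes[ref].edge.length = mean_len.get(ref, 0.0)
    return tree


@dataclass
class PhyloCovariance:
    """Phylogenetic relatedness matrix with its species ordering.

    ``matrix[i, j]`` is the shared root-to-MRCA branch length of species
    ``species_order[i]`` and ``species_order[j]``, divided by the maximum
    tip depth so the deepest diagonal entry equals 1 (all of them, for an
    ultrametric tree).
    """

    species_order: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.species_order)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match species_order length")

    @property
    def n_species(self) -> int:
        return len(self.species_order)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.matrix, index=self.species_order, columns=self.species_order
        ).to_csv(path)


def tree_to_phylo_covariance(
    tree: dendropy.Tree, species_order: list[str]
) -> PhyloCovariance:
    """Build the phylogenetic covariance matrix for ``species_order``.

    The tree is pruned to the requested species first; species absent from
    the tree raise ``ValueError`` listing the missing names. The matrix is
    rescaled by its maximum diagonal entry (tree height for ultrametric
    trees); an all-zero-depth tree is an error.
    """
    if len(set(species_order)) != len(species_order):
        raise ValueError("species_order contains duplicates")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [s for s in species_order if s not in tips]
    if missing:
        raise ValueError(f"species absent from tree: {missing}")

    work = tree.clone(depth=1)
    if set(species_order) != tips:
        work.retain_taxa_with_labels(species_order)

    idx = {name: i for i, name in enumerate(species_order)}
    n = len(species_order)
    cov = np.zeros((n, n))

    depth: dict[dendropy.Node, float] = {}
    below: dict[dendropy.Node, list[int]] = {}
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0  # the root edge is not shared history
        else:
            depth[node] = depth[node.parent_node] + float(node.edge.length or 0.0)

    for node in work.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            below[node] = [i]
            cov[i, i] = depth[node]
        else:
            kids = [below[c] for c in node.child_nodes()]
            d = depth[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            cov[i, j] = cov[j, i] = d
            below[node] = [i for k in kids for i in k]

    scale = cov.diagonal().max()
    if scale <= 0:
        raise ValueError("zero-depth tree: all branch lengths are 0")
    cov /= scale
    diag = cov.diagonal()
    if diag.max() - diag.min() > 1e-8:
        logger.warning(
            "tree is not ultrametric: tip depths vary between %.6g and %.6g "
            "(relative units)",
            diag.min(),
            diag.max(),
        )
    return PhyloCovariance(list(species_order), cov)
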