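"""Phylogenetic tree handling: Newick I/O, variance–covariance matrices,
Pagel's lambda transform, fixed-age clade grafting, and pruning.

Trees are rooted with branch lengths in millions of years (Myr).  The
phylogenetic variance–covariance (VCV) matrix has, for tips ``i`` and ``j``,
the shared root-to-MRCA path length off the diagonal and the root-to-tip
distance on the diagonal.  Pagel's lambda multiplies the off-diagonal
entries only; the diagonal is left unscaled, which is the standard form of
the transform.

Taxon-name matching everywhere in this package is exact string match after
trimming whitespace and replacing spaces with underscores.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

__all__ = [
    "NewickError",
    "TreeError",
    "PhyloTree",
    "VCVMatrix",
    "normalize_label",
    "parse_newick",
    "write_newick",
    "vcv_from_tree",
    "graft_clades",
    "prune_to_taxa",
]

#: relative tolerance used when deciding whether a tree is ultrametric
ULTRAMETRIC_RTOL = 1e-6


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips, ...)."""


class TreeError(ValueError):
    """A tree violates a structural precondition of an operation."""


def normalize_label(name: str) -> str:
    """Canonical taxon name: stripped, spaces unified to underscores."""
    return str(name).strip().replace(" ", "_")


class PhyloTree:
    """Rooted phylogeny with branch lengths in Myr.

    Thin wrapper around a :class:`dendropy.Tree` that enforces unique tip
    labels and mandatory branch lengths, and adds the path-length
    bookkeeping the comparative machinery needs.
    """

    def __init__(self, tree: dendropy.Tree, label: str | None = None):
        self._tree = tree
        self.label = label
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickError("tree contains an unlabelled tip")
            lab = normalize_label(leaf.taxon.label)
            if lab in seen:
                raise NewickError(f"duplicate tip label {lab!r}")
            seen.add(lab)
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                where = (
                    normalize_label(node.taxon.label)
                    if node.taxon is not None and node.taxon.label
                    else "an internal node"
                )
                raise NewickError(f"missing branch length on the edge above {where}")
            if node.edge.length < 0:
                raise TreeError(f"negative branch length {node.edge.length}")

    # -- basic queries ----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [normalize_label(l.taxon.label) for l in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def node_depths(self) -> dict:
        """Root-to-node path length for every node (root edge ignored)."""
        depths: dict = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + float(node.edge.length)
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {
            normalize_label(l.taxon.label): depths[l]
            for l in self._tree.leaf_node_iter()
        }

    @property
    def height(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = list(self.tip_depths().values())
        hi, lo = max(d), min(d)
        return hi == 0.0 or (hi - lo) <= rtol * hi

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1), label=self.label)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_tips={self.n_tips}, height={self.height:.4g})"


def parse_newick(text: str, label: str | None = None) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are mandatory; duplicate or missing tip labels raise
    :class:`NewickError` naming the offending token.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parser exception types
        raise NewickError(f"could not parse Newick: {exc}") from exc
    return PhyloTree(tree, label=label)


def write_newick(tree: PhyloTree) -> str:
    """Serialize to a single-line Newick string (lengths to 12 significant digits)."""
    s = tree._tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )
    return s.strip()


class VCVMatrix:
    """Phylogenetic variance–covariance matrix with its taxon order."""

    def __init__(self, matrix: np.ndarray, taxa: list[str]):
        self.matrix = np.asarray(matrix, dtype=float)
        self.taxa = list(taxa)
        if self.matrix.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxon list")

    def select(self, taxa) -> "VCVMatrix":
        """Row/column subselection (and reordering) by taxon name."""
        taxa = [normalize_label(t) for t in taxa]
        idx = [self.taxa.index(t) for t in taxa]
        return VCVMatrix(self.matrix[np.ix_(idx, idx)], taxa)

    def correlation(self) -> np.ndarray:
        """D^{-1/2} V D^{-1/2}; for an ultrametric tree this is V / height."""
        d = np.sqrt(np.diag(self.matrix))
        return self.matrix / np.outer(d, d)


def vcv_from_tree(
    tree: PhyloTree, lam: float = 1.0, *, allow_extended_lambda: bool = False
) -> VCVMatrix:
    """Phylogenetic VCV under Pagel's lambda.

    ``V[i, j]`` is the root-to-MRCA shared path length multiplied by ``lam``
    for ``i != j``; the diagonal holds the unscaled root-to-tip distances.
    Lambda outside [0, 1] loses the positive-semi-definiteness guarantee and
    is rejected unless ``allow_extended_lambda`` is set.
    """
    if not allow_extended_lambda and not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1]; got {lam}")

    depths = tree.node_depths()
    leaves = list(tree._tree.leaf_node_iter())
    n = len(leaves)
    index = {leaf: i for i, leaf in enumerate(leaves)}
    V = np.zeros((n, n))
    for leaf in leaves:
        V[index[leaf], index[leaf]] = depths[leaf]

    subtips: dict = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            subtips[node] = [index[node]]
            continue
        groups = [subtips[c] for c in node.child_nodes()]
        d = depths[node]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                V[np.ix_(groups[gi], groups[gj])] = d
                V[np.ix_(groups[gj], groups[gi])] = d
        subtips[node] = [i for g in groups for i in g]

    if lam != 1.0:
        diag = np.diag(V).copy()
        V = V * lam
        np.fill_diagonal(V, diag)
    taxa = [normalize_label(l.taxon.label) for l in leaves]
    return VCVMatrix(V, taxa)


def graft_clades(tree_a: PhyloTree, tree_b: PhyloTree, lca_age: float) -> PhyloTree:
    """Join two ultrametric clades under a new root dated at ``lca_age`` Myr.

    Each clade keeps its internal structure; the stem branch to a clade root
    is ``lca_age`` minus that clade's height, so the output is ultrametric
    with height exactly ``lca_age``.
    """
    for t, name in ((tree_a, "first"), (tree_b, "second")):
        if not t.is_ultrametric():
            raise TreeError(f"{name} tree is not ultrametric; cannot graft")
    ha, hb = tree_a.height, tree_b.height
    if lca_age <= ha or lca_age <= hb:
        raise TreeError(
            f"grafting age {lca_age} Myr conflicts with clade heights "
            f"{ha:.6g} and {hb:.6g} Myr"
        )
    na = write_newick(tree_a).rstrip().rstrip(";")
    nb = write_newick(tree_b).rstrip().rstrip(";")
    text = f"({na}:{lca_age - ha:.12g},{nb}:{lca_age - hb:.12g});"
    return parse_newick(text)


def prune_to_taxa(tree: PhyloTree, taxa) -> PhyloTree:
    """Induced subtree on ``taxa``: degree-2 nodes suppressed, path lengths kept.

    Requested names absent from the tree are reported through a
    ``UserWarning``; an empty intersection is an error.
    """
    requested = {normalize_label(t) for t in taxa}
    actual = {normalize_label(l.taxon.label): l.taxon.label
              for l in tree._tree.leaf_node_iter()}
    keep = requested & set(actual)
    missing = sorted(requested - set(actual))
    if missing:
        warnings.warn(f"taxa absent from tree: {', '.join(missing)}", UserWarning,
                      stacklevel=2)
    if not keep:
        raise TreeError("no requested taxon is present in the tree")
    clone = tree._tree.clone(depth=1)
    clone.retain_taxa_with_labels([actual[k] for k in sorted(keep)])
    pruned = PhyloTree(clone, label=tree.label)
    # if the kept tips all sat on one side of the old root, the old root and
    # the shared stem were collapsed; restore the stem so root-to-tip path
    # lengths (and hence VCV entries) match the original tree exactly
    ref = next(iter(keep))
    delta = tree.tip_depths()[ref] - pruned.tip_depths()[ref]
    if delta > 1e-12:
        import dendropy

        new_root = dendropy.Node()
        old_root = clone.seed_node
        clone.seed_node = new_root
        new_root.add_child(old_root)
        old_root.edge.length = delta
        pruned = PhyloTree(clone, label=tree.label)
    return pruned
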