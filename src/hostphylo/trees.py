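"""Rooted phylogenies: Newick I/O, patristic distances, Brownian covariance,
and strict-clock chronogram rescaling.

The tree container wraps a :class:`dendropy.Tree` and adds the matrix views
used downstream: the patristic distance matrix (path length between tips, in
the branch-length units of the tree, Myr for a chronogram) and the
phylogenetic covariance matrix V whose entry (i, j) is the shared root-to-LCA
path length — the Brownian-motion trait covariance up to a rate constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "TipMatrix",
    "DistanceMatrix",
    "CovarianceMatrix",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "patristic_distances",
    "phylo_covariance",
    "strict_clock_chronogram",
    "check_ultrametric",
    "resolve_polytomies",
]


class NewickParseError(ValueError):
    """Raised when Newick text cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the tree-model invariants."""


@dataclass
class TipMatrix:
    """A symmetric tip-by-tip matrix (distances or covariances).

    Attributes
    ----------
    labels : list of str
        Tip labels, fixing row/column order.
    values : ndarray of shape (n, n)
    """

    labels: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def reorder(self, labels: Sequence[str]) -> "TipMatrix":
        idx = [self._index[lab] for lab in labels]
        return TipMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# The two matrix views share one container; the aliases name their roles.
DistanceMatrix = TipMatrix
CovarianceMatrix = TipMatrix


class PhyloTree:
    """Rooted tree with branch lengths and unique, non-empty tip labels."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon" in str(exc):
                raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
                missing += 1
        if missing:
            logger.warning(
                "%d branch(es) lacked a length in the Newick input; set to 0", missing
            )
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            lab = leaf.taxon.label if leaf.taxon is not None else None
            if not lab:
                raise TreeValidationError("tree has a tip with an empty label")
            labels.append(lab)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is not None and node.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.edge.length} above "
                    f"{node.taxon.label if node.taxon else 'an internal node'}"
                )

    # -- basic views --------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self._tree.preorder_node_iter() if not n.is_leaf())

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_node_iter()
            if not n.is_leaf()
        )

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- depths and heights --------------------------------------------------

    def node_depths(self) -> dict:
        """Root-to-node path length for every node (root edge counts as 0)."""
        depths = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {
            leaf.taxon.label: depths[leaf] for leaf in self._tree.leaf_node_iter()
        }

    @property
    def height(self) -> float:
        return max(self.tip_depths().values())

    def postorder_index(self) -> dict:
        """Deterministic post-order node index (tips and internals)."""
        return {node: i for i, node in enumerate(self._tree.postorder_node_iter())}


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def patristic_distances(tree: PhyloTree) -> TipMatrix:
    """Pairwise path lengths between tips (sum of branch lengths)."""
    labels = tree.tip_labels
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    taxa = {leaf.taxon.label: leaf.taxon for leaf in tree.dendropy_tree.leaf_node_iter()}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return TipMatrix(labels, d)


def phylo_covariance(tree: PhyloTree) -> TipMatrix:
    """Brownian covariance V: V[i, j] = root-to-LCA(i, j) path length.

    Computed by a single post-order traversal: at each internal node of depth
    t, every pair of tips whose paths first meet there gets V = t.
    """
    if tree.dendropy_tree.seed_node is None:
        raise TreeValidationError("tree has no root; root it first")
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    depths = tree.node_depths()
    n = len(labels)
    V = np.zeros((n, n))
    tipsets: dict = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tipsets[node] = [i]
            V[i, i] = depths[node]
        else:
            children = [tipsets.pop(c) for c in node.child_nodes()]
            t = depths[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = V[j, i] = t
            tipsets[node] = [i for ch in children for i in ch]
    return TipMatrix(labels, V)


def check_ultrametric(tree: PhyloTree, rel_tol: float = 1e-6) -> tuple[bool, float]:
    """Report whether all tips are equidistant from the root.

    Returns ``(is_ultrametric, max_rel_dev)`` where the deviation is
    ``max_i |depth_i - mean depth| / mean depth``.
    """
    depths = np.array(list(tree.tip_depths().values()))
    mean = depths.mean()
    if mean == 0:
        return True, 0.0
    dev = float(np.max(np.abs(depths - mean)) / mean)
    return dev <= rel_tol, dev


def strict_clock_chronogram(tree: PhyloTree, root_age: float = 1.0) -> PhyloTree:
    """Rescale a phylogram to an ultrametric chronogram under a strict clock.

    With a single rate r on all branches, node ages are identified by the
    branch lengths alone: we minimise sum over branches of
    (observed_length - (h_parent - h_child))^2 over node heights h (tips at
    0), subject to h_parent >= h_child >= 0, then rescale heights so the root
    sits at ``root_age``. The unconstrained least-squares solution is used
    directly when it already satisfies the ordering constraints (always the
    case for clock-like data), otherwise an SLSQP solve with the explicit
    inequality constraints is run.
    """
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    out = tree.copy()
    dt = out.dendropy_tree
    internals = [n for n in dt.postorder_node_iter() if not n.is_leaf()]
    idx = {n: k for k, n in enumerate(internals)}
    edges = []  # (parent_col, child_col_or_None, length)
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            continue
        p = idx[node.parent_node]
        c = idx.get(node) if not node.is_leaf() else None
        edges.append((p, c, node.edge.length or 0.0))
    m, k = len(edges), len(internals)
    A = np.zeros((m, k))
    b = np.zeros(m)
    for r, (p, c, length) in enumerate(edges):
        A[r, p] = 1.0
        if c is not None:
            A[r, c] = -1.0
        b[r] = length
    h, *_ = np.linalg.lstsq(A, b, rcond=None)
    tol = 1e-12 * (abs(b).max() + 1.0)
    feasible = all(
        (h[p] - (h[c] if c is not None else 0.0)) >= -tol for p, c, _ in edges
    ) and h.min() >= -tol
    if not feasible:
        cons = [
            {
                "type": "ineq",
                "fun": (lambda x, p=p, c=c: x[p] - (x[c] if c is not None else 0.0)),
            }
            for p, c, _ in edges
        ]
        res = minimize(
            lambda x: float(((A @ x - b) ** 2).sum()),
            np.maximum(h, 0.0),
            jac=lambda x: 2.0 * A.T @ (A @ x - b),
            constraints=cons,
            bounds=[(0.0, None)] * k,
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        h = res.x
    h = np.maximum(h, 0.0)
    root_h = h[idx[dt.seed_node]]
    if root_h <= 0:
        raise ValueError("degenerate tree: fitted root height is zero")
    scale = root_age / root_h
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
            continue
        hp = h[idx[node.parent_node]]
        hc = h[idx[node]] if not node.is_leaf() else 0.0
        node.edge.length = max(hp - hc, 0.0) * scale
    return PhyloTree(dt)


def resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Break polytomies into binary nodes deterministically.

    Children are ordered by their smallest descendant tip label and folded
    left-to-right with zero-length internal branches, so the result is
    reproducible irrespective of input child order.
    """
    out = tree.copy()
    dt = out.dendropy_tree

    def min_tip(node):
        return min(l.taxon.label for l in node.leaf_iter())

    for node in list(dt.postorder_node_iter()):
        children = node.child_nodes()
        while len(children) > 2:
            children = sorted(children, key=min_tip)
            a, b_node = children[0], children[1]
            for ch in (a, b_node):
                node.remove_child(ch)
            joint = dendropy.Node()
            joint.edge.length = 0.0
            joint.add_child(a)
            joint.add_child(b_node)
            node.add_child(joint)
            children = node.child_nodes()
    return PhyloTree(dt)
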