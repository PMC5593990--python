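"""Phylogeny container, newick I/O and phylogenetic independent contrasts.

The tree is the substrate every analysis stage shares: clade extraction for
the per-node drift tests, branch bookkeeping for the per-branch selection
gradients, and the Felsenstein contrast recursion that estimates the
between-species (B) covariance while removing phylogenetic pseudo-replication.

Branch lengths are in time units (Myr for the intended data). Polytomies are
resolved into arbitrary bifurcations with zero-length inserted branches at
construction time; the contrast recursion replaces zero lengths with a small
positive epsilon proportional to tree depth.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TreeError",
    "NewickParseError",
    "Node",
    "Phylogeny",
    "ContrastSet",
    "read_newick",
    "clade_tips",
    "pic",
    "contrast_covariance",
]


class TreeError(ValueError):
    """Structural or data problem with a phylogeny."""


class NewickParseError(TreeError):
    """Malformed newick input; message carries position where available."""


_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}:;,']")


def _format_label(label: str) -> str:
    if label and _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


class Node:
    """A single tree node with parent/child links and an incoming branch length."""

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        kind = "tip" if self.is_tip else "internal"
        return f"<Node {self.label!r} ({kind}, length={self.length:g})>"


class Phylogeny:
    """Rooted phylogeny with uniquely labelled nodes.

    Tips must carry unique labels. Internal nodes without labels are assigned
    integer labels in preorder starting at ``n_tips + 1`` (so the root of an
    n-tip tree is node ``n+1``, the convention used for node tables).
    Polytomies are resolved into ladderized bifurcations with zero-length
    inserted branches.
    """

    def __init__(self, root: Node, resolve_polytomies: bool = True):
        self.root = root
        if resolve_polytomies:
            self._resolve_polytomies()
        self._index()

    # -- construction -----------------------------------------------------

    def _resolve_polytomies(self) -> None:
        for node in list(_walk_postorder(self.root)):
            while len(node.children) > 2:
                a, b = node.children[0], node.children[1]
                joint = Node(label=None, length=0.0)
                joint.parent = node
                joint.children = [a, b]
                a.parent = joint
                b.parent = joint
                node.children = [joint] + node.children[2:]
                logger.info(
                    "resolved polytomy under %r: grouped %r and %r with a "
                    "zero-length branch",
                    node.label, a.label, b.label,
                )

    def _index(self) -> None:
        post = list(_walk_postorder(self.root))
        self._postorder = post
        self._tips = [n for n in post if n.is_tip]
        used = set()
        for tip in self._tips:
            if tip.label is None:
                raise TreeError("every tip must carry a label")
            if tip.label in used:
                raise TreeError(f"duplicate tip label {tip.label!r}")
            used.add(tip.label)
        counter = len(self._tips) + 1
        for node in _walk_preorder(self.root):
            if node.is_tip:
                continue
            if node.label is None:
                while str(counter) in used:
                    counter += 1
                node.label = str(counter)
                counter += 1
            elif node.label in used:
                raise TreeError(f"duplicate node label {node.label!r}")
            used.add(node.label)
        for node in post:
            if node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length:g} at node {node.label!r}"
                )
        self._by_label = {n.label: n for n in post}

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return read_newick(text)

    # -- basic queries ----------------------------------------------------

    @property
    def tips(self) -> list[Node]:
        return list(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self._tips]

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def node(self, key: "str | Node") -> Node:
        if isinstance(key, Node):
            return key
        try:
            return self._by_label[key]
        except KeyError:
            raise TreeError(f"unknown node id {key!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def postorder(self) -> Iterator[Node]:
        return iter(self._postorder)

    def preorder(self) -> Iterator[Node]:
        return _walk_preorder(self.root)

    def internal_nodes(self) -> list[Node]:
        return [n for n in self._postorder if not n.is_tip]

    def branches(self) -> list[tuple[Node, Node]]:
        """All (parent, child) pairs, in preorder of the child."""
        return [(n.parent, n) for n in _walk_preorder(self.root) if n.parent is not None]

    def clade_tips(self, key: "str | Node") -> frozenset[str]:
        node = self.node(key)
        return frozenset(t.label for t in _walk_postorder(node) if t.is_tip)

    def depths(self) -> dict[str, float]:
        """Distance from the root to each node (root at 0)."""
        out: dict[str, float] = {self.root.label: 0.0}
        for node in _walk_preorder(self.root):
            if node.parent is not None:
                out[node.label] = out[node.parent.label] + node.length
        return out

    @property
    def depth(self) -> float:
        d = self.depths()
        return max(d[t.label] for t in self._tips)

    # -- derived trees ----------------------------------------------------

    def subtree(self, key: "str | Node") -> "Phylogeny":
        """Deep copy of the clade rooted at ``key`` (labels preserved)."""
        src = self.node(key)

        def _copy(n: Node) -> Node:
            m = Node(label=n.label, length=n.length)
            for c in n.children:
                m.add_child(_copy(c))
            return m

        new_root = _copy(src)
        new_root.length = 0.0
        new_root.parent = None
        return Phylogeny(new_root, resolve_polytomies=False)

    def copy(self) -> "Phylogeny":
        return self.subtree(self.root)

    # -- output -----------------------------------------------------------

    def to_newick(self, internal_labels: bool = True,
                  annotations: Mapping[str, str] | None = None) -> str:
        """Serialize to newick.

        ``annotations`` maps node label -> comment string inserted as
        ``[&...]`` after the node (used for branch-painted magnitudes).
        """

        def _fmt(n: Node) -> str:
            if n.is_tip:
                s = _format_label(n.label)
            else:
                inner = ",".join(_fmt(c) for c in n.children)
                lab = _format_label(n.label) if internal_labels else ""
                s = f"({inner}){lab}"
            if annotations and n.label in annotations:
                s += f"[&{annotations[n.label]}]"
            if n.parent is not None:
                s += f":{n.length:.10g}"
            return s

        return _fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips, root {self.root.label!r}>"


def _walk_postorder(root: Node) -> Iterator[Node]:
    stack: list[tuple[Node, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            yield node
        else:
            stack.append((node, True))
            for c in reversed(node.children):
                stack.append((c, False))


def _walk_preorder(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        for c in reversed(node.children):
            stack.append(c)


def read_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Polytomies are resolved into arbitrary (ladderized) bifurcations with
    zero-length inserted branches. Missing branch lengths default to 0.
    Negative branch lengths and malformed newick raise errors.
    """
    import dendropy

    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"newick string must end with ';' (offset {len(stripped)})"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc

    def _convert(dnode) -> Node:
        length = dnode.edge.length
        if length is None:
            length = 0.0
        if length < 0:
            raise TreeError(f"negative branch length {length:g} in newick input")
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = Node(label=label, length=length)
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
        return node

    root = _convert(dtree.seed_node)
    if root.is_tip and not root.children:
        raise NewickParseError("newick describes a single node, not a tree")
    return Phylogeny(root)


def clade_tips(tree: Phylogeny, node: "str | Node") -> frozenset[str]:
    """Tip labels of the subtree rooted at ``node`` (a tip returns itself)."""
    return tree.clade_tips(node)


# ---------------------------------------------------------------------------
# Phylogenetic independent contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastSet:
    """Standardized Felsenstein contrasts, one per internal node.

    ``contrasts`` has shape (n_internal, p); each row is already divided by
    its branch-length standard deviation ``sd`` (sqrt of summed adjusted
    branch lengths), so under Brownian motion the rows are iid with the
    Brownian rate matrix as covariance. ``root_value`` is the GLS/ML estimate
    of the root state produced by the same recursion.
    """

    node_ids: list[str]
    contrasts: np.ndarray
    sd: np.ndarray
    root_value: np.ndarray

    def __len__(self) -> int:
        return self.contrasts.shape[0]


def _epsilon(tree: Phylogeny, factor: float = 1e-8) -> float:
    depth = tree.depth
    return factor * depth if depth > 0 else factor


def pic(tree: Phylogeny, tip_values: Mapping[str, Iterable[float]],
        *, min_length_factor: float = 1e-8) -> ContrastSet:
    """Felsenstein phylogenetic independent contrasts, vector-valued.

    At each internal node joining children with values x1, x2 and adjusted
    branch lengths v1, v2 the contrast is (x1 - x2)/sqrt(v1 + v2), the node
    value is the weighted average (x1 v2 + x2 v1)/(v1 + v2), and the node's
    outgoing branch is lengthened by v1 v2/(v1 + v2). Zero-length branches
    (e.g. from polytomy resolution) are replaced by an epsilon proportional
    to tree depth.
    """
    tips = tree.tip_labels
    missing = [t for t in tips if t not in tip_values]
    if missing:
        raise TreeError(f"missing tip value(s) for {missing}")
    first = np.atleast_1d(np.asarray(tip_values[tips[0]], dtype=float))
    p = first.shape[0]
    eps = _epsilon(tree, min_length_factor)

    values: dict[Node, np.ndarray] = {}
    vlen: dict[Node, float] = {}
    node_ids: list[str] = []
    rows: list[np.ndarray] = []
    sds: list[float] = []
    warned_zero = False

    for node in tree.postorder():
        raw_len = node.length if node.parent is not None else 0.0
        if node.parent is not None and raw_len <= 0:
            if not warned_zero:
                logger.info("zero-length branch(es) replaced by epsilon %g", eps)
                warned_zero = True
            raw_len = eps
        if node.is_tip:
            vec = np.atleast_1d(np.asarray(tip_values[node.label], dtype=float))
            if vec.shape[0] != p:
                raise TreeError(
                    f"tip {node.label!r} has {vec.shape[0]} values, expected {p}"
                )
            values[node] = vec
            vlen[node] = raw_len
            continue
        if len(node.children) != 2:
            raise TreeError(
                f"internal node {node.label!r} is not bifurcating; "
                "construct the tree with polytomy resolution enabled"
            )
        c1, c2 = node.children
        v1, v2 = vlen[c1], vlen[c2]
        x1, x2 = values[c1], values[c2]
        s = np.sqrt(v1 + v2)
        rows.append((x1 - x2) / s)
        sds.append(s)
        node_ids.append(node.label)
        values[node] = (x1 * v2 + x2 * v1) / (v1 + v2)
        vlen[node] = raw_len + v1 * v2 / (v1 + v2)

    return ContrastSet(
        node_ids=node_ids,
        contrasts=np.array(rows, dtype=float).reshape(len(rows), p),
        sd=np.array(sds, dtype=float),
        root_value=values[tree.root],
    )


def contrast_covariance(contrasts: ContrastSet):
    """Between-species covariance (B) from standardized contrasts.

    Contrasts have expectation zero under Brownian motion, so the estimator
    is the mean of outer products with divisor equal to the number of
    contrasts, without mean-centering.
    """
    from .covmat import CovMatrix  # local import to avoid a cycle

    m = len(contrasts)
    if m < 1:
        raise TreeError("need at least one contrast")
    if m == 1:
        logger.warning("single contrast: B matrix is a rank-1 outer product")
    c = contrasts.contrasts
    values = c.T @ c / m
    return CovMatrix(values=values, role="B", provenance=None, n=m)
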