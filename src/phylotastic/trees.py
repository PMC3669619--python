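"""Rooted-tree data model with Newick/NEXUS I/O, MRCA and patristic distances.

The tree model is deliberately small: a :class:`Tree` owns :class:`Node`
objects linked parent↔children, each node carrying an optional label, an
optional branch length (edge to its parent; ``None`` means *unknown*, which is
distinct from ``0.0``) and an optional age (time before present, 0 = extant).

Conventions:

* Trees are rooted. Unrooted Newick input is read as rooted at the outermost
  node.
* Underscores in labels are significant characters by default (``Homo_sapiens``
  stays ``Homo_sapiens``); pass ``underscores_to_spaces=True`` to get the other
  common Newick convention.
* Tip labels must be unique within a tree — names are the join key of every
  downstream operation, so duplicates are a hard error.
"""

from __future__ import annotations

import io
import itertools
from typing import Iterable, Iterator, Optional

import dendropy
import numpy as np
import pandas as pd

from .errors import LabelLookupError, NewickParseError, TreeInvariantError

__all__ = [
    "Node",
    "Tree",
    "parse_newick",
    "write_newick",
    "parse_nexus_trees",
    "mrca",
    "patristic_matrix",
]

# Characters that force quoting when serializing a label.
_NEEDS_QUOTE = set("()[]{}:;,'\" \t\n")


class Node:
    """A single tree node.

    Parameters
    ----------
    label : str, optional
        Taxon or clade name. Tips must be labeled; internal nodes may be.
    branch_length : float, optional
        Length of the edge to the parent. ``None`` = unknown (not zero).
    age : float, optional
        Node age in time units before present (0 = present day).
    """

    __slots__ = ("id", "label", "branch_length", "age", "parent", "children")

    def __init__(self, label: Optional[str] = None,
                 branch_length: Optional[float] = None,
                 age: Optional[float] = None):
        self.id: int = -1  # assigned by Tree.reindex()
        self.label = label
        self.branch_length = branch_length
        self.age = age
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.id} {self.label!r} {kind}>"


class Tree:
    """A rooted phylogeny."""

    def __init__(self, root: Node, name: str = ""):
        self.root = root
        self.name = name
        self.reindex()

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    def reindex(self) -> None:
        """Assign preorder ids and rebuild the tip-label index."""
        self._tip_index: dict[str, Node] = {}
        for i, node in enumerate(self.preorder()):
            node.id = i
            if node.is_tip and node.label is not None:
                if node.label in self._tip_index:
                    raise TreeInvariantError(
                        f"duplicate tip label {node.label!r}")
                self._tip_index[node.label] = node

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def find_tip(self, label: str) -> Node:
        try:
            return self._tip_index[label]
        except KeyError:
            raise LabelLookupError([label]) from None

    def __len__(self) -> int:
        return sum(1 for _ in self.preorder())

    def n_tips(self) -> int:
        return len(self._tip_index)

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants, raising :class:`TreeInvariantError`."""
        seen = set()
        for node in self.preorder():
            if id(node) in seen:
                raise TreeInvariantError("cycle detected in parent graph")
            seen.add(id(node))
            if node.branch_length is not None:
                if not np.isfinite(node.branch_length) or node.branch_length < 0:
                    raise TreeInvariantError(
                        f"invalid branch length {node.branch_length!r} "
                        f"on node {node.label or node.id}")
            if (node.age is not None and node.parent is not None
                    and node.parent.age is not None
                    and node.parent.age < node.age - 1e-12):
                raise TreeInvariantError(
                    f"age inversion: node {node.label or node.id} older "
                    f"than its parent")
            for child in node.children:
                if child.parent is not node:
                    raise TreeInvariantError("broken parent link")
        self.reindex()  # re-raises on duplicate tip labels

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def ancestors(self, node: Node) -> Iterator[Node]:
        """Yield node, parent, ..., root."""
        while node is not None:
            yield node
            node = node.parent

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the named tips.

        ``mrca({x})`` is the tip ``x`` itself.
        """
        labels = list(labels)
        if not labels:
            raise ValueError("mrca requires at least one label")
        missing = [lb for lb in labels if lb not in self._tip_index]
        if missing:
            raise LabelLookupError(missing)
        nodes = [self._tip_index[lb] for lb in labels]
        common = None
        for node in nodes:
            path = set(id(a) for a in self.ancestors(node))
            common = path if common is None else (common & path)
        # deepest shared ancestor = first ancestor of any tip in the set
        for anc in self.ancestors(nodes[0]):
            if id(anc) in common:
                return anc
        raise TreeInvariantError("no common ancestor; tree is disconnected")

    def depths(self, missing_as_error: bool = True) -> dict[int, float]:
        """Root-to-node path lengths keyed by node id."""
        depth: dict[int, float] = {self.root.id: 0.0}
        for node in self.preorder():
            if node.is_root:
                continue
            if node.branch_length is None:
                if missing_as_error:
                    raise TreeInvariantError(
                        f"missing branch length on node "
                        f"{node.label or node.id}")
                bl = 0.0
            else:
                bl = node.branch_length
            depth[node.id] = depth[node.parent.id] + bl
        return depth

    def is_ultrametric(self, rel_tol: float = 1e-6) -> tuple[bool, Optional[str]]:
        """Whether all tips are equidistant from the root.

        Returns ``(ok, offending_tip_label)``; tolerance is relative to the
        maximum root-to-tip depth.
        """
        depth = self.depths()
        tip_depths = {n.label: depth[n.id] for n in self.tips()}
        dmax = max(tip_depths.values())
        tol = rel_tol * dmax if dmax > 0 else rel_tol
        for label, d in tip_depths.items():
            if abs(d - dmax) > tol:
                return False, label
        return True, None

    # ------------------------------------------------------------------
    # copy / compare
    # ------------------------------------------------------------------
    def copy(self) -> "Tree":
        def _clone(node: Node) -> Node:
            new = Node(node.label, node.branch_length, node.age)
            for child in node.children:
                new.add_child(_clone(child))
            return new
        return Tree(_clone(self.root), name=self.name)

    def isomorphic_to(self, other: "Tree", tol: float = 1e-9) -> bool:
        """Topology + labels + branch lengths equality, ignoring child order."""
        return (_canonical(self.root, tol) == _canonical(other.root, tol))

    def __repr__(self):  # pragma: no cover
        return f"<Tree {self.name!r} with {self.n_tips()} tips>"


def _canonical(node: Node, tol: float):
    bl = None if node.branch_length is None else round(node.branch_length / tol) * tol
    if node.is_tip:
        return (node.label, bl)
    kids = tuple(sorted((_canonical(c, tol) for c in node.children), key=repr))
    return (node.label, bl, kids)


# ----------------------------------------------------------------------
# Newick / NEXUS reading (dendropy-backed)
# ----------------------------------------------------------------------

def _from_dendropy(dtree: "dendropy.Tree", name: str = "") -> Tree:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        node = Node(label=label, branch_length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    tree = Tree(root, name=name)
    for node in tree.preorder():
        if node.branch_length is not None and node.branch_length < 0:
            raise NewickParseError(
                f"negative branch length {node.branch_length} on "
                f"{node.label or f'node {node.id}'}")
    if tree.root.branch_length == 0.0:
        # ";"-terminated root length of 0 is conventionally dropped
        pass
    return tree


def parse_newick(text: str, underscores_to_spaces: bool = False,
                 name: str = "") -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Quoted labels are honoured, ``[...]`` comments skipped. Underscores are
    significant unless ``underscores_to_spaces`` is set. Duplicate tip labels
    and negative branch lengths are errors.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    if not text.strip().endswith(";"):
        raise NewickParseError("Newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=not underscores_to_spaces,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy error messages carry token/position
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    try:
        return _from_dendropy(dtree, name=name)
    except TreeInvariantError as exc:
        raise NewickParseError(str(exc)) from exc


def parse_nexus_trees(text: str, underscores_to_spaces: bool = False) -> list[Tree]:
    """Parse all trees from the TREES block of a NEXUS document.

    A TRANSLATE table, when present, is resolved to plain labels.
    """
    try:
        tree_list = dendropy.TreeList.get(
            data=text,
            schema="nexus",
            preserve_underscores=not underscores_to_spaces,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed NEXUS: {exc}") from exc
    if len(tree_list) == 0:
        raise NewickParseError("no TREES block / TREE statements found")
    out = []
    for dtree in tree_list:
        name = dtree.label or ""
        out.append(_from_dendropy(dtree, name=name))
    return out


# ----------------------------------------------------------------------
# Newick writing (deterministic, ours)
# ----------------------------------------------------------------------

def format_length(x: float) -> str:
    """Shortest round-trip decimal; positional (no exponent) below 1e-3."""
    if x == int(x) and abs(x) < 1e16:
        return repr(int(x))
    s = repr(float(x))
    if "e" in s or "E" in s:
        s = np.format_float_positional(x, unique=True, trim="-")
    return s


def _quote_label(label: str) -> str:
    if label and not (_NEEDS_QUOTE & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: Tree, include_lengths: bool = True) -> str:
    """Serialize to Newick. Children appear in stored order; output is
    deterministic and round-trips through :func:`parse_newick`."""
    buf = io.StringIO()

    def emit(node: Node) -> None:
        if node.children:
            buf.write("(")
            for i, child in enumerate(node.children):
                if i:
                    buf.write(",")
                emit(child)
            buf.write(")")
        if node.label is not None:
            buf.write(_quote_label(node.label))
        if include_lengths and node.branch_length is not None:
            buf.write(":")
            buf.write(format_length(node.branch_length))

    emit(tree.root)
    buf.write(";")
    return buf.getvalue()


# ----------------------------------------------------------------------
# module-level conveniences mirroring Tree methods
# ----------------------------------------------------------------------

def mrca(tree: Tree, labels: Iterable[str]) -> Node:
    """Most recent common ancestor of the named tips (see :meth:`Tree.mrca`)."""
    return tree.mrca(labels)


def patristic_matrix(tree: Tree) -> pd.DataFrame:
    """Tip-to-tip path-length matrix as a labeled symmetric DataFrame.

    Requires every non-root branch length to be present. ``d(i,j)`` is the sum
    of branch lengths on the path from tip *i* up to the MRCA and down to *j*.
    """
    depth = tree.depths()
    labels = tree.tip_labels()
    index = {lb: k for k, lb in enumerate(labels)}
    n = len(labels)
    mat = np.zeros((n, n))

    # post-order merge of descendant tip sets: pairs first meeting at `node`
    # have distance depth(i) + depth(j) - 2*depth(node)
    tipsets: dict[int, list[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            tipsets[node.id] = [node.label]
            continue
        groups = [tipsets.pop(c.id) for c in node.children]
        for ga, gb in itertools.combinations(groups, 2):
            for la in ga:
                ia = index[la]
                da = depth[tree._tip_index[la].id]
                for lb in gb:
                    ib = index[lb]
                    d = da + depth[tree._tip_index[lb].id] - 2 * depth[node.id]
                    mat[ia, ib] = mat[ib, ia] = d
        merged = [lb for g in groups for lb in g]
        tipsets[node.id] = merged
    return pd.DataFrame(mat, index=labels, columns=labels)
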