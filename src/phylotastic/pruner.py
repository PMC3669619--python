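"""Megatree pruning via a denormalized taxon-to-root path index.

Pruning a handful of taxa out of a 10^4–10^5-tip tree is the workhorse
operation of a phylotastic workflow. Re-parsing and re-walking the whole tree
per query is wasteful; instead the tree is pre-processed once into one
taxon-to-root path per tip (:class:`PathStore`). A pruning query then touches
only the queried tips' paths: collect them, take the union of their node sets,
rebuild that sub-DAG as a tree, and suppress unifurcations (summing the
collapsed edge lengths). Cost scales with the query size and path depth, not
with the size of the source tree.

Semantics:

* the pruned tree contains exactly ``labels ∩ store tips`` as tips;
* every internal node of the result has ≥ 2 children;
* patristic distances among retained tips equal those in the source tree;
* internal labels of suppressed nodes are discarded (the surviving node keeps
  its own label);
* query labels that match *internal* node labels are not expanded — they are
  reported as not found (higher-taxon expansion is the grafter's job).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import PruneError, StoreError, TreeInvariantError
from .trees import Node, Tree, format_length

__all__ = ["PathStore", "PruneReport", "build_path_store", "prune",
           "prune_tree", "naive_prune"]

STORE_FORMAT_VERSION = "1"


@dataclass
class PruneReport:
    """What happened to each queried label."""
    retained: list[str] = field(default_factory=list)
    not_found: list[str] = field(default_factory=list)
    internal_only: list[str] = field(default_factory=list)  # matched an internal label
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "not_found": self.not_found,
            "not_found_internal": self.internal_only,
            "warnings": self.warnings,
        }


class PathStore:
    """Denormalized taxon-to-root index of a source tree.

    ``tip_paths[label]`` is the ordered list of ``(node id, edge length)``
    pairs from the tip itself up to (and including) the root; the root entry
    carries its own (usually absent) edge length. ``node_labels`` and
    ``node_order`` preserve internal labels and the source preorder, so
    rebuilt trees keep the source's child order.
    """

    def __init__(self, tree_name: str,
                 tip_paths: dict[str, list[tuple[int, Optional[float]]]],
                 node_labels: dict[int, Optional[str]],
                 node_order: dict[int, int]):
        self.tree_name = tree_name
        self.tip_paths = tip_paths
        self.node_labels = node_labels
        self.node_order = node_order
        roots = {path[-1][0] for path in tip_paths.values()}
        if len(roots) > 1:
            raise StoreError(f"paths end at {len(roots)} distinct roots")
        self.root_id = roots.pop() if roots else None

    @property
    def tip_count(self) -> int:
        return len(self.tip_paths)

    # ------------------------------------------------------------------
    # serialization: versioned, line-oriented, one tip per line
    # ------------------------------------------------------------------
    def dumps(self) -> str:
        """Serialize: header lines, then ``tip<TAB>node:len|node:len|...``."""
        buf = io.StringIO()
        buf.write(f"#phylotastic-pathstore\tv{STORE_FORMAT_VERSION}\n")
        buf.write(f"#tree\t{self.tree_name}\n")
        for nid in sorted(self.node_labels):
            label = self.node_labels[nid]
            if label is not None:
                buf.write(f"#label\t{nid}\t{label}\n")
        for label in self.tip_paths:  # insertion order = source tip order
            segs = "|".join(
                f"{nid}:{'' if ln is None else format_length(ln)}"
                for nid, ln in self.tip_paths[label])
            buf.write(f"{label}\t{segs}\n")
        return buf.getvalue()

    @classmethod
    def loads(cls, text: str) -> "PathStore":
        lines = text.splitlines()
        if not lines or not lines[0].startswith("#phylotastic-pathstore"):
            raise StoreError("not a path-store file (missing magic header)")
        version = lines[0].split("\t")[1]
        if version != f"v{STORE_FORMAT_VERSION}":
            raise StoreError(f"unsupported path-store version {version!r}")
        tree_name = ""
        node_labels: dict[int, Optional[str]] = {}
        tip_paths: dict[str, list[tuple[int, Optional[float]]]] = {}
        for line in lines[1:]:
            if not line:
                continue
            if line.startswith("#tree\t"):
                tree_name = line.split("\t", 1)[1]
            elif line.startswith("#label\t"):
                _, nid, label = line.split("\t", 2)
                node_labels[int(nid)] = label
            else:
                tip, segs = line.split("\t", 1)
                path = []
                for seg in segs.split("|"):
                    nid, _, ln = seg.partition(":")
                    path.append((int(nid), float(ln) if ln else None))
                tip_paths[tip] = path
        # ids double as the preorder rank (see build_path_store)
        node_order = {nid: nid for p in tip_paths.values() for nid, _ in p}
        store = cls(tree_name, tip_paths, node_labels, node_order)
        return store

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def load(cls, path) -> "PathStore":
        with open(path) as fh:
            return cls.loads(fh.read())


def build_path_store(tree: Tree) -> PathStore:
    """Denormalize ``tree`` into per-tip root paths.

    Node ids in the store are the source preorder ranks, so the store also
    encodes the source child order. Unlabeled tips are an error.
    """
    tree.reindex()
    node_labels: dict[int, Optional[str]] = {}
    tip_paths: dict[str, list[tuple[int, Optional[float]]]] = {}
    node_order: dict[int, int] = {}
    for node in tree.preorder():
        node_order[node.id] = node.id
        if not node.is_tip and node.label is not None:
            node_labels[node.id] = node.label
        if node.is_tip:
            if node.label is None:
                raise TreeInvariantError(f"unlabeled tip (node id {node.id})")
            node_labels[node.id] = node.label
            path = [(a.id, a.branch_length) for a in tree.ancestors(node)]
            tip_paths[node.label] = path
    return PathStore(tree.name, tip_paths, node_labels, node_order)


def prune(store: PathStore, labels: Iterable[str]) -> tuple[Tree, PruneReport]:
    """Prune the stored tree down to ``labels``.

    Returns ``(tree, report)``. Raises :class:`PruneError` when no queried
    label is a tip of the source tree.
    """
    labels = list(dict.fromkeys(labels))  # dedupe, keep order
    report = PruneReport()
    tip_node_ids = {p[0][0] for p in store.tip_paths.values()}
    internal_labels = {lb for nid, lb in store.node_labels.items()
                       if lb is not None and nid not in tip_node_ids}
    # classify
    hits = []
    tip_label_set = store.tip_paths.keys()
    for lb in labels:
        if lb in tip_label_set:
            hits.append(lb)
        elif lb in internal_labels:
            report.internal_only.append(lb)
        else:
            report.not_found.append(lb)
    if not hits:
        raise PruneError(
            f"no taxa found in source tree {store.tree_name!r} "
            f"({len(labels)} queried)")
    report.retained = list(hits)
    if len(hits) == 1:
        report.warnings.append(
            f"only one queried taxon ({hits[0]}) found; returning a "
            f"single-tip tree")

    # union of path nodes; record parent and edge-length per node
    keep: dict[int, tuple[Optional[int], Optional[float]]] = {}
    for lb in hits:
        path = store.tip_paths[lb]
        for k, (nid, ln) in enumerate(path):
            if nid in keep:
                break  # shared suffix already recorded
            parent = path[k + 1][0] if k + 1 < len(path) else None
            keep[nid] = (parent, ln)

    # rebuild: children sorted by source preorder rank for determinism
    children: dict[Optional[int], list[int]] = {}
    for nid, (parent, _) in keep.items():
        children.setdefault(parent, []).append(nid)
    for kids in children.values():
        kids.sort(key=lambda nid: store.node_order.get(nid, nid))
    root_id = children[None][0]

    def build(nid: int) -> Node:
        _, ln = keep[nid]
        node = Node(label=store.node_labels.get(nid), branch_length=ln)
        for cid in children.get(nid, []):
            node.add_child(build(cid))
        return node

    root = build(root_id)
    root = _suppress_unifurcations(root)
    root.branch_length = None  # root of a pruned tree has no parent edge
    tree = Tree(root, name=store.tree_name)
    return tree, report


def _sum_lengths(a: Optional[float], b: Optional[float]) -> Optional[float]:
    # unknown propagates: collapsing an edge of unknown length gives unknown
    if a is None and b is None:
        return None
    if a is None or b is None:
        return a if b is None else b
    return a + b


def _suppress_unifurcations(root: Node) -> Node:
    """Collapse every single-child internal node, summing edge lengths.

    The surviving (child) node keeps its own label; the suppressed node's
    label is discarded.
    """
    while len(root.children) == 1 and root.children:
        child = root.children[0]
        child.branch_length = _sum_lengths(root.branch_length,
                                           child.branch_length)
        child.parent = None
        root = child
    stack = [root]
    while stack:
        node = stack.pop()
        new_children = []
        for child in node.children:
            while len(child.children) == 1:
                grand = child.children[0]
                grand.branch_length = _sum_lengths(child.branch_length,
                                                   grand.branch_length)
                child = grand
            child.parent = node
            new_children.append(child)
            stack.append(child)
        node.children = new_children
    return root


def prune_tree(tree: Tree, labels: Iterable[str]) -> tuple[Tree, PruneReport]:
    """One-shot convenience: build the path store, then prune."""
    return prune(build_path_store(tree), labels)


# ----------------------------------------------------------------------
# reference implementation (repeated leaf deletion); used as the oracle
# in tests and kept here so the CLI can cross-check on demand
# ----------------------------------------------------------------------

def _delete_leaf(node: Node) -> None:
    """Remove a leaf, then collapse any unifurcation it leaves behind."""
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    if not parent.children:
        # parent became a childless internal node: delete it too
        if parent.parent is not None:
            _delete_leaf(parent)
    elif len(parent.children) == 1 and parent.parent is not None:
        child = parent.children[0]
        child.branch_length = _sum_lengths(parent.branch_length,
                                           child.branch_length)
        grand = parent.parent
        grand.children[grand.children.index(parent)] = child
        child.parent = grand


def naive_prune(tree: Tree, labels: Iterable[str]) -> Tree:
    """Prune by deleting unwanted tips one at a time, collapsing each
    resulting unifurcation immediately. The behavioural reference for
    :func:`prune`."""
    wanted = set(labels)
    work = tree.copy()
    doomed = [n for n in work.tips() if n.label not in wanted]
    if len(doomed) == work.n_tips():
        raise PruneError("no queried taxon present in tree")
    for tip in doomed:
        _delete_leaf(tip)
    root = _suppress_unifurcations(work.root)
    root.branch_length = None
    return Tree(root, name=tree.name)
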