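"""Taxonomic grafting in the style of Phylomatic.

A query taxon that is missing from a source tree can often still be placed
using taxonomy alone: walk its taxonomic derivation (a slash-delimited chain
such as ``order/family/genus/genus species``) from the least inclusive rank
upward and attach the taxon as a new child of the first tree node whose label
matches one of those ranks. Matching is case-insensitive and exact — fuzzy
name repair belongs upstream in TNRS.

New edges carry no branch length (absent, not zero); assigning lengths is the
scaling module's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import FormatError
from .trees import Node, Tree

__all__ = ["TaxonomicPath", "GraftReport", "parse_taxon_path",
           "format_taxon_path", "graft"]


@dataclass(frozen=True)
class TaxonomicPath:
    """Ordered taxonomic derivation from most to least inclusive rank.

    The final element (``terminal``) is the taxon to place.
    """
    ranks: tuple[str, ...]

    def __post_init__(self):
        if not self.ranks:
            raise FormatError("empty taxonomic path")
        for r in self.ranks:
            if not r:
                raise FormatError("empty segment in taxonomic path")

    @property
    def terminal(self) -> str:
        return self.ranks[-1]


def parse_taxon_path(text: str) -> TaxonomicPath:
    """Parse ``"order/family/genus/genus species"`` into a TaxonomicPath.

    Segments are whitespace-trimmed; case is preserved (matching is done
    case-insensitively later).
    """
    if not text or not text.strip():
        raise FormatError("empty taxonomic path string")
    segments = [seg.strip() for seg in text.strip().split("/")]
    if any(not seg for seg in segments):
        raise FormatError(f"empty segment in taxonomic path {text!r}")
    return TaxonomicPath(tuple(segments))


def format_taxon_path(path: TaxonomicPath) -> str:
    return "/".join(path.ranks)


@dataclass
class GraftReport:
    placements: dict[str, str] = field(default_factory=dict)  # taxon -> node label
    already_present: list[str] = field(default_factory=list)
    unplaceable: list[str] = field(default_factory=list)
    ambiguous: dict[str, int] = field(default_factory=dict)  # taxon -> n candidate nodes

    def to_dict(self) -> dict:
        return {
            "placements": self.placements,
            "already_present": self.already_present,
            "unplaceable": self.unplaceable,
            "ambiguous": {t: n for t, n in self.ambiguous.items()},
        }


def _tipify(name: str) -> str:
    """Canonical tip-label form of a taxon name (spaces → underscores)."""
    return name.replace(" ", "_")


def _fold(name: str) -> str:
    return name.replace("_", " ").strip().casefold()


def graft(tree: Tree, paths: Iterable[TaxonomicPath]) -> tuple[Tree, GraftReport]:
    """Attach each path's terminal to the deepest matching higher-taxon node.

    Placement rule: among the path's non-terminal ranks, the least inclusive
    one (genus before family before order) whose name labels a node in the
    *original* tree wins; the terminal is appended as a new (last) child of
    that node. A bare binomial (single-element path) falls back to matching
    its genus word. Taxa already present as tips are untouched; taxa with no
    matching rank are reported unplaceable; a rank matching several nodes is
    reported ambiguous and not placed.

    Existing nodes are never removed or relabeled; placement is independent
    of the order of ``paths`` (placements are resolved against the original
    tree and applied in sorted terminal order).
    """
    work = tree.copy()
    report = GraftReport()

    # index original labels, case-insensitively, space/underscore-insensitively
    label_nodes: dict[str, list[Node]] = {}
    for node in work.preorder():
        if node.label is not None:
            label_nodes.setdefault(_fold(node.label), []).append(node)
    tip_labels = {_fold(lb) for lb in work.tip_labels()}

    planned: list[tuple[str, Node]] = []
    seen_terminals: set[str] = set()
    for path in paths:
        terminal = path.terminal
        key = _fold(terminal)
        if key in seen_terminals:
            continue  # set semantics over the input list
        seen_terminals.add(key)
        if key in tip_labels:
            report.already_present.append(terminal)
            continue
        candidates: Sequence[str] = list(path.ranks[:-1])[::-1]  # least→most inclusive
        if not candidates:
            genus = terminal.replace("_", " ").split()[0]
            candidates = [genus] if genus and genus.casefold() != key else []
        placed = False
        for rank in candidates:
            nodes = label_nodes.get(_fold(rank), [])
            if len(nodes) > 1:
                report.ambiguous[terminal] = len(nodes)
                placed = True  # handled (as a failure); stop scanning
                break
            if len(nodes) == 1:
                planned.append((terminal, nodes[0]))
                report.placements[terminal] = nodes[0].label
                placed = True
                break
        if not placed:
            report.unplaceable.append(terminal)

    # apply in deterministic order, independent of input ordering
    for terminal, target in sorted(planned, key=lambda kv: _tipify(kv[0])):
        if target.is_tip:
            # the matched node is itself a tip: convert it to an internal
            # node keeping the original taxon as a same-named child tip
            original = Node(label=target.label)
            target.add_child(original)
        target.add_child(Node(label=_tipify(terminal)))
    work.reindex()
    return work, report
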