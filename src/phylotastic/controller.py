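"""End-to-end workflow: dirty names → resolution → source-tree selection →
(optional grafting) → pruning → (optional) age scaling → annotated tree.

This is the controller that chains the standalone services into the minimal
"list of names in, custom phylogeny out" workflow. Every run emits a
:class:`ProvenanceRecord` identifying the source tree and its citation, each
operation applied with its parameters, the per-name resolution decisions, and
a name-conservation ledger:

    |submitted| = |resolved kept| + |unresolved|
    |resolved kept| = |in output tree| + |not in source tree|

Each stage is also callable standalone (see the sibling modules); the
pipeline only orchestrates.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import __version__
from ._schema import load_schema, validate
from .datelife import ChronogramStore, query_ages
from .errors import PhylotasticError, PruneError, StoreError
from .grafter import TaxonomicPath, graft
from .pruner import prune_tree
from .scaling import CalibrationSet, bladj
from .tnrs import NameResolver, ResolverOptions, TableAdaptor, TaxonomyTable
from .trees import Tree, write_newick

__all__ = ["RegisteredTree", "WorkflowConfig", "ProvenanceRecord",
           "PipelineResult", "select_source_tree", "run_pipeline",
           "emit_provenance"]


def _tipify(name: str) -> str:
    return name.replace(" ", "_")


@dataclass
class RegisteredTree:
    id: str
    tree: Tree
    citation: str = ""


@dataclass
class WorkflowConfig:
    """Everything a pipeline run needs besides the name list."""
    trees: dict[str, RegisteredTree] = field(default_factory=dict)
    taxonomies: list[TaxonomyTable] = field(default_factory=list)
    resolution: str = "strict"            # strict | fuzzy | off
    scaling: str = "none"                 # none | bladj | datelife
    calibrations: Optional[CalibrationSet] = None
    chronogram_store: Optional[ChronogramStore] = None
    graft_missing: bool = False
    tree_id: Optional[str] = None         # user-supplied tree is mandatory
    output_format: str = "newick"

    def __post_init__(self):
        if self.resolution not in ("strict", "fuzzy", "off"):
            raise ValueError(f"bad resolution policy {self.resolution!r}")
        if self.scaling not in ("none", "bladj", "datelife"):
            raise ValueError(f"bad scaling mode {self.scaling!r}")
        if self.scaling == "bladj" and self.calibrations is None:
            raise ValueError("bladj scaling requires calibrations")
        if self.scaling == "datelife" and self.chronogram_store is None:
            raise ValueError("datelife scaling requires a chronogram store")
        ids = [rt.id for rt in self.trees.values()]
        if len(set(ids)) != len(ids):
            raise ValueError("registered tree ids must be unique")


@dataclass
class ProvenanceRecord:
    source_tree: str = ""
    citation: str = ""
    operations: list[dict] = field(default_factory=list)
    name_decisions: list[dict] = field(default_factory=list)
    ledger: dict = field(default_factory=dict)
    timestamp: str = ""
    tool_version: str = ""

    def to_dict(self) -> dict:
        return {
            "source_tree": self.source_tree,
            "citation": self.citation,
            "operations": self.operations,
            "name_decisions": self.name_decisions,
            "ledger": self.ledger,
            "timestamp": self.timestamp,
            "tool_version": self.tool_version,
        }


@dataclass
class PipelineResult:
    tree: Tree
    provenance: ProvenanceRecord

    @property
    def newick(self) -> str:
        return write_newick(self.tree)


def select_source_tree(trees: dict[str, RegisteredTree] | dict[str, Tree],
                       names: Iterable[str]) -> tuple[str, int]:
    """Pick the registered tree with the best coverage of ``names``.

    Coverage = |names ∩ tips| (after space→underscore normalization); ties
    go to the tree with fewer tips, then to the lexicographically smaller
    id. Raises :class:`PhylotasticError` when no tree covers any name.
    """
    if not trees:
        raise PhylotasticError("no registered source trees")
    wanted = {_tipify(n) for n in names}
    best = None
    for tree_id in sorted(trees):
        entry = trees[tree_id]
        tree = entry.tree if isinstance(entry, RegisteredTree) else entry
        tips = set(tree.tip_labels())
        coverage = len(wanted & tips)
        key = (-coverage, len(tips), tree_id)
        if best is None or key < best[0]:
            best = (key, tree_id, coverage)
    _, tree_id, coverage = best
    if coverage == 0:
        raise PhylotasticError(
            "no suitable source tree: zero coverage of the query everywhere")
    return tree_id, coverage


def _resolve_stage(names: Sequence[str], config: WorkflowConfig,
                   record: ProvenanceRecord) -> list[str]:
    """Run TNRS (or pass through) and log every per-name decision.

    Under ``fuzzy``, the highest-scoring match wins, exact score ties going
    to the alphabetically first matched name (flagged ambiguous). Under
    ``strict``, ambiguity at the top score drops the name with a warning.
    """
    if config.resolution == "off" or not config.taxonomies:
        for n in names:
            record.name_decisions.append(
                {"submitted": n, "matched": n, "score": None,
                 "source": None, "outcome": "kept", "ambiguous": False})
        record.operations.append(
            {"stage": "resolve", "parameters": {"policy": "off"}})
        return list(names)

    resolver = NameResolver([TableAdaptor(t) for t in config.taxonomies])
    options = ResolverOptions(fuzzy=(config.resolution == "fuzzy"))
    report = resolver.resolve("\n".join(names), options)
    kept: list[str] = []
    for group in report["names"]:
        submitted = group["submittedName"]
        matches = group["matches"]
        if not matches:
            record.name_decisions.append(
                {"submitted": submitted, "matched": None, "score": None,
                 "source": None, "outcome": "unresolved", "ambiguous": False})
            continue
        top_score = matches[0]["score"]
        top = [m for m in matches if m["score"] == top_score]
        distinct = sorted({m["matchedName"] for m in top})
        ambiguous = len(distinct) > 1
        if ambiguous and config.resolution == "strict":
            record.name_decisions.append(
                {"submitted": submitted, "matched": None, "score": top_score,
                 "source": None, "outcome": "dropped_ambiguous",
                 "ambiguous": True})
            continue
        winner = next(m for m in matches if m["matchedName"] == distinct[0])
        record.name_decisions.append(
            {"submitted": submitted, "matched": winner["matchedName"],
             "score": winner["score"], "source": winner["sourceId"],
             "outcome": "kept", "ambiguous": ambiguous})
        kept.append(winner["matchedName"])
    record.operations.append(
        {"stage": "resolve",
         "parameters": {"policy": config.resolution,
                        "sources": [t.source_id for t in config.taxonomies]}})
    return kept


def _taxon_path_for(name: str, tables: Sequence[TaxonomyTable]
                    ) -> Optional[TaxonomicPath]:
    """Build an order/family/genus/binomial derivation from taxonomy rows."""
    from .tnrs import normalize_name
    key = normalize_name(name)
    for table in tables:
        rowid = table.accepted.get(key)
        if rowid is None:
            continue
        row = table.df.iloc[rowid]
        cols = {c.lower(): c for c in table.df.columns}
        ranks = []
        for rank in ("order", "family"):
            if rank in cols and row[cols[rank]]:
                ranks.append(str(row[cols[rank]]))
        ranks.append(str(row[table.genus_col]))
        ranks.append(table.accepted_binomial(rowid))
        return TaxonomicPath(tuple(ranks))
    return None


def _datelife_scale(tree: Tree, store: ChronogramStore,
                    record: ProvenanceRecord) -> Tree:
    """Hybrid scaling: date internal nodes whose subtree tips the chronogram
    store can age, then interpolate the remainder bladj-style."""
    work = tree.copy()
    # temporary unique labels so ages can ride through the calibration set
    for node in work.preorder():
        if not node.is_tip and node.label is None:
            node.label = f"__dl{node.id}"
    ages: dict[str, float] = {}
    dated = 0
    for node in work.preorder():
        if node.is_tip:
            continue
        subtips = [t.label for t in _subtree_tips(node)]
        try:
            est = query_ages(store, subtips)
        except (StoreError, ValueError):
            continue
        best = min(est.per_source, key=lambda s: (-s.n_matched, s.source_id))
        age = best.mrca_age
        # keep ages consistent with an already-dated ancestor
        anc = node.parent
        ceiling = None
        while anc is not None:
            if anc.label in ages:
                ceiling = ages[anc.label]
                break
            anc = anc.parent
        if ceiling is not None and age > ceiling:
            continue  # conflicting estimate; leave to interpolation
        ages[node.label] = age
        dated += 1
    if work.root.label not in ages:
        raise StoreError("no dated source covers the root of the pruned tree")
    scaled = bladj(work, CalibrationSet(ages=ages))
    for node in scaled.preorder():
        if (node.label or "").startswith("__dl"):
            node.label = None
    scaled.reindex()
    record.operations.append(
        {"stage": "scale", "parameters": {"mode": "datelife",
                                          "nodes_dated": dated}})
    return scaled


def _subtree_tips(node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            yield n
        else:
            stack.extend(n.children)


def run_pipeline(names: Sequence[str] | str,
                 config: WorkflowConfig) -> PipelineResult:
    """Turn a list of taxon names into a custom phylogeny plus provenance.

    Stages run in order: resolve → select source tree → (graft missing
    taxa) → prune → (scale). Stage errors propagate with the stage name
    attached; the partially filled provenance record rides on the exception
    as ``exc.provenance``.
    """
    if isinstance(names, str):
        names = [ln.strip() for ln in names.splitlines() if ln.strip()]
    names = list(names)
    record = ProvenanceRecord(
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        tool_version=__version__)

    def fail(stage: str, exc: Exception):
        err = PhylotasticError(f"[{stage}] {exc}")
        err.provenance = record
        raise err from exc

    # 1. resolve
    try:
        resolved = _resolve_stage(names, config, record)
    except PhylotasticError as exc:
        fail("resolve", exc)
    unresolved = len(names) - len(resolved)

    # 2. source-tree selection
    try:
        if config.tree_id is not None:
            if config.tree_id not in config.trees:
                raise PhylotasticError(
                    f"unknown tree {config.tree_id!r}")
            tree_id = config.tree_id
            coverage = len({_tipify(n) for n in resolved}
                           & set(config.trees[tree_id].tree.tip_labels()))
        else:
            tree_id, coverage = select_source_tree(config.trees, resolved)
    except PhylotasticError as exc:
        fail("select", exc)
    registered = config.trees[tree_id]
    source = registered.tree
    record.source_tree = tree_id
    record.citation = registered.citation
    record.operations.append(
        {"stage": "select",
         "parameters": {"tree": tree_id, "coverage": coverage,
                        "user_supplied": config.tree_id is not None}})

    # 3. optional grafting of resolved-but-absent taxa
    if config.graft_missing and config.taxonomies:
        tips = set(source.tip_labels())
        missing = [n for n in resolved if _tipify(n) not in tips]
        paths = [p for p in (_taxon_path_for(n, config.taxonomies)
                             for n in missing) if p is not None]
        if paths:
            try:
                source, graft_report = graft(source, paths)
            except PhylotasticError as exc:
                fail("graft", exc)
            record.operations.append(
                {"stage": "graft",
                 "parameters": {"requested": len(paths),
                                "placed": len(graft_report.placements),
                                "unplaceable": graft_report.unplaceable}})

    # 4. prune
    query_tips = [_tipify(n) for n in resolved]
    try:
        tree, prune_report = prune_tree(source, query_tips)
    except PruneError as exc:
        fail("prune", exc)
    record.operations.append(
        {"stage": "prune",
         "parameters": {"query_size": len(query_tips),
                        "not_found": prune_report.not_found
                        + prune_report.internal_only}})

    # 5. scaling
    if config.scaling == "bladj":
        try:
            tree = bladj(tree, config.calibrations)
        except PhylotasticError as exc:
            fail("scale", exc)
        record.operations.append(
            {"stage": "scale",
             "parameters": {"mode": "bladj",
                            "n_calibrations": len(config.calibrations.ages)}})
    elif config.scaling == "datelife":
        try:
            tree = _datelife_scale(tree, config.chronogram_store, record)
        except PhylotasticError as exc:
            fail("scale", exc)

    in_output = tree.n_tips()
    record.ledger = {
        "submitted": len(names),
        "resolved_kept": len(resolved),
        "unresolved": unresolved,
        "in_output_tree": in_output,
        "not_in_source_tree": len(resolved) - in_output,
    }
    return PipelineResult(tree=tree, provenance=record)


def emit_provenance(record: ProvenanceRecord, validate_schema: bool = True
                    ) -> str:
    """Serialize a provenance record to schema-valid JSON."""
    doc = record.to_dict()
    if validate_schema:
        validate(doc, load_schema("provenance.schema.json"))
    return json.dumps(doc, indent=1, sort_keys=True)
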