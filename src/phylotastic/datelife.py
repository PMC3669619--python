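"""MRCA-age queries over a local store of time-calibrated trees.

A :class:`ChronogramStore` holds fossil-calibrated ultrametric trees
(chronograms), each pre-processed once into a labeled patristic distance
matrix. Answering "how old is the MRCA of these taxa?" is then pure array
work: match the query against the matrix row names, subset, and use the
ultrametric identity *mrca age = max pairwise distance / 2* — no tree
traversal per query. Records holding several trees (e.g. post-burnin
posterior samples) contribute one age per sample, and the answer across all
sources is reported as a range.

Taxon names are expected to be pre-resolved (run TNRS first); matching here
is exact on tip labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import StoreError
from .trees import Tree, parse_newick, patristic_matrix, write_newick, Node

__all__ = ["ChronogramRecord", "ChronogramStore", "AgeEstimate",
           "build_store", "query_ages", "render_estimate"]

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class ChronogramRecord:
    """One dated source: citation plus ≥1 ultrametric trees and their
    precomputed patristic matrices."""
    id: str
    citation: str
    trees: list[Tree]
    matrices: list[pd.DataFrame] = field(default_factory=list)

    @property
    def taxa(self) -> set[str]:
        out: set[str] = set()
        for m in self.matrices:
            out.update(m.index)
        return out


@dataclass
class SourceEstimate:
    source_id: str
    citation: str
    mrca_age: float            # age from the record's first (or only) tree
    n_matched: int
    sample_ages: list[float]   # one age per sample tree with >=2 matches
    matched_taxa: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        ages = sorted(self.sample_ages)
        return {"min": ages[0], "median": float(np.median(ages)),
                "max": ages[-1]}


@dataclass
class AgeEstimate:
    """Result of one age query: per-source estimates plus the overall range."""
    query_taxa: list[str]
    per_source: list[SourceEstimate]
    unmatched_sources: list[str]   # sources matching <2 query taxa

    @property
    def overall_range(self) -> tuple[float, float]:
        ages = [a for s in self.per_source for a in s.sample_ages]
        return (min(ages), max(ages))


class ChronogramStore:
    """A set of chronogram records, queryable by taxon sets."""

    def __init__(self, records: Sequence[ChronogramRecord] = ()):
        self.records: dict[str, ChronogramRecord] = {}
        for rec in records:
            if rec.id in self.records:
                raise StoreError(f"duplicate record id {rec.id!r}")
            self.records[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    # ------------------------------------------------------------------
    # serialization (single JSON document; trees as Newick strings)
    # ------------------------------------------------------------------
    def dumps(self) -> str:
        doc = {"format": "phylotastic-chronogram-store", "version": 1,
               "records": []}
        for rec_id in sorted(self.records):
            rec = self.records[rec_id]
            doc["records"].append({
                "id": rec.id,
                "citation": rec.citation,
                "trees": [write_newick(t) for t in rec.trees],
            })
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def loads(cls, text: str) -> "ChronogramStore":
        doc = json.loads(text)
        if doc.get("format") != "phylotastic-chronogram-store":
            raise StoreError("not a chronogram-store document")
        return build_store([(r["id"], r["citation"], r["trees"])
                            for r in doc["records"]])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def load(cls, path) -> "ChronogramStore":
        with open(path) as fh:
            return cls.loads(fh.read())


def build_store(records: Iterable[tuple[str, str, Sequence[str] | Sequence[Tree]]]
                ) -> ChronogramStore:
    """Build a store from ``(id, citation, trees)`` triples.

    Trees may be Newick strings or :class:`Tree` objects; each must carry
    full branch lengths and be ultrametric (within a relative tolerance of
    ``1e-6`` of the root depth — numerical slack for serialized chronograms,
    not a licence for non-clocklike trees). Patristic matrices are computed
    here, once.
    """
    out = []
    for rec_id, citation, raw_trees in records:
        trees: list[Tree] = []
        matrices: list[pd.DataFrame] = []
        for k, raw in enumerate(raw_trees):
            tree = raw if isinstance(raw, Tree) else parse_newick(
                raw, name=f"{rec_id}[{k}]")
            ok, offender = tree.is_ultrametric(rel_tol=ULTRAMETRIC_RTOL)
            if not ok:
                raise StoreError(
                    f"record {rec_id!r}, tree {k}: not ultrametric "
                    f"(tip {offender!r} deviates)")
            trees.append(tree)
            matrices.append(patristic_matrix(tree))
        out.append(ChronogramRecord(id=rec_id, citation=citation,
                                    trees=trees, matrices=matrices))
    return ChronogramStore(out)


def _mrca_age_from_matrix(matrix: pd.DataFrame, taxa: Sequence[str]) -> Optional[float]:
    present = [t for t in taxa if t in matrix.index]
    if len(present) < 2:
        return None
    sub = matrix.loc[present, present].to_numpy()
    return float(sub.max() / 2.0)


def query_ages(store: ChronogramStore, taxa: Iterable[str]) -> AgeEstimate:
    """Age of the MRCA of ``taxa`` in every source that contains ≥2 of them.

    Raises :class:`StoreError` when no source matches at least two taxa.
    The result is independent of the order in which taxa are listed.
    """
    taxa = sorted(set(taxa))
    if len(taxa) < 2:
        raise ValueError("age queries need at least two taxa")
    per_source: list[SourceEstimate] = []
    unmatched: list[str] = []
    for rec_id in sorted(store.records):
        rec = store.records[rec_id]
        sample_ages = []
        matched: set[str] = set()
        for matrix in rec.matrices:
            age = _mrca_age_from_matrix(matrix, taxa)
            if age is not None:
                sample_ages.append(age)
                matched.update(t for t in taxa if t in matrix.index)
        if sample_ages:
            per_source.append(SourceEstimate(
                source_id=rec.id, citation=rec.citation,
                mrca_age=sample_ages[0], n_matched=len(matched),
                sample_ages=sample_ages, matched_taxa=sorted(matched)))
        else:
            unmatched.append(rec.id)
    if not per_source:
        raise StoreError("no dated source matches at least two of the "
                         "queried taxa")
    return AgeEstimate(query_taxa=list(taxa), per_source=per_source,
                       unmatched_sources=unmatched)


def render_estimate(estimate: AgeEstimate, format: str = "json") -> str:
    """Render an :class:`AgeEstimate` as JSON (documented schema) or as a
    Newick tree of the matched taxa from the best-covering source, scaled so
    the root age equals that source's MRCA age.

    Best-covering source = most matched taxa; ties go to the
    lexicographically smaller source id. The ``median`` in sample summaries
    is this implementation's addition to the min/max range.
    """
    if format == "json":
        lo, hi = estimate.overall_range
        doc = {
            "query": estimate.query_taxa,
            "per_source": [
                {"id": s.source_id, "citation": s.citation,
                 "mrca_age": s.mrca_age, "n_matched": s.n_matched,
                 "sample_ages": s.sample_ages,
                 "sample_summary": s.summary()}
                for s in estimate.per_source],
            "no_estimate": estimate.unmatched_sources,
            "overall_range": [lo, hi],
        }
        return json.dumps(doc, indent=1, sort_keys=True)
    if format == "newick":
        best = min(estimate.per_source,
                   key=lambda s: (-s.n_matched, s.source_id))
        root = Node()
        for taxon in best.matched_taxa:
            root.add_child(Node(label=taxon, branch_length=best.mrca_age))
        return write_newick(Tree(root, name=best.source_id))
    raise ValueError(f"unknown render format {format!r}")
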