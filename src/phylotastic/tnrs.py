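"""Taxonomic name resolution (TNRS) over local CSV taxonomy tables.

Submitted names — possibly misspelled, deprecated, or synonyms — are matched
against one or more taxonomy sources, each wrapped in an *adaptor*. Every
match carries a score in [0, 1] (0 = unmatched sentinel, 1 = perfect match),
the adaptor id, and a URI identifying the accepted name. A meta-layer
aggregates the adaptors' answers without cross-source deduplication: all
candidate matches are returned side by side and the client chooses.

The API mirrors the asynchronous submit/retrieve token pattern of networked
name-resolution services: ``submit`` records a job and returns a token
immediately; the (potentially expensive, e.g. fuzzy) matching runs when the
job is processed; ``retrieve`` reports either ``pending`` or the finished
report. Everything here is in-process, but the JSON wire format is frozen so
a web facade could wrap it unchanged.

The table-backed matcher applies three techniques in order, stopping at the
first that hits:

1. exact binomial match in the genus + species columns (score 1.0);
2. the name appears elsewhere in a row — typically as an italic-tagged
   synonym (``<i>...</i>``) in a free-text column (score 0.9);
3. cross-field assembly: the genus word and the species epithet are found in
   *different* fields of the same row (score 0.8).

Scores for techniques 2 and 3 are this implementation's convention; the
score *range* is the contract. Optional fuzzy matching proposes accepted
binomials within edit distance ≤ 2, scored ``1 − distance/max(lengths)``.
"""

from __future__ import annotations

import io
import json
import re
import uuid
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import pandas as pd

from .errors import TNRSError

__all__ = ["NameMatch", "TaxonomyTable", "TableAdaptor", "BinaryAdaptor",
           "NameResolver", "ResolverOptions", "match_msw3", "fuzzy_match",
           "aggregate"]

_ITALIC_RE = re.compile(r"<i>\s*(.*?)\s*</i>", re.IGNORECASE | re.DOTALL)
_WORD_RE = re.compile(r"[A-Za-z][A-Za-z-]*")

SCORE_EXACT = 1.0
SCORE_SYNONYM = 0.9
SCORE_CROSS_FIELD = 0.8
FUZZY_MAX_DISTANCE = 2


def normalize_name(name: str) -> str:
    """Whitespace/underscore-insensitive, case-folded matching key."""
    return " ".join(name.replace("_", " ").split()).casefold()


@dataclass(frozen=True)
class NameMatch:
    """One candidate resolution of a submitted name."""
    submitted: str
    matched: str
    score: float
    source: str
    uri: str

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise TNRSError(f"score {self.score} outside [0, 1]")

    def to_dict(self) -> dict:
        return {"matchedName": self.matched, "score": self.score,
                "sourceId": self.source, "uri": self.uri}


class TaxonomyTable:
    """An in-memory taxonomy: ranked-name rows plus free-text synonym data.

    Expects a header row with at least ``Genus`` and ``Species`` columns
    (matched case-insensitively); any other columns — e.g. ``Family``,
    ``Order``, ``Author``, ``Synonyms`` — are kept and searched by the
    matching techniques. Synonym names are harvested at load time from
    ``<i>...</i>`` spans in every non-rank column.
    """

    def __init__(self, df: pd.DataFrame, source_id: str):
        self.source_id = source_id
        self.df = df.fillna("").astype(str)
        cols = {c.lower(): c for c in self.df.columns}
        try:
            self.genus_col = cols["genus"]
            self.species_col = cols["species"]
        except KeyError:
            raise TNRSError(
                f"taxonomy table {source_id!r} needs Genus and Species "
                f"columns; has {list(df.columns)}") from None
        self._other_cols = [c for c in self.df.columns
                            if c not in (self.genus_col, self.species_col)]
        self._build_indexes()

    @classmethod
    def from_csv(cls, path_or_buffer, source_id: str) -> "TaxonomyTable":
        df = pd.read_csv(path_or_buffer, dtype=str)
        return cls(df, source_id)

    @classmethod
    def from_csv_text(cls, text: str, source_id: str) -> "TaxonomyTable":
        return cls.from_csv(io.StringIO(text), source_id)

    # ------------------------------------------------------------------
    def _build_indexes(self) -> None:
        self.accepted: dict[str, int] = {}   # normalized binomial -> rowid
        self.synonyms: dict[str, list[int]] = {}
        self._row_words: list[list[set[str]]] = []  # per row, per field
        dupes = []
        for rowid, row in enumerate(self.df.itertuples(index=False)):
            rowd = row._asdict() if hasattr(row, "_asdict") else dict(
                zip(self.df.columns, row))
            binom = normalize_name(
                f"{rowd[self.genus_col]} {rowd[self.species_col]}")
            if binom in self.accepted:
                dupes.append(binom)
            self.accepted[binom] = rowid
            field_words = [set(w.casefold() for w in
                               _WORD_RE.findall(rowd[self.genus_col])),
                           set(w.casefold() for w in
                               _WORD_RE.findall(rowd[self.species_col]))]
            for col in self._other_cols:
                text = rowd[col]
                for m in _ITALIC_RE.finditer(text):
                    key = normalize_name(m.group(1))
                    if key:
                        self.synonyms.setdefault(key, []).append(rowid)
                field_words.append(
                    set(w.casefold() for w in _WORD_RE.findall(text)))
            self._row_words.append(field_words)
        if dupes:
            raise TNRSError(
                f"duplicate accepted binomials in {self.source_id!r}: "
                f"{sorted(set(dupes))[:5]}")

    # ------------------------------------------------------------------
    def accepted_binomial(self, rowid: int) -> str:
        row = self.df.iloc[rowid]
        return f"{row[self.genus_col]} {row[self.species_col]}".strip()

    def uri(self, rowid: int) -> str:
        return f"local:{self.source_id}/{rowid}"

    def __len__(self) -> int:
        return len(self.df)


def match_msw3(name: str, table: TaxonomyTable,
               source: Optional[str] = None) -> list[NameMatch]:
    """Three-technique exact matcher; the first technique that hits
    determines the result set and base score. Empty list = no hit."""
    source = source or table.source_id
    key = normalize_name(name)
    if not key:
        return []
    # technique 1: exact accepted binomial
    if key in table.accepted:
        rowid = table.accepted[key]
        return [NameMatch(name, table.accepted_binomial(rowid), SCORE_EXACT,
                          source, table.uri(rowid))]
    # technique 2: name found elsewhere in a row (italic-tagged synonyms)
    if key in table.synonyms:
        return [NameMatch(name, table.accepted_binomial(rowid), SCORE_SYNONYM,
                          source, table.uri(rowid))
                for rowid in sorted(set(table.synonyms[key]))]
    # technique 3: genus and epithet mentioned in different fields of one row
    words = key.split()
    if len(words) >= 2:
        genus, epithet = words[0], words[-1]
        hits = []
        for rowid, fields in enumerate(table._row_words):
            gfields = {i for i, ws in enumerate(fields) if genus in ws}
            efields = {i for i, ws in enumerate(fields) if epithet in ws}
            # need the genus and epithet in two *different* fields of the row
            if gfields and efields and len(gfields | efields) > 1:
                hits.append(rowid)
        if hits:
            return [NameMatch(name, table.accepted_binomial(rowid),
                              SCORE_CROSS_FIELD, source, table.uri(rowid))
                    for rowid in hits]
    return []


def fuzzy_match(name: str, table: TaxonomyTable,
                source: Optional[str] = None,
                max_distance: int = FUZZY_MAX_DISTANCE) -> list[NameMatch]:
    """Accepted binomials within edit distance ``max_distance`` of the query,
    scored ``1 − distance / max(len(query), len(candidate))``, sorted by
    descending score then alphabetically."""
    source = source or table.source_id
    key = normalize_name(name)
    out = []
    for binom, rowid in table.accepted.items():
        res = edlib.align(key, binom, task="distance", k=max_distance)
        dist = res["editDistance"]
        if dist < 0:  # beyond k
            continue
        score = 1.0 - dist / max(len(key), len(binom))
        out.append(NameMatch(name, table.accepted_binomial(rowid), score,
                             source, table.uri(rowid)))
    out.sort(key=lambda m: (-m.score, m.matched))
    return out


# ----------------------------------------------------------------------
# adaptors
# ----------------------------------------------------------------------

class TableAdaptor:
    """Full-featured local adaptor: three-technique matching plus optional
    edit-distance fuzzing over a :class:`TaxonomyTable`."""

    def __init__(self, table: TaxonomyTable, adaptor_id: Optional[str] = None):
        self.table = table
        self.id = adaptor_id or table.source_id

    def resolve(self, name: str, fuzzy: bool = False) -> list[NameMatch]:
        matches = match_msw3(name, self.table, source=self.id)
        if not matches and fuzzy:
            matches = fuzzy_match(name, self.table, source=self.id)
        return matches


class BinaryAdaptor:
    """Adaptor in the style of strict lookup services whose scores are only
    0 or 1: a name resolves iff it is exactly an accepted binomial."""

    def __init__(self, table: TaxonomyTable, adaptor_id: Optional[str] = None):
        self.table = table
        self.id = adaptor_id or f"{table.source_id}-exact"

    def resolve(self, name: str, fuzzy: bool = False) -> list[NameMatch]:
        key = normalize_name(name)
        if key in self.table.accepted:
            rowid = self.table.accepted[key]
            return [NameMatch(name, self.table.accepted_binomial(rowid), 1.0,
                              self.id, self.table.uri(rowid))]
        return []


def aggregate(results_by_adaptor: dict[str, list[NameMatch]]) -> list[NameMatch]:
    """Union of all adaptors' matches; no cross-source deduplication.

    Output order is deterministic and independent of adaptor ordering:
    descending score, then matched name, then source id.
    """
    merged = [m for matches in results_by_adaptor.values() for m in matches]
    merged.sort(key=lambda m: (-m.score, m.matched, m.source))
    return merged


# ----------------------------------------------------------------------
# asynchronous job registry
# ----------------------------------------------------------------------

@dataclass
class ResolverOptions:
    adaptors: Optional[Sequence[str]] = None  # subset of adaptor ids; None = all
    fuzzy: bool = False


@dataclass
class _Job:
    names: list[str]
    options: ResolverOptions
    status: str = "pending"
    results: Optional[list[dict]] = None


class NameResolver:
    """In-process submit/retrieve name-resolution service.

    ``submit`` accepts newline-separated names and returns a unique token;
    ``retrieve`` returns the pending marker or the finished report;
    ``process`` runs the (possibly expensive) matching for one or all
    pending jobs. ``resolve`` is the synchronous convenience wrapper.
    """

    def __init__(self, adaptors: Sequence[TableAdaptor | BinaryAdaptor]):
        ids = [a.id for a in adaptors]
        if len(set(ids)) != len(ids):
            raise TNRSError(f"duplicate adaptor ids: {ids}")
        self.adaptors = list(adaptors)
        self._jobs: dict[str, _Job] = {}

    def submit(self, names_text: str,
               options: Optional[ResolverOptions] = None) -> str:
        names = [ln.strip() for ln in names_text.splitlines() if ln.strip()]
        if not names:
            raise TNRSError("no names submitted (input is empty/blank)")
        token = uuid.uuid4().hex
        self._jobs[token] = _Job(names=names, options=options or
                                 ResolverOptions())
        return token

    def status(self, token: str) -> str:
        return self._job(token).status

    def process(self, token: Optional[str] = None) -> None:
        """Run matching for one job (or every pending job)."""
        tokens = [token] if token else [t for t, j in self._jobs.items()
                                        if j.status == "pending"]
        for t in tokens:
            job = self._job(t)
            if job.status == "done":
                continue
            selected = self.adaptors
            if job.options.adaptors is not None:
                wanted = set(job.options.adaptors)
                selected = [a for a in self.adaptors if a.id in wanted]
            groups = []
            for name in job.names:
                per_adaptor = {a.id: a.resolve(name, fuzzy=job.options.fuzzy)
                               for a in selected}
                groups.append({
                    "submittedName": name,
                    "matches": [m.to_dict() for m in aggregate(per_adaptor)],
                })
            job.results = groups
            job.status = "done"

    def retrieve(self, token: str) -> dict:
        job = self._job(token)
        if job.status != "done":
            return {"status": job.status, "names": []}
        return {"status": "done", "names": job.results}

    def resolve(self, names_text: str,
                options: Optional[ResolverOptions] = None) -> dict:
        """submit + process + retrieve in one call."""
        token = self.submit(names_text, options)
        self.process(token)
        return self.retrieve(token)

    def _job(self, token: str) -> _Job:
        try:
            return self._jobs[token]
        except KeyError:
            raise TNRSError(f"unknown token {token!r}") from None


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=1, sort_keys=True)
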