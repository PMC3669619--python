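# Methods

This note documents the algorithms and conventions behind each module, the
design choices made where the design was genuinely open, what the synthetic
data generators do and do not emulate, and known limitations.

## Tree model and serialization

Trees are rooted; unrooted Newick input is read as rooted at the outermost
node. A node's branch length is the edge to its parent; **absent is not
zero** — `None` means "unknown", and pruning propagates knowledge
accordingly (a collapsed chain whose edges are all unknown yields an unknown
merged edge). Underscores in labels are significant characters by default,
so `Homo_sapiens` round-trips byte-identically; a reader option
(`underscores_to_spaces`) provides the other common Newick convention.
Duplicate tip labels are a hard error everywhere: tip labels are the join
key of the whole system (resolution output, pruning queries, age queries all
meet on them).

Parsing (Newick and the NEXUS TREES block, with TRANSLATE indirection) is
delegated to dendropy; writing is our own serializer because the toolkit
needs deterministic output for reproducible pipelines: children are emitted
in stored order, numbers use the shortest decimal representation that
round-trips (never scientific notation), and labels containing structural
characters are single-quoted with internal quotes doubled. Supported
formats are Newick and minimal NEXUS only; NeXML/PhyloXML/RDF
representations are out of scope.

Patristic distances are computed by a single post-order pass (tips meeting
at a node contribute `depth(i) + depth(j) − 2·depth(node)`), returned as a
labeled pandas DataFrame. `mrca` uses ancestor-set intersection; the test
suite checks it against a brute-force root-path oracle.

## Pruning via taxon-to-root path stores

Pruning must be fast on trees of 10⁴–10⁵ tips where naive per-query
traversal of the whole tree is wasteful. The tree is denormalized **once**
into a `PathStore`: for every tip, the ordered list of `(ancestor id, edge
length)` pairs up to the root. Node ids are the source preorder ranks, which
both identifies nodes and encodes the source child order.

A query then:

1. intersects the queried labels with the stored tips (labels matching only
   *internal* nodes are reported as "not found (internal)" — expanding a
   higher taxon to its members is the grafter's concern, not the pruner's);
2. walks each hit's path until reaching an already-collected node (paths
   share suffixes, so total work is the size of the union, not the sum);
3. rebuilds the union as a tree, ordering children by source preorder rank;
4. suppresses unifurcations, summing collapsed edge lengths; the surviving
   (child) node keeps its own label and the suppressed node's label is
   discarded.

Work grows with query size and path depth, not source size. A one-taxon
intersection returns a single-tip tree plus a warning; an empty intersection
is an error. The store serializes to a versioned, line-oriented text format
(`tip<TAB>node:len|node:len|…` plus header lines for the tree name and
internal labels) that round-trips byte-identically.

The behavioural reference (`naive_prune`) deletes unwanted tips one at a
time and collapses each resulting unifurcation immediately; the test suite
and the acceptance script assert isomorphism between the two
implementations and conservation of patristic distances among retained tips
to 1e-9.

## Taxonomic grafting

A taxon absent from the tree is placed from its slash-delimited derivation
(most- to least-inclusive, e.g. `Primates/Hominidae/Gorilla/Gorilla
beringei`). Scanning the non-terminal ranks from least inclusive upward, the
first rank that labels **exactly one** node of the original tree wins and
the taxon is appended as a new last child of that node. Conventions:

* matching is case-insensitive and space/underscore-insensitive but exact —
  misspelling repair belongs upstream in name resolution;
* a rank matching several nodes makes the taxon "ambiguous": it is reported,
  not placed (and not guessed);
* a bare binomial falls back to matching its genus word;
* grafting onto a node that is currently a tip converts it to an internal
  node and retains the original taxon as a same-named child tip, preserving
  the placed-versus-framework distinction;
* new edges get **no** branch length (unknown, not zero) — ages are the
  scaling module's job;
* placements are resolved against the original tree and applied in sorted
  terminal order, so the result is independent of input order, and grafted
  taxa never serve as attachment points for one another.

## bladj age interpolation

Input: a topology plus a calibration set (label → age; the root must be
calibrated, tips default to age 0 so fossil tips need explicit entries).
Ages are in whatever time unit the calibrations use (typically Ma);
0 = present.

"Evenly spaced" is made precise as follows. Nodes are visited in preorder;
a node, once dated, is fixed for everything below it, so the nearest fixed
ancestor of the node being processed is simply its parent. For undated node
*v* with parent age `a_top` (`k_top = 1` edge above), the algorithm picks
among fixed descendants reachable through undated nodes the one with the
most intervening nodes (ties → larger age), giving `a_bot` at `k_bot`
edges, and sets

```
age(v) = a_top − (a_top − a_bot) · k_top / (k_top + k_bot)
```

On a chain between two calibrations this spaces the intermediate ages
exactly evenly (root 10 over one intermediate → 5; root 9 over two → 6 and
3), and processing top-down reproduces the longest-chain behaviour familiar
from Phylocom's bladj. The exact tie rule of the original program is not
documented anywhere we could verify, so the rule above is this package's
own, stated rather than asserted as identical.

Pathological calibration sets (a long chain on one side of a node, an old
fixed child on the other) can make the formula undercut a fixed descendant;
the age is clamped to the oldest fixed descendant below the node, which can
produce zero-length branches. Collisions (equal ages) are legal and warn.
Calibrated nodes are exact fixed points, so the procedure is idempotent.
Outputs always satisfy root-to-tip age monotonicity, branch lengths ≥ 0 and
path-length conservation (root-to-tip path sums equal root age − tip age).

## Chronogram age queries

A chronogram store holds records of `(id, citation, one or more ultrametric
trees)` — several trees per record model posterior/post-burnin samples. At
build time every tree is checked for ultrametricity (relative tolerance
1e-6 of root depth — numerical slack for serialized chronograms, not
permission for non-clocklike trees; the deviating tip is named on
rejection) and converted once into a labeled patristic matrix.

A query of ≥2 taxa reports, for every source with ≥2 matches, the MRCA age
as **max pairwise patristic distance / 2** — exact on ultrametric trees and
pure array work, no traversal. Sample trees each contribute an age; the
summary adds min/median/max (the median is this package's addition to the
range). The overall range spans all sources and samples, so growing the
store can only widen it. Rendering: JSON under a shipped schema, or a
star tree of the best-covering source's matched taxa with tip edges equal
to that source's MRCA age (most matches wins; ties go to the
lexicographically smaller source id). Taxon names must be pre-resolved —
run name resolution first; matching here is exact on tip labels.

## Name resolution

Adaptors wrap local CSV taxonomy tables (header row with at least Genus and
Species columns; any other columns are carried and searched). Synonyms are
harvested at load time from `<i>…</i>` spans in every non-rank column. The
exact matcher applies three techniques in order, stopping at the first hit:

1. identical binomial in the Genus + Species columns — score 1.0;
2. the name appears elsewhere in a row (italic-tagged synonym) — score 0.9;
3. genus word and species epithet found in two *different* fields of the
   same row — score 0.8.

The score range [0, 1] with 0 = unmatched and 1 = perfect is the contract;
the 0.9/0.8 base scores for techniques 2–3 are this implementation's
convention. A second adaptor style (`BinaryAdaptor`) emits only 0/1,
modelling strict lookup services. Fuzzy matching proposes accepted
binomials within edit distance ≤ 2 (edlib), scored
`1 − d / max(len(query), len(candidate))`, sorted by descending score then
alphabetically; one-character corruptions always recover the true name.

The submit/retrieve API is an in-process job registry: `submit` returns a
unique token immediately, matching runs at `process` time, `retrieve`
reports `pending` or the finished report (one group per submitted name, all
adaptors' matches side by side — never merged across sources; choosing is
the client's job). The JSON wire format is frozen in a shipped schema so a
web facade could wrap the registry unchanged. URIs use a documented
`local:<source>/<rowid>` scheme; resolvable URIs are out of scope.

## Pipeline and provenance

`run_pipeline` chains resolve → select → (graft) → prune → (scale).
Selection maximizes |resolved names ∩ tips|, breaking ties by fewer total
tips then lexicographic id; a user-supplied tree bypasses selection and is
mandatory. Under the `fuzzy` policy the highest-scoring match wins with
exact ties going to the alphabetically first matched name (flagged
ambiguous in provenance); under `strict`, top-score ambiguity drops the
name with a warning. The optional datelife scaling mode dates every pruned
internal node whose subtree the chronogram store can age (conflicting,
non-monotonic estimates are skipped) and interpolates the remainder
bladj-style — a hybrid that goes beyond either component alone.

Every run emits a provenance record (schema-valid JSON): source tree and
citation, each operation with parameters, per-name decisions, timestamp and
tool version, plus the ledger `|submitted| = |kept| + |unresolved|` and
`|kept| = |in output| + |not in source|`, asserted per run. Branch-level
provenance is a sidecar JSON, not inline Newick comments, keeping the tree
consumable by standard tools. Identical inputs and configuration give
byte-identical trees and (timestamp aside) identical provenance.

## Synthetic data

Generators are pure functions of their spec (a seed fully determines the
output). Random topologies come from equal-rates splitting of a uniformly
chosen tip — structurally valid, *not* a realistic diversification model;
ultrametric trees draw each internal node's age as a uniform fraction
(0.3–0.9) of its parent's, with the root at `age_root` (default 100 time
units). Taxonomy tables mimic the ranked-columns-plus-free-text-synonyms
layout of large mammal taxonomies, with italic-tagged alternates embedded
in a configurable fraction of rows (default 0.3). Name corruption applies
exactly *n* single-character edits and verifies the resulting edit distance.

Because these fixtures are clean by construction, passing tests demonstrate
algorithmic correctness — oracle equivalence, conservation laws, recovery
guarantees — not robustness to the messiness of real taxonomies (homonyms
across kingdoms, rank inconsistencies, encoding noise), which would need
real data to assess. The packaged 18-tip mammal tree is a synthetic
demonstration fixture whose topology follows textbook mammal
relationships; it is not a published phylogeny.

## Problem sizes and tolerances

The test suite and acceptance script use: pruner/oracle agreement on 500
random (tree ≤ 1000 tips, query ≤ 20 taxa) pairs; one 50,000-tip store
smoke test with 20 ten-taxon queries; 200 random calibrated trees for the
age-interpolation invariants; 100 random chronograms / 500 queries for the
age-query oracle; a 1000-row taxonomy with 1000 one-edit corruptions for
fuzzy recovery; 100 random grafting cases and 100 end-to-end pipeline runs.
Numeric comparisons use 1e-9 absolute tolerance for length arithmetic and
1e-6 relative tolerance for ultrametricity checks.

## Known limitations

* Higher-taxon queries are not expanded during pruning (reported, not
  resolved); only grafting consumes rank information.
* No supertree synthesis: one source tree per run.
* Fuzzy matching is bounded at edit distance 2; it is a typo repairer, not
  a spell checker.
* The grafting ambiguity rule (report, don't guess) means trees with
  duplicated rank labels need manual disambiguation.
* Age interpolation uses node counts only — no rate smoothing, no character
  data, no cladogenesis model.
* The pruner's path store is rebuilt in memory per process; there is no
  on-disk index beyond the flat serialization.
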