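# phylotastic

Custom phylogenies from taxon-name lists, entirely offline.

Comparative biologists rarely need a new phylogenetic inference — they need a
*slice* of an existing expert tree: "give me a tree, with branch lengths, for
exactly these 40 species". Getting that slice by hand means fixing misspelled
and outdated names, finding a published megatree that covers the list,
pruning it down, grafting on the few species the tree lacks, and putting ages
on the nodes. This package implements that whole workflow as a composable
library and CLI:

* **trees** — a small rooted-tree model with Newick/NEXUS reading,
  deterministic Newick writing, MRCA and patristic-distance computation.
* **tnrs** — taxonomic name resolution over local CSV taxonomy tables: an
  asynchronous submit/retrieve token API, per-source adaptors, match scores
  in [0, 1], a three-technique exact matcher (accepted binomial; italic-tagged
  synonym; cross-field genus + epithet assembly) and edit-distance-≤2 fuzzy
  matching scored `1 − d/max(|query|, |candidate|)`.
* **pruner** — megatree pruning through a denormalized *taxon-to-root path
  store*: the tree is pre-processed once into one ancestor path per tip, so a
  query touches only the queried tips' paths (union of path nodes → rebuild →
  suppress unifurcations, summing collapsed edge lengths). Query cost scales
  with query size and depth, not with the 10⁴–10⁵ tips of the source tree.
* **grafter** — Phylomatic-style taxonomic grafting: a taxon missing from the
  tree is attached under the least-inclusive rank of its
  `order/family/genus/genus species` derivation that labels a tree node.
* **scaling** — bladj-style age interpolation: calibrated nodes keep their
  ages, uncalibrated nodes are spaced evenly (by node count) along the chain
  between their nearest fixed ancestor and best fixed descendant, and branch
  lengths become parent-age − child-age.
* **datelife** — MRCA-age queries over a store of ultrametric chronograms,
  each pre-processed into a patristic matrix so a query is row-matching plus
  the ultrametric identity *age = max pairwise distance / 2*; multiple
  sources yield a range.
* **controller** — the end-to-end pipeline (resolve → select best-coverage
  source tree → graft → prune → scale) with a per-run provenance record and
  an exact name-conservation ledger.
* **fixtures** — seed-deterministic synthetic data: random trees, ultrametric
  chronograms, MSW3-like taxonomy tables, name corruption, and a packaged
  18-tip mammal demonstration tree.

## Worked example

Prune the packaged mammal tree down to three species, repairing one
misspelling on the way:

```sh
phylotastic run --demo --resolve fuzzy \
    --species "Homo sapien,Pan troglodytes,Mus musculus"
```

prints the tree on stdout:

```
((Homo_sapiens,Pan_troglodytes),Mus_musculus);
```

and the provenance record on stderr (abridged):

```json
{
 "citation": "Packaged synthetic demonstration mammal tree",
 "ledger": {
  "in_output_tree": 3, "not_in_source_tree": 0,
  "resolved_kept": 3, "submitted": 3, "unresolved": 0
 },
 "name_decisions": [
  {"submitted": "Homo sapien", "matched": "Homo sapiens",
   "score": 0.9166666666666666, "outcome": "kept", "ambiguous": false}
 ]
}
```

Reading the output: `Homo sapien` is one edit away from the accepted
binomial, so fuzzy matching scores it 1 − 1/12 ≈ 0.917 and keeps it; the
ledger confirms all three submitted names survived into the output tree.
The same run is available from Python:

```python
from phylotastic import RegisteredTree, WorkflowConfig, run_pipeline
from phylotastic.fixtures import mammal_fixture

tree, taxonomy = mammal_fixture()
config = WorkflowConfig(trees={"m": RegisteredTree("m", tree, "demo")},
                        taxonomies=[taxonomy], resolution="fuzzy")
result = run_pipeline(["Homo sapien", "Pan troglodytes", "Mus musculus"],
                      config)
print(result.newick)   # ((Homo_sapiens,Pan_troglodytes),Mus_musculus);
```

Each stage also runs standalone: `phylotastic prune`, `graft`, `bladj`,
`datelife`, `tnrs` and `fixtures` — see `--help` on each.

## Documentation

`docs/methods.md` describes the algorithms, their assumptions, the numerical
conventions (tie-breaking, tolerances, degenerate inputs) and the known
limitations. JSON schemas for the three machine-readable outputs (name
resolution reports, age estimates, provenance records) ship in
`src/phylotastic/schemas/`.
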