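"""End-to-end pipeline: selection, orchestration, provenance, ledger."""

import json

import numpy as np
import pytest

from phylotastic import (CalibrationSet, RegisteredTree, WorkflowConfig,
                         build_store, emit_provenance, parse_newick,
                         prune_tree, run_pipeline, select_source_tree,
                         write_newick)
from phylotastic._schema import load_schema, validate
from phylotastic.errors import PhylotasticError
from phylotastic.fixtures import (GeneratorSpec, corrupt_name,
                                  mammal_fixture, random_taxonomy,
                                  random_tree, random_ultrametric_tree)

from conftest import make_random_trees


def _registry(*trees):
    return {t.name: RegisteredTree(id=t.name, tree=t, citation=f"cite:{t.name}")
            for t in trees}


class TestSelectSourceTree:
    def test_higher_coverage_wins(self):
        t1 = parse_newick("((A,B),(C,D));")
        t1.name = "big-hit"
        t2 = parse_newick("((A,X),(Y,Z));")
        t2.name = "small-hit"
        tid, cov = select_source_tree(_registry(t1, t2), ["A", "B", "C"])
        assert tid == "big-hit" and cov == 3

    def test_tie_broken_by_fewer_tips(self):
        small = parse_newick("(A,B);")
        small.name = "small"
        big = parse_newick("((A,B),(C,(D,(E,F))));")
        big.name = "big"
        tid, _ = select_source_tree(_registry(small, big), ["A", "B"])
        assert tid == "small"

    def test_zero_coverage_everywhere_errors(self):
        t = parse_newick("(A,B);")
        t.name = "t"
        with pytest.raises(PhylotasticError, match="no suitable"):
            select_source_tree(_registry(t), ["X"])

    def test_matches_argmax_oracle_on_random_registries(self):
        rng = np.random.default_rng(7)
        for batch in range(20):
            trees = make_random_trees(4, seed=500 + batch, max_tips=25,
                                      min_tips=3)
            for i, t in enumerate(trees):
                t.name = f"r{i}"
            pool = sorted({lb for t in trees for lb in t.tip_labels()})
            query = list(rng.choice(pool, size=min(8, len(pool)),
                                    replace=False))
            registry = _registry(*trees)
            tid, cov = select_source_tree(registry, query)
            # oracle: exhaustive intersection counts with the documented ties
            counts = {t.name: len(set(query) & set(t.tip_labels()))
                      for t in trees}
            best = min(counts, key=lambda k: (-counts[k],
                                              len(registry[k].tree.tip_labels()),
                                              k))
            assert tid == best and cov == counts[best]


class TestRunPipeline:
    def test_clean_names_scaling_off_equals_direct_prune(self, mammal):
        tree, _ = mammal
        names = ["Homo_sapiens", "Pan_troglodytes", "Mus_musculus"]
        config = WorkflowConfig(trees=_registry_of(tree), resolution="off")
        result = run_pipeline(names, config)
        direct, _ = prune_tree(tree, names)
        assert result.newick == write_newick(direct)

    def test_worked_example_via_full_pipeline(self, mammal):
        tree, table = mammal
        config = WorkflowConfig(trees=_registry_of(tree), taxonomies=[table],
                                resolution="strict")
        result = run_pipeline(
            ["Homo sapiens", "Pan troglodytes", "Mus musculus"], config)
        assert result.newick == \
            "((Homo_sapiens,Pan_troglodytes),Mus_musculus);"

    def test_misspelled_name_recovered_under_fuzzy(self, mammal):
        tree, table = mammal
        bad = corrupt_name("Homo sapiens", 1, seed=3)
        config = WorkflowConfig(trees=_registry_of(tree), taxonomies=[table],
                                resolution="fuzzy")
        result = run_pipeline([bad, "Mus musculus"], config)
        assert "Homo_sapiens" in result.tree.tip_labels()
        decision = result.provenance.name_decisions[0]
        assert decision["submitted"] == bad
        assert decision["matched"] == "Homo sapiens"
        assert decision["score"] < 1.0

    def test_unresolved_names_are_dropped_and_counted(self, mammal):
        tree, table = mammal
        config = WorkflowConfig(trees=_registry_of(tree), taxonomies=[table],
                                resolution="strict")
        result = run_pipeline(
            ["Homo sapiens", "Qqqq zzzz", "Mus musculus"], config)
        ledger = result.provenance.ledger
        assert ledger["submitted"] == 3
        assert ledger["unresolved"] == 1
        assert ledger["resolved_kept"] == 2

    def test_stage_errors_carry_stage_name_and_partial_provenance(self, mammal):
        tree, _ = mammal
        config = WorkflowConfig(trees=_registry_of(tree), resolution="off",
                                tree_id=tree.name)
        with pytest.raises(PhylotasticError, match=r"\[prune\]") as excinfo:
            run_pipeline(["Nothing_here", "Also_absent"], config)
        assert excinfo.value.provenance.operations  # resolve+select recorded

    def test_grafting_extends_coverage(self, mammal):
        tree, table = mammal
        import pandas as pd
        from phylotastic.tnrs import TaxonomyTable
        df = pd.concat([table.df, pd.DataFrame([{
            "Order": "Primates", "Family": "Hominidae", "Genus": "Gorilla",
            "Species": "beringei", "Author": "Matschie, 1903",
            "Synonyms": ""}])], ignore_index=True)
        table2 = TaxonomyTable(df, source_id="extended")
        config = WorkflowConfig(trees=_registry_of(tree),
                                taxonomies=[table2], resolution="strict",
                                graft_missing=True)
        result = run_pipeline(
            ["Homo sapiens", "Gorilla beringei", "Mus musculus"], config)
        assert "Gorilla_beringei" in result.tree.tip_labels()
        stages = [op["stage"] for op in result.provenance.operations]
        assert "graft" in stages

    def test_bladj_scaling_stage(self, mammal):
        tree, _ = mammal
        # calibrate the source root; querying across the root-most split
        # keeps that node (and its label) in the pruned tree
        labeled = tree.copy()
        labeled.root.label = "root"
        labeled.name = tree.name
        config = WorkflowConfig(
            trees=_registry_of(labeled), resolution="off", scaling="bladj",
            calibrations=CalibrationSet(ages={"root": 90.0}))
        result = run_pipeline(
            ["Homo_sapiens", "Mus_musculus", "Monodelphis_domestica"], config)
        depth = result.tree.depths()
        for tip in result.tree.tips():
            assert depth[tip.id] == pytest.approx(90.0)

    def test_datelife_scaling_stage(self):
        chrono = random_ultrametric_tree(
            GeneratorSpec(n_tips=20, seed=77, age_root=120.0))
        topo = chrono.copy()
        for n in topo.preorder():
            n.branch_length = None
        topo.name = "topo"
        store = build_store([("src", "cite", [chrono])])
        config = WorkflowConfig(trees=_registry_of(topo), resolution="off",
                                scaling="datelife", chronogram_store=store)
        query = chrono.tip_labels()[:6]
        result = run_pipeline(query, config)
        # recovered ages must match the chronogram's for matching clades
        depth = result.tree.depths()
        true_depth = chrono.depths()
        got = {t.label: depth[t.id] for t in result.tree.tips()}
        root_age = result.tree.root.age
        node = chrono.mrca(query)
        assert root_age == pytest.approx(120.0 - true_depth[node.id])

    def test_user_supplied_tree_is_mandatory(self, mammal):
        tree, _ = mammal
        other = parse_newick("((Homo_sapiens,Gallus_gallus),Xenopus_laevis);")
        other.name = "other"
        registry = {**_registry_of(tree), **_registry_of(other)}
        config = WorkflowConfig(trees=registry, resolution="off",
                                tree_id="other")
        result = run_pipeline(["Homo_sapiens", "Gallus_gallus"], config)
        assert result.provenance.source_tree == "other"

    def test_determinism(self, mammal):
        tree, table = mammal
        config = WorkflowConfig(trees=_registry_of(tree), taxonomies=[table],
                                resolution="fuzzy")
        names = ["Homo sapien", "Mus musculus", "Felis catus"]
        r1 = run_pipeline(names, config)
        r2 = run_pipeline(names, config)
        assert r1.newick == r2.newick
        d1, d2 = r1.provenance.to_dict(), r2.provenance.to_dict()
        d1.pop("timestamp"), d2.pop("timestamp")
        assert d1 == d2


class TestProvenance:
    def test_emit_is_schema_valid_json(self, mammal):
        tree, table = mammal
        config = WorkflowConfig(trees=_registry_of(tree), taxonomies=[table],
                                resolution="strict")
        result = run_pipeline(["Homo sapiens", "Mus musculus"], config)
        text = emit_provenance(result.provenance)
        doc = json.loads(text)
        validate(doc, load_schema("provenance.schema.json"))
        assert doc["citation"].startswith("cite:")

    def test_ledger_balances_on_random_runs(self):
        from phylotastic.fixtures import random_binomials
        rng = np.random.default_rng(19)
        schema = load_schema("provenance.schema.json")
        checked = 0
        for seed in range(100):
            pool = [b.replace(" ", "_")
                    for b in random_binomials(20, seed=seed)]
            tree = random_tree(GeneratorSpec(n_tips=20, seed=seed,
                                             with_lengths=False,
                                             label_pool=pool))
            tree.name = f"t{seed}"
            table = random_taxonomy(GeneratorSpec(n_tips=20, seed=seed),
                                    tip_labels=tree.tip_labels())
            labels = tree.tip_labels()
            query = []
            for i in range(6):
                name = labels[int(rng.integers(len(labels)))].replace("_", " ")
                r = rng.random()
                if r < 0.3:
                    name = corrupt_name(name, 1, seed=seed * 10 + i)
                elif r < 0.45:
                    name = f"Unknown{i} species{i}"   # unresolvable
                query.append(name)
            config = WorkflowConfig(trees=_registry_of(tree),
                                    taxonomies=[table], resolution="fuzzy")
            try:
                result = run_pipeline(query, config)
            except PhylotasticError:
                continue  # everything unresolved; nothing to check
            ledger = result.provenance.ledger
            assert ledger["submitted"] == len(query)
            assert ledger["submitted"] == (ledger["resolved_kept"]
                                           + ledger["unresolved"])
            assert ledger["resolved_kept"] == (ledger["in_output_tree"]
                                               + ledger["not_in_source_tree"])
            # the decision log agrees with the counts
            kept = sum(1 for d in result.provenance.name_decisions
                       if d["outcome"] == "kept")
            assert kept == ledger["resolved_kept"]
            validate(result.provenance.to_dict(), schema)
            checked += 1
        assert checked >= 80


def _registry_of(tree):
    name = tree.name or "tree"
    return {name: RegisteredTree(id=name, tree=tree, citation=f"cite:{name}")}
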