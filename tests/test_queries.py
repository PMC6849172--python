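"""One Health query family: native execution, SPARQL identity, chains."""

import pytest

from onehealthnlp import association_graph as ag
from onehealthnlp import ontology as onto
from onehealthnlp import queries as q
from onehealthnlp.association_graph import ValidationLabel as VL
from onehealthnlp.concept_mapping import ConceptRecord, ConceptTable


@pytest.fixture(scope="module")
def mini():
    table = ConceptTable(
        [
            ConceptRecord("C1", "glaucoma", semantic_types=frozenset({"T047"}),
                          semantic_group="DISO", xrefs=frozenset({"111", "112"})),
            ConceptRecord("C2", "trabeculotomy",
                          semantic_types=frozenset({"T061"}),
                          semantic_group="PROC", xrefs=frozenset({"211"})),
            ConceptRecord("C3", "eye pain", semantic_types=frozenset({"T184"}),
                          semantic_group="DISO", xrefs=frozenset()),
            ConceptRecord("C4", "timolol", semantic_types=frozenset({"T121"}),
                          semantic_group="CHEM", xrefs=frozenset({"411", "412"})),
            ConceptRecord("C5", "tonometry", semantic_types=frozenset({"T060"}),
                          semantic_group="PROC", xrefs=frozenset({"511"})),
        ]
    )
    tuples = [
        ag.AssociationTuple("VetCN", "CBOW", "C1", "C2", VL.REL_EXACT_APPROX),
        ag.AssociationTuple("VetCN", "CBOW", "C1", "C3", VL.REL_INEXACT_HIERARCHY),
        ag.AssociationTuple("VetCN", "CBOW", "C1", "C4", VL.UNREL_EXCLUDED),
        ag.AssociationTuple("VetCN", "CBOW", "C1", "C5", VL.ITSELF),
        ag.AssociationTuple("PMSB", "CBOW", "C1", "C2", VL.REL_EXACT_APPROX),
        ag.AssociationTuple("PMSB", "CBOW", "C1", "C4", VL.REL_INEXACT_BACKGROUND),
    ]
    prov = [
        ag.ProvenanceInput(t.subject_cui, t.object_cui, t.label, "doc",
                           ("excerpt",))
        for t in tuples
    ]
    return table, tuples, prov


class TestTypeQuery:
    def test_procedure_type_included_under_q1(self, mini):
        table, tuples, _ = mini
        result = q.run_type_query(tuples, table, q.q1(), "VetCN")
        assert ("C1", "C2") in result.cui_pairs  # T061 therapeutic procedure
        assert ("C1", "C5") in result.cui_pairs  # T060 diagnostic procedure

    def test_disease_only_candidate_excluded_under_q2(self, mini):
        table, tuples, _ = mini
        result = q.run_type_query(tuples, table, q.q2(), "VetCN")
        assert result.cui_pairs == frozenset({("C1", "C3")})

    def test_group_query_q3(self, mini):
        table, tuples, _ = mini
        result = q.run_type_query(tuples, table, q.q3(), "VetCN")
        assert result.cui_pairs == frozenset({("C1", "C4")})

    def test_matches_brute_force_filter(self, bundle):
        spec = q.q2()
        result = q.run_type_query(bundle.tuples, bundle.concept_table, spec, "SYNTH")
        brute = {
            t.pair
            for t in bundle.tuples
            if t.object_cui in bundle.concept_table
            and bundle.concept_table[t.object_cui].semantic_types & spec.type_ids
        }
        assert result.cui_pairs == brute

    def test_malformed_type_id_rejected(self):
        with pytest.raises(ValueError, match="unknown semantic-type"):
            q.QuerySpec("bad", q.TYPE_FILTER, frozenset({"X99"}))


class TestValidatedQuery:
    def test_negative_label_dropped(self, mini):
        table, tuples, _ = mini
        result = q.run_validated_query(tuples, table, q.q3(), "VetCN")
        assert result.cui_pairs == frozenset()  # the only CHEM pair is excluded

    def test_all_positive_fixture_keeps_everything(self, mini):
        table, tuples, _ = mini
        base = q.run_type_query(tuples, table, q.q1(), "VetCN")
        validated = q.run_validated_query(tuples, table, q.q1(), "VetCN")
        assert validated.cui_pairs == base.cui_pairs  # q1 pairs all positive

    def test_unlabelled_pair_raises(self, mini):
        table, _, _ = mini
        tuples = [ag.AssociationTuple("VetCN", "CBOW", "C1", "C2", None)]
        with pytest.raises(ag.UnlabeledPairError):
            q.run_validated_query(tuples, table, q.q1(), "VetCN")

    def test_itself_excludable_by_flag(self, mini):
        table, tuples, _ = mini
        with_itself = q.run_validated_query(tuples, table, q.q1(), "VetCN")
        without = q.run_validated_query(
            tuples, table, q.q1(), "VetCN", include_itself=False
        )
        assert ("C1", "C5") in with_itself.cui_pairs
        assert ("C1", "C5") not in without.cui_pairs


class TestUnion:
    def test_disjoint_inputs_sum(self):
        a = q.QueryResult(frozenset({("C1", "C2")}))
        b = q.QueryResult(frozenset({("C1", "C3")}))
        assert len(q.union_across_datasets([a, b])) == 2

    def test_identical_inputs_collapse(self):
        a = q.QueryResult(frozenset({("C1", "C2")}))
        assert len(q.union_across_datasets([a, a])) == 1

    def test_shared_pairs_counted_once(self, mini):
        table, tuples, _ = mini
        vet = q.run_validated_query(tuples, table, q.q1(), "VetCN")
        pmsb = q.run_validated_query(tuples, table, q.q1(), "PMSB")
        union = q.union_across_datasets([vet, pmsb])
        assert len(union) < len(vet) + len(pmsb)  # (C1, C2) shared
        assert vet.cui_pairs <= union.cui_pairs
        assert pmsb.cui_pairs <= union.cui_pairs


class TestSnomedMapping:
    def test_xrefless_candidate_dropped(self, mini):
        table, tuples, _ = mini
        base = q.run_validated_query(tuples, table, q.q2(), "VetCN")
        vm = q.map_pairs_to_snomed(base, table)
        assert ("C1", "C3") not in vm.cui_pairs  # C3 has no xref

    def test_expansion_is_cartesian_product(self, mini):
        table, tuples, _ = mini
        base = q.run_validated_query(tuples, table, q.q3(), "PMSB")
        vs = q.map_pairs_to_snomed(base, table, expand=True)
        # target C1 has 2 xrefs, candidate C4 has 2 -> 4 terminology pairs
        assert vs.snomed_pairs == frozenset(
            {("111", "411"), ("111", "412"), ("112", "411"), ("112", "412")}
        )

    def test_vm_never_larger_than_vs(self, bundle):
        for family in (q.q1, q.q2, q.q3):
            base = q.run_validated_query(
                bundle.tuples, bundle.concept_table, family(), "SYNTH"
            )
            vm = q.map_pairs_to_snomed(base, bundle.concept_table)
            vs = q.map_pairs_to_snomed(base, bundle.concept_table, expand=True)
            assert len(vm.cui_pairs) <= len(vs.snomed_pairs) or not vs.snomed_pairs


class TestDescendantsQuery:
    def test_leaf_candidates_give_empty_result(self, mini):
        table, tuples, _ = mini
        ontology = onto.AxiomSet(
            [onto.SubClassOf(onto.Named("211"), onto.Named("111"))]
        )
        index = onto.subsumption_closure(ontology)
        base = q.map_pairs_to_snomed(
            q.run_validated_query(tuples, table, q.q1(), "VetCN"), table, expand=True
        )
        result = q.descendants_query(base, table, {"C1": index})
        assert result.descendant_classes["C1"] == frozenset()

    def test_planted_subtree_recovered(self, mini):
        table, tuples, _ = mini
        # plant 5 descendants below candidate class 211
        axioms = [onto.SubClassOf(onto.Named(f"d{i}"), onto.Named("211"))
                  for i in range(3)]
        axioms += [onto.SubClassOf(onto.Named(f"e{i}"), onto.Named("d0"))
                   for i in range(2)]
        index = onto.subsumption_closure(onto.AxiomSet(axioms))
        base = q.map_pairs_to_snomed(
            q.run_validated_query(tuples, table, q.q1(), "VetCN"), table, expand=True
        )
        with pytest.warns(UserWarning):  # 511 absent from this module
            result = q.descendants_query(base, table, {"C1": index})
        assert result.descendant_classes["C1"] == frozenset(
            {"d0", "d1", "d2", "e0", "e1"}
        )


class TestChainMonotonicity:
    @pytest.mark.parametrize("family", ["q1", "q2", "q3"])
    def test_refinements_shrink(self, bundle, family):
        spec = q.QUERY_SPECS[family]()
        base = q.run_type_query(bundle.tuples, bundle.concept_table, spec, "SYNTH")
        validated = q.run_validated_query(
            bundle.tuples, bundle.concept_table, spec, "SYNTH"
        )
        vm = q.map_pairs_to_snomed(validated, bundle.concept_table)
        vs = q.map_pairs_to_snomed(validated, bundle.concept_table, expand=True)
        union = q.union_across_datasets([validated])
        assert validated.cui_pairs <= base.cui_pairs
        assert vm.cui_pairs <= validated.cui_pairs
        assert len(vm.cui_pairs) <= len(vs.snomed_pairs) or not vm.cui_pairs
        assert validated.cui_pairs <= union.cui_pairs


class TestSparqlIdentity:
    @pytest.mark.parametrize("family", ["q1", "q2", "q3"])
    def test_native_and_sparql_agree(self, bundle, family):
        spec = q.QUERY_SPECS[family]()
        graph = ag.build_association_graph(
            bundle.tuples, bundle.provenance, bundle.concept_table
        )
        native = q.run_type_query(
            bundle.tuples, bundle.concept_table, spec, "SYNTH"
        )
        assert q.run_sparql_pairs(graph, spec) == native.cui_pairs
        validated = q.run_validated_query(
            bundle.tuples, bundle.concept_table, spec, "SYNTH"
        )
        assert q.run_sparql_pairs(graph, spec, validated=True) == validated.cui_pairs
        vm = q.map_pairs_to_snomed(validated, bundle.concept_table)
        assert (
            q.run_sparql_pairs(graph, spec, validated=True, snomed_mapped=True)
            == vm.cui_pairs
        )
        vs = q.map_pairs_to_snomed(validated, bundle.concept_table, expand=True)
        assert q.run_sparql_snomed_pairs(graph, spec) == vs.snomed_pairs


class TestCountTable:
    def test_shape_and_sums(self, mini):
        table, tuples, _ = mini
        results = {
            name: q.run_type_query(tuples, table, q.QUERY_SPECS[name](), "VetCN")
            for name in ("q1", "q2", "q3")
        }
        ct = q.count_table(results, ["C1"])
        assert set(ct) == {"C1"}
        assert ct["C1"]["q1"] == 2 and ct["C1"]["q2"] == 1 and ct["C1"]["q3"] == 1
        for name, result in results.items():
            assert sum(row[name] for row in ct.values()) == len(result)
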