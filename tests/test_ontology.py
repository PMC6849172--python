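"""⊥-locality module extraction and told subsumption closure."""

import itertools

import pytest

from onehealthnlp import ontology as onto
from onehealthnlp.ontology import (
    And,
    AxiomSet,
    EquivalentTo,
    Named,
    Signature,
    Some,
    SubClassOf,
)
from onehealthnlp.synthetic import random_ontology


def sig(*classes, props=()):
    return Signature.of(class_ids=classes, property_ids=props)


class TestBotLocality:
    def test_lhs_outside_signature_is_local(self):
        ax = SubClassOf(Named("A"), Named("B"))
        assert onto.is_bot_local(ax, sig("X"))

    def test_lhs_inside_signature_is_non_local(self):
        ax = SubClassOf(Named("A"), Named("B"))
        assert not onto.is_bot_local(ax, sig("A"))

    def test_existential_rhs_does_not_make_axiom_local(self):
        # A ⊑ ∃r.C with A ∈ Σ, r ∉ Σ: the consequent is not trivially
        # satisfied under the ⊥-interpretation, so the axiom is needed
        ax = SubClassOf(Named("A"), Some("r", Named("C")))
        assert not onto.is_bot_local(ax, sig("A"))

    def test_conjunction_with_one_bottom_conjunct_is_bottom(self):
        ax = SubClassOf(And((Named("A"), Named("B"))), Named("C"))
        assert onto.is_bot_local(ax, sig("A"))  # B ∉ Σ empties the conjunction
        assert not onto.is_bot_local(ax, sig("A", "B"))

    def test_equivalence_local_only_when_both_sides_bottom(self):
        ax = EquivalentTo(Named("A"), Named("B"))
        assert onto.is_bot_local(ax, sig("X"))
        assert not onto.is_bot_local(ax, sig("A"))
        assert not onto.is_bot_local(ax, sig("B"))


def _told_edges(ontology):
    """Independent told-subsumption oracle used by the soundness tests."""
    edges = set()
    for ax in ontology:
        if isinstance(ax, SubClassOf) and isinstance(ax.lhs, Named):
            for sup in _named(ax.rhs):
                edges.add((ax.lhs.id, sup))
        elif isinstance(ax, EquivalentTo):
            if isinstance(ax.lhs, Named) and isinstance(ax.rhs, Named):
                edges.add((ax.lhs.id, ax.rhs.id))
                edges.add((ax.rhs.id, ax.lhs.id))
            elif isinstance(ax.lhs, Named):
                for sup in _named(ax.rhs):
                    edges.add((ax.lhs.id, sup))
            elif isinstance(ax.rhs, Named):
                for sup in _named(ax.lhs):
                    edges.add((ax.rhs.id, sup))
    return edges


def _named(expr):
    if isinstance(expr, Named):
        return [expr.id]
    if isinstance(expr, And):
        return [n for c in expr.conjuncts for n in _named(c)]
    return []


def _warshall_closure(edges, nodes):
    reach = {n: {n} for n in nodes}
    for a, b in edges:
        reach.setdefault(a, {a}).add(b)
        reach.setdefault(b, {b})
    changed = True
    while changed:
        changed = False
        for a in reach:
            new = set()
            for b in reach[a]:
                new |= reach.get(b, {b})
            if not new <= reach[a]:
                reach[a] |= new
                changed = True
    return reach


class TestModuleExtraction:
    def test_chain_superclasses_included(self):
        ontology = AxiomSet(
            [SubClassOf(Named("A"), Named("B")), SubClassOf(Named("B"), Named("C"))]
        )
        module = onto.extract_bot_module(ontology, sig("A"))
        assert list(module) == list(ontology)

    def test_disjoint_seed_gives_empty_module(self):
        ontology = AxiomSet([SubClassOf(Named("A"), Named("B"))])
        with pytest.warns(UserWarning, match="absent"):
            module = onto.extract_bot_module(ontology, sig("ZZZ"))
        assert len(module) == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_module_preserves_seed_signature_told_entailments(self, seed):
        ontology = random_ontology(seed, n_classes=50)
        all_classes = sorted(ontology.signature().class_ids)
        import random as _random

        seed_classes = _random.Random(seed).sample(all_classes, 5)
        module = onto.extract_bot_module(ontology, sig(*seed_classes))
        full = _warshall_closure(_told_edges(ontology), all_classes)
        part = _warshall_closure(_told_edges(module), all_classes)
        for a, b in itertools.permutations(seed_classes, 2):
            assert (b in part.get(a, {a})) == (b in full[a]), (seed, a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotence(self, seed):
        ontology = random_ontology(seed)
        seed_sig = sig(*sorted(ontology.signature().class_ids)[:5])
        m1 = onto.extract_bot_module(ontology, seed_sig)
        m2 = onto.extract_bot_module(m1, seed_sig)
        assert list(m1) == list(m2)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_signature(self, seed):
        ontology = random_ontology(seed)
        classes = sorted(ontology.signature().class_ids)
        small = onto.extract_bot_module(ontology, sig(*classes[:3]))
        large = onto.extract_bot_module(ontology, sig(*classes[:8]))
        assert set(map(str, small)) <= set(map(str, large))

    def test_module_never_exceeds_ontology(self):
        ontology = random_ontology(99)
        module = onto.extract_bot_module(
            ontology, sig(*ontology.signature().class_ids)
        )
        assert len(module) <= len(ontology)


class TestSubsumptionClosure:
    def test_transitivity(self):
        ontology = AxiomSet(
            [SubClassOf(Named("A"), Named("B")), SubClassOf(Named("B"), Named("C"))]
        )
        index = onto.subsumption_closure(ontology)
        assert "C" in index.ancestors("A")
        assert index.entails("A", "C")

    def test_equivalence_is_mutual(self):
        index = onto.subsumption_closure(
            AxiomSet([EquivalentTo(Named("A"), Named("B"))])
        )
        assert "B" in index.ancestors("A") and "A" in index.ancestors("B")
        assert "B" in onto.descendants(index, "A", strict=True)

    def test_cycle_merged_into_equivalence_bucket(self):
        ontology = AxiomSet(
            [
                SubClassOf(Named("A"), Named("B")),
                SubClassOf(Named("B"), Named("A")),
                SubClassOf(Named("A"), Named("C")),
            ]
        )
        index = onto.subsumption_closure(ontology)
        assert index.bucket["A"] == index.bucket["B"] == frozenset({"A", "B"})
        assert index.entails("B", "C")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_warshall_oracle(self, seed):
        ontology = random_ontology(seed, n_classes=30)
        index = onto.subsumption_closure(ontology)
        nodes = sorted(ontology.signature().class_ids)
        oracle = _warshall_closure(_told_edges(ontology), nodes)
        for n in nodes:
            assert index.ancestors(n) == oracle[n]

    def test_named_conjuncts_of_definition_are_ancestors(self):
        ontology = AxiomSet(
            [EquivalentTo(Named("A"), And((Named("B"), Some("r", Named("C")))))]
        )
        index = onto.subsumption_closure(ontology)
        assert "B" in index.ancestors("A")
        assert "C" not in index.ancestors("A")  # existential filler, not told


class TestDescendants:
    def _tree(self, depth=3):
        axioms = []
        nodes = ["n0"]
        count = 1
        level = ["n0"]
        for _ in range(depth):
            nxt = []
            for parent in level:
                for _ in range(2):
                    cid = f"n{count}"
                    count += 1
                    axioms.append(SubClassOf(Named(cid), Named(parent)))
                    nxt.append(cid)
                    nodes.append(cid)
            level = nxt
        return AxiomSet(axioms), nodes

    def test_leaf_has_no_strict_descendants(self):
        axset, nodes = self._tree()
        index = onto.subsumption_closure(axset)
        assert onto.descendants(index, nodes[-1], strict=True) == set()

    def test_three_level_binary_tree_root(self):
        # depth-2 binary tree below the root: 2 + 4 = 6 strict descendants
        axset, _ = self._tree(depth=2)
        index = onto.subsumption_closure(axset)
        assert len(onto.descendants(index, "n0", strict=True)) == 6

    def test_descendants_transitive(self):
        axset, nodes = self._tree()
        index = onto.subsumption_closure(axset)
        d_root = onto.descendants(index, "n0", strict=True)
        for mid in ("n1", "n2"):
            assert onto.descendants(index, mid, strict=True) <= d_root

    def test_unknown_class_warns_and_returns_empty(self):
        index = onto.subsumption_closure(AxiomSet([]))
        with pytest.warns(UserWarning, match="unknown class"):
            assert onto.descendants(index, "missing") == set()


class TestSyntax:
    def test_parse_round_trip(self):
        lines = [
            "SubClassOf(123 456)",
            "SubClassOf(123 ObjectSomeValuesFrom(p1 789))",
            "EquivalentClasses(77 ObjectIntersectionOf(456 "
            "ObjectSomeValuesFrom(p2 123)))",
        ]
        axioms = [onto.parse_axiom(line) for line in lines]
        assert [str(a) for a in axioms] == lines

    def test_file_round_trip(self, tmp_path, bundle):
        path = tmp_path / "onto.ofn"
        onto.write_ontology(bundle.ontology, path)
        back = onto.read_ontology(path)
        assert [str(a) for a in back] == [str(a) for a in bundle.ontology]

    def test_unsupported_constructor_rejected(self):
        with pytest.raises(ValueError, match="DisjointClasses"):
            onto.parse_axiom("DisjointClasses(A B)")

    def test_turtle_subclass_reader(self, tmp_path):
        ttl = """
        @prefix ex: <http://example.org/> .
        @prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
        ex:A rdfs:subClassOf ex:B .
        ex:B rdfs:subClassOf ex:C .
        """
        path = tmp_path / "frag.ttl"
        path.write_text(ttl)
        axset = onto.read_turtle_subclass_fragment(path)
        index = onto.subsumption_closure(axset)
        assert index.entails("A", "C")
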