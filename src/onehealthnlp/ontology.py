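"""Locality-based (BOT) module extraction over a terminology ontology.

The supported fragment matches large clinical terminology releases
(expressivity ALER): named classes, conjunctions, and existential
"attribute-value" restrictions, combined in SubClassOf and
EquivalentClasses axioms.

⊥-locality: with every entity *outside* a signature Σ interpreted as the
empty set, an axiom is ⊥-local when it becomes a tautology, and can be
dropped without changing any entailment over Σ.  In this fragment an
expression is ⊥-equivalent iff

* it is a named class not in Σ,
* it is a conjunction with at least one ⊥-equivalent conjunct, or
* it is an existential whose property is outside Σ or whose filler is
  ⊥-equivalent;

``SubClassOf(C, D)`` is ⊥-local iff C is ⊥-equivalent (⊥ ⊑ D always
holds); ``EquivalentClasses(C, D)`` is ⊥-local iff both sides are.
Module extraction is the usual fixpoint: add every non-local axiom,
grow the working signature with its entities, repeat until stable.

Subsumption queries use the *told* closure — the reflexive-transitive
closure of asserted subclass edges after unfolding equivalences — not a
full description-logic classification.  Subsumptions that only follow
through existential fillers are therefore not derived; the trade-off is
documented in the package's methods note.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Union

import networkx as nx


# ---------------------------------------------------------------------------
# class expressions and axioms


@dataclass(frozen=True)
class Named:
    id: str

    def __str__(self) -> str:
        return self.id


@dataclass(frozen=True)
class And:
    conjuncts: tuple["ClassExpression", ...]

    def __post_init__(self) -> None:
        if not self.conjuncts:
            raise ValueError("empty conjunction")

    def __str__(self) -> str:
        inner = " ".join(str(c) for c in self.conjuncts)
        return f"ObjectIntersectionOf({inner})"


@dataclass(frozen=True)
class Some:
    prop: str
    filler: "ClassExpression"

    def __str__(self) -> str:
        return f"ObjectSomeValuesFrom({self.prop} {self.filler})"


ClassExpression = Union[Named, And, Some]


@dataclass(frozen=True)
class SubClassOf:
    lhs: ClassExpression
    rhs: ClassExpression

    def __str__(self) -> str:
        return f"SubClassOf({self.lhs} {self.rhs})"


@dataclass(frozen=True)
class EquivalentTo:
    lhs: ClassExpression
    rhs: ClassExpression

    def __str__(self) -> str:
        return f"EquivalentClasses({self.lhs} {self.rhs})"


Axiom = Union[SubClassOf, EquivalentTo]


def expression_signature(expr: ClassExpression) -> tuple[set[str], set[str]]:
    """(class IDs, property IDs) used in an expression."""
    classes: set[str] = set()
    props: set[str] = set()
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, Named):
            classes.add(e.id)
        elif isinstance(e, And):
            stack.extend(e.conjuncts)
        elif isinstance(e, Some):
            props.add(e.prop)
            stack.append(e.filler)
        else:
            raise TypeError(f"unsupported class expression: {e!r}")
    return classes, props


def axiom_signature(axiom: Axiom) -> tuple[set[str], set[str]]:
    lc, lp = expression_signature(axiom.lhs)
    rc, rp = expression_signature(axiom.rhs)
    return lc | rc, lp | rp


@dataclass(frozen=True)
class Signature:
    class_ids: frozenset[str] = frozenset()
    property_ids: frozenset[str] = frozenset()

    @classmethod
    def of(
        cls, class_ids: Iterable[str] = (), property_ids: Iterable[str] = ()
    ) -> "Signature":
        return cls(frozenset(class_ids), frozenset(property_ids))

    def union(self, classes: set[str], props: set[str]) -> "Signature":
        return Signature(self.class_ids | classes, self.property_ids | props)


@dataclass
class AxiomSet:
    """An ordered collection of axioms in the supported fragment."""

    axioms: list[Axiom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.axioms)

    def __iter__(self):
        return iter(self.axioms)

    def signature(self) -> Signature:
        classes: set[str] = set()
        props: set[str] = set()
        for ax in self.axioms:
            c, p = axiom_signature(ax)
            classes |= c
            props |= p
        return Signature(frozenset(classes), frozenset(props))


# ---------------------------------------------------------------------------
# ⊥-locality


def _bottom_equivalent(expr: ClassExpression, sig: Signature) -> bool:
    if isinstance(expr, Named):
        return expr.id not in sig.class_ids
    if isinstance(expr, And):
        return any(_bottom_equivalent(c, sig) for c in expr.conjuncts)
    if isinstance(expr, Some):
        return expr.prop not in sig.property_ids or _bottom_equivalent(
            expr.filler, sig
        )
    raise TypeError(f"unsupported class expression: {expr!r}")


def is_bot_local(axiom: Axiom, signature: Signature) -> bool:
    """True when the axiom is trivially satisfied under the ⊥-interpretation
    of entities outside the signature."""
    if isinstance(axiom, SubClassOf):
        return _bottom_equivalent(axiom.lhs, signature)
    if isinstance(axiom, EquivalentTo):
        return _bottom_equivalent(axiom.lhs, signature) and _bottom_equivalent(
            axiom.rhs, signature
        )
    raise TypeError(f"unsupported axiom: {axiom!r}")


@dataclass
class LocalityModule(AxiomSet):
    """The extracted module, with the seed signature it was built for."""

    seed: Signature = field(default_factory=Signature)


def extract_bot_module(ontology: AxiomSet, seed: Signature) -> LocalityModule:
    """⊥-locality fixpoint extraction.

    The module contains every axiom non-local w.r.t. the growing
    signature; axiom order follows the ontology for determinism.  Seed
    entities absent from the ontology signature are tolerated (terminology
    cross-references can dangle) and simply contribute nothing.
    """
    onto_sig = ontology.signature()
    dangling = set(seed.class_ids) - set(onto_sig.class_ids)
    if dangling:
        warnings.warn(
            f"{len(dangling)} signature class(es) absent from the ontology: "
            f"{sorted(dangling)[:5]}..."
        )
    sig = seed
    in_module = [False] * len(ontology.axioms)
    changed = True
    while changed:
        changed = False
        for i, ax in enumerate(ontology.axioms):
            if in_module[i]:
                continue
            if not is_bot_local(ax, sig):
                in_module[i] = True
                c, p = axiom_signature(ax)
                sig = sig.union(c, p)
                changed = True
    return LocalityModule(
        axioms=[ax for i, ax in enumerate(ontology.axioms) if in_module[i]],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# told subsumption closure


def _named_conjuncts(expr: ClassExpression) -> list[str]:
    if isinstance(expr, Named):
        return [expr.id]
    if isinstance(expr, And):
        out: list[str] = []
        for c in expr.conjuncts:
            out.extend(_named_conjuncts(c))
        return out
    return []  # existentials contribute no told superclass


class SubsumptionIndex:
    """Reflexive-transitive told subclass closure over named classes.

    Equivalences (including subclass cycles, which are merged into one
    equivalence bucket) make the member classes mutual ancestors and
    descendants.
    """

    def __init__(self, ontology: AxiomSet):
        g = nx.DiGraph()
        for cls in ontology.signature().class_ids:
            g.add_node(cls)
        for ax in ontology:
            if isinstance(ax, SubClassOf):
                if isinstance(ax.lhs, Named):
                    for sup in _named_conjuncts(ax.rhs):
                        g.add_edge(ax.lhs.id, sup)
            elif isinstance(ax, EquivalentTo):
                if isinstance(ax.lhs, Named) and isinstance(ax.rhs, Named):
                    g.add_edge(ax.lhs.id, ax.rhs.id)
                    g.add_edge(ax.rhs.id, ax.lhs.id)
                elif isinstance(ax.lhs, Named):
                    for sup in _named_conjuncts(ax.rhs):
                        g.add_edge(ax.lhs.id, sup)
                elif isinstance(ax.rhs, Named):
                    for sup in _named_conjuncts(ax.lhs):
                        g.add_edge(ax.rhs.id, sup)
        self.graph = g
        # merge subclass cycles into equivalence buckets
        scc = list(nx.strongly_connected_components(g))
        self.bucket: dict[str, frozenset[str]] = {}
        for comp in scc:
            fs = frozenset(comp)
            for cls in comp:
                self.bucket[cls] = fs

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.graph

    def ancestors(self, class_id: str, strict: bool = False) -> set[str]:
        if class_id not in self.graph:
            warnings.warn(f"unknown class {class_id!r}; empty ancestor set")
            return set()
        anc = nx.descendants(self.graph, class_id)  # edges point subclass->superclass
        anc |= self.bucket[class_id]
        if strict:
            anc.discard(class_id)
        else:
            anc.add(class_id)
        return anc

    def entails(self, sub: str, sup: str) -> bool:
        return sup in self.ancestors(sub)


def subsumption_closure(ontology: AxiomSet) -> SubsumptionIndex:
    return SubsumptionIndex(ontology)


def descendants(
    index: SubsumptionIndex, class_id: str, strict: bool = True
) -> set[str]:
    """Told descendants of a class; ``strict`` excludes the class itself."""
    if class_id not in index:
        warnings.warn(f"unknown class {class_id!r}; empty descendant set")
        return set()
    desc = nx.ancestors(index.graph, class_id)
    desc |= index.bucket[class_id]
    if strict:
        desc.discard(class_id)
    else:
        desc.add(class_id)
    return desc


# ---------------------------------------------------------------------------
# line-oriented functional-style syntax

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_expression(tokens: list[str], pos: int) -> tuple[ClassExpression, int]:
    tok = tokens[pos]
    if tok == "ObjectIntersectionOf":
        if tokens[pos + 1] != "(":
            raise ValueError("expected '(' after ObjectIntersectionOf")
        pos += 2
        conjuncts = []
        while tokens[pos] != ")":
            expr, pos = parse_expression(tokens, pos)
            conjuncts.append(expr)
        return And(tuple(conjuncts)), pos + 1
    if tok == "ObjectSomeValuesFrom":
        if tokens[pos + 1] != "(":
            raise ValueError("expected '(' after ObjectSomeValuesFrom")
        prop = tokens[pos + 2]
        filler, pos = parse_expression(tokens, pos + 3)
        if tokens[pos] != ")":
            raise ValueError("unclosed ObjectSomeValuesFrom")
        return Some(prop, filler), pos + 1
    if tok in ("(", ")"):
        raise ValueError(f"unexpected {tok!r}")
    return Named(tok), pos + 1


def parse_axiom(line: str) -> Axiom:
    tokens = _TOKEN_RE.findall(line)
    if not tokens:
        raise ValueError("empty axiom line")
    head = tokens[0]
    if head not in ("SubClassOf", "EquivalentClasses"):
        raise ValueError(f"unsupported axiom constructor: {head!r}")
    if tokens[1] != "(" or tokens[-1] != ")":
        raise ValueError(f"malformed axiom: {line!r}")
    lhs, pos = parse_expression(tokens, 2)
    rhs, pos = parse_expression(tokens, pos)
    if tokens[pos] != ")":
        raise ValueError(f"trailing tokens in axiom: {line!r}")
    return SubClassOf(lhs, rhs) if head == "SubClassOf" else EquivalentTo(lhs, rhs)


def read_ontology(path) -> AxiomSet:
    """Line-oriented functional syntax; '#' comments and blanks skipped."""
    axioms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            axioms.append(parse_axiom(line))
    return AxiomSet(axioms)


def write_ontology(ontology: AxiomSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ax in ontology:
            fh.write(str(ax) + "\n")


def read_turtle_subclass_fragment(path) -> AxiomSet:
    """Subclass-only fragment from a Turtle file (rdfs:subClassOf between
    named classes); restrictions are out of scope for this reader."""
    import rdflib
    from rdflib.namespace import RDFS

    g = rdflib.Graph()
    g.parse(path, format="turtle")
    axioms = []
    for s, o in sorted(g.subject_objects(RDFS.subClassOf)):
        if isinstance(s, rdflib.URIRef) and isinstance(o, rdflib.URIRef):
            axioms.append(SubClassOf(Named(_local(s)), Named(_local(o))))
    return AxiomSet(axioms)


def _local(uri) -> str:
    text = str(uri)
    for sep in ("#", "/"):
        if sep in text:
            text = text.rsplit(sep, 1)[1]
    return text
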