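"""Population of the lexicon and association+provenance OWL graphs.

Two RDF graphs carry the mined knowledge:

* a **lexicon graph** (lemon-style): one *lexical topic* per target term,
  one *lexicon* per (dataset, architecture, target) holding its top-20
  candidate *lexical entries*, each entry ``denotes`` the concept(s)
  chosen as its focus; the lexicon is ``correlated with`` a dataset node
  and a neural-model node;
* an **association graph** (OBAN-style): a direction-free "sometimes
  true" *association* per concept pair, separated from its *provenance*
  (evidence label, source document, one or more excerpts, free-text
  dates).  Every association must carry at least one provenance node with
  at least one excerpt.

Concepts are *punned*: the same IRI is typed both as an OWL class (so the
semantic-type hierarchy applies to it) and used as an individual in
association facts.  Six validation labels describe how a candidate
concept matched the evidence source; the first four are the positive set
(the pair is clinically meaningful), the last two are negatives:

    ITSELF, REL_EXACT_APPROX, REL_INEXACT_HIERARCHY,
    REL_INEXACT_BACKGROUND | UNREL_NOT_CLINICAL, UNREL_EXCLUDED
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence
from urllib.parse import quote

import rdflib
from rdflib import Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .embeddings import CandidateRanking

BASE = Namespace("http://onehealthnlp.example.org/kb/")
LEMON = Namespace("http://lemon-model.net/lemon#")
ONTOLEX = Namespace("http://www.w3.org/ns/lemon/ontolex#")
OBAN = Namespace("http://purl.org/oban/")
USTG = Namespace("http://onehealthnlp.example.org/ustg#")
RO_CORRELATED_WITH = URIRef("http://purl.obolibrary.org/obo/RO_0002610")


class ValidationLabel(enum.Enum):
    """How a candidate concept matched the evidence-based reference."""

    ITSELF = "Itself"
    REL_EXACT_APPROX = "Relatedness by exact/approximate match"
    REL_INEXACT_HIERARCHY = (
        "Relatedness by inexact match (hypernym/hyponym) or (hyponym/hypernym)"
    )
    REL_INEXACT_BACKGROUND = "Relatedness by inexact match (background knowledge)"
    UNREL_NOT_CLINICAL = "Unrelated: not clinically meaningful"
    UNREL_EXCLUDED = "Unrelated: excluded"

    @property
    def is_positive(self) -> bool:
        return self in POSITIVE_LABELS


POSITIVE_LABELS = frozenset(
    {
        ValidationLabel.ITSELF,
        ValidationLabel.REL_EXACT_APPROX,
        ValidationLabel.REL_INEXACT_HIERARCHY,
        ValidationLabel.REL_INEXACT_BACKGROUND,
    }
)
NEGATIVE_LABELS = frozenset(
    {ValidationLabel.UNREL_NOT_CLINICAL, ValidationLabel.UNREL_EXCLUDED}
)


class UnlabeledPairError(ValueError):
    """A concept pair reached validation without a label."""


class MissingProvenanceError(ValueError):
    """An association was built without any provenance/excerpt."""


def slug(name: str) -> str:
    """Stable IRI slug: lowercase, '_' preserved, unsafe chars percent-encoded."""
    return quote(name.lower(), safe="_-.,")


def iri(name: str) -> URIRef:
    return BASE[slug(name)]


@dataclass(frozen=True)
class AssociationTuple:
    """(target concept, candidate concept, label) for one dataset/model."""

    dataset: str
    architecture: str
    subject_cui: str
    object_cui: str
    label: ValidationLabel | None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.subject_cui, self.object_cui)

    @property
    def pair_name(self) -> str:
        return f"({self.subject_cui},{self.object_cui})"


@dataclass(frozen=True)
class ProvenanceInput:
    """Evidence attached to one association."""

    subject_cui: str
    object_cui: str
    label: ValidationLabel
    source_document: str
    excerpts: tuple[str, ...]
    date_creation_association: str = ""
    source_date_issued: str = ""

    def __post_init__(self) -> None:
        if not self.excerpts:
            raise MissingProvenanceError(
                f"association ({self.subject_cui},{self.object_cui}) "
                "needs at least one excerpt"
            )


def load_core_scaffold() -> rdflib.Graph:
    """The shipped class scaffold: semantic-type tree (with part-of links
    to the group level), lexicon/association skeletons, evidence-label
    classes.  Populated graphs can be unioned with it for reasoning-style
    queries over the type hierarchy."""
    from importlib.resources import files

    g = rdflib.Graph()
    g.parse(
        data=files("onehealthnlp.data").joinpath("core_scaffold.ttl").read_text(),
        format="turtle",
    )
    _bind(g)
    return g


def _add_concept(graph: rdflib.Graph, table, cui: str) -> URIRef:
    """Emit a punned concept node with its types, group and xrefs."""
    node = iri(cui)
    graph.add((node, RDF.type, OWL.Class))
    graph.add((node, RDF.type, USTG.MetathesaurusConcept))
    if table is not None and cui in table:
        rec = table[cui]
        graph.add((node, RDFS.label, Literal(rec.preferred_name, lang="en")))
        for t in sorted(rec.semantic_types):
            graph.add((node, USTG.hasSemanticType, USTG[t]))
            graph.add((node, RDFS.subClassOf, USTG[t]))
        if rec.semantic_group:
            graph.add((node, USTG.inSemanticGroup, USTG[rec.semantic_group]))
        for x in sorted(rec.xrefs):
            graph.add((node, USTG.hasDbXrefInSCT, Literal(x)))
    return node


def build_lexicon_graph(
    rankings: Sequence[CandidateRanking],
    focus: Mapping[str, Iterable[str]],
    table=None,
    unmapped_ok: Iterable[str] = (),
) -> rdflib.Graph:
    """Populate the lemon-style lexicon graph from candidate rankings.

    ``focus`` maps every n-gram (targets and candidates) to its focus
    CUIs.  A candidate with no focus CUI must be listed in
    ``unmapped_ok``, otherwise an error is raised: silent gaps in the
    lexicalization layer would break downstream queries.
    """
    g = rdflib.Graph()
    _bind(g)
    unmapped_ok = set(unmapped_ok)
    for ranking in rankings:
        topic = iri(ranking.target)
        g.add((topic, RDF.type, LEMON.LexicalTopic))
        g.add((topic, RDFS.label, Literal(ranking.target, lang="en")))
        lex_name = f"{ranking.dataset}_{ranking.architecture}_{ranking.target}"
        lexicon = iri(lex_name)
        g.add((lexicon, RDF.type, LEMON.Lexicon))
        g.add((lexicon, RDFS.label, Literal(lex_name, lang="en")))
        g.add((lexicon, LEMON.topic, topic))
        g.add((lexicon, RO_CORRELATED_WITH, iri(f"{ranking.dataset} dataset")))
        g.add((lexicon, RO_CORRELATED_WITH, iri(ranking.architecture)))
        for candidate, _cos in ranking.candidates:
            entry = iri(f"entry {candidate}")
            g.add((entry, RDF.type, LEMON.LexicalEntry))
            g.add((entry, RDFS.label, Literal(candidate, lang="en")))
            g.add((lexicon, LEMON.entry, entry))
            cuis = sorted(focus.get(candidate, ()))
            if not cuis and candidate not in unmapped_ok:
                raise ValueError(
                    f"candidate {candidate!r} has no focus concept and is "
                    "not whitelisted as unmapped"
                )
            for cui in cuis:
                g.add((entry, ONTOLEX.denotes, _add_concept(g, table, cui)))
    return g


def build_association_graph(
    tuples: Sequence[AssociationTuple],
    provenance: Sequence[ProvenanceInput],
    table=None,
) -> rdflib.Graph:
    """Populate the OBAN-style association graph.

    One association node per unique (subject, object) pair — duplicate
    insertions are idempotent — and one provenance node per
    (pair, evidence label).  An association lacking any provenance row
    raises :class:`MissingProvenanceError`.
    """
    prov_by_pair: dict[tuple[str, str], list[ProvenanceInput]] = {}
    for p in provenance:
        prov_by_pair.setdefault((p.subject_cui, p.object_cui), []).append(p)

    g = rdflib.Graph()
    _bind(g)
    seen: set[tuple[str, str]] = set()
    for t in tuples:
        if t.pair in seen:
            continue
        seen.add(t.pair)
        if t.pair not in prov_by_pair:
            raise MissingProvenanceError(
                f"association {t.pair_name} has no provenance/excerpt"
            )
        assoc = iri(t.pair_name)
        g.add((assoc, RDF.type, OBAN.association))
        g.add((assoc, RDFS.label, Literal(t.pair_name, lang="en")))
        g.add((assoc, OBAN.association_has_subject, _add_concept(g, table, t.subject_cui)))
        g.add((assoc, OBAN.association_has_object, _add_concept(g, table, t.object_cui)))
        for p in prov_by_pair[t.pair]:
            prov_name = f"({p.subject_cui},{p.object_cui},{p.label.value})"
            prov = iri(prov_name)
            g.add((prov, RDF.type, OBAN.provenance))
            g.add((prov, RDFS.label, Literal(prov_name, lang="en")))
            g.add((prov, BASE.is_about, assoc))
            g.add((prov, BASE.has_evidence, BASE[f"label_{p.label.name.lower()}"]))
            g.add((prov, BASE.has_source, iri(p.source_document)))
            g.add(
                (iri(p.source_document), RDFS.label, Literal(p.source_document, lang="en"))
            )
            for k, text in enumerate(p.excerpts):
                exc = iri(f"{prov_name} excerpt {k}")
                g.add((exc, RDF.type, BASE.Excerpt))
                g.add((exc, BASE.excerpt_text, Literal(text)))
                g.add((prov, BASE.has_excerpt, exc))
            if p.date_creation_association:
                g.add(
                    (prov, BASE.date_creation_association,
                     Literal(p.date_creation_association))
                )
            if p.source_date_issued:
                g.add((prov, BASE.source_date_issued, Literal(p.source_date_issued)))
    return g


def _bind(g: rdflib.Graph) -> None:
    g.bind("kb", BASE)
    g.bind("lemon", LEMON)
    g.bind("ontolex", ONTOLEX)
    g.bind("oban", OBAN)
    g.bind("ustg", USTG)
    g.bind("owl", OWL)


SERIALIZATION_FORMATS = ("turtle", "xml", "nt")


def serialize_graph(graph: rdflib.Graph, path, format: str = "turtle") -> None:
    """Write the graph; 'nt' output is sorted, hence byte-deterministic."""
    if format not in SERIALIZATION_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; choose from {SERIALIZATION_FORMATS}"
        )
    if format == "nt":
        lines = sorted(
            graph.serialize(format="nt").splitlines()
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(line for line in lines if line) + "\n")
    else:
        graph.serialize(destination=str(path), format=format, encoding="utf-8")


def parse_graph(path, format: str = "turtle") -> rdflib.Graph:
    g = rdflib.Graph()
    g.parse(str(path), format=format)
    return g


def validation_precision(
    labels: Iterable[ValidationLabel | None],
) -> float:
    """Precision (percent, 2 dp) of a labelled pair group.

    Positive labels (Itself, the three Relatedness variants) are true
    positives; the two Unrelated labels are false positives.  ``None``
    raises :class:`UnlabeledPairError`.
    """
    tp = fp = 0
    for i, label in enumerate(labels):
        if label is None:
            raise UnlabeledPairError(f"pair #{i} carries no validation label")
        if label in POSITIVE_LABELS:
            tp += 1
        else:
            fp += 1
    if tp + fp == 0:
        raise ValueError("empty pair group")
    return round(100.0 * tp / (tp + fp), 2)


# ---------------------------------------------------------------------------
# 3-tuple TSV interface


def read_association_tsv(path) -> tuple[list[AssociationTuple], list[ProvenanceInput]]:
    """TSV: dataset, architecture, target_cui, candidate_cui, label,
    source_document, excerpt, date_creation, source_issued."""
    by_value = {label.value: label for label in ValidationLabel}
    tuples: list[AssociationTuple] = []
    provenance: list[ProvenanceInput] = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()  # header
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ds, arch, sub, obj, label, doc, excerpt, d1, d2 = line.split("\t")
            vlabel = by_value.get(label) or ValidationLabel[label]
            tuples.append(AssociationTuple(ds, arch, sub, obj, vlabel))
            provenance.append(
                ProvenanceInput(sub, obj, vlabel, doc, (excerpt,), d1, d2)
            )
    return tuples, provenance


def write_association_tsv(
    tuples: Sequence[AssociationTuple],
    provenance: Sequence[ProvenanceInput],
    path,
) -> None:
    prov_by_pair = {(p.subject_cui, p.object_cui): p for p in provenance}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "dataset\tarchitecture\ttarget_cui\tcandidate_cui\tlabel\t"
            "source_document\texcerpt\tdate_creation\tsource_issued\n"
        )
        for t in tuples:
            p = prov_by_pair[t.pair]
            fh.write(
                "\t".join(
                    [
                        t.dataset,
                        t.architecture,
                        t.subject_cui,
                        t.object_cui,
                        t.label.name if t.label else "",
                        p.source_document,
                        p.excerpts[0],
                        p.date_creation_association,
                        p.source_date_issued,
                    ]
                )
                + "\n"
            )
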