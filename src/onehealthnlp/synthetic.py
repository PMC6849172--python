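"""Synthetic study inputs with known ground truth.

The real inputs of the pipeline — large veterinary/biomedical corpora, a
licensed metathesaurus, a licensed clinical terminology ontology, a
short-form sense inventory and expert validation labels — cannot be
redistributed.  This module generates structurally faithful stand-ins
with *planted* ground truth so that every pipeline stage is testable:

* a topic-mixture corpus: each record is about one target condition and
  samples preferentially from that condition's related-term cluster, so
  that embedding neighbourhoods are recoverable; multiword collocations
  are planted with exact adjacent-occurrence counts; abbreviation tokens
  replace their long forms at a configurable rate;
* a concept table covering every planted clinical term, with semantic
  types spanning the query families (procedures, findings, chemicals),
  a semantic group column, and terminology cross-references for a stated
  fraction of concepts;
* a terminology ontology: a subclass DAG of stated depth and branching
  with existential attribute-value axioms on a fraction of classes;
* a sense inventory (short form -> ranked long forms) and gold labels
  for short-form detection and pair validation.

All randomness flows from one seed; identical specs yield identical
fixtures.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .association_graph import AssociationTuple, ProvenanceInput, ValidationLabel
from .concept_mapping import ConceptRecord, ConceptTable
from .corpus import TextCorpus
from .ontology import (
    And,
    AxiomSet,
    EquivalentTo,
    Named,
    Some,
    SubClassOf,
)

Q1_TYPES = ("T058", "T059", "T060", "T061")
Q2_TYPES = ("T033", "T034", "T184")
CHEM_TYPES = ("T121", "T109", "T116")
FILLER_TYPES = ("T071", "T170", "T078")

DEFAULT_LABEL_MIX = {
    ValidationLabel.ITSELF: 0.05,
    ValidationLabel.REL_EXACT_APPROX: 0.45,
    ValidationLabel.REL_INEXACT_HIERARCHY: 0.2,
    ValidationLabel.REL_INEXACT_BACKGROUND: 0.2,
    ValidationLabel.UNREL_NOT_CLINICAL: 0.06,
    ValidationLabel.UNREL_EXCLUDED: 0.04,
}

DEFAULT_UNITS = ("mg", "ml", "mmHg", "g/dL", "kg", "mmol/L", "bpm", "IU")

# everyday words for the common-word list and corpus filler
_COMMON = (
    "the of and a to in is was for on with as at by an be this from or "
    "which not are but had his they her she you we their has have will "
    "one all can its it he been were there when who more no out up so "
    "said about into than them only some could time us"
).split()


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_targets: int = 3
    n_related_per_target: int = 8
    vocab_size: int = 120  # filler vocabulary size
    n_records: int = 600
    record_length: int = 18
    planted_collocations: tuple[tuple[str, int], ...] = (
        ("heart failure", 60),
        ("chronic kidney disease", 40),
    )
    # short form, long form (joined), substitution rate; the defaults
    # abbreviate target terms so planted collocation counts stay exact
    abbreviation_map: tuple[tuple[str, str, float], ...] = (
        ("GLC", "glaucoma", 0.2),
        ("EPI", "epilepsy", 0.2),
    )
    concept_count: int = 60
    xref_rate: float = 0.6
    ontology_depth: int = 4
    ontology_branching: int = 3
    existential_rate: float = 0.3
    label_mix: tuple[tuple[ValidationLabel, float], ...] = tuple(
        DEFAULT_LABEL_MIX.items()
    )

    def __post_init__(self) -> None:
        weights = [w for _, w in self.label_mix]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("label mix must sum to 1")
        if self.n_targets < 1 or self.vocab_size < 10 or self.n_records < 10:
            raise ValueError("fixture spec too small to be meaningful")


@dataclass
class FixtureBundle:
    """Everything the pipeline needs, plus the planted ground truth."""

    spec: FixtureSpec
    corpus: TextCorpus
    units: frozenset[str]
    common_words: frozenset[str]
    sense_inventory: dict[str, list[str]]
    concept_table: ConceptTable
    ontology: AxiomSet
    targets: list[str]  # target n-grams
    related: dict[str, list[str]]  # target -> related-term cluster
    gold_sf: dict[str, bool]  # n-gram -> has meaningful short form
    tuples: list[AssociationTuple]
    provenance: list[ProvenanceInput]
    planted: dict[str, int] = field(default_factory=dict)
    signatures: dict[str, set[str]] = field(default_factory=dict)


_TARGET_POOL = (
    "glaucoma epilepsy asthma diabetes obesity anaemia arthritis "
    "hypertension osteoarthritis dermatitis pancreatitis"
).split()

_RELATED_STEMS = (
    "therapy procedure scan assay finding symptom swelling lesion "
    "inhibitor blocker agonist supplement biopsy culture screening "
    "murmur tremor rash effusion fibrosis"
).split()


def gen_corpus(spec: FixtureSpec) -> tuple[TextCorpus, dict]:
    """Topic-mixture corpus with planted collocations and abbreviations.

    Returns the corpus and a ground-truth dict with the target terms,
    their related clusters and exact planted-collocation counts.
    """
    rng = random.Random(spec.seed)
    targets = list(_TARGET_POOL[: spec.n_targets])
    if len(targets) < spec.n_targets:
        targets += [f"condition{i}" for i in range(len(targets), spec.n_targets)]
    related = {
        t: [
            f"{t[:4]}_{_RELATED_STEMS[j % len(_RELATED_STEMS)]}{j}"
            for j in range(spec.n_related_per_target)
        ]
        for t in targets
    }
    fillers = [f"w{i:03d}" for i in range(spec.vocab_size)]
    common = list(_COMMON)

    phrase_tokens = {tok for phrase, _ in spec.planted_collocations
                     for tok in phrase.split()}

    records: list[list[str]] = []
    for _ in range(spec.n_records):
        topic = rng.choice(targets)
        rec: list[str] = []
        for _ in range(spec.record_length):
            u = rng.random()
            if u < 0.22:
                rec.append(topic)
            elif u < 0.55:
                rec.append(rng.choice(related[topic]))
            elif u < 0.8:
                rec.append(rng.choice(common))
            else:
                tok = rng.choice(fillers)
                if tok in phrase_tokens:
                    tok = fillers[0]
                rec.append(tok)
        records.append(rec)

    # plant collocations with exact adjacent counts; interior boundaries of
    # already-planted phrases are forbidden insertion points so one phrase
    # can never split another
    planted_counts: dict[str, int] = {}
    forbidden: list[set[int]] = [set() for _ in records]
    for phrase, count in spec.planted_collocations:
        toks = phrase.split()
        if count > spec.n_records * 3:
            raise ValueError(
                f"planted phrase {phrase!r} count {count} exceeds corpus budget"
            )
        for _ in range(count):
            for _attempt in range(100):
                ri = rng.randrange(len(records))
                pos = rng.randrange(len(records[ri]) + 1)
                if pos not in forbidden[ri]:
                    break
            else:  # pragma: no cover - saturated corpus
                raise ValueError("could not find a free insertion point")
            records[ri][pos:pos] = toks
            shift = len(toks)
            forbidden[ri] = {p + shift if p >= pos else p for p in forbidden[ri]}
            forbidden[ri] |= set(range(pos + 1, pos + shift))
        planted_counts["_".join(toks)] = count

    # abbreviation substitution: replace the long form token by the short
    # form at the stated rate (post-phrase ground truth uses the joined form)
    abbrev_used: dict[str, int] = {}
    for short, long_joined, rate in spec.abbreviation_map:
        long_tokens = long_joined.split("_")
        n = len(long_tokens)
        for rec in records:
            for i in range(len(rec) - n + 1):
                if rec[i : i + n] == long_tokens and rng.random() < rate:
                    rec[i : i + n] = [short]
                    abbrev_used[short] = abbrev_used.get(short, 0) + 1

    corpus = TextCorpus(
        records=tuple(" ".join(rec) for rec in records), lowercased=False
    )
    truth = {
        "targets": targets,
        "related": related,
        "planted": planted_counts,
        "abbrev_used": abbrev_used,
    }
    return corpus, truth


def gen_terminology(
    spec: FixtureSpec, truth: dict
) -> tuple[ConceptTable, AxiomSet, dict[str, list[str]], dict]:
    """Concept table, ontology, sense inventory and gold labels.

    Every planted clinical phrase gets a concept whose synonym matches
    its surface form; a stated fraction of concepts carries
    cross-references into the ontology DAG.
    """
    rng = random.Random(spec.seed + 1)
    targets: list[str] = truth["targets"]
    related: dict[str, list[str]] = truth["related"]

    # ontology DAG: complete tree of given depth/branching, plus random
    # extra subclass edges (DAG) and existential axioms
    classes: list[str] = []
    axioms: list = []
    root = "100000000"
    classes.append(root)
    level = [root]
    next_id = 100000001
    for _ in range(spec.ontology_depth):
        new_level = []
        for parent in level:
            for _ in range(spec.ontology_branching):
                cid = str(next_id)
                next_id += 1
                classes.append(cid)
                axioms.append(SubClassOf(Named(cid), Named(parent)))
                new_level.append(cid)
        level = new_level
    prop_ids = ["p363698007", "p116676008"]  # attribute properties
    for cid in classes[1:]:
        if rng.random() < spec.existential_rate:
            other = rng.choice(classes)
            prop = rng.choice(prop_ids)
            if rng.random() < 0.5:
                axioms.append(
                    SubClassOf(Named(cid), Some(prop, Named(other)))
                )
            else:
                parent = rng.choice(classes)
                axioms.append(
                    EquivalentTo(
                        Named(cid),
                        And((Named(parent), Some(prop, Named(other)))),
                    )
                )
    ontology = AxiomSet(axioms)

    # concept table: targets (T047), related terms cycling through the
    # query families, then generic fillers
    records: list[ConceptRecord] = []
    xref_iter = iter(classes[1:] * 3)
    cui_no = 1

    def next_cui() -> str:
        nonlocal cui_no
        cui = f"C{cui_no:07d}"
        cui_no += 1
        return cui

    concept_of: dict[str, str] = {}
    type_cycle = [Q1_TYPES, Q2_TYPES, CHEM_TYPES, (FILLER_TYPES[0],)]
    for t in targets:
        cui = next_cui()
        concept_of[t] = cui
        records.append(
            ConceptRecord(
                cui=cui,
                preferred_name=t,
                synonyms=frozenset({t}),
                semantic_types=frozenset({"T047"}),
                semantic_group="DISO",
                xrefs=frozenset({next(xref_iter)}),
            )
        )
    for t in targets:
        for j, term in enumerate(related[t]):
            cui = next_cui()
            concept_of[term] = cui
            family = type_cycle[j % len(type_cycle)]
            stype = family[j % len(family)]
            group = "CHEM" if family is CHEM_TYPES else (
                "PROC" if family is Q1_TYPES else "DISO"
            )
            xrefs: frozenset[str] = frozenset()
            if rng.random() < spec.xref_rate:
                xrefs = frozenset({next(xref_iter)})
                if rng.random() < 0.25:
                    xrefs |= {next(xref_iter)}
            records.append(
                ConceptRecord(
                    cui=cui,
                    preferred_name=term.replace("_", " "),
                    synonyms=frozenset({term.replace("_", " ")}),
                    semantic_types=frozenset({stype}),
                    semantic_group=group,
                    xrefs=xrefs,
                )
            )
    for phrase in truth["planted"]:
        if phrase in concept_of:
            continue
        cui = next_cui()
        concept_of[phrase] = cui
        records.append(
            ConceptRecord(
                cui=cui,
                preferred_name=phrase.replace("_", " "),
                synonyms=frozenset({phrase.replace("_", " ")}),
                semantic_types=frozenset({"T047"}),
                semantic_group="DISO",
                xrefs=frozenset({next(xref_iter)}),
            )
        )
    while len(records) < spec.concept_count:
        cui = next_cui()
        records.append(
            ConceptRecord(
                cui=cui,
                preferred_name=f"filler concept {cui}",
                synonyms=frozenset({f"filler concept {cui}"}),
                semantic_types=frozenset({rng.choice(FILLER_TYPES)}),
                semantic_group="OBJC",
            )
        )
    table = ConceptTable(records)

    # sense inventory: the planted abbreviations (rank 1 correct) plus a
    # decoy sense each
    inventory: dict[str, list[str]] = {}
    for short, long_joined, _rate in spec.abbreviation_map:
        inventory[short] = [long_joined.replace("_", " "), "decoy expansion"]

    gold = {
        "concept_of": concept_of,
        "gold_sf": {short: True for short, _, _ in spec.abbreviation_map},
    }
    return table, ontology, inventory, gold


def gen_validation(
    spec: FixtureSpec, truth: dict, concept_of: dict[str, str]
) -> tuple[list[AssociationTuple], list[ProvenanceInput]]:
    """Assign validation labels to (target, related) concept pairs from
    the configured label mix; deterministic for a fixed seed."""
    rng = random.Random(spec.seed + 2)
    labels, weights = zip(*spec.label_mix)
    tuples: list[AssociationTuple] = []
    provenance: list[ProvenanceInput] = []
    for t in truth["targets"]:
        subject = concept_of[t]
        for arch in ("CBOW", "SKIPGRAM"):
            for term in truth["related"][t]:
                obj = concept_of[term]
                label = rng.choices(labels, weights)[0]
                tuples.append(
                    AssociationTuple("SYNTH", arch, subject, obj, label)
                )
                provenance.append(
                    ProvenanceInput(
                        subject,
                        obj,
                        label,
                        f"Best practice: {t}",
                        (f"excerpt about {term.replace('_', ' ')}",),
                        "May-2018",
                        "09-Dec-2016",
                    )
                )
    return tuples, provenance


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Full fixture bundle: corpus, lexicons, terminology, gold labels."""
    corpus, truth = gen_corpus(spec)
    table, ontology, inventory, gold = gen_terminology(spec, truth)
    tuples, provenance = gen_validation(spec, truth, gold["concept_of"])
    signatures = {
        gold["concept_of"][t]: set.union(
            set(table[gold["concept_of"][t]].xrefs),
            *(
                set(table[gold["concept_of"][r]].xrefs)
                for r in truth["related"][t]
            ),
        )
        for t in truth["targets"]
    }
    return FixtureBundle(
        spec=spec,
        corpus=corpus,
        units=frozenset(DEFAULT_UNITS),
        common_words=frozenset(_COMMON),
        sense_inventory=inventory,
        concept_table=table,
        ontology=ontology,
        targets=truth["targets"],
        related=truth["related"],
        gold_sf=gold["gold_sf"],
        tuples=tuples,
        provenance=provenance,
        planted=truth["planted"],
        signatures=signatures,
    )


def random_ontology(seed: int, n_classes: int = 50) -> AxiomSet:
    """Random toy ontology in the supported fragment, for property tests."""
    rng = random.Random(seed)
    classes = [f"K{i}" for i in range(n_classes)]
    props = ["r1", "r2"]
    axioms: list = []
    for i in range(1, n_classes):
        # parent index < i keeps the subclass graph acyclic
        parent = classes[rng.randrange(i)]
        axioms.append(SubClassOf(Named(classes[i]), Named(parent)))
    for _ in range(n_classes // 3):
        a, b, c = rng.sample(classes, 3)
        kind = rng.random()
        if kind < 0.4:
            axioms.append(SubClassOf(Named(a), Some(rng.choice(props), Named(b))))
        elif kind < 0.7:
            axioms.append(
                SubClassOf(Named(a), And((Named(b), Some(rng.choice(props), Named(c)))))
            )
        else:
            axioms.append(
                EquivalentTo(
                    Named(a), And((Named(b), Some(rng.choice(props), Named(c))))
                )
            )
    return AxiomSet(axioms)


# ---------------------------------------------------------------------------
# disk output


def write_fixtures(bundle: FixtureBundle, outdir) -> None:
    """Write the bundle as the plain-text files the CLI consumes."""
    from pathlib import Path

    from .concept_mapping import write_concept_table
    from .corpus import write_corpus
    from .association_graph import write_association_tsv
    from .ontology import write_ontology

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_corpus(bundle.corpus, out / "corpus.txt")
    (out / "units.txt").write_text("\n".join(sorted(bundle.units)) + "\n")
    (out / "common_words.txt").write_text(
        "\n".join(sorted(bundle.common_words)) + "\n"
    )
    with open(out / "senses.tsv", "w", encoding="utf-8") as fh:
        for short, longs in sorted(bundle.sense_inventory.items()):
            for rank, lf in enumerate(longs, start=1):
                fh.write(f"{short}\t{lf}\t{rank}\n")
    write_concept_table(bundle.concept_table, out / "concepts.tsv")
    write_ontology(bundle.ontology, out / "ontology.ofn")
    with open(out / "gold_sf.tsv", "w", encoding="utf-8") as fh:
        fh.write("ngram\thas_short_form\n")
        for ngram, has_sf in sorted(bundle.gold_sf.items()):
            fh.write(f"{ngram}\t{int(has_sf)}\n")
    write_association_tsv(bundle.tuples, bundle.provenance, out / "gold_validation.tsv")
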