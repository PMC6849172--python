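"""The "One Health" query family over the populated graphs.

Three base queries filter candidate concepts by broad category:

* **q1** — health-care activities: semantic types T058 (health care
  activity) and its subtypes T059 (laboratory), T060 (diagnostic) and
  T061 (therapeutic/preventive procedure);
* **q2** — findings: T033 (finding), T034 (lab/test result), T184 (sign
  or symptom);
* **q3** — the CHEM semantic group (chemicals & drugs).

Refinements chain monotonically: ``qiV`` keeps only pairs whose
validation label is positive; ``qiVU`` unions the validated results of
several datasets (the "One Health" step — veterinary and human-medicine
evidence combined); ``qiVM`` keeps pairs whose candidate concept is
cross-referenced to the terminology ontology; ``qiVS`` expands each CUI
pair into the cartesian product of its target x candidate
cross-references; ``qiVR`` retrieves the strict told descendants of the
candidate classes inside the target's locality module.

Every query is implemented natively over the tuple/table model and can
also be emitted as SPARQL against the serialized association graph;
both routes return identical result sets (tested).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import rdflib

from .association_graph import (
    BASE,
    OBAN,
    USTG,
    AssociationTuple,
    POSITIVE_LABELS,
    UnlabeledPairError,
)
from .concept_mapping import ConceptTable
from .ontology import SubsumptionIndex, descendants

TYPE_FILTER = "TYPE_FILTER"
GROUP_FILTER = "GROUP_FILTER"

_TYPE_ID_RE = re.compile(r"^T\d{3}$")


@dataclass(frozen=True)
class QuerySpec:
    name: str
    family: str
    type_ids: frozenset[str] = frozenset()
    group: str = ""

    def __post_init__(self) -> None:
        if self.family == TYPE_FILTER:
            if not self.type_ids:
                raise ValueError("TYPE_FILTER query needs type IDs")
            bad = [t for t in self.type_ids if not _TYPE_ID_RE.match(t)]
            if bad:
                raise ValueError(f"unknown semantic-type ID(s): {sorted(bad)}")
        elif self.family == GROUP_FILTER:
            if not self.group:
                raise ValueError("GROUP_FILTER query needs a group ID")
        else:
            raise ValueError(f"unknown query family: {self.family!r}")


def q1() -> QuerySpec:
    return QuerySpec("q1", TYPE_FILTER, frozenset({"T058", "T059", "T060", "T061"}))


def q2() -> QuerySpec:
    return QuerySpec("q2", TYPE_FILTER, frozenset({"T033", "T034", "T184"}))


def q3() -> QuerySpec:
    return QuerySpec("q3", GROUP_FILTER, group="CHEM")


QUERY_SPECS = {"q1": q1, "q2": q2, "q3": q3}


@dataclass(frozen=True)
class QueryResult:
    """Deduplicated result pairs of one query stage."""

    cui_pairs: frozenset[tuple[str, str]]
    snomed_pairs: frozenset[tuple[str, str]] | None = None
    descendant_classes: Mapping[str, frozenset[str]] | None = None

    @property
    def per_target_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for target, _cand in self.cui_pairs:
            counts[target] = counts.get(target, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.cui_pairs)


def _matches(spec: QuerySpec, table: ConceptTable, cui: str) -> bool:
    if cui not in table:
        return False
    rec = table[cui]
    if spec.family == TYPE_FILTER:
        return bool(rec.semantic_types & spec.type_ids)
    return rec.semantic_group == spec.group


def run_type_query(
    tuples: Sequence[AssociationTuple],
    table: ConceptTable,
    spec: QuerySpec,
    dataset: str,
) -> QueryResult:
    """Base query: pairs whose candidate concept matches the filter."""
    pairs = {
        t.pair
        for t in tuples
        if t.dataset == dataset and _matches(spec, table, t.object_cui)
    }
    return QueryResult(frozenset(pairs))


def run_validated_query(
    tuples: Sequence[AssociationTuple],
    table: ConceptTable,
    spec: QuerySpec,
    dataset: str,
    include_itself: bool = True,
) -> QueryResult:
    """Validated refinement qiV: only positively labelled pairs survive."""
    pairs = set()
    for t in tuples:
        if t.dataset != dataset or not _matches(spec, table, t.object_cui):
            continue
        if t.label is None:
            raise UnlabeledPairError(f"pair {t.pair_name} carries no label")
        if t.label not in POSITIVE_LABELS:
            continue
        if not include_itself and t.label.name == "ITSELF":
            continue
        pairs.add(t.pair)
    return QueryResult(frozenset(pairs))


def union_across_datasets(results: Sequence[QueryResult]) -> QueryResult:
    """qiVU: the "One Health" union of per-dataset validated results."""
    if not results:
        raise ValueError("union of zero query results")
    pairs: set[tuple[str, str]] = set()
    for r in results:
        pairs |= r.cui_pairs
    return QueryResult(frozenset(pairs))


def map_pairs_to_snomed(
    result: QueryResult, table: ConceptTable, expand: bool = False
) -> QueryResult:
    """qiVM (``expand=False``) and qiVS (``expand=True``).

    qiVM keeps CUI pairs whose candidate has at least one terminology
    cross-reference.  qiVS replaces each surviving CUI pair with the
    cartesian product of target-xrefs x candidate-xrefs (a pair whose
    target has no xref contributes nothing).
    """
    kept: set[tuple[str, str]] = set()
    snomed: set[tuple[str, str]] = set()
    for target, cand in result.cui_pairs:
        cand_xrefs = sorted(table[cand].xrefs) if cand in table else []
        if not cand_xrefs:
            continue
        kept.add((target, cand))
        if expand:
            target_xrefs = sorted(table[target].xrefs) if target in table else []
            for tx in target_xrefs:
                for cx in cand_xrefs:
                    snomed.add((tx, cx))
    return QueryResult(
        frozenset(kept), snomed_pairs=frozenset(snomed) if expand else None
    )


def descendants_query(
    result: QueryResult,
    table: ConceptTable,
    module_indexes: Mapping[str, SubsumptionIndex],
) -> QueryResult:
    """qiVR: strict told descendants of candidate classes, per target.

    ``module_indexes`` maps a target CUI to the subsumption index of its
    locality module.  Candidate classes absent from the module are
    skipped with a warning; descendants are always module members.
    """
    per_target: dict[str, frozenset[str]] = {}
    for target in sorted({t for t, _ in result.cui_pairs}):
        index = module_indexes.get(target)
        if index is None:
            warnings.warn(f"no locality module for target {target!r}; skipped")
            continue
        cand_classes: set[str] = set()
        for t, cand in result.cui_pairs:
            if t == target and cand in table:
                cand_classes |= table[cand].xrefs
        found: set[str] = set()
        for cls in sorted(cand_classes):
            if cls not in index:
                warnings.warn(
                    f"candidate class {cls!r} absent from the module of {target!r}"
                )
                continue
            found |= descendants(index, cls, strict=True)
        per_target[target] = frozenset(found)
    return QueryResult(
        result.cui_pairs,
        snomed_pairs=result.snomed_pairs,
        descendant_classes=per_target,
    )


# ---------------------------------------------------------------------------
# SPARQL route


def sparql_pairs_query(
    spec: QuerySpec, validated: bool = False, snomed_mapped: bool = False
) -> str:
    """SPARQL text for qi / qiV / qiVM over the association graph."""
    if spec.family == TYPE_FILTER:
        values = " ".join(f"ustg:{t}" for t in sorted(spec.type_ids))
        type_clause = f"?o ustg:hasSemanticType ?t .\n  VALUES ?t {{ {values} }}"
    else:
        type_clause = f"?o ustg:inSemanticGroup ustg:{spec.group} ."
    validated_clause = ""
    if validated:
        labels = " ".join(
            f"kb:label_{label.name.lower()}" for label in sorted(
                POSITIVE_LABELS, key=lambda l: l.name
            )
        )
        validated_clause = (
            "?p kb:is_about ?a .\n  ?p kb:has_evidence ?ev .\n"
            f"  VALUES ?ev {{ {labels} }}"
        )
    snomed_clause = "?o ustg:hasDbXrefInSCT ?x ." if snomed_mapped else ""
    body = "\n  ".join(
        clause
        for clause in (
            "?a a oban:association .",
            "?a oban:association_has_subject ?s .",
            "?a oban:association_has_object ?o .",
            type_clause,
            validated_clause,
            snomed_clause,
        )
        if clause
    )
    return (
        f"PREFIX oban: <{OBAN}>\n"
        f"PREFIX ustg: <{USTG}>\n"
        f"PREFIX kb: <{BASE}>\n"
        f"SELECT DISTINCT ?s ?o WHERE {{\n  {body}\n}}"
    )


def sparql_snomed_pairs_query(spec: QuerySpec) -> str:
    """SPARQL text for qiVS (terminology class pairs)."""
    base = sparql_pairs_query(spec, validated=True)
    return base.replace(
        "SELECT DISTINCT ?s ?o WHERE {",
        "SELECT DISTINCT ?sx ?ox WHERE {\n  ?s ustg:hasDbXrefInSCT ?sx .\n"
        "  ?o ustg:hasDbXrefInSCT ?ox .",
    )


def _cui_from_iri(node) -> str:
    local = str(node).rsplit("/", 1)[1]
    return local.upper()


def run_sparql_pairs(
    graph: rdflib.Graph,
    spec: QuerySpec,
    validated: bool = False,
    snomed_mapped: bool = False,
) -> frozenset[tuple[str, str]]:
    """Execute a pair query over a populated association graph."""
    rows = graph.query(sparql_pairs_query(spec, validated, snomed_mapped))
    return frozenset((_cui_from_iri(s), _cui_from_iri(o)) for s, o in rows)


def run_sparql_snomed_pairs(
    graph: rdflib.Graph, spec: QuerySpec
) -> frozenset[tuple[str, str]]:
    rows = graph.query(sparql_snomed_pairs_query(spec))
    return frozenset((str(sx), str(ox)) for sx, ox in rows)


def count_table(
    results: Mapping[str, QueryResult], targets: Sequence[str]
) -> dict[str, dict[str, int]]:
    """Per-target count table (rows: targets, columns: query names)."""
    table: dict[str, dict[str, int]] = {t: {} for t in targets}
    for qname, result in results.items():
        counts = result.per_target_counts
        for t in targets:
            table[t][qname] = counts.get(t, 0)
    return table
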