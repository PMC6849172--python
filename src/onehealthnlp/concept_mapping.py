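"""Concept normalization of n-grams and the four-label mapping evaluation.

An n-gram is normalized against a concept table (CUI, names/synonyms,
semantic types, semantic group, terminology cross-references) by a
dictionary mapper: exact synonym match after replacing "_" with spaces
and case-folding, falling back to a greedy longest-span decomposition
into synonym-matching sub-phrases.  The mapper is the reference
implementation of a pluggable interface (term in, candidate CUIs out), so
an external normalizer can be swapped in without touching the evaluation
code.

Expert assessment of mapper output uses four labels:

* ``SM`` (single map)     — one CUI capturing the full meaning;
* ``MM`` (multiple maps)  — several CUIs, at least one a focus concept;
* ``IM`` (incorrect map)  — CUIs returned, none correct;
* ``NM`` (not mapped)     — nothing returned.

Every assessed n-gram is assumed to be a biomedical/clinical term, so
there are no true negatives: SM and MM count as TP, IM as FP, NM as FN,
and precision/recall/F follow from the counts.  F is always computed from
the integer counts, 2TP/(2TP+FP+FN) — equivalent to the harmonic mean of
the *unrounded* P and R — because the harmonic mean of the rounded
percentages differs in the second decimal for some cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

SM = "SM"
MM = "MM"
IM = "IM"
NM = "NM"
ASSESSMENT_LABELS = (SM, MM, IM, NM)


class UndefinedMetricError(ZeroDivisionError):
    """A precision/recall denominator is zero."""


class ConflictingLabelError(ValueError):
    """One unique n-gram carries inconsistent assessment labels."""


@dataclass(frozen=True)
class ConceptRecord:
    """One row of the mini-metathesaurus: a concept and its lexicalizations."""

    cui: str
    preferred_name: str
    synonyms: frozenset[str] = frozenset()
    semantic_types: frozenset[str] = frozenset()
    semantic_group: str = ""
    xrefs: frozenset[str] = frozenset()  # terminology-ontology class IDs

    def __post_init__(self) -> None:
        if not self.semantic_types:
            raise ValueError(f"concept {self.cui} needs >= 1 semantic type")

    def surface_forms(self) -> set[str]:
        return {self.preferred_name, *self.synonyms}


class ConceptTable:
    """CUI-indexed concept records with a case-folded synonym index."""

    def __init__(self, records: Iterable[ConceptRecord]):
        self.records: dict[str, ConceptRecord] = {}
        self._by_synonym: dict[str, set[str]] = {}
        for rec in records:
            if rec.cui in self.records:
                raise ValueError(f"duplicate CUI {rec.cui}")
            self.records[rec.cui] = rec
            for form in rec.surface_forms():
                self._by_synonym.setdefault(form.casefold(), set()).add(rec.cui)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, cui: str) -> bool:
        return cui in self.records

    def __getitem__(self, cui: str) -> ConceptRecord:
        return self.records[cui]

    def lookup(self, phrase: str) -> list[str]:
        """CUIs whose synonym set contains the phrase (case-folded)."""
        return sorted(self._by_synonym.get(phrase.casefold(), ()))

    def semantic_types_of(self, cui: str) -> set[str]:
        return set(self.records[cui].semantic_types) if cui in self.records else set()


def map_term(ngram: str, table: ConceptTable) -> list[str]:
    """Dictionary normalization of an n-gram to candidate CUIs.

    Pipeline: "_" -> space, case-fold, exact synonym match; otherwise a
    greedy longest-span decomposition into synonym-matching sub-phrases
    (longest match first, left to right, unmatched tokens skipped).  An
    n-gram with no matching span maps to the empty list.
    """
    phrase = ngram.replace("_", " ").strip()
    if not phrase:
        return []
    exact = table.lookup(phrase)
    if exact:
        return exact
    tokens = phrase.split()
    found: list[str] = []
    i = 0
    while i < len(tokens):
        for j in range(len(tokens), i, -1):
            span = " ".join(tokens[i:j])
            cuis = table.lookup(span)
            if cuis:
                found.extend(c for c in cuis if c not in found)
                i = j
                break
        else:
            i += 1
    return found


@dataclass(frozen=True)
class MappingAssessment:
    """Expert judgement of mapper output for one n-gram."""

    ngram: str
    label: str
    focus_cuis: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.label not in ASSESSMENT_LABELS:
            raise ValueError(f"unknown assessment label: {self.label!r}")
        if self.label == SM and len(self.focus_cuis) != 1:
            raise ValueError("SM requires exactly one focus CUI")


@dataclass(frozen=True)
class EvaluationCell:
    """A no-true-negatives contingency: tp + fp + fn covers every term."""

    tp: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn


def assessment_to_counts(labels: Sequence[MappingAssessment | str]) -> EvaluationCell:
    """SM and MM are true positives, IM false positives, NM false negatives."""
    tp = fp = fn = 0
    for item in labels:
        label = item.label if isinstance(item, MappingAssessment) else item
        if label in (SM, MM):
            tp += 1
        elif label == IM:
            fp += 1
        elif label == NM:
            fn += 1
        else:
            raise ValueError(f"unknown assessment label: {label!r}")
    return EvaluationCell(tp, fp, fn)


def prf(cell: EvaluationCell) -> tuple[float, float, float]:
    """(precision %, recall %, F %) to 2 decimals, F from the counts."""
    if cell.tp + cell.fp == 0 or cell.tp + cell.fn == 0:
        raise UndefinedMetricError(f"undefined metric for {cell}")
    p = 100.0 * cell.tp / (cell.tp + cell.fp)
    r = 100.0 * cell.tp / (cell.tp + cell.fn)
    f = 100.0 * 2 * cell.tp / (2 * cell.tp + cell.fp + cell.fn)
    return round(p, 2), round(r, 2), round(f, 2)


def f_measure(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of (already rounded) printed percentages, 2 decimals."""
    if precision_pct + recall_pct == 0:
        raise UndefinedMetricError("P + R is zero")
    return round(2 * precision_pct * recall_pct / (precision_pct + recall_pct), 2)


def macro_average(
    values: Sequence[Sequence[float]],
) -> tuple[float, ...]:
    """Arithmetic mean of per-target printed (2-decimal) metric tuples.

    Reported evaluations average the rounded per-target percentages, so
    the macro row is the mean of those printed values, re-rounded.
    """
    if not values:
        raise ValueError("macro average of an empty list")
    width = len(values[0])
    return tuple(
        round(sum(v[i] for v in values) / len(values), 2) for i in range(width)
    )


def micro_average(
    assessments: Iterable[MappingAssessment],
) -> tuple[float, float, float]:
    """Pooled P/R/F over unique n-grams (each counted once).

    The same n-gram may appear in several candidate lists; micro-averaging
    deduplicates it.  Inconsistent labels for one unique n-gram raise
    :class:`ConflictingLabelError` rather than being silently resolved.
    """
    seen: dict[str, str] = {}
    for a in assessments:
        if a.ngram in seen and seen[a.ngram] != a.label:
            raise ConflictingLabelError(
                f"n-gram {a.ngram!r} labelled both {seen[a.ngram]} and {a.label}"
            )
        seen[a.ngram] = a.label
    return prf(assessment_to_counts(list(seen.values())))


def counts_from_prf(
    precision_pct: float, recall_pct: float, n: int
) -> EvaluationCell:
    """Recover the integer contingency behind printed P/R percentages.

    Searches tp in [1, n] for (tp, fp, fn) with tp+fp+fn = n whose exact
    percentages round to the printed 2-decimal values.  Raises when no or
    several contingencies are consistent — printed percentages at these
    list sizes pin the counts down uniquely in practice.
    """
    solutions = []
    for tp in range(1, n + 1):
        for fp in range(0, n - tp + 1):
            fn = n - tp - fp
            if round(100.0 * tp / (tp + fp), 2) == round(precision_pct, 2) and round(
                100.0 * tp / (tp + fn), 2
            ) == round(recall_pct, 2):
                solutions.append(EvaluationCell(tp, fp, fn))
    if len(solutions) != 1:
        raise ValueError(
            f"P={precision_pct} R={recall_pct} at n={n} has "
            f"{len(solutions)} consistent contingencies"
        )
    return solutions[0]


# ---------------------------------------------------------------------------
# significance testing


def paired_ttest(
    values_exp1: Sequence[float], values_exp2: Sequence[float]
) -> tuple[float, float]:
    """Classical paired Student t-test (n-1 df), two-sided.

    Raises ``ValueError`` on unequal lengths, fewer than two pairs, or a
    zero-variance difference vector (all differences identical makes the
    statistic undefined).
    """
    if len(values_exp1) != len(values_exp2):
        raise ValueError("paired test needs equally long value lists")
    if len(values_exp1) < 2:
        raise ValueError("paired test needs >= 2 pairs")
    diffs = [a - b for a, b in zip(values_exp1, values_exp2)]
    if max(diffs) == min(diffs):
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(values_exp1, values_exp2)
    return float(res.statistic), float(res.pvalue)


def pooled_ttest(
    values_exp1: Sequence[float], values_exp2: Sequence[float]
) -> tuple[float, float]:
    """Two-sample equal-variance Student t-test, two-sided.

    Provided alongside :func:`paired_ttest` because published comparisons
    of the two normalization experiments report p-values that follow the
    pooled two-sample form of the statistic.
    """
    if len(values_exp1) < 2 or len(values_exp2) < 2:
        raise ValueError("two-sample test needs >= 2 values per group")
    res = stats.ttest_ind(values_exp1, values_exp2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# TSV IO


def read_concept_table(path) -> ConceptTable:
    """TSV: cui, preferred_name, synonyms|, semantic_types|, group, xrefs|."""
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("cui\t"):
            raise ValueError("concept table must start with a 'cui' header row")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cui, name, syns, types, group, xrefs = line.split("\t")
            records.append(
                ConceptRecord(
                    cui=cui,
                    preferred_name=name,
                    synonyms=frozenset(s for s in syns.split("|") if s),
                    semantic_types=frozenset(t for t in types.split("|") if t),
                    semantic_group=group,
                    xrefs=frozenset(x for x in xrefs.split("|") if x),
                )
            )
    return ConceptTable(records)


def write_concept_table(table: ConceptTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cui\tpreferred_name\tsynonyms\tsemantic_types\tgroup\txrefs\n")
        for cui in sorted(table.records):
            rec = table.records[cui]
            fh.write(
                "\t".join(
                    [
                        rec.cui,
                        rec.preferred_name,
                        "|".join(sorted(rec.synonyms)),
                        "|".join(sorted(rec.semantic_types)),
                        rec.semantic_group,
                        "|".join(sorted(rec.xrefs)),
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class AssessmentRow:
    """One line of an assessment file (dataset x architecture x target)."""

    dataset: str
    architecture: str
    target: str
    ngram: str
    experiment: str
    label: str
    focus_cuis: frozenset[str] = frozenset()


def read_assessments(path) -> list[AssessmentRow]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()  # header
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ds, arch, target, ngram, exp, label, cuis = line.split("\t")
            rows.append(
                AssessmentRow(
                    ds,
                    arch,
                    target,
                    ngram,
                    exp,
                    label,
                    frozenset(c for c in cuis.split("|") if c),
                )
            )
    return rows


def write_assessments(rows: Sequence[AssessmentRow], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("dataset\tarchitecture\ttarget\tngram\texperiment\tlabel\tfocus_cuis\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.dataset,
                        r.architecture,
                        r.target,
                        r.ngram,
                        r.experiment,
                        r.label,
                        "|".join(sorted(r.focus_cuis)),
                    ]
                )
                + "\n"
            )
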