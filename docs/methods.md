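# Methods

`onehealthnlp` implements a text-to-knowledge pipeline for clinical
concept pairs: it learns multiword terms from free-text corpora, finds
semantically related candidate terms with word embeddings, normalizes
them to concepts, attaches expert validation labels, represents the
result as OWL lexicon and association graphs, and answers a family of
"One Health" queries (human- and veterinary-medicine evidence combined)
over those graphs together with locality-based modules of a terminology
ontology.  This note records the models, the tunable parameters, the
numerical decisions, and what the synthetic fixtures do and do not show.

## Phrase learning (word2phrase)

Tokenization splits on Unicode whitespace only; punctuation and numbers
stay attached to tokens, so artifacts like `(copd)_is_a` are legitimate
n-grams.  A bigram *a b* is joined into `a_b` when its discounted
score

    score(a, b) = (count(ab) − δ) / (count(a) · count(b)) · N

exceeds a threshold, with *N* the corpus token count.  Defaults:
`min_count = 5`, `δ = 5`, `passes = 2` (pass *p* can build n-grams of up
to 2^p tokens — two passes cover the 3–4-token clinical phrases that
occur in practice).  The threshold has no universal value because the
score scales with *N*; it is a required, corpus-dependent setting (the
test fixtures use 50).  Veterinary narrative corpora are lowercased
before learning (their casing is erratic); literature corpora are not,
so acronyms such as `CKD` survive.  Phrase learning is fully
deterministic.

## Embeddings and candidate retrieval

The reference trainer implements negative-sampling CBOW and Skip-gram:
vocabulary restricted to n-grams with frequency **strictly greater**
than `min_count` (default 5), window sampled uniformly in 1..`window`
(default 5), 5 negative samples from the unigram^0.75 distribution,
linearly decaying learning rate from 0.025, single-threaded and
deterministic for a fixed seed.  The trainer is pluggable — word2vec
text-format vectors from any external tool can be read in — because the
package's contribution is the retrieval and everything downstream, not
the optimizer.  Defaults here (dimension 40–50, 3–5 epochs in tests)
are sized for the synthetic corpora; they are assumptions, not tuned
reproductions of any particular study configuration.

Candidate retrieval is exact: the top-k (default 20) vocabulary terms
by cosine similarity, excluding the target, ties broken by descending
cosine then lexicographic order.  Target-term selection keeps n-grams
with frequency > 1000 that map to a concept with a required semantic
type (default T047, disease or syndrome); the final shortlist is a human
decision and enters as an input.

## Short-form detector

A rule-based classifier over the `_`-separated tokens of an n-gram,
backed by a measurement-unit lexicon and a ranked common-word list.
Label precedence: `SF_NU` (number + unit, auto-mapped to the generic
measurement concept C0242485) > `SF_U` (unit, auto-mapped to
unit-of-measure C1519795) > `SF` (any other short-form token) > `NONE`.
A token is a short-form candidate when it is not a common word and has
≥ 2 uppercase letters, or is all-caps of length ≥ 2, or mixes letters
and digits, or is all-lowercase of length ≤ 3.  Unit lookup tries exact
match first, then case-insensitive (`g/dL` and `g/dl` both hit);
common-word lookup is case-sensitive by default so that an all-caps
token is never excused by its lowercase homograph.

The rule set intentionally reproduces two documented error modes: an
all-lowercase abbreviation of four or more letters (`echo`) is missed,
and a non-clinical all-caps token (`US`) is flagged.  Expansion replaces
each flagged `SF` token with the rank-1 sense from a TSV sense
inventory, with a per-term override table standing in for manual
disambiguation; inside multi-token n-grams the expansion's spaces become
`_` to preserve tokenization.

Detector evaluation is two-sided: the SF side (TP = correctly flagged,
FP = flagged but not meaningful, FN = missed) and the NONE side with the
roles swapped.

## Concept normalization and its evaluation

The reference mapper is a dictionary normalizer: `_` → space, case-fold,
exact synonym match against the concept table, else greedy longest-span
decomposition into synonym-matching sub-phrases.  It implements the same
term-in/CUIs-out interface an external normalizer would, so the
evaluation code never depends on which mapper produced the candidates.

Assessment uses four labels: SM (single correct map), MM (multiple maps
including a focus concept), IM (mapped but wrong), NM (not mapped).
Because every assessed n-gram is assumed to be a clinical term there are
no true negatives: TP = SM+MM, FP = IM, FN = NM, and tp+fp+fn equals the
batch size.  F is always computed from the integer counts,
2TP/(2TP+FP+FN) — identical to the harmonic mean of the unrounded P and
R, and occasionally different in the second decimal from the harmonic
mean of the rounded percentages.  Macro averages are taken over the
printed (2-decimal) per-target values and re-rounded, matching how such
tables are conventionally reported; micro averages pool counts over
unique n-grams, with inconsistent duplicate labels raised as errors
rather than resolved silently.

`counts_from_prf` inverts printed precision/recall percentages at a
known list size back to the unique integer contingency; this is how the
pooled micro counts (tp=481/fp=87/fn=45 and tp=548/fp=45/fn=20 over 613
unique terms) are recovered at run time instead of being stored.

Significance of the expansion effect (EXP-2 vs EXP-1) over the 44
(target × architecture × dataset) value pairs is available in two forms:
the classical paired t-test (`paired_ttest`, n−1 df) and the pooled
equal-variance two-sample test (`pooled_ttest`).  The reference
p-values bundled with the benchmark tables (1.046e-4 precision,
1.077e-3 recall, 1.191e-5 F) are reproduced exactly by the pooled form
and not by the paired form (which gives ~1.3e-6 / 3.5e-5 / 6.7e-7 on the
same pairs); both are exposed so users can choose the design they mean.

## Graphs

The lexicon graph follows the lemon pattern: a lexical topic per target,
a lexicon per (dataset, architecture, target) with its candidate entries,
`denotes` links from entries to concepts, and `correlated with` links to
dataset and model nodes.  The association graph follows the OBAN
pattern: a direction-free "sometimes true" association node per concept
pair, named `(CUI1,CUI2)`, separated from provenance nodes named
`(CUI1,CUI2,label)` that carry the evidence label, source document, at
least one excerpt, and free-text dates (date typing is deliberately
relaxed — publication dates of sources are often imprecise).  Concepts
are punned: one IRI typed both as OWL class (under its semantic-type
classes) and used as an individual in association facts.  IRIs are
stable slugs (lowercase, `_` preserved, unsafe characters
percent-encoded).  Serialization: Turtle and RDF/XML for interchange,
sorted N-Triples when byte-deterministic output is wanted.  Structural
validation (round-trip isomorphism, provenance reachability) replaces
DL consistency checking; no reasoner is invoked.

Validation labels form a closed six-way enumeration; Itself plus the
three Relatedness labels are the positive set, the two Unrelated labels
are negatives, and validation precision is 100·TP/(TP+FP) over a pair
group.

## Locality-based modules and told closure

Module extraction implements plain ⊥-locality over the ALER fragment
(named classes, conjunctions, existential restrictions): an expression
is ⊥-equivalent iff it is a class outside the signature, a conjunction
with at least one ⊥-equivalent conjunct, or an existential whose
property is outside the signature or whose filler is ⊥-equivalent; a
SubClassOf axiom is local iff its left side is ⊥-equivalent, an
EquivalentClasses axiom iff both sides are.  Extraction is the standard
fixpoint (add every non-local axiom, grow the signature, repeat).  The
star variant is not implemented; plain ⊥ suffices for the entailment-
preservation guarantees used here.

Subsumption queries use the *told* closure: reflexive-transitive closure
of asserted subclass edges, after rewriting named-named equivalences as
mutual edges and adding edges from a defined class to the named
conjuncts of its definition.  Subclass cycles are merged into
equivalence buckets.  This is weaker than full EL classification —
subsumptions that hold only through existential fillers are not derived
— and the module-soundness guarantees are therefore stated and tested
with respect to told entailment.  Signature IDs absent from the ontology
warn rather than fail, because metathesaurus-to-terminology
cross-references can dangle.

## Queries

q1 filters candidate concepts to health-care-activity types (T058/T059/
T060/T061), q2 to findings (T033/T034/T184), q3 to the CHEM semantic
group.  qiV intersects with positively labelled pairs (Itself included
by default; a flag excludes it for reporting).  qiVU unions validated
per-dataset results — the One Health step.  qiVM keeps pairs whose
candidate has ≥ 1 terminology cross-reference; qiVS expands pairs into
the cartesian product of target × candidate cross-references; qiVR
returns strict told descendants of candidate classes inside the
target's locality module, reported per target.  Every query runs
natively over the tuple/table model and as SPARQL over the populated
graph; the test suite asserts both routes return identical sets.

## Synthetic fixtures

The generator emulates the structure, not the language, of the real
inputs: a topic-mixture corpus (each record samples preferentially from
one condition's related-term cluster, which is what makes embedding
neighbourhoods recoverable), collocations planted with exact adjacent
counts (insertion points inside already-planted phrases are forbidden),
abbreviation substitution at a configurable rate, a concept table
spanning the query families, a subclass DAG with existential attribute
axioms, and validation labels drawn from a configurable mix.  Fixture
sizes in the test suite (hundreds of records, tens of concepts,
~50-class ontologies) were chosen as the smallest scales at which every
planted signal is comfortably recoverable.

What passing fixture tests show: the algorithms are correct on inputs
whose ground truth is known.  What they do not show: performance on real
clinical language — misspellings, local jargon, sense ambiguity,
terminology gaps — which is exactly what the bundled benchmark figures
(evaluated by domain experts on licensed corpora) quantify.  The
corpus-scale numbers of that benchmark (vocabulary sizes, module axiom
counts, per-query pair counts) depend on licensed resources and are out
of scope; the acceptance script instead reports property rates
(collocation recovery, top-k/oracle agreement, module soundness, SPARQL
/native identity) measured on the synthetic fixtures.

## Known limitations

* Told closure under-approximates DL classification (documented above);
  module *extraction* itself is exact ⊥-locality.
* The dictionary mapper has no ranking or word-sense disambiguation; it
  is a reference implementation of the mapper interface, not a
  competitor to a full normalizer.
* Spelling correction, de-identification and sentence splitting are out
  of scope.
* The phrase-score threshold is corpus-dependent and must be set by the
  user.
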