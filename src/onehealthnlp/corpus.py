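"""Corpus normalization and multiword phrase (n-gram) learning.

Free-text clinical corpora — one record per line (a PubMed title/abstract,
a veterinary consultation narrative, ...) — are tokenized on whitespace
only.  Punctuation and numbers stay attached to their tokens, so artifacts
like ``"(copd)_is_a"`` can legitimately arise from phrase joining.

Phrase learning follows the word2phrase collocation procedure: a bigram
``a b`` is joined into the single token ``a_b`` when its discounted
pointwise-mutual-information style score

    score(a, b) = (count(ab) - delta) / (count(a) * count(b)) * N

exceeds a threshold, where ``N`` is the corpus token count.  Running the
procedure for ``p`` passes can build n-grams of up to ``2**p`` tokens
(pass 1 makes bigrams, pass 2 joins bigrams with bigrams, ...).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

JOIN_CHAR = "_"


@dataclass(frozen=True)
class TextCorpus:
    """A tokenizable corpus: one document/consultation per record."""

    records: tuple[str, ...]
    lowercased: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def tokens(self) -> Iterable[list[str]]:
        """Whitespace token lists, one per record."""
        for record in self.records:
            yield record.split()

    def total_tokens(self) -> int:
        return sum(len(toks) for toks in self.tokens())


@dataclass
class PhraseModel:
    """Learned collocations: which adjacent token pairs get joined.

    ``bigram_scores`` holds the score of every pair that passed the
    threshold at some pass; ``vocabulary`` the unigram/joined-token counts
    observed during the final pass.
    """

    vocabulary: dict[str, int] = field(default_factory=dict)
    bigram_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    join_char: str = JOIN_CHAR
    passes: int = 1
    min_count: int = 5
    delta: float = 5.0
    threshold: float = 100.0


def normalize_text(raw: str | Iterable[str], lowercase: bool = False) -> TextCorpus:
    """Split raw text into a record-per-line corpus, optionally lowercased.

    Numbers and punctuation (including parentheses) are preserved as token
    content; only the case transform is applied.  Veterinary narrative
    corpora are conventionally lowercased (their casing is erratic);
    literature corpora are left intact so acronyms like "CKD" survive.
    """
    if isinstance(raw, str):
        lines = raw.splitlines()
    else:
        lines = [line.rstrip("\n") for line in raw]
    records = []
    for line in lines:
        text = line.lower() if lowercase else line
        records.append(" ".join(text.split()))
    return TextCorpus(records=tuple(records), lowercased=lowercase)


def _pair_counts(corpus: TextCorpus) -> tuple[Counter, Counter, int]:
    unigrams: Counter = Counter()
    pairs: Counter = Counter()
    total = 0
    for toks in corpus.tokens():
        unigrams.update(toks)
        total += len(toks)
        pairs.update(zip(toks, toks[1:]))
    return unigrams, pairs, total


def score_pair(
    count_ab: int, count_a: int, count_b: int, total: int, delta: float
) -> float:
    """word2phrase bigram score; <= 0 whenever count_ab <= delta."""
    return (count_ab - delta) / (count_a * count_b) * total


def _one_pass(
    corpus: TextCorpus,
    min_count: int,
    delta: float,
    threshold: float,
    scores: dict[tuple[str, str], float],
) -> TextCorpus:
    unigrams, pairs, total = _pair_counts(corpus)
    joinable: dict[tuple[str, str], float] = {}
    for (a, b), c_ab in pairs.items():
        if unigrams[a] < min_count or unigrams[b] < min_count:
            continue
        s = score_pair(c_ab, unigrams[a], unigrams[b], total, delta)
        if s > threshold:
            joinable[(a, b)] = s
    scores.update(joinable)
    new_records = []
    for toks in corpus.tokens():
        out: list[str] = []
        i = 0
        while i < len(toks):
            # greedy left-to-right, non-overlapping joins (word2phrase style)
            if i + 1 < len(toks) and (toks[i], toks[i + 1]) in joinable:
                out.append(toks[i] + JOIN_CHAR + toks[i + 1])
                i += 2
            else:
                out.append(toks[i])
                i += 1
        new_records.append(" ".join(out))
    return TextCorpus(records=tuple(new_records), lowercased=corpus.lowercased)


def learn_phrases(
    corpus: TextCorpus,
    min_count: int = 5,
    delta: float = 5.0,
    threshold: float = 100.0,
    passes: int = 2,
) -> PhraseModel:
    """Learn a multi-pass phrase model from a corpus.

    Deterministic for fixed inputs.  Raises ``ValueError`` on a
    non-positive threshold or invalid ``min_count``/``passes``.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    if passes < 1:
        raise ValueError(f"passes must be >= 1, got {passes}")
    scores: dict[tuple[str, str], float] = {}
    seen: Counter = Counter()
    working = corpus
    for _ in range(passes):
        unigrams, _, _ = _pair_counts(working)
        for t, c in unigrams.items():
            seen[t] = max(seen[t], c)
        working = _one_pass(working, min_count, delta, threshold, scores)
    unigrams, _, _ = _pair_counts(working)
    for t, c in unigrams.items():
        seen[t] = max(seen[t], c)
    # tokens of every scored pair were counted at their scoring pass, so
    # the >= min_count filter keeps them in the vocabulary
    vocabulary = {t: c for t, c in seen.items() if c >= min_count}
    return PhraseModel(
        vocabulary=vocabulary,
        bigram_scores=scores,
        passes=passes,
        min_count=min_count,
        delta=delta,
        threshold=threshold,
    )


def apply_phrases(corpus: TextCorpus, model: PhraseModel) -> TextCorpus:
    """Join every modeled adjacent pair in the corpus, ``model.passes`` times.

    Token count never increases; the character content of each record is
    conserved up to inserted join characters.
    """
    working = corpus
    for _ in range(model.passes):
        new_records = []
        for toks in working.tokens():
            out: list[str] = []
            i = 0
            while i < len(toks):
                if i + 1 < len(toks) and (toks[i], toks[i + 1]) in model.bigram_scores:
                    out.append(toks[i] + model.join_char + toks[i + 1])
                    i += 2
                else:
                    out.append(toks[i])
                    i += 1
            new_records.append(" ".join(out))
        working = TextCorpus(records=tuple(new_records), lowercased=corpus.lowercased)
    return working


def ngram_frequencies(corpus: TextCorpus) -> dict[str, int]:
    """Frequency of every n-gram (token) in the corpus.

    The counts sum to the corpus token count and are invariant to record
    order.
    """
    counts: Counter = Counter()
    for toks in corpus.tokens():
        counts.update(toks)
    return dict(counts)


def write_frequencies(freqs: Mapping[str, int], path) -> None:
    """Two-column TSV (ngram, count), descending count then lexicographic."""
    with open(path, "w", encoding="utf-8") as fh:
        for ngram, count in sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{ngram}\t{count}\n")


def read_corpus(path, lowercase: bool = False) -> TextCorpus:
    with open(path, encoding="utf-8") as fh:
        return normalize_text(fh.read(), lowercase=lowercase)


def write_corpus(corpus: TextCorpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for record in corpus.records:
            fh.write(record + "\n")
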