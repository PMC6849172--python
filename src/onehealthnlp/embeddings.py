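"""Neural embeddings over phrased corpora and cosine-ranked candidate terms.

Two classic word2vec architectures are provided by a compact reference
trainer (negative sampling, linearly decaying learning rate):

* ``CBOW`` — the averaged context window predicts the centre n-gram;
* ``SKIPGRAM`` — the centre n-gram predicts each context n-gram.

The trainer is deliberately pluggable: anything that returns an
:class:`EmbeddingModel` (e.g. vectors read from a word2vec text file
produced by an external tool) can stand upstream of candidate retrieval.
Retrieval itself is exhaustive: for a target term the ``k`` vocabulary
n-grams with the highest cosine similarity are returned (default k=20),
which is exact, not approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .corpus import TextCorpus

CBOW = "CBOW"
SKIPGRAM = "SKIPGRAM"


class OutOfVocabularyError(KeyError):
    """Raised when a requested term has no vector."""

    def __init__(self, term: str):
        super().__init__(term)
        self.term = term

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"term not in embedding vocabulary: {self.term!r}"


@dataclass
class EmbeddingModel:
    architecture: str
    dimension: int
    vocabulary: list[str]
    vectors: np.ndarray  # shape (len(vocabulary), dimension)
    min_count: int = 5
    index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.vocabulary)}
        if self.vectors.shape != (len(self.vocabulary), self.dimension):
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match "
                f"({len(self.vocabulary)}, {self.dimension})"
            )

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def vector(self, term: str) -> np.ndarray:
        try:
            return self.vectors[self.index[term]]
        except KeyError:
            raise OutOfVocabularyError(term) from None


@dataclass(frozen=True)
class CandidateRanking:
    """Top-k cosine neighbours of a target term, best first."""

    target: str
    candidates: tuple[tuple[str, float], ...]
    k: int
    architecture: str = ""
    dataset: str = ""


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; symmetric and scale-invariant."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def train_embeddings(
    corpus: TextCorpus,
    architecture: str = SKIPGRAM,
    dimension: int = 50,
    min_count: int = 5,
    seed: int = 1,
    window: int = 5,
    negative: int = 5,
    epochs: int = 5,
    alpha: float = 0.025,
) -> EmbeddingModel:
    """Train negative-sampling embeddings on a (phrased) corpus.

    The vocabulary keeps only n-grams with corpus frequency strictly
    greater than ``min_count``.  Training is deterministic for a fixed
    seed (single-threaded).  Raises ``ValueError`` when the corpus is
    empty or no n-gram survives the frequency cut.
    """
    if architecture not in (CBOW, SKIPGRAM):
        raise ValueError(f"unknown architecture: {architecture!r}")
    if len(corpus) == 0 or corpus.total_tokens() == 0:
        raise ValueError("cannot train embeddings on an empty corpus")

    freqs: dict[str, int] = {}
    for toks in corpus.tokens():
        for t in toks:
            freqs[t] = freqs.get(t, 0) + 1
    vocab = sorted(t for t, c in freqs.items() if c > min_count)
    if not vocab:
        raise ValueError(
            f"no n-gram has frequency > min_count={min_count}; "
            "lower min_count or supply a larger corpus"
        )
    index = {t: i for i, t in enumerate(vocab)}
    sentences = [
        np.array([index[t] for t in toks if t in index], dtype=np.int64)
        for toks in corpus.tokens()
    ]
    sentences = [s for s in sentences if len(s) >= 2]
    if not sentences:
        raise ValueError(
            "no record retains >= 2 in-vocabulary tokens; the corpus is "
            "smaller than a context window"
        )

    rng = np.random.default_rng(seed)
    n = len(vocab)
    vec_in = (rng.random((n, dimension)) - 0.5) / dimension
    vec_out = np.zeros((n, dimension))

    # unigram^(3/4) negative-sampling distribution
    counts = np.array([freqs[t] for t in vocab], dtype=float)
    noise = counts**0.75
    noise /= noise.sum()

    total_steps = max(1, epochs * sum(len(s) for s in sentences))
    step = 0
    for _ in range(epochs):
        for sent in sentences:
            windows = rng.integers(1, window + 1, size=len(sent))
            for pos, center in enumerate(sent):
                lr = alpha * max(1e-4, 1.0 - step / total_steps)
                step += 1
                w = int(windows[pos])
                lo, hi = max(0, pos - w), min(len(sent), pos + w + 1)
                context = np.concatenate((sent[lo:pos], sent[pos + 1 : hi]))
                if len(context) == 0:
                    continue
                negs = rng.choice(n, size=negative, p=noise)
                targets = np.concatenate(([center], negs))
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                if architecture == CBOW:
                    h = vec_in[context].mean(axis=0)
                    scores = vec_out[targets] @ h
                    g = (labels - _sigmoid(scores)) * lr
                    grad_h = g @ vec_out[targets]
                    vec_out[targets] += np.outer(g, h)
                    vec_in[context] += grad_h / len(context)
                else:
                    h = vec_in[center]
                    for ctx in context:
                        scores = vec_out[targets] @ vec_in[ctx]
                        g = (labels - _sigmoid(scores)) * lr
                        grad = g @ vec_out[targets]
                        vec_out[targets] += np.outer(g, vec_in[ctx])
                        vec_in[ctx] += grad
                    h = None  # noqa: F841 (skip-gram updates in place)

    return EmbeddingModel(
        architecture=architecture,
        dimension=dimension,
        vocabulary=vocab,
        vectors=vec_in,
        min_count=min_count,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def top_k_candidates(
    model: EmbeddingModel,
    target: str,
    k: int = 20,
    architecture: str | None = None,
    dataset: str = "",
) -> CandidateRanking:
    """Exhaustive top-k cosine neighbours of ``target`` (target excluded).

    Ties are broken by descending cosine then lexicographic n-gram order.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if target not in model:
        raise OutOfVocabularyError(target)
    tvec = model.vector(target)
    norms = np.linalg.norm(model.vectors, axis=1)
    norms[norms == 0] = np.inf  # zero vectors never rank
    sims = (model.vectors @ tvec) / (norms * np.linalg.norm(tvec))
    order = sorted(
        (i for i in range(len(model.vocabulary)) if model.vocabulary[i] != target),
        key=lambda i: (-sims[i], model.vocabulary[i]),
    )
    chosen = order[:k]
    return CandidateRanking(
        target=target,
        candidates=tuple((model.vocabulary[i], float(sims[i])) for i in chosen),
        k=k,
        architecture=architecture or model.architecture,
        dataset=dataset,
    )


def select_target_terms(
    freqs: Mapping[str, int],
    mapper: Callable[[str], Sequence[str]],
    concept_types: Callable[[str], set[str]],
    min_freq: int = 1000,
    required_semantic_type: str = "T047",
) -> list[str]:
    """Candidate target terms: frequent n-grams mapping to a required type.

    ``mapper`` resolves an n-gram to candidate concept IDs and
    ``concept_types`` gives the semantic types of a concept.  An n-gram
    qualifies when its frequency exceeds ``min_freq`` and at least one
    mapped concept carries ``required_semantic_type`` (by default
    T047, "Disease or Syndrome").  Final curation of the returned list is
    a human decision, not computed here.
    """
    selected = []
    for ngram, count in sorted(freqs.items()):
        if count <= min_freq:
            continue
        cuis = mapper(ngram)
        if any(required_semantic_type in concept_types(c) for c in cuis):
            selected.append(ngram)
    return selected


# ---------------------------------------------------------------------------
# word2vec text format


def write_word2vec(model: EmbeddingModel, path) -> None:
    """word2vec text format: header "count dim", then "term v1 ... vd"."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(model.vocabulary)} {model.dimension}\n")
        for term, vec in zip(model.vocabulary, model.vectors):
            fh.write(term + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


def read_word2vec(path, architecture: str = "", min_count: int = 0) -> EmbeddingModel:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        count, dim = int(header[0]), int(header[1])
        vocab: list[str] = []
        vecs = np.empty((count, dim))
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split(" ")
            vocab.append(parts[0])
            vecs[i] = [float(x) for x in parts[1 : dim + 1]]
    return EmbeddingModel(
        architecture=architecture or "IMPORTED",
        dimension=dim,
        vocabulary=vocab,
        vectors=vecs,
        min_count=min_count,
    )


def write_rankings(rankings: Sequence[CandidateRanking], path) -> None:
    """Ranking TSV: target, candidate, cosine (6 dp), rank, architecture, dataset."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("target\tcandidate\tcosine\trank\tarchitecture\tdataset\n")
        for r in rankings:
            for rank, (cand, cos) in enumerate(r.candidates, start=1):
                fh.write(
                    f"{r.target}\t{cand}\t{cos:.6f}\t{rank}\t{r.architecture}\t{r.dataset}\n"
                )
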