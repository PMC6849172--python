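import pytest
from hypothesis import settings

from onehealthnlp import corpus as corpus_mod

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from onehealthnlp import embeddings as emb
from onehealthnlp import short_forms as sf
from onehealthnlp import synthetic


@pytest.fixture(scope="session")
def fixture_spec():
    return synthetic.FixtureSpec(seed=11, n_records=500)


@pytest.fixture(scope="session")
def bundle(fixture_spec):
    return synthetic.generate(fixture_spec)


@pytest.fixture(scope="session")
def phrased_corpus(bundle):
    model = corpus_mod.learn_phrases(bundle.corpus, threshold=50)
    return corpus_mod.apply_phrases(bundle.corpus, model)


@pytest.fixture(scope="session")
def cbow_model(phrased_corpus):
    return emb.train_embeddings(
        phrased_corpus, architecture=emb.CBOW, dimension=40,
        min_count=5, seed=7, epochs=3,
    )


@pytest.fixture(scope="session")
def lexicons(bundle):
    return sf.ShortFormLexicons(
        units=bundle.units, common_words=bundle.common_words
    )
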