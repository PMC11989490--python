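import pytest

from afdebut.extractor import builtin_schema
from afdebut.negation import builtin_rules
from afdebut.pipeline import extract_corpus
from afdebut.sectioner import builtin_lexicon
from afdebut.synthetic import GenerationConfig, generate_corpus


@pytest.fixture(scope="session")
def es_lexicon():
    return builtin_lexicon("spanish")


@pytest.fixture(scope="session")
def es_schema():
    return builtin_schema("spanish")


@pytest.fixture(scope="session")
def es_rules():
    return builtin_rules("spanish")


@pytest.fixture(scope="session")
def en_lexicon():
    return builtin_lexicon("english")


@pytest.fixture(scope="session")
def noisy_corpus():
    """Default-noise Spanish corpus: (config, reports, coded, gold)."""
    config = GenerationConfig(n_patients=100, seed=3)
    reports, coded, gold = generate_corpus(config)
    return config, reports, coded, gold


@pytest.fixture(scope="session")
def zero_noise_corpus():
    config = GenerationConfig(n_patients=100, seed=3, negation_rate=0.0,
                              synonym_rate=0.0, distractor_rate=0.0,
                              coding_fp_rate=0.0, coding_fn_rate=0.0)
    reports, coded, gold = generate_corpus(config)
    return config, reports, coded, gold


@pytest.fixture(scope="session")
def noisy_vectors(noisy_corpus, es_schema, es_lexicon, es_rules):
    _, reports, _, _ = noisy_corpus
    return extract_corpus(reports, es_schema, es_lexicon, es_rules)


@pytest.fixture(scope="session")
def zero_noise_vectors(zero_noise_corpus, es_schema, es_lexicon, es_rules):
    _, reports, _, _ = zero_noise_corpus
    return extract_corpus(reports, es_schema, es_lexicon, es_rules)
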