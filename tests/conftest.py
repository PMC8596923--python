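import pytest

from ppio.dictionary import compile_dictionary
from ppio.synthetic import PlantSpec, gen_corpus, gen_toy_ontology


@pytest.fixture(scope="session")
def toy_ontology():
    return gen_toy_ontology(terms_per_category=10, seed=1)


@pytest.fixture(scope="session")
def toy_dictionary(toy_ontology):
    return compile_dictionary(toy_ontology)


@pytest.fixture(scope="session")
def small_corpus(toy_ontology):
    spec = PlantSpec(n_sentences=40, terms_per_category=10, plants_per_sentence=2.0, seed=3)
    return gen_corpus(toy_ontology, spec)
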