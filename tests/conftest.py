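from datetime import date

import pytest

from attesa import GeneratorConfig, Pipeline, compile_grammar, generate_corpus


@pytest.fixture(scope="session")
def grammar():
    return compile_grammar()


@pytest.fixture(scope="session")
def pipeline():
    return Pipeline()


@pytest.fixture(scope="session")
def anchor():
    return date(2021, 6, 15)


@pytest.fixture(scope="session")
def clean_corpus():
    """Small seed-fixed corpus without typos or distractors."""
    cfg = GeneratorConfig(n_texts=1500, prevalence=0.05, typo_rate=0.0,
                          distractor_rate=0.0, seed=42)
    texts, golds = generate_corpus(cfg)
    return cfg, texts, golds
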