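import pytest
from hypothesis import settings

from medextract.lexicon import build_lexicon

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from medextract.synthetic_corpus import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def toy_lexicon():
    return build_lexicon(
        [
            ("doliprane", "N02BE01", "medication_name"),
            ("paracetamol", "N02BE01", "medication_name"),
            ("paracetamol codeine", "N02BE51", "medication_name"),
            ("kardegic", "B01AC06", "medication_name"),
            ("acide acetylsalicylique", "B01AC06", "medication_name"),
            ("antibiotherapie", "J01", "medication_class"),
        ]
    )


@pytest.fixture(scope="session")
def clean_corpus():
    """Small zero-noise corpus shared by rule/feature tests."""
    cfg = GeneratorConfig(
        n_documents=30, seed=7, alias_rate=0.0, paraphrase_rate=0.0, typo_rate=0.0
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def noisy_corpus():
    cfg = GeneratorConfig(n_documents=40, seed=11)
    return generate_corpus(cfg)
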