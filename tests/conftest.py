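import numpy as np
import pytest

from petweak.synthetic import demo_ontology, generate_cohort


@pytest.fixture(scope="session")
def ontology():
    return demo_ontology()


@pytest.fixture(scope="session")
def small_cohort(ontology):
    """40 exams with tiny volumes; includes neutral sentences."""
    prevalences = {rid: 0.35 for rid in ontology.leaves()}
    return generate_cohort(
        ontology,
        n_exams=40,
        prevalences=prevalences,
        volume_shape=(32, 32, 8),
        neutral_sentence_rate=0.4,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_cohort(ontology):
    """Unambiguous reports only (no neutral sentences)."""
    prevalences = {rid: 0.35 for rid in ontology.leaves()}
    return generate_cohort(
        ontology,
        n_exams=40,
        prevalences=prevalences,
        volume_shape=(32, 32, 8),
        neutral_sentence_rate=0.0,
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
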