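import numpy as np
import pytest

from crowdscreen import agents, synthetic
from crowdscreen.corpus_io import Corpus, Record


@pytest.fixture
def tiny_corpus():
    """Three hand-written records with known labels."""
    return Corpus(records=[
        Record(record_id="a", title="cat", body="x", known_label=1),
        Record(record_id="b", title="dog", body="y", known_label=0),
        Record(record_id="c", title="cat dog", body="z", known_label=None),
    ])


@pytest.fixture
def labeled_corpus():
    """Fully labeled separable synthetic corpus, 40 records."""
    return synthetic.generate_corpus(
        synthetic.CorpusSpec(n_records=40, prevalence=0.15,
                             separability=0.9, seed=11))


@pytest.fixture
def bayes_chain():
    return agents.single_agent_chain(agents.bayes_learner(0))


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_corpus(labels, prefix="r"):
    """Corpus with the given true labels and distinct one-token texts."""
    return Corpus(records=[
        Record(record_id=f"{prefix}{i}", title=f"tok{i}", body="",
               known_label=lb)
        for i, lb in enumerate(labels)
    ])
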