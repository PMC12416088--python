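import numpy as np
import pytest

from crowdscreen import agents as ag
from crowdscreen import synthetic
from crowdscreen.errors import (CrowdScreenError, DuplicateLabelError,
                                ValidationError)
from crowdscreen.features import FeatureCache, VectorizerSpec
from crowdscreen.learning import BalancerSpec, ClassifierSpec, QuerierSpec

from conftest import make_corpus


def random_agent(name="rnd", handoff=None):
    return ag.AgentSpec(name=name, querier=QuerierSpec(strategy="random"),
                        handoff=handoff or ag.HandoffPolicy(kind="never"))


def model_agent(name="mdl", handoff=None, seed=0):
    return ag.AgentSpec(
        name=name,
        vectorizer=VectorizerSpec(kind="tfidf"),
        classifier=ClassifierSpec(algorithm="multinomial-bayes",
                                  random_seed=seed),
        balancer=BalancerSpec(),
        querier=QuerierSpec(strategy="max"),
        handoff=handoff or ag.HandoffPolicy(kind="never"),
    )


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

def test_querier_is_mandatory():
    with pytest.raises((ValidationError, TypeError)):
        ag.AgentSpec(name="x", querier=None)


def test_classifier_requires_vectorizer():
    with pytest.raises(ValidationError):
        ag.AgentSpec(name="x", querier=QuerierSpec(),
                     classifier=ClassifierSpec(algorithm="logistic"))


def test_handoff_threshold_positive():
    with pytest.raises(ValidationError):
        ag.HandoffPolicy(kind="labeled_count", threshold=0)


def test_chain_needs_an_agent():
    with pytest.raises(ValidationError):
        ag.AgentChain(agents=())


# ---------------------------------------------------------------------------
# stopping / hand-off
# ---------------------------------------------------------------------------

def chain_of(*agents_):
    return ag.AgentChain(agents=tuple(agents_))


def test_min_training_ready():
    state = ag.ScreenState.from_corpus(make_corpus([1, 0, 0]))
    assert not ag.min_training_ready(state)
    state.apply_label("r0", 1)
    assert not ag.min_training_ready(state)
    state.apply_label("r1", 0)
    assert ag.min_training_ready(state)


def test_delta_k_handoff_with_successor():
    corpus = make_corpus([0] * 120 + [1])
    chain = chain_of(
        random_agent(handoff=ag.HandoffPolicy(kind="consecutive_irrelevant",
                                              threshold=100)),
        random_agent(name="rnd2"))
    state = ag.ScreenState.from_corpus(corpus)
    for i in range(100):
        state.apply_label(f"r{i}", 0)
    assert state.delta_k == 100
    assert ag.evaluate_stopping(state, chain) is ag.StopDecision.HANDOFF


def test_relevant_label_resets_delta_k():
    corpus = make_corpus([0] * 100 + [1, 0])
    state = ag.ScreenState.from_corpus(corpus)
    for i in range(99):
        state.apply_label(f"r{i}", 0)
    assert state.delta_k == 99
    state.apply_label("r100", 1)
    assert state.delta_k == 0
    chain = chain_of(
        random_agent(handoff=ag.HandoffPolicy(kind="consecutive_irrelevant",
                                              threshold=100)),
        random_agent(name="rnd2"))
    assert ag.evaluate_stopping(state, chain) is ag.StopDecision.CONTINUE


def test_empty_pool_is_global_stop_regardless_of_policy():
    corpus = make_corpus([1, 0])
    chain = chain_of(random_agent(), random_agent(name="rnd2"))
    state = ag.ScreenState.from_corpus(corpus)
    state.apply_label("r0", 1)
    state.apply_label("r1", 0)
    assert ag.evaluate_stopping(state, chain) is ag.StopDecision.GLOBAL_STOP


def test_handoff_without_successor_is_global_stop():
    corpus = make_corpus([1, 0, 0, 0])
    chain = chain_of(random_agent(
        handoff=ag.HandoffPolicy(kind="labeled_count", threshold=1)))
    state = ag.ScreenState.from_corpus(corpus)
    state.apply_label("r0", 1)
    assert ag.evaluate_stopping(state, chain) is ag.StopDecision.GLOBAL_STOP


def test_labeled_fraction_handoff():
    corpus = make_corpus([1] + [0] * 19)   # |K| = 20; 5% = 1 label
    chain = chain_of(
        random_agent(handoff=ag.HandoffPolicy(kind="labeled_fraction",
                                              threshold=0.05)),
        random_agent(name="rnd2"))
    state = ag.ScreenState.from_corpus(corpus)
    state.apply_label("r0", 1)
    assert ag.evaluate_stopping(state, chain) is ag.StopDecision.HANDOFF


def test_user_stop_wins():
    corpus = make_corpus([1, 0, 0])
    chain = chain_of(random_agent())
    state = ag.ScreenState.from_corpus(corpus)
    state.user_stop = True
    assert ag.evaluate_stopping(state, chain) is ag.StopDecision.GLOBAL_STOP


# ---------------------------------------------------------------------------
# advance_chain
# ---------------------------------------------------------------------------

def test_advance_resets_segment_counters_keeps_labels():
    corpus = make_corpus([1, 0, 0, 0, 0])
    chain = chain_of(
        random_agent(handoff=ag.HandoffPolicy(kind="labeled_count",
                                              threshold=2)),
        model_agent())
    state = ag.ScreenState.from_corpus(corpus)
    state.apply_label("r0", 1)
    state.apply_label("r1", 0)
    assert state.k == 2 and state.delta_k == 1
    ag.advance_chain(state, chain)
    assert state.active_agent == 1
    assert state.k == 0 and state.k_pos == 0 and state.k_neg == 0
    assert state.delta_k == 0                     # reset on hand-off
    assert state.relevant == {"r0"} and state.irrelevant == {"r1"}


def test_advance_without_successor_is_internal_error():
    state = ag.ScreenState.from_corpus(make_corpus([1, 0]))
    with pytest.raises(CrowdScreenError):
        ag.advance_chain(state, chain_of(random_agent()))


def test_handoff_reuses_feature_cache():
    corpus = synthetic.generate_corpus(
        synthetic.CorpusSpec(n_records=30, prevalence=0.2, seed=4))
    cache = FeatureCache()
    chain = chain_of(
        model_agent(name="m1", handoff=ag.HandoffPolicy(
            kind="labeled_count", threshold=4)),
        model_agent(name="m2"))
    state = ag.ScreenState.from_corpus(corpus)
    rng = np.random.default_rng(0)
    rel = [r.record_id for r in corpus if r.known_label == 1]
    irr = [r.record_id for r in corpus if r.known_label == 0]
    batch = [rel[0], irr[0], rel[1], irr[1], irr[2], irr[3]]
    for rid in batch:
        ag.run_cycle_iteration(state, chain,
                               [(rid, corpus.by_id(rid).known_label)],
                               cache, rng)
    assert state.active_agent == 1
    assert cache.n_builds == 1   # same vectorizer spec -> one build


# ---------------------------------------------------------------------------
# run_cycle_iteration
# ---------------------------------------------------------------------------

def test_cycle_trains_once_min_ready(rng):
    corpus = make_corpus([1, 0, 1, 0, 0])
    chain = chain_of(model_agent())
    state = ag.ScreenState.from_corpus(corpus)
    state, decision, outcome = ag.run_cycle_iteration(
        state, chain, [("r0", 1), ("r1", 0)], FeatureCache(), rng)
    assert decision is ag.StopDecision.CONTINUE
    assert outcome.trained
    assert outcome.training_set_size == 2
    assert sorted(outcome.ranking) == ["r2", "r3", "r4"]


def test_cycle_random_ranking_before_min_ready(rng):
    corpus = make_corpus([1, 0, 1, 0, 0])
    chain = chain_of(model_agent())
    state = ag.ScreenState.from_corpus(corpus)
    state, decision, outcome = ag.run_cycle_iteration(
        state, chain, [("r0", 1)], FeatureCache(), rng)
    assert decision is ag.StopDecision.CONTINUE
    assert not outcome.trained
    assert sorted(outcome.ranking) == ["r1", "r2", "r3", "r4"]


def test_cycle_empty_batch_reevaluates_only(rng):
    corpus = make_corpus([1, 0, 0])
    chain = chain_of(random_agent())
    state = ag.ScreenState.from_corpus(corpus)
    before = (set(state.pool), state.k)
    state, decision, _ = ag.run_cycle_iteration(state, chain, [],
                                                FeatureCache(), rng)
    assert decision is ag.StopDecision.CONTINUE
    assert (set(state.pool), state.k) == before


def test_duplicate_label_raises(rng):
    corpus = make_corpus([1, 0, 0])
    chain = chain_of(random_agent())
    state = ag.ScreenState.from_corpus(corpus)
    ag.run_cycle_iteration(state, chain, [("r0", 1)], FeatureCache(), rng)
    with pytest.raises(DuplicateLabelError):
        ag.run_cycle_iteration(state, chain, [("r0", 0)], FeatureCache(), rng)


def test_separable_corpus_ranks_relevant_first(rng):
    """All classifiers put every relevant pool record above every
    irrelevant one on a linearly separable 2-term corpus."""
    labels = [1, 1, 1, 0, 0, 0, 1, 0, 1, 0]
    from crowdscreen.corpus_io import Corpus, Record
    corpus = Corpus(records=[
        Record(record_id=f"r{i}", title="aaa bbb" if lb else "ccc ddd",
               known_label=lb)
        for i, lb in enumerate(labels)
    ])
    for algo in ("multinomial-bayes", "logistic", "linear-svm",
                 "random-forest"):
        agent = ag.AgentSpec(
            name=algo,
            vectorizer=VectorizerSpec(kind="onehot", ngram_range=(1, 1)),
            classifier=ClassifierSpec(algorithm=algo, random_seed=0),
            querier=QuerierSpec(strategy="max"),
        )
        state = ag.ScreenState.from_corpus(corpus)
        state.apply_label("r0", 1)
        state.apply_label("r3", 0)
        outcome = ag.compute_ranking(state, agent, FeatureCache(),
                                     np.random.default_rng(0))
        truth = [corpus.by_id(rid).known_label for rid in outcome.ranking]
        n_rel = sum(truth)
        assert truth == [1] * n_rel + [0] * (len(truth) - n_rel), algo


def test_chain_serialization_roundtrip():
    chain = ag.worked_example_chain(seed=5)
    config = ag.chain_to_config(chain)
    back = ag.chain_from_config(config)
    assert back == chain
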