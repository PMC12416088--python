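import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdscreen.corpus_io import Corpus, Record
from crowdscreen.errors import ConsistencyError, InsufficientTrainingError
from crowdscreen.features import VectorizerSpec, fit_transform
from crowdscreen.learning import (BalancerSpec, ClassifierSpec, QuerierSpec,
                                  ScoredPool, compute_sample_weights,
                                  rank_pool, train_and_score)


# ---------------------------------------------------------------------------
# balancer
# ---------------------------------------------------------------------------

def test_balanced_classes_get_unit_weights():
    w = compute_sample_weights([1, 0], BalancerSpec())
    np.testing.assert_allclose(w, [1.0, 1.0])


def test_inverse_frequency_weights():
    w = compute_sample_weights([1, 0, 0, 0], BalancerSpec())
    np.testing.assert_allclose(w, [2.0, 2 / 3, 2 / 3, 2 / 3])
    assert w.mean() == pytest.approx(1.0)


def test_single_class_is_error():
    with pytest.raises(InsufficientTrainingError):
        compute_sample_weights([1, 1, 1], BalancerSpec())


def test_multiplier_scales_relevant_side():
    w = compute_sample_weights([1, 0], BalancerSpec(
        relevant_weight_multiplier=3.0))
    np.testing.assert_allclose(w, [3.0, 1.0])


def test_mean_weight_is_one_for_any_imbalance():
    for labels in ([1, 0, 0], [1, 1, 0, 0, 0, 0, 0], [1] * 5 + [0] * 45):
        w = compute_sample_weights(labels, BalancerSpec())
        assert w.mean() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# training & scoring
# ---------------------------------------------------------------------------

def _toy_corpus():
    return Corpus(records=[
        Record(record_id="d1", title="a a", known_label=1),
        Record(record_id="d2", title="b b", known_label=0),
        Record(record_id="d3", title="a", known_label=None),
    ])


def test_bayes_matches_hand_computed_posterior():
    # onehot features; Laplace alpha=1; uniform priors via balanced weights
    corpus = _toy_corpus()
    fm = fit_transform(corpus, VectorizerSpec(kind="onehot",
                                              ngram_range=(1, 1)))
    labels = [1, 0, None]
    weights = compute_sample_weights([1, 0], BalancerSpec())
    pool = train_and_score(fm, labels, weights,
                           ClassifierSpec(algorithm="multinomial-bayes"),
                           record_ids=corpus.ids)
    assert pool.score_kind == "probability"
    # d1 onehot = [a], d2 = [b]; theta_a|rel = (1+1)/(1+2), theta_a|irr = 1/3
    # posterior(rel | d3=[a]) = (2/3)/(2/3 + 1/3) = 2/3
    assert pool.scores["d3"] == pytest.approx(2 / 3, abs=1e-9)
    assert pool.scores["d3"] > 0.5


def test_logistic_scores_are_probabilities(labeled_corpus):
    fm = fit_transform(labeled_corpus, VectorizerSpec(kind="tfidf"))
    labels = list(labeled_corpus.labels)
    labels[-5:] = [None] * 5
    y = [lb for lb in labels if lb is not None]
    weights = compute_sample_weights(y, BalancerSpec())
    pool = train_and_score(fm, labels, weights,
                           ClassifierSpec(algorithm="logistic", random_seed=0),
                           record_ids=labeled_corpus.ids)
    assert pool.score_kind == "probability"
    assert all(0.0 <= s <= 1.0 for s in pool.scores.values())


def test_svm_gives_decision_scores(labeled_corpus):
    fm = fit_transform(labeled_corpus, VectorizerSpec(kind="tfidf"))
    labels = list(labeled_corpus.labels)
    labels[-5:] = [None] * 5
    y = [lb for lb in labels if lb is not None]
    pool = train_and_score(fm, labels,
                           compute_sample_weights(y, BalancerSpec()),
                           ClassifierSpec(algorithm="linear-svm",
                                          random_seed=0),
                           record_ids=labeled_corpus.ids)
    assert pool.score_kind == "decision"


def test_weight_two_equals_duplicated_row():
    """Doubling a row's weight must equal duplicating the row."""
    corpus = Corpus(records=[
        Record(record_id="p", title="a a b", known_label=1),
        Record(record_id="q", title="b b c", known_label=0),
        Record(record_id="s", title="a c", known_label=None),
    ])
    fm = fit_transform(corpus, VectorizerSpec(kind="onehot",
                                              ngram_range=(1, 1)))
    dup_corpus = Corpus(records=[
        Record(record_id="p", title="a a b", known_label=1),
        Record(record_id="p2", title="a a b", known_label=1),
        Record(record_id="q", title="b b c", known_label=0),
        Record(record_id="s", title="a c", known_label=None),
    ])
    fm_dup = fit_transform(dup_corpus, VectorizerSpec(kind="onehot",
                                                      ngram_range=(1, 1)))
    for algo in ("multinomial-bayes", "logistic"):
        spec = ClassifierSpec(algorithm=algo, random_seed=0)
        weighted = train_and_score(fm, [1, 0, None],
                                   np.array([2.0, 1.0]), spec,
                                   record_ids=corpus.ids)
        duplicated = train_and_score(fm_dup, [1, 1, 0, None],
                                     np.array([1.0, 1.0, 1.0]), spec,
                                     record_ids=dup_corpus.ids)
        assert weighted.scores["s"] == pytest.approx(
            duplicated.scores["s"], abs=1e-9), algo


def test_single_class_training_is_error(tiny_corpus):
    fm = fit_transform(tiny_corpus, VectorizerSpec(kind="onehot",
                                                   ngram_range=(1, 1)))
    with pytest.raises(InsufficientTrainingError):
        train_and_score(fm, [1, 1, None], None,
                        ClassifierSpec(algorithm="logistic"))


def test_determinism_fixed_seed(labeled_corpus):
    fm = fit_transform(labeled_corpus, VectorizerSpec(kind="tfidf"))
    labels = list(labeled_corpus.labels)
    labels[-8:] = [None] * 8
    y = [lb for lb in labels if lb is not None]
    w = compute_sample_weights(y, BalancerSpec())
    spec = ClassifierSpec(algorithm="random-forest", random_seed=3,
                          hyperparameters={"n_estimators": 20})
    a = train_and_score(fm, labels, w, spec, record_ids=labeled_corpus.ids)
    b = train_and_score(fm, labels, w, spec, record_ids=labeled_corpus.ids)
    assert a.scores == b.scores


# ---------------------------------------------------------------------------
# rank_pool
# ---------------------------------------------------------------------------

ORDER = ["r1", "r2", "r3"]


def test_max_descending():
    pool = ScoredPool({"r1": 0.9, "r2": 0.1, "r3": 0.5}, "probability")
    assert rank_pool(pool, QuerierSpec(strategy="max"), ORDER) == \
        ["r1", "r3", "r2"]


def test_uncertainty_with_tie_break():
    pool = ScoredPool({"r1": 0.9, "r2": 0.1, "r3": 0.5}, "probability")
    # distances 0.4, 0.4, 0.0; tie broken by corpus position
    assert rank_pool(pool, QuerierSpec(strategy="uncertainty"), ORDER) == \
        ["r3", "r1", "r2"]


def test_uncertainty_decision_boundary_zero():
    pool = ScoredPool({"r1": -2.0, "r2": 0.1, "r3": 1.5}, "decision")
    assert rank_pool(pool, QuerierSpec(strategy="uncertainty"), ORDER) == \
        ["r2", "r3", "r1"]


def test_hybrid_epsilon_zero_equals_max(rng):
    pool = ScoredPool({"r1": 0.9, "r2": 0.1, "r3": 0.5}, "probability")
    q = QuerierSpec(strategy="hybrid", random_fraction=0.0)
    assert rank_pool(pool, q, ORDER, rng) == \
        rank_pool(pool, QuerierSpec(strategy="max"), ORDER)


def test_top_down_is_corpus_order():
    assert rank_pool(None, QuerierSpec(strategy="top_down"),
                     ["a", "b", "c", "d"], pool_ids=["d", "b", "a"]) == \
        ["a", "b", "d"]


def test_random_is_seeded_permutation():
    q = QuerierSpec(strategy="random")
    a = rank_pool(None, q, ORDER, np.random.default_rng(0), pool_ids=ORDER)
    b = rank_pool(None, q, ORDER, np.random.default_rng(0), pool_ids=ORDER)
    assert a == b and sorted(a) == sorted(ORDER)


def test_missing_score_is_consistency_error():
    pool = ScoredPool({"r1": 0.9}, "probability")
    with pytest.raises(ConsistencyError):
        rank_pool(pool, QuerierSpec(strategy="max"), ORDER, pool_ids=ORDER)


@settings(max_examples=60, deadline=None)
@given(
    scores=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12),
    strategy=st.sampled_from(["max", "uncertainty", "hybrid", "random",
                              "top_down"]),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_rank_pool_is_permutation_and_deterministic(scores, strategy, seed):
    ids = [f"r{i}" for i in range(len(scores))]
    pool = ScoredPool(dict(zip(ids, scores)), "probability")
    q = QuerierSpec(strategy=strategy)
    a = rank_pool(pool, q, ids, np.random.default_rng(seed), pool_ids=ids)
    b = rank_pool(pool, q, ids, np.random.default_rng(seed), pool_ids=ids)
    assert sorted(a) == sorted(ids)      # permutation of the pool
    assert a == b                        # deterministic under the seed
    if strategy == "max":                # brute-force sort oracle
        oracle = [rid for _, _, rid in
                  sorted((-s, i, rid)
                         for i, (rid, s) in enumerate(zip(ids, scores)))]
        assert a == oracle
    if strategy == "uncertainty":
        oracle = [rid for _, _, rid in
                  sorted((abs(s - 0.5), i, rid)
                         for i, (rid, s) in enumerate(zip(ids, scores)))]
        assert a == oracle
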