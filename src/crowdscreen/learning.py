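"""Balanced weighting, classifier training/scoring, and pool ranking.

The querier turns model scores into a screening order:

* ``max`` — descending relevance score (certainty sampling);
* ``uncertainty`` — ascending distance to the decision boundary
  (0.5 for probabilities, 0 for decision values);
* ``hybrid`` — the ``max`` order with a seeded fraction of random pool
  records promoted into random positions;
* ``random`` — seeded shuffle;
* ``top_down`` — original corpus order.

Ties are always broken by ascending corpus position, so every ranking is
exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import (ConsistencyError, InsufficientTrainingError,
                     ValidationError)

CLASSIFIER_ALGORITHMS = ("multinomial-bayes", "logistic", "linear-svm",
                         "random-forest")
QUERY_STRATEGIES = ("max", "uncertainty", "hybrid", "random", "top_down")


@dataclass(frozen=True)
class BalancerSpec:
    kind: str = "balanced"                   # {"balanced", "none"}
    relevant_weight_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("balanced", "none"):
            raise ValidationError(f"unknown balancer kind {self.kind!r}")
        if self.relevant_weight_multiplier <= 0:
            raise ValidationError("relevant_weight_multiplier must be > 0")


@dataclass(frozen=True)
class ClassifierSpec:
    algorithm: str = "linear-svm"
    hyperparameters: tuple = ()              # sorted (name, value) pairs
    random_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.algorithm not in CLASSIFIER_ALGORITHMS:
            raise ValidationError(f"unknown classifier {self.algorithm!r}")
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(self, "hyperparameters",
                               tuple(sorted(self.hyperparameters.items())))

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)


@dataclass(frozen=True)
class QuerierSpec:
    strategy: str = "max"
    random_fraction: float = 0.05            # hybrid only
    random_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strategy not in QUERY_STRATEGIES:
            raise ValidationError(f"unknown query strategy {self.strategy!r}")
        if not (0.0 <= self.random_fraction <= 1.0):
            raise ValidationError("random_fraction must lie in [0, 1]")


@dataclass
class ScoredPool:
    """Relevance scores for the unlabeled records."""

    scores: dict[str, float]
    score_kind: str                          # {"probability", "decision"}

    def __post_init__(self) -> None:
        if self.score_kind == "probability":
            for rid, s in self.scores.items():
                if not (0.0 <= s <= 1.0):
                    raise ValidationError(
                        f"probability score for {rid!r} outside [0,1]: {s}"
                    )


def compute_sample_weights(labels: Sequence[int],
                           balancer: BalancerSpec) -> np.ndarray:
    """Inverse-class-frequency weights.

    Weight for class c is ``multiplier_c * N / (2 * N_c)`` where the
    multiplier applies to the relevant class only; with multiplier 1 the
    mean weight is exactly 1.
    """
    y = np.asarray(labels)
    n = len(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InsufficientTrainingError(
            "balanced weighting needs at least one example of each class"
        )
    if balancer.kind == "none":
        return np.ones(n)
    w_pos = balancer.relevant_weight_multiplier * n / (2.0 * n_pos)
    w_neg = n / (2.0 * n_neg)
    return np.where(y == 1, w_pos, w_neg).astype(float)


def _build_estimator(spec: ClassifierSpec):
    hp = spec.hp
    seed = spec.random_seed
    if spec.algorithm == "multinomial-bayes":
        from sklearn.naive_bayes import MultinomialNB
        return MultinomialNB(alpha=hp.get("alpha", 1.0))
    if spec.algorithm == "logistic":
        from sklearn.linear_model import LogisticRegression
        return LogisticRegression(C=hp.get("C", 1.0), max_iter=2000,
                                  random_state=seed)
    if spec.algorithm == "linear-svm":
        from sklearn.svm import LinearSVC
        return LinearSVC(C=hp.get("C", 1.0), loss="squared_hinge",
                         random_state=seed)
    if spec.algorithm == "random-forest":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 100)), random_state=seed)
    raise ValidationError(spec.algorithm)  # pragma: no cover


def score_kind_for(spec: ClassifierSpec) -> str:
    return "decision" if spec.algorithm == "linear-svm" else "probability"


def train_and_score(
    features,
    labels: Sequence[Optional[int]],
    weights: Optional[np.ndarray],
    classifier: ClassifierSpec,
    record_ids: Optional[Sequence[str]] = None,
) -> ScoredPool:
    """Train on labeled rows; score the unlabeled rows.

    ``labels`` is aligned to the feature rows with ``None`` marking the
    pool.  ``weights`` is aligned to the *labeled* rows in order of
    appearance; pass None for uniform weights.
    """
    X = getattr(features, "matrix", features)
    n = X.shape[0]
    if len(labels) != n:
        raise ValidationError(f"{len(labels)} labels for {n} feature rows")
    if record_ids is None:
        record_ids = [str(i) for i in range(n)]
    labeled_idx = [i for i, lb in enumerate(labels) if lb is not None]
    pool_idx = [i for i, lb in enumerate(labels) if lb is None]
    y = np.array([labels[i] for i in labeled_idx])
    if len(labeled_idx) < 2 or len(set(y.tolist())) < 2:
        raise InsufficientTrainingError(
            "training needs at least one relevant and one irrelevant label"
        )
    est = _build_estimator(classifier)
    est.fit(X[labeled_idx], y, sample_weight=weights)
    kind = score_kind_for(classifier)
    if not pool_idx:
        return ScoredPool(scores={}, score_kind=kind)
    X_pool = X[pool_idx]
    if kind == "probability":
        pos_col = int(np.where(est.classes_ == 1)[0][0])
        raw = est.predict_proba(X_pool)[:, pos_col]
        raw = np.clip(raw, 0.0, 1.0)
    else:
        raw = est.decision_function(X_pool)
        if est.classes_[1] != 1:  # ensure higher = more relevant
            raw = -raw
    scores = {record_ids[i]: float(s) for i, s in zip(pool_idx, raw)}
    return ScoredPool(scores=scores, score_kind=kind)


def rank_pool(
    scored_pool: Optional[ScoredPool],
    querier: QuerierSpec,
    corpus_order: Sequence[str],
    rng: Optional[np.random.Generator] = None,
    pool_ids: Optional[Sequence[str]] = None,
) -> list[str]:
    """Order the pool for screening.  Output is a permutation of the pool.

    ``corpus_order`` is the full corpus id sequence; it supplies both the
    top-down order and the global ascending-position tie-break.
    """
    pos = {rid: i for i, rid in enumerate(corpus_order)}
    if pool_ids is None:
        if scored_pool is None:
            raise ConsistencyError("pool_ids required when no scores given")
        pool_ids = list(scored_pool.scores)
    pool = sorted(pool_ids, key=pos.__getitem__)   # canonical base order

    strategy = querier.strategy
    if strategy == "top_down":
        return pool
    if strategy == "random":
        if rng is None:
            rng = np.random.default_rng(querier.random_seed)
        perm = rng.permutation(len(pool))
        return [pool[i] for i in perm]

    if scored_pool is None:
        raise ConsistencyError(f"strategy {strategy!r} needs scores")
    missing = [rid for rid in pool if rid not in scored_pool.scores]
    if missing:
        raise ConsistencyError(
            f"no score for pool records {missing[:5]!r}"
        )
    scores = scored_pool.scores

    if strategy in ("max", "hybrid"):
        ranking = sorted(pool, key=lambda r: (-scores[r], pos[r]))
        if strategy == "hybrid" and querier.random_fraction > 0 and pool:
            if rng is None:
                rng = np.random.default_rng(querier.random_seed)
            n_promote = math.ceil(querier.random_fraction * len(pool))
            chosen_idx = rng.choice(len(pool), size=n_promote, replace=False)
            chosen = [pool[i] for i in sorted(chosen_idx.tolist())]
            ranking = [r for r in ranking if r not in set(chosen)]
            for rid in chosen:
                insert_at = int(rng.integers(0, len(ranking) + 1))
                ranking.insert(insert_at, rid)
        return ranking

    if strategy == "uncertainty":
        boundary = 0.5 if scored_pool.score_kind == "probability" else 0.0
        return sorted(pool, key=lambda r: (abs(scores[r] - boundary), pos[r]))

    raise ValidationError(strategy)  # pragma: no cover
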