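"""Agent chain and the active-learning cycle.

An *agent* is one learner configuration (vectorizer + classifier +
balancer + querier) together with a hand-off policy that decides when to
pass control to the next agent in the chain.  Only the querier is
mandatory; model-free agents (random, top-down) have no classifier.

State bookkeeping follows the set algebra of a screening project: the
corpus ``K`` is partitioned at all times into labeled-relevant,
labeled-irrelevant and the unlabeled pool; per-agent batch counters and
the trailing consecutive-irrelevant run drive hand-off decisions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus_io import Corpus
from .errors import (CrowdScreenError, DuplicateLabelError, ValidationError)
from .features import FeatureCache, VectorizerSpec, feature_cache_get_or_build
from .learning import (BalancerSpec, ClassifierSpec, QuerierSpec,
                       compute_sample_weights, rank_pool, train_and_score)

HANDOFF_KINDS = ("labeled_count", "labeled_fraction", "consecutive_irrelevant",
                 "never")


@dataclass(frozen=True)
class HandoffPolicy:
    """When the active agent yields control.

    ``labeled_count``: after *threshold* labels under this agent;
    ``labeled_fraction``: after labeling *threshold* × |K| records under
    this agent; ``consecutive_irrelevant``: once the trailing run of
    irrelevant labels reaches *threshold*; ``never``: only the global
    stop ends this agent.
    """

    kind: str = "never"
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in HANDOFF_KINDS:
            raise ValidationError(f"unknown hand-off kind {self.kind!r}")
        if self.kind != "never" and self.threshold <= 0:
            raise ValidationError("hand-off threshold must be > 0")


@dataclass(frozen=True)
class RetrainPolicy:
    """Whether/how often an agent retrains after new labels arrive."""

    retrain: bool = True
    batch_size: int = 1

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


@dataclass(frozen=True)
class AgentSpec:
    name: str
    querier: QuerierSpec
    vectorizer: Optional[VectorizerSpec] = None
    classifier: Optional[ClassifierSpec] = None
    balancer: BalancerSpec = BalancerSpec()
    handoff: HandoffPolicy = HandoffPolicy()
    retrain: RetrainPolicy = RetrainPolicy()

    def __post_init__(self) -> None:
        if self.querier is None:
            raise ValidationError("an agent must have a querier")
        if (self.classifier is None) != (self.vectorizer is None):
            raise ValidationError(
                "classifier and vectorizer must be given together"
            )

    @property
    def has_model(self) -> bool:
        return self.classifier is not None


@dataclass(frozen=True)
class AgentChain:
    agents: tuple[AgentSpec, ...]
    global_stop: str = "chain_exhausted"     # descriptive metadata

    def __post_init__(self) -> None:
        if len(self.agents) < 1:
            raise ValidationError("a chain needs at least one agent")
        if not isinstance(self.agents, tuple):
            object.__setattr__(self, "agents", tuple(self.agents))

    def __len__(self) -> int:
        return len(self.agents)

    def agent_at(self, i: int) -> AgentSpec:
        return self.agents[i]

    def has_successor(self, i: int) -> bool:
        return i + 1 < len(self.agents)


class StopDecision(enum.Enum):
    CONTINUE = "continue"
    HANDOFF = "handoff"
    GLOBAL_STOP = "global_stop"


@dataclass
class ScreenState:
    """Live set algebra of one screening project."""

    corpus: Corpus
    relevant: set[str] = field(default_factory=set)      # labeled relevant
    irrelevant: set[str] = field(default_factory=set)    # labeled irrelevant
    pool: set[str] = field(default_factory=set)          # unlabeled
    k: int = 0                  # labels under the current agent
    k_pos: int = 0
    k_neg: int = 0
    delta_k: int = 0            # trailing run of irrelevant labels
    ranking: list[str] = field(default_factory=list)
    allocations: dict[str, str] = field(default_factory=dict)  # record -> user
    active_agent: int = 0
    finished: bool = False
    user_stop: bool = False
    label_order: list[tuple[str, int]] = field(default_factory=list)

    @classmethod
    def from_corpus(cls, corpus: Corpus) -> "ScreenState":
        return cls(corpus=corpus, pool=set(corpus.ids))

    # -- invariant helpers -------------------------------------------------

    def check_invariants(self) -> None:
        all_ids = set(self.corpus.ids)
        parts = (self.relevant, self.irrelevant, self.pool)
        if self.relevant & self.irrelevant or self.relevant & self.pool \
                or self.irrelevant & self.pool:
            raise CrowdScreenError("label partitions overlap")
        if self.relevant | self.irrelevant | self.pool != all_ids:
            raise CrowdScreenError("partitions do not cover the corpus")
        if not set(self.allocations) <= self.pool:
            raise CrowdScreenError("allocation of a labeled record")
        run = 0
        for _, lb in reversed(self.label_order):
            if lb == 0:
                run += 1
            else:
                break
        # delta_k is reset on hand-off, so it can only be the tail of the run
        if self.delta_k > run:
            raise CrowdScreenError("delta_k exceeds the trailing run")

    @property
    def labeled_count(self) -> int:
        return len(self.relevant) + len(self.irrelevant)

    def label_of(self, record_id: str) -> Optional[int]:
        if record_id in self.relevant:
            return 1
        if record_id in self.irrelevant:
            return 0
        return None

    def apply_label(self, record_id: str, label: int) -> None:
        """Move one record out of the pool; update all counters."""
        if record_id not in self.pool:
            if record_id in self.relevant or record_id in self.irrelevant:
                raise DuplicateLabelError(f"record {record_id!r} already labeled")
            raise ValidationError(f"unknown record {record_id!r}")
        if label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {label!r}")
        self.pool.discard(record_id)
        self.allocations.pop(record_id, None)
        if label == 1:
            self.relevant.add(record_id)
            self.k_pos += 1
            self.delta_k = 0
        else:
            self.irrelevant.add(record_id)
            self.k_neg += 1
            self.delta_k += 1
        self.k += 1
        self.label_order.append((record_id, label))

    def labels_aligned(self) -> list[Optional[int]]:
        """Labels in corpus order (None = pool)."""
        return [self.label_of(rid) for rid in self.corpus.ids]


# ---------------------------------------------------------------------------
# Stopping / hand-off evaluation
# ---------------------------------------------------------------------------

def min_training_ready(state: ScreenState) -> bool:
    """True once at least one relevant and one irrelevant label exist."""
    return len(state.relevant) >= 1 and len(state.irrelevant) >= 1


def _handoff_met(state: ScreenState, policy: HandoffPolicy) -> bool:
    if policy.kind == "labeled_count":
        return state.k >= policy.threshold
    if policy.kind == "labeled_fraction":
        return state.k >= policy.threshold * len(state.corpus)
    if policy.kind == "consecutive_irrelevant":
        return state.delta_k >= policy.threshold
    return False


def evaluate_stopping(state: ScreenState, chain: AgentChain) -> StopDecision:
    """Decide continue / hand-off / global stop for the active agent.

    The global stop fires when the pool is empty, when the user requested
    a stop, or when a hand-off condition is met with no successor agent.
    """
    if state.user_stop:
        return StopDecision.GLOBAL_STOP
    if not state.pool:
        return StopDecision.GLOBAL_STOP
    agent = chain.agent_at(state.active_agent)
    if _handoff_met(state, agent.handoff):
        if chain.has_successor(state.active_agent):
            return StopDecision.HANDOFF
        return StopDecision.GLOBAL_STOP
    return StopDecision.CONTINUE


def advance_chain(state: ScreenState, chain: AgentChain) -> ScreenState:
    """Activate the next agent; labels carry over, segment counters reset.

    The trailing-irrelevant counter resets too: each agent's stopping run
    is judged on its own labels.  Live allocations persist into the new
    agent's queue.
    """
    if not chain.has_successor(state.active_agent):
        raise CrowdScreenError("advance_chain called with no successor agent")
    state.active_agent += 1
    state.k = 0
    state.k_pos = 0
    state.k_neg = 0
    state.delta_k = 0
    return state


# ---------------------------------------------------------------------------
# Ranking / cycle
# ---------------------------------------------------------------------------

@dataclass
class RankingOutcome:
    ranking: list[str]
    trained: bool
    training_set_size: int
    model_name: str


def compute_ranking(
    state: ScreenState,
    agent: AgentSpec,
    cache: Optional[FeatureCache],
    rng: np.random.Generator,
) -> RankingOutcome:
    """Produce the screening order the active agent would serve now.

    Model agents without a minimum training set (one label per class)
    fall back to a random ranking, as do explicit random/top-down
    queriers — neither triggers any training.
    """
    order = state.corpus.ids
    pool_ids = [rid for rid in order if rid in state.pool]
    tss = state.labeled_count
    if not agent.has_model:
        ranking = rank_pool(None, agent.querier, order, rng, pool_ids=pool_ids)
        return RankingOutcome(ranking, False, tss, agent.name)
    if not min_training_ready(state):
        fallback = QuerierSpec(strategy="random")
        ranking = rank_pool(None, fallback, order, rng, pool_ids=pool_ids)
        return RankingOutcome(ranking, False, tss, agent.name)
    fm = feature_cache_get_or_build(cache, state.corpus, agent.vectorizer)
    labels = state.labels_aligned()
    labeled_y = [lb for lb in labels if lb is not None]
    weights = compute_sample_weights(labeled_y, agent.balancer)
    scored = train_and_score(fm, labels, weights, agent.classifier,
                             record_ids=order)
    ranking = rank_pool(scored, agent.querier, order, rng, pool_ids=pool_ids)
    return RankingOutcome(ranking, True, tss, agent.name)


def run_cycle_iteration(
    state: ScreenState,
    chain: AgentChain,
    labels_in: Sequence[tuple[str, int]],
    cache: Optional[FeatureCache] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ScreenState, StopDecision, Optional[RankingOutcome]]:
    """One synchronous active-learning cycle.

    Applies a batch of labels, evaluates stopping (advancing the chain on
    hand-off), and — when continuing — refreshes the ranking with the
    active agent's learner.  Returns the updated state, the final
    decision, and the new ranking (None when the run globally stopped).
    """
    if rng is None:
        rng = np.random.default_rng()
    for record_id, label in labels_in:
        state.apply_label(record_id, label)
    decision = evaluate_stopping(state, chain)
    while decision is StopDecision.HANDOFF:
        advance_chain(state, chain)
        decision = evaluate_stopping(state, chain)
    if decision is StopDecision.GLOBAL_STOP:
        state.finished = True
        return state, StopDecision.GLOBAL_STOP, None
    outcome = compute_ranking(state, chain.agent_at(state.active_agent),
                              cache, rng)
    state.ranking = outcome.ranking
    return state, decision, outcome


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

def default_learner(seed: Optional[int] = None) -> AgentSpec:
    """Single fast agent: TF-IDF (uni+bigram) + linear SVM + max querier."""
    return AgentSpec(
        name="ultra",
        vectorizer=VectorizerSpec(kind="tfidf", ngram_range=(1, 2)),
        classifier=ClassifierSpec(algorithm="linear-svm", random_seed=seed),
        balancer=BalancerSpec(kind="balanced"),
        querier=QuerierSpec(strategy="max"),
        handoff=HandoffPolicy(kind="never"),
    )


def bayes_learner(seed: Optional[int] = None) -> AgentSpec:
    """TF-IDF (uni+bigram) + multinomial naive Bayes + max querier."""
    return AgentSpec(
        name="tfidf-bayes",
        vectorizer=VectorizerSpec(kind="tfidf", ngram_range=(1, 2)),
        classifier=ClassifierSpec(algorithm="multinomial-bayes",
                                  random_seed=seed),
        balancer=BalancerSpec(kind="balanced"),
        querier=QuerierSpec(strategy="max"),
        handoff=HandoffPolicy(kind="never"),
    )


def worked_example_chain(consecutive_irrelevant: int = 100,
                         seed: Optional[int] = None) -> AgentChain:
    """Four sequential agents: random calibration, random top-up, a fast
    model, and a final model, each later agent stopping on a trailing run
    of irrelevant labels."""
    return AgentChain(agents=(
        AgentSpec(
            name="calibration-random",
            querier=QuerierSpec(strategy="random"),
            handoff=HandoffPolicy(kind="labeled_count", threshold=100),
        ),
        AgentSpec(
            name="topup-random",
            querier=QuerierSpec(strategy="random"),
            handoff=HandoffPolicy(kind="labeled_fraction", threshold=0.05),
        ),
        AgentSpec(
            name="fast-model",
            vectorizer=VectorizerSpec(kind="tfidf", ngram_range=(1, 2)),
            classifier=ClassifierSpec(algorithm="multinomial-bayes",
                                      random_seed=seed),
            balancer=BalancerSpec(kind="balanced"),
            querier=QuerierSpec(strategy="max"),
            handoff=HandoffPolicy(kind="consecutive_irrelevant",
                                  threshold=consecutive_irrelevant),
        ),
        AgentSpec(
            name="final-model",
            vectorizer=VectorizerSpec(kind="tfidf", ngram_range=(1, 2)),
            classifier=ClassifierSpec(algorithm="linear-svm", random_seed=seed),
            balancer=BalancerSpec(kind="balanced"),
            querier=QuerierSpec(strategy="max"),
            handoff=HandoffPolicy(kind="consecutive_irrelevant",
                                  threshold=consecutive_irrelevant),
        ),
    ))


def single_agent_chain(agent: AgentSpec) -> AgentChain:
    return AgentChain(agents=(agent,))


# -- (de)serialization for the project file ---------------------------------

def chain_to_config(chain: AgentChain) -> dict:
    def spec(obj):
        if obj is None:
            return None
        d = {}
        for f in obj.__dataclass_fields__:
            v = getattr(obj, f)
            if isinstance(v, tuple) and f != "hyperparameters":
                v = list(v)
            elif f == "hyperparameters":
                v = dict(v)
            d[f] = v
        return d

    return {
        "global_stop": chain.global_stop,
        "agents": [
            {
                "name": a.name,
                "querier": spec(a.querier),
                "vectorizer": spec(a.vectorizer),
                "classifier": spec(a.classifier),
                "balancer": spec(a.balancer),
                "handoff": spec(a.handoff),
                "retrain": spec(a.retrain),
            }
            for a in chain.agents
        ],
    }


def chain_from_config(config: dict) -> AgentChain:
    def mk(cls, d, **tweaks):
        if d is None:
            return None
        d = dict(d)
        d.update(tweaks)
        for key in ("ngram_range",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "hyperparameters" in d and isinstance(d["hyperparameters"], dict):
            d["hyperparameters"] = tuple(sorted(d["hyperparameters"].items()))
        return cls(**d)

    agents = []
    for a in config["agents"]:
        agents.append(AgentSpec(
            name=a["name"],
            querier=mk(QuerierSpec, a["querier"]),
            vectorizer=mk(VectorizerSpec, a["vectorizer"]),
            classifier=mk(ClassifierSpec, a["classifier"]),
            balancer=mk(BalancerSpec, a["balancer"]),
            handoff=mk(HandoffPolicy, a["handoff"]),
            retrain=mk(RetrainPolicy, a["retrain"]),
        ))
    return AgentChain(agents=tuple(agents),
                      global_stop=config.get("global_stop", "chain_exhausted"))
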