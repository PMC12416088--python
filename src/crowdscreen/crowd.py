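"""Multi-annotator queue service with worker-limited asynchronous retraining.

The contract is discrete-event: time is an integer tick supplied by the
caller (or by a scripted schedule), every transition is deterministic
under a seed, and the full event stream is recorded so invariants —
allocation uniqueness, bounded retrain concurrency — can be checked over
any replay.

A retrain uses exactly the labels present when it starts; labels arriving
while a model trains are folded into the *next* round.  Annotators are
never blocked by training: a request at time t is answered from the
ranking in force at t.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import agents as ag
from .corpus_io import Corpus, EventRow
from .errors import (DuplicateLabelError, OwnershipError, ValidationError)
from .features import FeatureCache, feature_cache_get_or_build
from .learning import (compute_sample_weights, rank_pool, train_and_score)

_EPOCH_ISO = "2025-01-23T09:00:"  # cosmetic base for tick timestamps


def tick_to_iso(tick: int) -> str:
    """Deterministic ISO-8601 timestamp (ms precision) for integer ticks."""
    minutes, rem = divmod(int(tick), 60)
    base_min = minutes % 60
    hours = 9 + minutes // 60
    return f"2025-01-23T{hours:02d}:{base_min:02d}:{rem:02d}.000"


@dataclass(frozen=True)
class Annotator:
    user_id: str
    active: bool = True


@dataclass(frozen=True)
class TaskServerConfig:
    """Worker pool limits for asynchronous retraining.

    ``retrain_duration`` is the number of ticks a retrain occupies a
    worker; 0 makes retraining synchronous (completes within the tick of
    the triggering label).
    """

    n_workers: int = 2
    retrain_duration: int = 0

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValidationError("n_workers must be >= 1")
        if self.retrain_duration < 0:
            raise ValidationError("retrain_duration must be >= 0")


@dataclass
class CrowdEvent:
    time: int
    kind: str          # request | label | retrain_start | retrain_done
                       # | handoff | stop | release
    payload: dict = field(default_factory=dict)


@dataclass
class _Allocation:
    record_id: str
    user_id: str
    queue_iteration: int
    queue_rank: int


@dataclass
class _InFlightRetrain:
    due: int
    seq: int
    agent_index: int
    labels_snapshot: list
    training_set_size: int


class CrowdSession:
    """One live screening project served to a crowd of annotators."""

    def __init__(
        self,
        corpus: Corpus,
        chain: ag.AgentChain,
        config: TaskServerConfig = TaskServerConfig(),
        seed: Optional[int] = None,
        annotators: Optional[Sequence[Union[str, Annotator]]] = None,
        log_allocations: bool = True,
    ) -> None:
        self.corpus = corpus
        self.chain = chain
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.cache = FeatureCache()
        self.state = ag.ScreenState.from_corpus(corpus)
        self.events: list[CrowdEvent] = []
        self.event_log: list[EventRow] = []
        self.log_allocations = log_allocations
        self._allocs: dict[str, _Allocation] = {}      # record_id -> alloc
        self._user_alloc: dict[str, str] = {}          # user_id -> record_id
        self._row_no = 0
        self._seq = 0
        self._busy_workers = 0
        self._in_flight: list[tuple[int, int, _InFlightRetrain]] = []  # heap
        self._labels_since_start = 0
        self._pending_handoff_retrain = False
        self.iteration = 1
        self._served_in_iteration = 0
        self.known_users: Optional[set[str]] = None
        if annotators is not None:
            self.known_users = {
                a.user_id if isinstance(a, Annotator) else str(a)
                for a in annotators
            }
        # initial ranking (random until the minimum training set exists)
        outcome = ag.compute_ranking(self.state, self._agent(), self.cache,
                                     self.rng)
        self.state.ranking = outcome.ranking
        self._model_name = outcome.model_name
        self._model_tss = outcome.training_set_size

    # -- helpers -----------------------------------------------------------

    def _agent(self) -> ag.AgentSpec:
        return self.chain.agent_at(self.state.active_agent)

    def _check_user(self, user_id: str) -> None:
        if self.known_users is not None and user_id not in self.known_users:
            raise ValidationError(f"unknown annotator {user_id!r}")

    def _next_row_no(self) -> int:
        self._row_no += 1
        return self._row_no

    def _emit(self, time: int, kind: str, **payload) -> None:
        self.events.append(CrowdEvent(time=time, kind=kind, payload=payload))

    # -- annotator-facing operations --------------------------------------

    def request_record(self, user_id: str, time: int = 0) -> Optional[str]:
        """Hand the highest-ranked unallocated pool record to a user.

        Re-requesting without labeling returns the same record.  Returns
        None when every pool record is already allocated elsewhere.
        """
        self._check_user(user_id)
        held = self._user_alloc.get(user_id)
        if held is not None:
            return held
        for rid in self.state.ranking:
            if rid in self.state.pool and rid not in self._allocs:
                self._served_in_iteration += 1
                alloc = _Allocation(rid, user_id, self.iteration,
                                    self._served_in_iteration)
                self._allocs[rid] = alloc
                self._user_alloc[user_id] = rid
                self.state.allocations[rid] = user_id
                self._emit(time, "request", user_id=user_id, record_id=rid)
                if self.log_allocations:
                    self.event_log.append(EventRow(
                        row_no=self._next_row_no(),
                        record_id=rid,
                        label=None,
                        labeling_time=None,
                        training_set_size=self._model_tss,
                        queue_iteration=alloc.queue_iteration,
                        queue_rank=alloc.queue_rank,
                        model_name=self._model_name,
                        user_id=user_id,
                    ))
                return rid
        self._emit(time, "request", user_id=user_id, record_id=None)
        return None

    def release_record(self, user_id: str, time: int = 0) -> None:
        """Return an allocation to the pool without labeling it."""
        self._check_user(user_id)
        rid = self._user_alloc.pop(user_id, None)
        if rid is not None:
            self._allocs.pop(rid, None)
            self.state.allocations.pop(rid, None)
            self._emit(time, "release", user_id=user_id, record_id=rid)

    def submit_label(self, user_id: str, record_id: str, label: int,
                     time: int = 0, note: str = "",
                     tags: Optional[list] = None) -> None:
        """Apply one label; trigger retraining when a worker is free."""
        self._check_user(user_id)
        alloc = self._allocs.get(record_id)
        if alloc is not None and alloc.user_id != user_id:
            raise OwnershipError(
                f"record {record_id!r} is allocated to {alloc.user_id!r}"
            )
        if self.state.label_of(record_id) is not None:
            raise DuplicateLabelError(f"record {record_id!r} already labeled")
        if alloc is None:
            # single-user / scripted mode: label an unallocated pool record
            self._served_in_iteration += 1
            alloc = _Allocation(record_id, user_id, self.iteration,
                                self._served_in_iteration)
        self.state.apply_label(record_id, label)
        self._allocs.pop(record_id, None)
        self._user_alloc.pop(user_id, None)
        self._labels_since_start += 1
        self._emit(time, "label", user_id=user_id, record_id=record_id,
                   label=label)
        self.event_log.append(EventRow(
            row_no=self._next_row_no(),
            record_id=record_id,
            label=label,
            labeling_time=tick_to_iso(time),
            training_set_size=self._model_tss,
            queue_iteration=alloc.queue_iteration,
            queue_rank=alloc.queue_rank,
            model_name=self._model_name,
            user_id=user_id,
            note=note,
            tags=list(tags or []),
        ))
        decision = ag.evaluate_stopping(self.state, self.chain)
        if decision is ag.StopDecision.GLOBAL_STOP:
            self.state.finished = True
            self._emit(time, "stop")
            return
        if decision is ag.StopDecision.HANDOFF:
            ag.advance_chain(self.state, self.chain)
            self._emit(time, "handoff",
                       to_agent=self._agent().name)
            self._start_retrain(time, force=True)
            return
        agent = self._agent()
        if (agent.has_model and agent.retrain.retrain
                and ag.min_training_ready(self.state)):
            self._start_retrain(time)

    # -- task-server side --------------------------------------------------

    def _start_retrain(self, time: int, force: bool = False) -> None:
        if self._busy_workers >= self.config.n_workers:
            if force:
                self._pending_handoff_retrain = True
            return
        self._busy_workers += 1
        self._labels_since_start = 0
        self._seq += 1
        job = _InFlightRetrain(
            due=time + self.config.retrain_duration,
            seq=self._seq,
            agent_index=self.state.active_agent,
            labels_snapshot=self.state.labels_aligned(),
            training_set_size=self.state.labeled_count,
        )
        self._emit(time, "retrain_start", agent=self._agent().name,
                   training_set_size=job.training_set_size)
        heapq.heappush(self._in_flight, (job.due, job.seq, job))
        if self.config.retrain_duration == 0:
            self.complete_retrain(time)

    def _ranking_from_snapshot(self, job: _InFlightRetrain) -> list[str]:
        agent = self.chain.agent_at(job.agent_index)
        order = self.corpus.ids
        pool_ids = [rid for rid in order if rid in self.state.pool]
        if not agent.has_model:
            return rank_pool(None, agent.querier, order, self.rng,
                             pool_ids=pool_ids)
        snapshot = job.labels_snapshot
        labeled_y = [lb for lb in snapshot if lb is not None]
        if len(set(labeled_y)) < 2:
            fallback = ag.QuerierSpec(strategy="random")
            return rank_pool(None, fallback, order, self.rng,
                             pool_ids=pool_ids)
        fm = feature_cache_get_or_build(self.cache, self.corpus,
                                        agent.vectorizer)
        weights = compute_sample_weights(labeled_y, agent.balancer)
        scored = train_and_score(fm, snapshot, weights, agent.classifier,
                                 record_ids=order)
        return rank_pool(scored, agent.querier, order, self.rng,
                         pool_ids=pool_ids)

    def complete_retrain(self, time: int,
                         new_ranking: Optional[list[str]] = None) -> None:
        """Finish the earliest in-flight retrain; swap the ranking atomically.

        Live allocations are untouched — their holders keep their records.
        """
        if not self._in_flight:
            raise ValidationError("no retrain in flight")
        _, _, job = heapq.heappop(self._in_flight)
        if new_ranking is None:
            new_ranking = self._ranking_from_snapshot(job)
        self.state.ranking = new_ranking
        self.iteration += 1
        self._served_in_iteration = 0
        agent = self.chain.agent_at(job.agent_index)
        self._model_name = agent.name
        self._model_tss = job.training_set_size
        self._busy_workers -= 1
        self._emit(time, "retrain_done", agent=agent.name,
                   training_set_size=job.training_set_size)
        if self.state.finished:
            return
        if self._pending_handoff_retrain:
            self._pending_handoff_retrain = False
            self._start_retrain(time, force=True)
        elif self._labels_since_start > 0:
            agent_now = self._agent()
            if (agent_now.has_model and agent_now.retrain.retrain
                    and ag.min_training_ready(self.state)):
                self._start_retrain(time)

    def drain_due(self, now: int) -> None:
        """Complete every in-flight retrain whose due time has arrived."""
        while self._in_flight and self._in_flight[0][0] <= now:
            due = self._in_flight[0][0]
            self.complete_retrain(due)

    def request_user_stop(self, time: int = 0) -> None:
        self.state.user_stop = True
        self.state.finished = True
        self._emit(time, "stop", reason="user_stop")


# ---------------------------------------------------------------------------
# Scripted schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScriptAction:
    """One deterministic annotator action: request / label / release / stop.

    ``label`` left as None means the annotator acts as an oracle and the
    record's known corpus label is used.
    """

    time: int
    user_id: str
    action: str
    record_id: Optional[str] = None
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.action not in ("request", "label", "release", "stop"):
            raise ValidationError(f"unknown script action {self.action!r}")


def run_crowd_schedule(
    corpus: Corpus,
    chain: ag.AgentChain,
    annotator_script: Iterable[Union[ScriptAction, tuple]],
    config: TaskServerConfig = TaskServerConfig(),
    seed: Optional[int] = None,
    annotators: Optional[Sequence[str]] = None,
) -> tuple[list[EventRow], CrowdSession]:
    """Replay a deterministic annotator script through a crowd session.

    Returns the emitted event log and the finished session (whose
    ``events`` stream holds every request/label/retrain transition for
    invariant checking).
    """
    script = [a if isinstance(a, ScriptAction) else ScriptAction(*a)
              for a in annotator_script]
    script.sort(key=lambda a: a.time)
    session = CrowdSession(corpus, chain, config=config, seed=seed,
                           annotators=annotators)
    for action in script:
        session.drain_due(action.time)
        if session.state.finished and action.action != "stop":
            continue
        if action.action == "request":
            session.request_record(action.user_id, time=action.time)
        elif action.action == "label":
            rid = action.record_id
            if rid is None:
                rid = session._user_alloc.get(action.user_id)
                if rid is None:
                    continue  # nothing held; oracle has nothing to label
            label = action.label
            if label is None:
                label = corpus.by_id(rid).known_label
                if label is None:
                    raise ValidationError(
                        f"record {rid!r} has no known label to replay"
                    )
            session.submit_label(action.user_id, rid, label, time=action.time)
        elif action.action == "release":
            session.release_record(action.user_id, time=action.time)
        elif action.action == "stop":
            session.request_user_stop(time=action.time)
    if session._in_flight:
        last = max(due for due, _, _ in session._in_flight)
        session.drain_due(last)
    return session.event_log, session
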