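"""Synthetic labeled corpora and crowd fixtures.

``generate_corpus`` builds bag-of-token documents from two multinomial
vocabularies: relevant documents mix signal and background tokens in a
tunable proportion (``separability``); irrelevant documents draw from the
background only.  The optimal classifier on this family is well
specified, which makes it a controlled stand-in for real screening
corpora (low relevant prevalence, class-separable vocabulary).

``generate_crowd_fixture`` constructs a complete multi-annotator replay:
a labeled corpus, a deterministic annotator script and a three-agent
chain (random calibration → fast model → final model) tuned so the final
agent's consecutive-irrelevant stop fires with a chosen number of
records still allocated-but-unlabeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import agents as ag
from .corpus_io import Corpus, Record
from .crowd import CrowdSession, ScriptAction, TaskServerConfig
from .errors import GenerationError, ValidationError
from .features import VectorizerSpec
from .learning import (BalancerSpec, ClassifierSpec, QuerierSpec, rank_pool)


@dataclass(frozen=True)
class CorpusSpec:
    n_records: int = 100
    prevalence: float = 0.1
    vocab_size_signal: int = 40
    vocab_size_background: int = 200
    separability: float = 0.9
    doc_length: int = 30
    label_noise: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("prevalence", "separability", "label_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.vocab_size_signal < 1 or self.vocab_size_background < 1:
            raise ValidationError("vocabulary sizes must be >= 1")
        if self.n_records < 1:
            raise ValidationError("n_records must be >= 1")


@dataclass(frozen=True)
class FixtureSpec:
    n_records: int = 100
    n_annotators: int = 4
    n_relevant: int = 9
    outstanding_allocations: int = 3
    mid_agent_labels: int = 15       # labels under the middle agent
    separability: float = 0.92
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0 <= self.outstanding_allocations < self.n_records):
            raise ValidationError(
                "outstanding_allocations must be < n_records"
            )
        if self.n_annotators < 1:
            raise ValidationError("need at least one annotator")
        if self.outstanding_allocations > self.n_annotators:
            raise ValidationError(
                "each outstanding allocation is held by a distinct "
                "annotator, so outstanding_allocations <= n_annotators"
            )


def _token_stream(rng: np.random.Generator, vocab: list[str],
                  n: int) -> list[str]:
    idx = rng.integers(0, len(vocab), size=n)
    return [vocab[i] for i in idx]


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Fully labeled synthetic corpus, deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    n_rel = int(round(spec.prevalence * n))
    rel_idx = set(rng.choice(n, size=n_rel, replace=False).tolist())
    labels = [1 if i in rel_idx else 0 for i in range(n)]
    corpus = _corpus_from_labels(labels, spec, rng)
    if spec.label_noise > 0:
        flips = rng.random(n) < spec.label_noise
        for rec, flip in zip(corpus.records, flips):
            if flip:
                rec.known_label = 1 - rec.known_label
    return corpus


def _corpus_from_labels(labels: list[int], spec: CorpusSpec,
                        rng: np.random.Generator) -> Corpus:
    signal = [f"sig{i:04d}" for i in range(spec.vocab_size_signal)]
    background = [f"bg{i:04d}" for i in range(spec.vocab_size_background)]
    width = max(4, len(str(len(labels))))
    records = []
    for i, label in enumerate(labels):
        length = max(3, int(rng.poisson(spec.doc_length)))
        if label == 1:
            from_signal = rng.random(length) < spec.separability
            tokens = [
                signal[int(rng.integers(0, len(signal)))] if s
                else background[int(rng.integers(0, len(background)))]
                for s in from_signal
            ]
        else:
            tokens = _token_stream(rng, background, length)
        title = " ".join(tokens[:5])
        body = " ".join(tokens[5:])
        records.append(Record(record_id=f"r{i:0{width}d}", title=title,
                              body=body, known_label=label))
    return Corpus(records=records, source_format="synthetic")


# ---------------------------------------------------------------------------
# Crowd fixture
# ---------------------------------------------------------------------------

def _fixture_chain(spec: FixtureSpec, delta_k: int,
                   seed: int) -> ag.AgentChain:
    """Random calibration → fast model → final model, Table-3 style."""
    return ag.AgentChain(agents=(
        ag.AgentSpec(
            name="agent-1-random",
            querier=QuerierSpec(strategy="random"),
            handoff=ag.HandoffPolicy(kind="labeled_count", threshold=2),
        ),
        ag.AgentSpec(
            name="agent-2-fast",
            vectorizer=VectorizerSpec(kind="tfidf", ngram_range=(1, 2)),
            classifier=ClassifierSpec(algorithm="multinomial-bayes",
                                      random_seed=seed),
            balancer=BalancerSpec(kind="balanced"),
            querier=QuerierSpec(strategy="max"),
            handoff=ag.HandoffPolicy(kind="labeled_count",
                                     threshold=spec.mid_agent_labels),
        ),
        ag.AgentSpec(
            name="agent-3-final",
            vectorizer=VectorizerSpec(kind="tfidf", ngram_range=(1, 2)),
            classifier=ClassifierSpec(algorithm="multinomial-bayes",
                                      random_seed=seed),
            balancer=BalancerSpec(kind="balanced"),
            querier=QuerierSpec(strategy="max"),
            handoff=ag.HandoffPolicy(kind="consecutive_irrelevant",
                                     threshold=delta_k),
        ),
    ))


@dataclass
class CrowdFixture:
    corpus: Corpus
    script: list[ScriptAction]
    chain: ag.AgentChain
    config: TaskServerConfig
    seed: int
    expected_labeled: int
    annotators: list[str] = field(default_factory=list)


def _fixture_corpus(spec: FixtureSpec, seed: int) -> Corpus:
    """Labeled corpus whose first randomly-served record is relevant and
    second irrelevant, so the calibration agent always yields a usable
    minimum training set."""
    n = spec.n_records
    width = max(4, len(str(n)))
    ids = [f"r{i:0{width}d}" for i in range(n)]
    # reproduce the session's very first ranking: a seeded random shuffle
    probe_rng = np.random.default_rng(seed)
    first_ranking = rank_pool(None, QuerierSpec(strategy="random"), ids,
                              probe_rng, pool_ids=ids)
    label_rng = np.random.default_rng(seed + 1)
    forced_rel = first_ranking[0]
    forced_irr = first_ranking[1]
    candidates = [rid for rid in ids if rid not in (forced_rel, forced_irr)]
    extra = label_rng.choice(len(candidates), size=spec.n_relevant - 1,
                             replace=False)
    rel_ids = {forced_rel} | {candidates[i] for i in extra.tolist()}
    labels = [1 if rid in rel_ids else 0 for rid in ids]
    cspec = CorpusSpec(n_records=n, prevalence=spec.n_relevant / n,
                       separability=spec.separability, seed=seed + 2)
    return _corpus_from_labels(labels, cspec,
                               np.random.default_rng(seed + 2))


def _drive_fixture(corpus: Corpus, chain: ag.AgentChain, spec: FixtureSpec,
                   seed: int, probe: bool):
    """Drive a session annotator-by-annotator, deciding skip points on the
    fly; returns the recorded script and (in probe mode) the stop diagnostics.
    """
    users = [f"{i + 1:02d}" for i in range(spec.n_annotators)]
    config = TaskServerConfig(n_workers=2, retrain_duration=0)
    session = CrowdSession(corpus, chain, config=config, seed=seed,
                           annotators=users)
    script: list[ScriptAction] = []
    target_labeled = spec.n_records - spec.outstanding_allocations
    mid_skips = max(0, spec.outstanding_allocations - 1)
    want_final_skip = spec.outstanding_allocations > 0
    skips_done = 0
    final_skip_done = False
    request_no = 0
    t = 0
    u = 0
    rotation = list(users)   # annotators still working; skippers drop out
    deltas: list[tuple[int, int, int]] = []  # (labeled_count, agent, delta_k)

    while not session.state.finished:
        if not rotation:
            raise GenerationError("every annotator left the rotation")
        user = rotation[u % len(rotation)]
        u += 1
        rid = session.request_record(user, time=t)
        script.append(ScriptAction(time=t, user_id=user, action="request"))
        t += 1
        if rid is None:
            raise GenerationError("pool exhausted before the stop fired")
        request_no += 1
        truth = corpus.by_id(rid).known_label
        labeled = session.state.labeled_count
        skip = False
        if skips_done < mid_skips and request_no >= 14 and truth == 0:
            skip = True
            skips_done += 1
        elif (want_final_skip and not final_skip_done
                and skips_done == mid_skips
                and labeled == target_labeled - 1 and truth == 0):
            skip = True
            final_skip_done = True
        if skip:
            # the holder walks away: the record stays allocated forever
            rotation.remove(user)
            u = 0
            continue
        session.submit_label(user, rid, truth, time=t)
        script.append(ScriptAction(time=t, user_id=user, action="label"))
        t += 1
        deltas.append((session.state.labeled_count,
                       session.state.active_agent, session.state.delta_k))
        if probe and session.state.labeled_count >= target_labeled:
            break
        if session.state.labeled_count > spec.n_records:  # pragma: no cover
            raise GenerationError("runaway schedule")
    return session, script, deltas, skips_done, final_skip_done


def generate_crowd_fixture(spec: FixtureSpec = FixtureSpec()) -> CrowdFixture:
    """Build a deterministic multi-annotator replay of the worked example.

    The returned script, replayed through ``crowd.run_crowd_schedule``,
    reaches the final agent's consecutive-irrelevant stop with exactly
    ``spec.outstanding_allocations`` records allocated but never labeled,
    i.e. a labeled count of ``n_records - outstanding_allocations``.
    """
    last_err: Optional[str] = None
    for attempt in range(25):
        seed = spec.seed + 1000 * attempt
        try:
            return _try_fixture(spec, seed)
        except GenerationError as exc:
            last_err = str(exc)
    raise GenerationError(
        f"could not generate a fixture for {spec} after 25 attempts; "
        f"last failure: {last_err}"
    )


def _try_fixture(spec: FixtureSpec, seed: int) -> CrowdFixture:
    corpus = _fixture_corpus(spec, seed)
    target_labeled = spec.n_records - spec.outstanding_allocations

    # probe run: no stopping rule on the last agent, just observe delta_k
    probe_chain = _fixture_chain(spec, delta_k=10 ** 9, seed=seed)
    _, _, deltas, skips, final_skip = _drive_fixture(
        corpus, probe_chain, spec, seed, probe=True)
    if skips < max(0, spec.outstanding_allocations - 1):
        raise GenerationError("mid-run skip points never became available")
    if spec.outstanding_allocations > 0 and not final_skip:
        raise GenerationError(
            "no irrelevant record available for the final outstanding "
            "allocation"
        )
    final = [d for d in deltas if d[0] == target_labeled]
    if not final:
        raise GenerationError("probe run never reached the target count")
    threshold = final[-1][2]
    if threshold < 1:
        raise GenerationError("last label before the stop must be irrelevant")
    # the stop must fire for the FIRST time at the target count
    first_hit = next(c for c, a, dk in deltas
                     if a == len(probe_chain) - 1 and dk >= threshold)
    if first_hit != target_labeled:
        raise GenerationError(
            f"trailing-irrelevant run would stop early at {first_hit} labels"
        )

    chain = _fixture_chain(spec, delta_k=threshold, seed=seed)
    session, script, _, _, _ = _drive_fixture(corpus, chain, spec, seed,
                                              probe=False)
    if session.state.labeled_count != target_labeled:
        raise GenerationError(
            f"replay labeled {session.state.labeled_count}, "
            f"wanted {target_labeled}"
        )
    if len(session.state.allocations) != spec.outstanding_allocations:
        raise GenerationError(
            f"{len(session.state.allocations)} allocations outstanding, "
            f"wanted {spec.outstanding_allocations}"
        )
    users = [f"{i + 1:02d}" for i in range(spec.n_annotators)]
    return CrowdFixture(
        corpus=corpus,
        script=script,
        chain=chain,
        config=TaskServerConfig(n_workers=2, retrain_duration=0),
        seed=seed,
        expected_labeled=target_labeled,
        annotators=users,
    )
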