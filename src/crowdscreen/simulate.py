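"""Single-oracle full simulation over a completely labeled corpus.

The simulator re-enacts screening as if one annotator labeled the
top-ranked record at every step, answering each query with the record's
true label.  By default the run stops as soon as every relevant record
has been found (``stop_if="min"``); any unscreened remainder is then
ranked once more with the most recent model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import agents as ag
from .corpus_io import Corpus, EventRow, ProjectFile
from .errors import ValidationError
from .features import FeatureCache
from .crowd import tick_to_iso

_ORACLE_USER = "oracle"


@dataclass
class SimulationConfig:
    corpus: Corpus
    chain: ag.AgentChain
    priors: list[str] = field(default_factory=list)
    stop_if: Union[str, int] = "min"     # "min" | "full" | integer budget
    seed: Optional[int] = None
    batch_size: int = 1                  # labels between retrains

    def __post_init__(self) -> None:
        if isinstance(self.stop_if, str):
            if self.stop_if not in ("min", "full"):
                raise ValidationError(
                    f"stop_if must be 'min', 'full' or an integer, "
                    f"got {self.stop_if!r}"
                )
        elif int(self.stop_if) < 1:
            raise ValidationError("stop_if budget must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        unknown = [r.record_id for r in self.corpus if r.known_label is None]
        if unknown:
            raise ValidationError(
                f"simulation requires a fully labeled corpus; "
                f"{len(unknown)} records lack labels (e.g. {unknown[:3]})"
            )
        ids = set(self.corpus.ids)
        bad = [p for p in self.priors if p not in ids]
        if bad:
            raise ValidationError(f"prior ids not in corpus: {bad}")


@dataclass
class ResultRow:
    order: int                 # 1-based labeling position
    record_id: str
    label: int                 # true label assigned by the oracle
    training_set_size: int     # labels behind the ranking that served it
    iteration: int
    agent_name: str


@dataclass
class SimulationResult:
    rows: list[ResultRow]
    final_ranking: list[str]   # unscreened remainder, most-recent-model order
    n_records: int
    n_relevant: int            # true relevant count in the corpus
    config: SimulationConfig
    event_log: list[EventRow] = field(default_factory=list)

    @property
    def n_screened(self) -> int:
        return len(self.rows)

    @property
    def n_relevant_found(self) -> int:
        return sum(1 for r in self.rows if r.label == 1)

    @property
    def screening_labels(self) -> list[int]:
        return [r.label for r in self.rows]

    def to_project_file(self) -> ProjectFile:
        return ProjectFile(
            metadata={"kind": "simulation", "n_records": self.n_records},
            learner_config=ag.chain_to_config(self.config.chain),
            priors=list(self.config.priors),
            seed=self.config.seed,
            event_log=list(self.event_log),
        )


class Simulation:
    """Stateful wrapper mirroring label-then-review usage."""

    def __init__(self, config: SimulationConfig) -> None:
        self.config = config
        self._extra_priors: list[str] = []
        self.result: Optional[SimulationResult] = None

    def label(self, record_ids: Sequence[str]) -> "Simulation":
        ids = set(self.config.corpus.ids)
        bad = [r for r in record_ids if r not in ids]
        if bad:
            raise ValidationError(f"unknown record ids: {bad}")
        self._extra_priors.extend(record_ids)
        return self

    def review(self, progress: bool = False) -> SimulationResult:
        cfg = self.config
        priors = list(dict.fromkeys(list(cfg.priors) + self._extra_priors))
        cfg = SimulationConfig(
            corpus=cfg.corpus, chain=cfg.chain, priors=priors,
            stop_if=cfg.stop_if, seed=cfg.seed, batch_size=cfg.batch_size,
        )
        self.result = run_simulation(cfg, progress=progress)
        return self.result


def label_priors(sim: Simulation, record_ids: Sequence[str]) -> Simulation:
    """Register records to be labeled with their true labels before cycle 1."""
    return sim.label(record_ids)


def run_simulation(config: SimulationConfig,
                   progress: bool = False) -> SimulationResult:
    """Run the full screening simulation.

    Stopping order per step: the ``stop_if`` condition is checked after
    every applied label; the chain's own hand-off and global stopping
    rules are evaluated before each new query.
    """
    corpus = config.corpus
    chain = config.chain
    rng = np.random.default_rng(config.seed)
    cache = FeatureCache()
    state = ag.ScreenState.from_corpus(corpus)
    truth = {r.record_id: r.known_label for r in corpus}
    n_relevant = sum(1 for v in truth.values() if v == 1)

    rows: list[ResultRow] = []
    log: list[EventRow] = []
    tick = 0

    def record_label(rid: str, outcome: ag.RankingOutcome,
                     iteration: int, rank_in_iter: int) -> None:
        nonlocal tick
        tick += 1
        label = truth[rid]
        state.apply_label(rid, label)
        rows.append(ResultRow(
            order=len(rows) + 1, record_id=rid, label=label,
            training_set_size=outcome.training_set_size,
            iteration=iteration, agent_name=outcome.model_name,
        ))
        log.append(EventRow(
            row_no=len(log) + 1, record_id=rid, label=label,
            labeling_time=tick_to_iso(tick),
            training_set_size=outcome.training_set_size,
            queue_iteration=iteration, queue_rank=rank_in_iter,
            model_name=outcome.model_name, user_id=_ORACLE_USER,
        ))
        if progress and len(rows) % 25 == 0:
            found = sum(1 for r in rows if r.label == 1)
            print(f"  relevant found: {found}/{n_relevant} | "
                  f"labeled: {len(rows)}/{len(corpus)}")

    def budget_reached() -> bool:
        if config.stop_if == "min":
            return sum(1 for r in rows if r.label == 1) >= n_relevant
        if config.stop_if == "full":
            return not state.pool
        return len(rows) >= int(config.stop_if)

    # -- priors: labeled with true labels before the first cycle ----------
    outcome = ag.RankingOutcome([], False, 0,
                                chain.agent_at(0).name)
    iteration = 0
    for rid in dict.fromkeys(config.priors):
        if state.label_of(rid) is None:
            record_label(rid, outcome, iteration, 0)

    last_outcome: Optional[ag.RankingOutcome] = None
    labels_since_rank = 0
    while not budget_reached():
        decision = ag.evaluate_stopping(state, chain)
        while decision is ag.StopDecision.HANDOFF:
            ag.advance_chain(state, chain)
            decision = ag.evaluate_stopping(state, chain)
        if decision is ag.StopDecision.GLOBAL_STOP:
            break
        agent = chain.agent_at(state.active_agent)
        if last_outcome is None or last_outcome.model_name != agent.name:
            need_rank = True          # first cycle, or control just changed
        elif (agent.has_model and agent.retrain.retrain
                and ag.min_training_ready(state)):
            # an untrained fallback ranking is replaced as soon as the
            # minimum training set exists; a trained one every batch
            need_rank = (not last_outcome.trained
                         or labels_since_rank >= config.batch_size)
        else:
            need_rank = False
        if need_rank:
            last_outcome = ag.compute_ranking(state, agent, cache, rng)
            state.ranking = last_outcome.ranking
            iteration += 1
            labels_since_rank = 0
        # serve the next unlabeled record from the ranking in force
        rid = next((r for r in state.ranking if r in state.pool), None)
        if rid is None:
            break
        labels_since_rank += 1
        record_label(rid, last_outcome, iteration, labels_since_rank)

    # -- final ranking of the unscreened remainder -------------------------
    final_ranking: list[str] = []
    if state.pool:
        agent = chain.agent_at(state.active_agent)
        final_outcome = ag.compute_ranking(state, agent, cache, rng)
        final_ranking = final_outcome.ranking
    state.finished = True
    return SimulationResult(
        rows=rows, final_ranking=final_ranking, n_records=len(corpus),
        n_relevant=n_relevant, config=config, event_log=log,
    )


# ---------------------------------------------------------------------------
# Prior sampling
# ---------------------------------------------------------------------------

def sample_priors(
    corpus: Corpus,
    n_sets: int,
    rng: Union[int, np.random.Generator, None] = None,
    p: float = 0.5,
) -> list[list[str]]:
    """Sample prior sets from a fully labeled corpus.

    Per-class set sizes are drawn as 1 + Geometric(p) counted in failures
    before the first success (equivalently a geometric on {1, 2, ...}),
    capped at the class size; members are uniform without replacement.
    Every set holds at least one relevant and one irrelevant record.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    relevant = [r.record_id for r in corpus if r.known_label == 1]
    irrelevant = [r.record_id for r in corpus if r.known_label == 0]
    if not relevant or not irrelevant:
        raise ValidationError(
            "prior sampling needs at least one record of each class"
        )
    sets: list[list[str]] = []
    for _ in range(n_sets):
        n_rel = min(int(rng.geometric(p)), len(relevant))
        n_irr = min(int(rng.geometric(p)), len(irrelevant))
        picked_rel = rng.choice(len(relevant), size=n_rel, replace=False)
        picked_irr = rng.choice(len(irrelevant), size=n_irr, replace=False)
        chosen = [relevant[i] for i in sorted(picked_rel.tolist())]
        chosen += [irrelevant[i] for i in sorted(picked_irr.tolist())]
        sets.append(chosen)
    return sets
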