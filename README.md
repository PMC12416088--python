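# crowdscreen

A desk-scale library + CLI for **multiagent, multi-annotator
active-learning-to-rank screening** of text records (systematic-review
style title/abstract screening). A chain of *agents* — each a feature
extractor, classifier, balancer and query strategy plus a hand-off
policy — ranks an unlabeled pool, serves records to a crowd of
annotators asynchronously, retrains as labels arrive, hands control from
agent to agent, logs every event reproducibly, and can replay the whole
process in full simulation mode on labeled corpora with standard
screening-evaluation metrics.

## Package layout

| module       | role |
|--------------|------|
| `corpus_io`  | CSV/TSV/XLSX and RIS corpora, labeled exports, the event log and its replay, the zip project file |
| `features`   | one-hot and TF-IDF (uni+bigram) vectorizers with a fingerprinted feature cache |
| `learning`   | balanced sample weights, classifier training/scoring, pool ranking under five query strategies |
| `agents`     | agent specs, hand-off/global stopping rules, the active-learning cycle, named presets |
| `crowd`      | discrete-event multi-annotator queue service with worker-limited asynchronous retraining |
| `simulate`   | single-oracle full simulation over a labeled corpus; geometric prior sampling |
| `metrics`    | recall curve, confusion, WSS, ERF, TD/ATD, normalized loss, loss comparison |
| `synthetic`  | labeled-corpus generator and the worked-example crowd fixture |

## Quick start

```python
from crowdscreen import agents, simulate, synthetic, metrics

corpus = synthetic.generate_corpus(
    synthetic.CorpusSpec(n_records=300, prevalence=0.1, seed=0))
chain = agents.single_agent_chain(agents.default_learner(seed=0))
result = simulate.run_simulation(
    simulate.SimulationConfig(corpus=corpus, chain=chain, seed=0))
print(metrics.compute_report(result).to_json())
```

### CLI

```bash
crowdscreen generate corpus -o corpus.csv --seed 5
crowdscreen simulate corpus.csv -o run.zip --learner ultra --stop-if min --seed 5
crowdscreen metrics run.zip --dataset corpus.csv -o metrics.json
crowdscreen plot recall run.zip --dataset corpus.csv -o recall.png
crowdscreen generate fixture -o fixture_dir/
```

`--learner` presets: `ultra` (TF-IDF uni+bigram + linear SVM, max
querier), `bayes` (TF-IDF + multinomial naive Bayes), `worked-example`
(four-agent chain: random calibration → random top-up → fast model →
final model, with consecutive-irrelevant stops).

## Conventions and documented choices

* **Labels.** Tabular files: column `included` (or `label`; `included`
  wins) with 1 / 0 / blank. RIS files: `N1` lines carrying
  `ASReview_relevant` / `ASReview_irrelevant`.
* **Record ids** are taken from an `id`/`record_id` column when present,
  otherwise 0-based positional ids are assigned at read time.
* **TF-IDF dialect:** raw counts, idf = ln((1+N)/(1+df)) + 1, L2 row
  normalization, lexicographic vocabulary, tokens split on
  non-alphanumerics and lowercased, no stop words.
* **Balancer:** inverse-class-frequency weights
  `multiplier_c · N / (2 N_c)`; mean weight 1 at multiplier 1.
* **Queriers:** `max` (descending score), `uncertainty` (ascending
  distance to 0.5 for probabilities / 0 for decision values), `hybrid`
  (max order with ⌈ε·n⌉ random records promoted to random positions,
  ε = 0.05 by default), `random`, `top_down`. Ties always break by
  ascending corpus position, so rankings are exactly reproducible.
* **Metric formulas** (the literature names these but conventions vary;
  these are this package's definitions): WSS@r = (N−n_r)/N − (1−r);
  ERF@f = r(⌊fN⌋)/R − f; TD = screening position / N with unscreened
  records extrapolated through the final model ranking; ATD = mean TD;
  loss = normalized area between achieved and perfect recall step
  curves, 0 for perfect, 1 for worst.
* **Event log:** fixed CSV header
  `row_no,record_id,label,labeling_time,training_set_size,queue_iteration,queue_rank,model_name,user_id,note,tags,exclusion_reasons,discuss`.
  Allocation events appear as rows with an empty label and no timestamp;
  `replay_event_log` recovers labeled / relevant / outstanding counts
  from the log alone and validates its invariants.
* **Crowd contract** is discrete-event and deterministic under a seed:
  integer-tick scripts, at most `n_workers` concurrent retrains, retrain
  snapshots use exactly the labels present at retrain start, annotators
  are never blocked by training, and allocations never expire.

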