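"""Evaluation metrics over finished screening runs.

All metrics are derived from the recall curve — cumulative relevant
records found as a function of the number screened — together with the
final model ranking for records never screened.

Definitions used here (documented choices, see README):

* ``WSS@r``  = (N - n_r)/N - (1 - r), n_r the smallest screening depth
  reaching recall r;
* ``ERF@f``  = r(⌊f·N⌋)/R - f;
* ``TD``     = 1-based screening position / N (unscreened records use
  their extrapolated final-ranking position);
* ``ATD``    = mean TD over all relevant records;
* ``loss``   = (A_perfect - A_actual) / (A_perfect - A_worst), areas
  under the cumulative-relevant step curve over positions 1..N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

from .errors import (DegenerateCurveError, UndefinedMetricError,
                     ValidationError)


@dataclass
class RecallCurve:
    """Cumulative relevant found after screening i records, i = 1..n."""

    N: int                       # total records in the corpus
    R: int                       # total relevant in the corpus
    found: list[int]             # cumulative counts, one per screened record

    def __post_init__(self) -> None:
        prev = 0
        for i, r in enumerate(self.found, start=1):
            if r < prev or r > min(i, self.R):
                raise ValidationError(
                    f"invalid recall curve at position {i}: {r}"
                )
            prev = r

    @property
    def n_screened(self) -> int:
        return len(self.found)

    def found_at(self, i: int) -> int:
        """r(i), extended flat beyond the screened prefix; r(0) = 0."""
        if i <= 0:
            return 0
        if i <= len(self.found):
            return self.found[i - 1]
        return self.found[-1] if self.found else 0

    def recall_at(self, i: int) -> float:
        if self.R == 0:
            raise DegenerateCurveError("no relevant records")
        return self.found_at(i) / self.R


def recall_curve(result) -> RecallCurve:
    """Build the recall curve from a SimulationResult (or any object with
    ``screening_labels``, ``n_records`` and ``n_relevant``)."""
    labels = result.screening_labels
    found = []
    total = 0
    for lb in labels:
        total += 1 if lb == 1 else 0
        found.append(total)
    return RecallCurve(N=result.n_records, R=result.n_relevant, found=found)


def curve_from_labels(labels: Sequence[int], N: Optional[int] = None,
                      R: Optional[int] = None) -> RecallCurve:
    """Recall curve straight from an ordered 0/1 label sequence."""
    if N is None:
        N = len(labels)
    if R is None:
        R = sum(1 for lb in labels if lb == 1)
    found = []
    total = 0
    for lb in labels:
        total += 1 if lb == 1 else 0
        found.append(total)
    return RecallCurve(N=N, R=R, found=found)


def wss_at(curve: RecallCurve, level: float) -> float:
    """Work saved over sampling at recall ``level``."""
    if curve.R == 0:
        raise DegenerateCurveError("WSS undefined with no relevant records")
    target = level * curve.R
    n_r = None
    for i in range(1, curve.n_screened + 1):
        if curve.found_at(i) >= target - 1e-12:
            n_r = i
            break
    if n_r is None:
        raise UndefinedMetricError(
            f"recall never reaches {level} within the screened prefix"
        )
    return (curve.N - n_r) / curve.N - (1.0 - level)


def erf_at(curve: RecallCurve, fraction: float) -> float:
    """Extra relevant records found at screening fraction ``fraction``."""
    if not (0.0 <= fraction <= 1.0):
        raise ValidationError("fraction must lie in [0, 1]")
    if curve.R == 0:
        raise DegenerateCurveError("ERF undefined with no relevant records")
    i = int(fraction * curve.N)
    return curve.found_at(i) / curve.R - fraction


def _screening_position(result, record_id: str) -> int:
    """1-based position; unscreened records extrapolate via final ranking."""
    for row in result.rows:
        if row.record_id == record_id:
            return row.order
    try:
        rank = result.final_ranking.index(record_id)
    except ValueError:
        raise ValidationError(
            f"record {record_id!r} neither screened nor in the final ranking"
        )
    return result.n_screened + rank + 1


def time_to_discovery(result, record_id: str) -> float:
    """Fraction of the corpus screened before finding one relevant record."""
    truth = {r.record_id: r.known_label for r in result.config.corpus}
    if truth.get(record_id) != 1:
        raise ValidationError(f"record {record_id!r} is not relevant")
    return _screening_position(result, record_id) / result.n_records


def atd(result) -> float:
    """Average time to discovery over every relevant record."""
    relevant = [r.record_id for r in result.config.corpus
                if r.known_label == 1]
    if not relevant:
        raise DegenerateCurveError("ATD undefined with no relevant records")
    tds = [time_to_discovery(result, rid) for rid in relevant]
    return sum(tds) / len(tds)


def loss_norm(curve: RecallCurve) -> float:
    """Normalized area loss in [0, 1]: 0 = perfect ordering, 1 = worst.

    Requires a complete curve (all relevant found, or N records
    screened); the step areas are evaluated in exact rational arithmetic
    before the final division.
    """
    N, R = curve.N, curve.R
    if R == 0 or R == N:
        raise DegenerateCurveError(
            "loss undefined when the corpus is single-class"
        )
    if curve.found_at(curve.n_screened) < R and curve.n_screened < N:
        raise UndefinedMetricError(
            "loss needs a curve complete to all-relevant-found or full screen"
        )
    a_actual = sum(Fraction(curve.found_at(i)) for i in range(1, N + 1))
    a_perfect = sum(Fraction(min(i, R)) for i in range(1, N + 1))
    a_worst = sum(Fraction(max(0, i - (N - R))) for i in range(1, N + 1))
    return float((a_perfect - a_actual) / (a_perfect - a_worst))


def confusion_at(result, cutoff: int) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) treating the first ``cutoff`` screened as positive."""
    curve = recall_curve(result)
    if not (1 <= cutoff <= curve.N):
        raise ValidationError(f"cutoff must lie in [1, {curve.N}]")
    tp = curve.found_at(cutoff)
    fp = min(cutoff, curve.n_screened) - tp
    # records predicted positive but never screened count as irrelevant picks
    if cutoff > curve.n_screened:
        fp += cutoff - curve.n_screened
    fn = curve.R - tp
    tn = curve.N - cutoff - fn
    return tp, fp, tn, fn


def compare_mean_losses(loss_a: float, loss_b: float) -> float:
    """Percent decrease from loss_a to loss_b, one-decimal display rounding."""
    if loss_a <= 0:
        raise ValidationError("baseline mean loss must be positive")
    return round(100.0 * (loss_a - loss_b) / loss_a, 1)


@dataclass
class MetricsReport:
    """Bundle of evaluation metrics for one finished run."""

    n_records: int
    n_relevant: int
    n_screened: int
    recall: dict[str, float]
    wss: dict[str, float]
    erf: dict[str, float]
    td: dict[str, float]
    atd: float
    loss: Optional[float]
    confusion: dict[str, tuple[int, int, int, int]]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_relevant": self.n_relevant,
            "n_screened": self.n_screened,
            "recall": self.recall,
            "wss": self.wss,
            "erf": self.erf,
            "td": self.td,
            "atd": self.atd,
            "loss": self.loss,
            "confusion": {k: list(v) for k, v in self.confusion.items()},
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def compute_report(
    result,
    wss_levels: Sequence[float] = (0.95,),
    erf_fractions: Sequence[float] = (0.10,),
    recall_points: Sequence[float] = (0.10, 0.25, 0.50),
) -> MetricsReport:
    """Full metric report for a finished simulation result."""
    curve = recall_curve(result)
    rec = {f"@{p:g}": round(curve.recall_at(int(p * curve.N)), 4)
           for p in recall_points}
    wss = {}
    for lvl in wss_levels:
        try:
            wss[f"@{lvl:g}"] = round(wss_at(curve, lvl), 4)
        except UndefinedMetricError:
            wss[f"@{lvl:g}"] = None
    erf = {f"@{f:g}": round(erf_at(curve, f), 4) for f in erf_fractions}
    relevant = [r.record_id for r in result.config.corpus
                if r.known_label == 1]
    td = {rid: round(time_to_discovery(result, rid), 4) for rid in relevant}
    try:
        loss = round(loss_norm(curve), 4)
    except (DegenerateCurveError, UndefinedMetricError):
        loss = None
    cut = max(1, curve.n_screened)
    confusion = {str(cut): confusion_at(result, cut)}
    from . import agents as ag
    return MetricsReport(
        n_records=curve.N,
        n_relevant=curve.R,
        n_screened=curve.n_screened,
        recall=rec,
        wss=wss,
        erf=erf,
        td=td,
        atd=round(atd(result), 4),
        loss=loss,
        confusion=confusion,
        provenance={"chain": ag.chain_to_config(result.config.chain),
                    "seed": result.config.seed,
                    "stop_if": str(result.config.stop_if)},
    )
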