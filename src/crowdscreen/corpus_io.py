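"""Corpus and event-log I/O.

Reads screening corpora from tabular files (CSV/TSV/XLSX) and RIS
reference files, writes labeled exports back out, and serializes the
append-only event log that makes a screening run replayable.

Label conventions
-----------------
Tabular files carry labels in a column named ``included`` or ``label``
(case-insensitive; ``included`` wins when both are present): ``1`` means
relevant, ``0`` irrelevant, blank unknown.  RIS files carry labels as
``N1`` note lines holding the sentinel tags ``ASReview_relevant`` /
``ASReview_irrelevant``.

Record identity: when the input has no id column, 0-based positional ids
(as strings) are assigned at read time; they are stable per file.
"""

from __future__ import annotations

import csv
import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

RELEVANT_TAG = "ASReview_relevant"
IRRELEVANT_TAG = "ASReview_irrelevant"

#: Fixed header of the exported event log (order is part of the contract).
EVENT_LOG_COLUMNS = [
    "row_no",
    "record_id",
    "label",
    "labeling_time",
    "training_set_size",
    "queue_iteration",
    "queue_rank",
    "model_name",
    "user_id",
    "note",
    "tags",
    "exclusion_reasons",
    "discuss",
]

_TITLE_ALIASES = ("title", "primary_title")
_BODY_ALIASES = ("abstract", "body", "text", "notes_abstract")
_ID_ALIASES = ("record_id", "id")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Record:
    """One screenable document.

    ``known_label`` is ``1`` (relevant), ``0`` (irrelevant) or ``None``
    (unknown).
    """

    record_id: str
    title: str = ""
    body: str = ""
    known_label: Optional[int] = None
    tags: list[str] = field(default_factory=list)
    note: str = ""
    exclusion_reasons: list[str] = field(default_factory=list)
    discuss_flag: bool = False
    #: verbatim (tag, value) pairs from RIS input, preserved on round-trip
    ris_fields: Optional[list[tuple[str, str]]] = None

    def __post_init__(self) -> None:
        if self.known_label not in (0, 1, None):
            raise ValidationError(
                f"label for record {self.record_id!r} must be 0, 1 or unknown, "
                f"got {self.known_label!r}"
            )

    @property
    def text(self) -> str:
        """Title and body joined; the string fed to the vectorizer."""
        return f"{self.title} {self.body}".strip()


@dataclass
class Corpus:
    """An ordered collection of records with unique ids.

    Order is preserved exactly as read; the top-down querier and all
    tie-breaking rules depend on it.
    """

    records: list[Record]
    source_format: str = "csv"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValidationError(f"duplicate record id {rec.record_id!r}")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> Record:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    @property
    def labels(self) -> list[Optional[int]]:
        return [r.known_label for r in self.records]

    @property
    def texts(self) -> list[str]:
        return [r.text for r in self.records]

    def by_id(self, record_id: str) -> Record:
        for r in self.records:
            if r.record_id == record_id:
                return r
        raise KeyError(record_id)

    def position(self, record_id: str) -> int:
        for i, r in enumerate(self.records):
            if r.record_id == record_id:
                return i
        raise KeyError(record_id)


@dataclass
class EventRow:
    """One row of the project export: a labeling or allocation event.

    Allocation events (a record handed to an annotator but not yet
    labeled) have ``label is None`` and ``labeling_time is None``.
    """

    row_no: int
    record_id: str
    label: Optional[int] = None
    labeling_time: Optional[str] = None
    training_set_size: Optional[int] = None
    queue_iteration: Optional[int] = None
    queue_rank: Optional[int] = None
    model_name: str = ""
    user_id: str = ""
    note: str = ""
    tags: list[str] = field(default_factory=list)
    exclusion_reasons: list[str] = field(default_factory=list)
    discuss_flag: bool = False

    @property
    def is_allocation(self) -> bool:
        return self.label is None

    def to_csv_values(self) -> list[str]:
        return [
            str(self.row_no),
            self.record_id,
            "" if self.label is None else str(self.label),
            self.labeling_time or "",
            "" if self.training_set_size is None else str(self.training_set_size),
            "" if self.queue_iteration is None else str(self.queue_iteration),
            "" if self.queue_rank is None else str(self.queue_rank),
            self.model_name,
            self.user_id,
            self.note,
            ";".join(self.tags),
            ";".join(self.exclusion_reasons),
            "1" if self.discuss_flag else "",
        ]

    @classmethod
    def from_csv_values(cls, values: Sequence[str]) -> "EventRow":
        if len(values) != len(EVENT_LOG_COLUMNS):
            raise FormatError(
                f"event-log row has {len(values)} columns, "
                f"expected {len(EVENT_LOG_COLUMNS)}"
            )
        (row_no, record_id, label, t, tss, qit, qrk, model, user,
         note, tags, excl, discuss) = values
        return cls(
            row_no=int(row_no),
            record_id=record_id,
            label=int(label) if label != "" else None,
            labeling_time=t or None,
            training_set_size=int(tss) if tss != "" else None,
            queue_iteration=int(qit) if qit != "" else None,
            queue_rank=int(qrk) if qrk != "" else None,
            model_name=model,
            user_id=user,
            note=note,
            tags=tags.split(";") if tags else [],
            exclusion_reasons=excl.split(";") if excl else [],
            discuss_flag=discuss == "1",
        )


@dataclass
class ReplaySummary:
    """Counts recovered by replaying an event log."""

    labeled_count: int
    relevant_count: int
    irrelevant_count: int
    allocated_unlabeled_count: int
    never_touched_count: int
    segments: list[tuple[str, int]]          # (model_name, n labeled rows)
    per_user_counts: dict[str, int]          # labels per user_id


@dataclass
class ProjectFile:
    """Everything needed to reconstruct a screening run.

    Serialized as a zip containing ``config.json`` (metadata, learner
    chain, priors, seed) plus ``event_log.csv`` and optional cached
    feature matrices in Matrix Market format.
    """

    metadata: dict = field(default_factory=dict)
    learner_config: dict = field(default_factory=dict)
    priors: list[str] = field(default_factory=list)
    seed: Optional[int] = None
    event_log: list[EventRow] = field(default_factory=list)
    feature_matrices: dict = field(default_factory=dict)  # name -> scipy sparse

    def save(self, path: Union[str, Path]) -> None:
        from scipy.io import mmwrite

        config = {
            "metadata": self.metadata,
            "learner": self.learner_config,
            "priors": self.priors,
            "seed": self.seed,
            "feature_matrices": sorted(self.feature_matrices),
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("config.json", json.dumps(config, indent=2, sort_keys=True))
            zf.writestr("event_log.csv", event_log_to_csv(self.event_log))
            for name, mat in sorted(self.feature_matrices.items()):
                buf = io.BytesIO()
                mmwrite(buf, mat)
                zf.writestr(f"features/{name}.mtx", buf.getvalue())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ProjectFile":
        from scipy.io import mmread

        with zipfile.ZipFile(path) as zf:
            config = json.loads(zf.read("config.json").decode("utf-8"))
            log = event_log_from_csv(zf.read("event_log.csv").decode("utf-8"))
            mats = {}
            for name in config.get("feature_matrices", []):
                data = zf.read(f"features/{name}.mtx")
                mats[name] = mmread(io.BytesIO(data)).tocsr()
        return cls(
            metadata=config["metadata"],
            learner_config=config["learner"],
            priors=config["priors"],
            seed=config["seed"],
            event_log=log,
            feature_matrices=mats,
        )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _parse_label(value) -> Optional[int]:
    if value is None:
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    s = str(value).strip()
    if s == "" or s.lower() == "nan":
        return None
    try:
        num = float(s)
    except ValueError:
        raise ValidationError(f"unparseable label value {value!r}")
    if num == 1:
        return 1
    if num == 0:
        return 0
    raise ValidationError(f"label value must be 0, 1 or blank, got {value!r}")


def _find_column(columns: Iterable[str], aliases: Sequence[str]) -> Optional[str]:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def read_tabular(path: Union[str, Path], dialect: Optional[str] = None) -> Corpus:
    """Read a CSV/TSV/XLSX corpus.

    Requires a header row with at least a title or body column.  The
    label column (``included`` preferred, then ``label``) maps 1 to
    relevant, 0 to irrelevant and blank to unknown.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect is None:
        suffix = path.suffix.lower().lstrip(".")
        dialect = {"csv": "csv", "tsv": "tsv", "xlsx": "xlsx"}.get(suffix, "csv")
    try:
        if dialect == "xlsx":
            df = pd.read_excel(path, dtype=object)
        else:
            sep = "\t" if dialect == "tsv" else ","
            df = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=False,
                             na_values=[])
    except Exception as exc:  # pandas raises many flavors on garbage input
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    if df.shape[1] == 0 or len(df) == 0 and df.shape[1] == 0:
        raise FormatError(f"{path} is empty")

    title_col = _find_column(df.columns, _TITLE_ALIASES)
    body_col = _find_column(df.columns, _BODY_ALIASES)
    if title_col is None and body_col is None:
        raise FormatError(
            f"{path} has neither a title nor a body/abstract column "
            f"(columns: {list(df.columns)})"
        )
    id_col = _find_column(df.columns, _ID_ALIASES)
    label_col = _find_column(df.columns, ("included",))
    if label_col is None:
        label_col = _find_column(df.columns, ("label",))

    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        rid = str(row[id_col]).strip() if id_col is not None else str(i)
        title = str(row[title_col]) if title_col is not None else ""
        body = str(row[body_col]) if body_col is not None else ""
        label = _parse_label(row[label_col]) if label_col is not None else None
        records.append(Record(record_id=rid, title=title, body=body,
                              known_label=label))
    return Corpus(records=records, source_format=dialect)


def write_labeled(
    corpus: Corpus,
    labels: Sequence[Optional[int]],
    path: Union[str, Path],
    format: str = "csv",
) -> None:
    """Write a corpus with (possibly partial) labels for re-import.

    Tabular formats use an ``included`` column (blank for unknown); RIS
    uses the sentinel ``N1`` tags.
    """
    if len(labels) != len(corpus):
        raise ValidationError(
            f"{len(labels)} labels for {len(corpus)} records"
        )
    path = Path(path)
    if format == "ris":
        _write_ris(corpus, labels, path)
        return
    df = pd.DataFrame(
        {
            "record_id": corpus.ids,
            "title": [r.title for r in corpus],
            "abstract": [r.body for r in corpus],
            "included": ["" if lb is None else int(lb) for lb in labels],
        }
    )
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "tsv":
        df.to_csv(path, index=False, sep="\t")
    elif format == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise ValidationError(f"unknown output format {format!r}")


# ---------------------------------------------------------------------------
# RIS I/O
# ---------------------------------------------------------------------------
# Minimal RIS dialect: "XX  - value" lines, records terminated by "ER  - ".
# One N1 line per note/tag; unknown fields are preserved verbatim.

_RIS_TAG_SEP = "  - "


def _parse_ris_text(text: str) -> list[list[tuple[str, str]]]:
    refs: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    saw_tag = False
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if len(line) >= 2 and line[:2].isalnum() and line[2:].startswith(_RIS_TAG_SEP[:2]):
            tag = line[:2]
            value = line[len("XX") + len(_RIS_TAG_SEP):] if len(line) > 6 else ""
            saw_tag = True
            if tag == "ER":
                refs.append(current)
                current = []
            else:
                current.append((tag, value))
        elif current:
            # continuation line: append to previous value
            tag, value = current[-1]
            current[-1] = (tag, value + " " + line.strip())
        else:
            raise FormatError(f"malformed RIS line: {line!r}")
    if not saw_tag:
        raise FormatError("not a RIS file: no tagged lines found")
    if current:
        raise FormatError("malformed RIS: reference not terminated by ER")
    return refs


def read_ris(path: Union[str, Path]) -> Corpus:
    """Read a RIS reference file.

    Labels live in ``N1`` fields: a line containing ``ASReview_relevant``
    maps to 1, ``ASReview_irrelevant`` to 0, anything else is kept as a
    note and the label stays unknown.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    text = path.read_text(encoding="utf-8")
    refs = _parse_ris_text(text)
    records = []
    for i, fields in enumerate(refs):
        title = ""
        body = ""
        rid = str(i)
        label: Optional[int] = None
        notes: list[str] = []
        extra: list[tuple[str, str]] = []
        for tag, value in fields:
            if tag in ("TI", "T1") and not title:
                title = value
            elif tag in ("AB", "N2") and not body:
                body = value
            elif tag == "ID":
                rid = value.strip()
            elif tag == "N1":
                if value.strip() == RELEVANT_TAG:
                    label = 1
                elif value.strip() == IRRELEVANT_TAG:
                    label = 0
                else:
                    notes.append(value)
            else:
                extra.append((tag, value))
        records.append(
            Record(record_id=rid, title=title, body=body, known_label=label,
                   note="; ".join(notes), ris_fields=extra)
        )
    return Corpus(records=records, source_format="ris")


def _write_ris(corpus: Corpus, labels: Sequence[Optional[int]], path: Path) -> None:
    lines: list[str] = []
    for rec, label in zip(corpus, labels):
        fields: list[tuple[str, str]] = [("TY", "JOUR"), ("ID", rec.record_id)]
        if rec.title:
            fields.append(("TI", rec.title))
        if rec.body:
            fields.append(("AB", rec.body))
        if label == 1:
            fields.append(("N1", RELEVANT_TAG))
        elif label == 0:
            fields.append(("N1", IRRELEVANT_TAG))
        if rec.note:
            for chunk in rec.note.split("; "):
                if chunk:
                    fields.append(("N1", chunk))
        for tag, value in rec.ris_fields or []:
            fields.append((tag, value))
        for tag, value in fields:
            lines.append(f"{tag}{_RIS_TAG_SEP}{value}")
        lines.append(f"ER{_RIS_TAG_SEP}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Event log
# ---------------------------------------------------------------------------

def event_log_to_csv(rows: Sequence[EventRow]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(EVENT_LOG_COLUMNS)
    for row in rows:
        writer.writerow(row.to_csv_values())
    return buf.getvalue()


def event_log_from_csv(text: str) -> list[EventRow]:
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("empty event log")
    if header != EVENT_LOG_COLUMNS:
        raise FormatError(f"unexpected event-log header: {header}")
    return [EventRow.from_csv_values(row) for row in reader if row]


def write_event_log(project_or_rows, path: Union[str, Path]) -> None:
    """Write the event log of a project (or a bare list of rows) as CSV."""
    rows = getattr(project_or_rows, "event_log", project_or_rows)
    Path(path).write_text(event_log_to_csv(rows), encoding="utf-8")


def read_event_log(path: Union[str, Path]) -> list[EventRow]:
    return event_log_from_csv(Path(path).read_text(encoding="utf-8"))


def replay_event_log(log: Sequence[EventRow], corpus_size: int) -> ReplaySummary:
    """Recompute run summary counts from an event log alone.

    Pure function of the log: two replays always give identical
    summaries.  Validates the EventRow invariants and raises
    :class:`IntegrityError` on violation.
    """
    labeled: dict[str, int] = {}
    allocated: set[str] = set()
    per_user: dict[str, int] = {}
    segments: list[tuple[str, int]] = []
    last_row_no = 0
    seg_model: Optional[str] = None
    seg_count = 0
    seg_max_tss: Optional[int] = None

    for row in log:
        if row.row_no <= last_row_no:
            raise IntegrityError(
                f"row_no must be strictly increasing, got {row.row_no} "
                f"after {last_row_no}"
            )
        last_row_no = row.row_no
        if row.is_allocation and row.labeling_time is not None:
            raise IntegrityError(
                f"row {row.row_no}: unlabeled row carries a labeling_time"
            )
        if row.model_name != seg_model:
            if seg_model is not None:
                segments.append((seg_model, seg_count))
            seg_model = row.model_name
            seg_count = 0
            seg_max_tss = None
        if row.training_set_size is not None:
            if seg_max_tss is not None and row.training_set_size < seg_max_tss:
                raise IntegrityError(
                    f"row {row.row_no}: training_set_size decreased from "
                    f"{seg_max_tss} to {row.training_set_size} within "
                    f"segment {seg_model!r}"
                )
            seg_max_tss = row.training_set_size
        if row.is_allocation:
            allocated.add(row.record_id)
        else:
            if row.record_id in labeled:
                raise IntegrityError(
                    f"record {row.record_id!r} labeled twice"
                )
            labeled[row.record_id] = row.label
            seg_count += 1
            per_user[row.user_id] = per_user.get(row.user_id, 0) + 1
    if seg_model is not None:
        segments.append((seg_model, seg_count))

    allocated_unlabeled = {rid for rid in allocated if rid not in labeled}
    touched = set(labeled) | allocated_unlabeled
    if len(touched) > corpus_size:
        raise IntegrityError(
            f"log touches {len(touched)} records but corpus has {corpus_size}"
        )
    return ReplaySummary(
        labeled_count=len(labeled),
        relevant_count=sum(1 for v in labeled.values() if v == 1),
        irrelevant_count=sum(1 for v in labeled.values() if v == 0),
        allocated_unlabeled_count=len(allocated_unlabeled),
        never_touched_count=corpus_size - len(touched),
        segments=segments,
        per_user_counts=per_user,
    )
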