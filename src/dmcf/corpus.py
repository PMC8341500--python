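"""Search-log ingestion and the in-memory corpus of per-visit search sequences.

A clinician search log is a UTF-8 TSV with header
``timestamp  physician_id  patient_id  visit_id  term`` (tab-separated), one
search event per line, ISO 8601 timestamps, no quoting.  Events are grouped by
(physician, patient, visit) into ordered search sequences: the sequence of
terms a physician searches for on a patient during one visit.  Additional
visits of the same patient with the same physician produce additional
sequences; sequences are never merged across visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LOG_COLUMNS = ["timestamp", "physician_id", "patient_id", "visit_id", "term"]

__all__ = [
    "LOG_COLUMNS",
    "NormalizationConfig",
    "SearchEvent",
    "SearchSequence",
    "SearchCorpus",
    "Vocabulary",
    "load_log",
    "write_log",
    "corpus_from_frame",
    "corpus_stats",
]


class LogFormatError(ValueError):
    """Raised for a malformed search-log file (bad header, row or timestamp)."""


@dataclass(frozen=True)
class NormalizationConfig:
    """How raw term strings are normalized on load.

    Real logs mix case freely ("HGB" vs "hgb"); by default terms are
    lower-cased and internal whitespace is collapsed so that such variants
    share one vocabulary entry.  ``collapse_repeats`` optionally drops
    consecutive duplicate terms within a visit; the default keeps them, since
    a repeated search is a legitimate self-transition.  ``session_timeout``
    (minutes) is used only when the log carries no visit ids: events of the
    same (physician, patient) pair separated by more than the timeout are
    split into separate inferred visits.
    """

    lowercase: bool = True
    collapse_whitespace: bool = True
    collapse_repeats: bool = False
    session_timeout: float = 240.0

    def normalize_term(self, term: str) -> str:
        out = term.strip()
        if self.collapse_whitespace:
            out = " ".join(out.split())
        if self.lowercase:
            out = out.lower()
        return out


@dataclass(frozen=True)
class SearchEvent:
    """One search: physician ``y`` searched ``term`` on patient ``p`` in visit ``v``."""

    timestamp: pd.Timestamp
    physician_id: str
    patient_id: str
    visit_id: str
    term: str


@dataclass
class SearchSequence:
    """Ordered terms searched by one physician on one patient during one visit."""

    physician_id: str
    patient_id: str
    visit_id: str
    terms: list[str]
    timestamps: list[pd.Timestamp]

    def __len__(self) -> int:
        return len(self.terms)

    def events(self) -> list[SearchEvent]:
        return [
            SearchEvent(ts, self.physician_id, self.patient_id, self.visit_id, t)
            for t, ts in zip(self.terms, self.timestamps)
        ]


class Vocabulary:
    """Dense, stable string-to-index mapping (first-appearance order)."""

    def __init__(self, items: Iterable[str] = ()):
        self.items: list[str] = []
        self.index: dict[str, int] = {}
        for it in items:
            self.add(it)

    def add(self, item: str) -> int:
        ix = self.index.get(item)
        if ix is None:
            ix = len(self.items)
            self.index[item] = ix
            self.items.append(item)
        return ix

    def get(self, item: str) -> int | None:
        return self.index.get(item)

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, item: str) -> bool:
        return item in self.index

    def __getitem__(self, ix: int) -> str:
        return self.items[ix]


@dataclass
class SearchCorpus:
    """A collection of search sequences plus physician/patient/term vocabularies.

    Sequences are kept in canonical order (first timestamp, then ids) and the
    vocabularies assign dense integer indices 0..n-1 in order of first
    appearance, so every downstream model is deterministic given the corpus.
    """

    sequences: list[SearchSequence] = field(default_factory=list)
    physicians: Vocabulary = field(default_factory=Vocabulary)
    patients: Vocabulary = field(default_factory=Vocabulary)
    terms: Vocabulary = field(default_factory=Vocabulary)

    @classmethod
    def from_sequences(cls, sequences: Sequence[SearchSequence]) -> "SearchCorpus":
        seqs = sorted(
            sequences,
            key=lambda s: (s.timestamps[0], s.physician_id, s.patient_id, s.visit_id),
        )
        corpus = cls(sequences=list(seqs))
        for s in corpus.sequences:
            corpus.physicians.add(s.physician_id)
            corpus.patients.add(s.patient_id)
            for t in s.terms:
                corpus.terms.add(t)
        return corpus

    @property
    def n_events(self) -> int:
        return sum(len(s) for s in self.sequences)

    def iter_events(self) -> Iterable[SearchEvent]:
        for s in self.sequences:
            yield from s.events()

    def to_frame(self) -> pd.DataFrame:
        """All events as a DataFrame in global timestamp order (ties keep
        sequence order), matching the on-disk log dialect."""
        rows = [
            (e.timestamp, e.physician_id, e.patient_id, e.visit_id, e.term)
            for e in self.iter_events()
        ]
        df = pd.DataFrame(rows, columns=LOG_COLUMNS)
        return df.sort_values("timestamp", kind="stable", ignore_index=True)


def _group_into_sequences(
    df: pd.DataFrame, config: NormalizationConfig
) -> list[SearchSequence]:
    sequences: list[SearchSequence] = []
    # stable sort within each (y, p, v) group keeps input order on timestamp ties
    for (y, p, v), grp in df.groupby(
        ["physician_id", "patient_id", "visit_id"], sort=False
    ):
        grp = grp.sort_values("timestamp", kind="stable")
        terms = list(grp["term"])
        stamps = list(grp["timestamp"])
        if config.collapse_repeats:
            keep = [0] + [i for i in range(1, len(terms)) if terms[i] != terms[i - 1]]
            terms = [terms[i] for i in keep]
            stamps = [stamps[i] for i in keep]
        sequences.append(SearchSequence(y, p, v, terms, stamps))
    return sequences


def _infer_visits(df: pd.DataFrame, timeout_minutes: float) -> pd.Series:
    """Assign session visit ids per (physician, patient) using an inactivity gap."""
    gap = pd.Timedelta(minutes=timeout_minutes)
    visit_ids = pd.Series("", index=df.index, dtype=object)
    for (y, p), grp in df.groupby(["physician_id", "patient_id"], sort=False):
        grp = grp.sort_values("timestamp", kind="stable")
        new_session = grp["timestamp"].diff() > gap
        session_no = new_session.cumsum()
        visit_ids.loc[grp.index] = [
            f"session:{y}:{p}:{k}" for k in session_no.astype(int)
        ]
    return visit_ids


def load_log(
    path: str | Path, normalization: NormalizationConfig | None = None
) -> SearchCorpus:
    """Read a search log and assemble the corpus of per-visit sequences.

    Raises :class:`LogFormatError`, naming the offending line, for a bad
    header, wrong column count or an unparseable timestamp.  An empty file
    (header only) yields an empty corpus.  Rows with an empty ``visit_id``
    are assigned inferred session visits via the normalization config's
    inactivity timeout.
    """
    config = normalization or NormalizationConfig()
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header == "":
            return SearchCorpus()
        if header.split("\t") != LOG_COLUMNS:
            raise LogFormatError(
                f"{path}:1: bad header {header!r}; expected tab-separated {LOG_COLUMNS}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(LOG_COLUMNS):
                raise LogFormatError(
                    f"{path}:{lineno}: expected {len(LOG_COLUMNS)} columns, got {len(parts)}"
                )
            ts, y, p, v, term = parts
            try:
                stamp = pd.Timestamp(ts)
            except ValueError as exc:
                raise LogFormatError(
                    f"{path}:{lineno}: unparseable timestamp {ts!r}"
                ) from exc
            if pd.isna(stamp):
                raise LogFormatError(f"{path}:{lineno}: missing timestamp")
            term = config.normalize_term(term)
            if not term:
                raise LogFormatError(f"{path}:{lineno}: empty term after normalization")
            rows.append((stamp, y, p, v, term))
    if not rows:
        return SearchCorpus()
    df = pd.DataFrame(rows, columns=LOG_COLUMNS)
    missing_visit = df["visit_id"] == ""
    if missing_visit.any():
        inferred = _infer_visits(df[missing_visit], config.session_timeout)
        df.loc[missing_visit, "visit_id"] = inferred
    return SearchCorpus.from_sequences(_group_into_sequences(df, config))


def corpus_from_frame(
    df: pd.DataFrame, normalization: NormalizationConfig | None = None
) -> SearchCorpus:
    """Build a corpus from an in-memory event table with the log columns.

    Accepts any DataFrame carrying the five log columns; timestamps are
    coerced with :func:`pandas.to_datetime`, terms normalized per config.
    """
    config = normalization or NormalizationConfig()
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise LogFormatError(f"missing log columns: {missing}")
    if df.empty:
        return SearchCorpus()
    df = df.loc[:, LOG_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if df["timestamp"].isna().any():
        bad = int(df.index[df["timestamp"].isna()][0])
        raise LogFormatError(f"row {bad}: unparseable timestamp")
    for col in ("physician_id", "patient_id", "visit_id", "term"):
        df[col] = df[col].astype(str)
    df["term"] = [config.normalize_term(t) for t in df["term"]]
    if (df["term"] == "").any():
        bad = int(df.index[df["term"] == ""][0])
        raise LogFormatError(f"row {bad}: empty term after normalization")
    df = df.reset_index(drop=True)
    missing_visit = df["visit_id"] == ""
    if missing_visit.any():
        inferred = _infer_visits(df[missing_visit], config.session_timeout)
        df.loc[missing_visit, "visit_id"] = inferred
    return SearchCorpus.from_sequences(_group_into_sequences(df, config))


def write_log(corpus: SearchCorpus, path: str | Path) -> None:
    """Write the corpus back to the TSV log dialect (round-trips exactly)."""
    df = corpus.to_frame()
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(LOG_COLUMNS) + "\n")
        for ts, y, p, v, t in df.itertuples(index=False):
            fh.write(f"{ts.isoformat()}\t{y}\t{p}\t{v}\t{t}\n")


def corpus_stats(corpus: SearchCorpus) -> pd.Series:
    """Summary counts of the corpus.

    Mirrors the standard log-summary table: number of patients, physicians,
    terms and sequences, total searched terms, terms per patient, and the
    mean sequence length.  An empty corpus reports zeros.
    """
    n_seq = len(corpus.sequences)
    total = corpus.n_events
    n_p = len(corpus.patients)
    return pd.Series(
        {
            "n_patients": float(n_p),
            "n_physicians": float(len(corpus.physicians)),
            "n_terms": float(len(corpus.terms)),
            "n_sequences": float(n_seq),
            "total_searches": float(total),
            "searches_per_patient": total / n_p if n_p else 0.0,
            "mean_sequence_length": total / n_seq if n_seq else 0.0,
        }
    )
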