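"""Domain types, on-disk event-log schemas, readers/writers, cohort filtering.

Three event-log kinds are supported, each as JSONL (one JSON object per
line, the primary format) or CSV with a header row:

``keystroke``
    ``participant_id`` (str), ``timestamp`` (UTC epoch milliseconds, int),
    ``package`` (app package name, or raw domain for browsers), ``url``
    (optional str), ``text`` (full current contents of the active text field).
``location``
    ``participant_id``, ``timestamp`` (ms), ``lat``, ``lon`` (degrees).
``survey``
    ``participant_id``, ``question`` (str), ``response`` (str).

Timestamps are interpreted in fixed UTC; a "day" is always the UTC calendar
day of the epoch timestamp, which keeps day-based features reproducible in
the absence of per-participant timezone information.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd

__all__ = [
    "KeystrokeEvent",
    "MessageLine",
    "LocationFix",
    "SurveyLabel",
    "CohortConfig",
    "ReadResult",
    "read_event_log",
    "write_event_log",
    "filter_min_days",
    "write_feature_matrix",
    "read_feature_matrix",
    "utc_day",
]

LogKind = Literal["keystroke", "location", "survey"]


def utc_day(timestamp_ms: int) -> date:
    """UTC calendar date of an epoch-millisecond timestamp."""
    return datetime.fromtimestamp(timestamp_ms / 1000.0, tz=timezone.utc).date()


@dataclass(frozen=True)
class KeystrokeEvent:
    """One snapshot of a text field taken at a keystroke.

    The sensing app records the *full current contents* of the active text
    field on every keypress, so consecutive events are near-duplicates
    (``"H"``, ``"He"``, ``"Hel"`` ...); :mod:`phenorisk.dedup` collapses them.
    """

    participant_id: str
    timestamp: int
    package: str
    text: str
    url: str | None = None

    @property
    def day(self) -> date:
        return utc_day(self.timestamp)


@dataclass(frozen=True)
class MessageLine:
    """A deduplicated final line of typed text attributed to a day and app."""

    participant_id: str
    day: date
    package: str
    text: str


@dataclass(frozen=True)
class LocationFix:
    """A raw GPS fix; the logger records fixes only while the phone moves."""

    participant_id: str
    timestamp: int
    lat: float
    lon: float

    @property
    def day(self) -> date:
        return utc_day(self.timestamp)


@dataclass(frozen=True)
class SurveyLabel:
    """Per-question binary outcome; value is 'yes', 'no' or 'missing'."""

    participant_id: str
    question_id: str
    value: str  # {"yes", "no", "missing"}


@dataclass
class CohortConfig:
    """Pipeline-wide constants.

    Defaults carry the analysis constants: a 30-day minimum of keystroke
    data for inclusion, the 0.6 dedup similarity threshold, a 100 m
    mean-shift radius, and the 5-participant vocabulary floor.
    """

    min_days: int = 30
    similarity_threshold: float = 0.6
    mean_shift_radius_m: float = 100.0
    min_users_vocab: int = 5
    gap_max_s: float = 300.0
    category_map_path: str | None = None
    lexicon_paths: list[str] = field(default_factory=list)
    dictionary_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.min_days < 1:
            raise ValueError("min_days must be >= 1")
        if not 0.0 < self.similarity_threshold < 1.0:
            raise ValueError("similarity_threshold must lie in (0, 1)")


@dataclass
class ReadResult:
    """Parsed records plus per-file quality counters."""

    records: list
    n_malformed: int = 0
    n_rejected: int = 0

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


_KEYSTROKE_FIELDS = ("participant_id", "timestamp", "package", "text")
_LOCATION_FIELDS = ("participant_id", "timestamp", "lat", "lon")
_SURVEY_FIELDS = ("participant_id", "question", "response")


def _parse_keystroke(obj: dict) -> KeystrokeEvent | None:
    try:
        ts = int(obj["timestamp"])
        package = str(obj["package"]).strip()
        if ts < 0 or not package:
            return None
        url = obj.get("url") or None
        return KeystrokeEvent(
            participant_id=str(obj["participant_id"]),
            timestamp=ts,
            package=package,
            text=str(obj.get("text", "")),
            url=str(url) if url else None,
        )
    except (KeyError, TypeError, ValueError):
        return None


def _parse_location(obj: dict) -> LocationFix | None:
    try:
        lat = float(obj["lat"])
        lon = float(obj["lon"])
        ts = int(obj["timestamp"])
        if ts < 0 or not -90.0 <= lat <= 90.0 or not -180.0 <= lon <= 180.0:
            return None
        return LocationFix(str(obj["participant_id"]), ts, lat, lon)
    except (KeyError, TypeError, ValueError):
        return None


def _parse_survey(obj: dict) -> SurveyLabel | None:
    try:
        return SurveyLabel(
            participant_id=str(obj["participant_id"]),
            question_id=str(obj["question"]),
            value=str(obj["response"]),
        )
    except (KeyError, TypeError):
        return None


_PARSERS = {
    "keystroke": _parse_keystroke,
    "location": _parse_location,
    "survey": _parse_survey,
}


def _iter_raw(path: Path) -> Iterator[dict | None]:
    """Yield raw dicts from a JSONL or CSV log; None for an unparseable line."""
    if path.suffix.lower() == ".csv":
        with path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                yield row
    else:
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError:
                    yield None
                    continue
                yield obj if isinstance(obj, dict) else None


def read_event_log(path: str | Path, kind: LogKind) -> ReadResult:
    """Read a typed event log, sorted by (participant, timestamp).

    Malformed lines are skipped and counted in ``n_malformed``; records that
    parse but violate field invariants (negative timestamp, out-of-bounds
    coordinate, empty package) are counted in ``n_rejected``.  An unreadable
    file raises.
    """
    path = Path(path)
    if kind not in _PARSERS:
        raise ValueError(f"unknown log kind: {kind!r}")
    parse = _PARSERS[kind]
    records, n_bad, n_rej = [], 0, 0
    for obj in _iter_raw(path):
        if obj is None:
            n_bad += 1
            continue
        rec = parse(obj)
        if rec is None:
            n_rej += 1
            continue
        records.append(rec)
    if kind == "survey":
        records.sort(key=lambda r: (r.participant_id, r.question_id))
    else:
        records.sort(key=lambda r: (r.participant_id, r.timestamp))
    return ReadResult(records, n_malformed=n_bad, n_rejected=n_rej)


def write_event_log(records: Iterable, path: str | Path, kind: LogKind) -> None:
    """Write records as JSONL in the documented schema (lossless round-trip)."""
    path = Path(path)
    with path.open("w") as fh:
        for r in records:
            if kind == "keystroke":
                obj = {
                    "participant_id": r.participant_id,
                    "timestamp": r.timestamp,
                    "package": r.package,
                    "text": r.text,
                }
                if r.url:
                    obj["url"] = r.url
            elif kind == "location":
                obj = {
                    "participant_id": r.participant_id,
                    "timestamp": r.timestamp,
                    "lat": r.lat,
                    "lon": r.lon,
                }
            elif kind == "survey":
                obj = {
                    "participant_id": r.participant_id,
                    "question": r.question_id,
                    "response": r.value,
                }
            else:
                raise ValueError(f"unknown log kind: {kind!r}")
            fh.write(json.dumps(obj) + "\n")


def filter_min_days(
    events: Iterable[KeystrokeEvent], min_days: int = 30
) -> set[str]:
    """Participants with at least ``min_days`` distinct UTC days of data.

    A day counts if the participant produced at least one keystroke event on
    it.  The boundary is inclusive: exactly ``min_days`` distinct days keeps
    the participant.
    """
    days: dict[str, set[date]] = {}
    for ev in events:
        days.setdefault(ev.participant_id, set()).add(ev.day)
    return {pid for pid, d in days.items() if len(d) >= min_days}


def write_feature_matrix(rows: pd.DataFrame | dict, path: str | Path) -> None:
    """Write a per-participant feature matrix as CSV.

    Accepts a DataFrame indexed by participant id (or a mapping participant →
    {feature: value}).  Column names carry their feature-group prefix
    (``app.``, ``loc.``, ``word.``, ``risky.``, ``dict.``, ``emb.``).
    Missing features are written as empty cells.  Duplicate participant ids
    are a hard error.
    """
    if isinstance(rows, dict):
        rows = pd.DataFrame.from_dict(rows, orient="index")
    if rows.index.duplicated().any():
        dupes = rows.index[rows.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate participant_id(s): {dupes}")
    out = rows.sort_index()
    out = out[sorted(out.columns)]
    out.to_csv(path, index_label="participant_id")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature matrix written by :func:`write_feature_matrix`.

    Missing cells come back as NaN, the package-wide missing marker.
    """
    df = pd.read_csv(path, index_col="participant_id")
    df.index = df.index.astype(str)
    return df
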