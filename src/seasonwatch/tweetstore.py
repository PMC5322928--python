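"""Data model and I/O for tweet streams.

A *stream* is a sequence of :class:`TweetRecord` ordered by timestamp,
covering a declared :class:`CoveragePeriod`.  Records carry optional
manual-annotation fields (relevance to the target species, and whether a
relevant claim could be verified, e.g. from an attached photo).

Timestamps are stored and compared in UTC; calendar aggregation (weekly
counts, monthly strata) derives local dates only at aggregation time.
All date intervals in this package are half-open ``[start, end)`` unless
a type explicitly says otherwise.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "TweetRecord",
    "CoveragePeriod",
    "RELEVANCE_VALUES",
    "VERIFIABILITY_VALUES",
    "TweetParseError",
    "read_tweets",
    "write_tweets",
    "filter_period",
]

RELEVANCE_VALUES = ("relevant", "irrelevant")
VERIFIABILITY_VALUES = (
    "verifiable_true_positive",
    "verifiable_false_positive",
    "unverifiable",
)


class TweetParseError(ValueError):
    """A record on disk could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class TweetRecord:
    """One post: an id, a UTC timestamp, raw text, and optional annotations.

    ``verifiability`` may only be set when ``relevance`` is set: the
    verifiable / unverifiable distinction applies to tweets that were
    manually judged at all.
    """

    id: str
    timestamp: datetime
    text: str
    geotag: tuple[float, float] | None = None
    user_location: str | None = None
    relevance: str | None = None
    verifiability: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("tweet id must be non-empty")
        ts = self.timestamp
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        else:
            ts = ts.astimezone(timezone.utc)
        object.__setattr__(self, "timestamp", ts)
        if self.relevance is not None and self.relevance not in RELEVANCE_VALUES:
            raise ValueError(f"bad relevance {self.relevance!r}")
        if self.verifiability is not None:
            if self.relevance is None:
                raise ValueError("verifiability requires a relevance label")
            if self.verifiability not in VERIFIABILITY_VALUES:
                raise ValueError(f"bad verifiability {self.verifiability!r}")

    @property
    def date(self) -> date:
        return self.timestamp.date()


@dataclass(frozen=True)
class CoveragePeriod:
    """Declared capture period ``[start, end)`` with unreliable-capture gaps.

    Gaps mark intervals where the upstream collector could not reliably
    capture posts; weekly aggregation masks them rather than reading the
    zero counts as absence of the species.
    """

    start: date
    end: date
    gaps: tuple[tuple[date, date], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("coverage start must precede end")
        gaps = tuple(sorted((tuple(g) for g in self.gaps), key=lambda g: g[0]))
        for a, b in gaps:
            if not (self.start <= a < b <= self.end):
                raise ValueError(f"gap ({a}, {b}) outside coverage period")
        for (_, b1), (a2, _) in zip(gaps, gaps[1:]):
            if a2 < b1:
                raise ValueError("coverage gaps overlap")
        object.__setattr__(self, "gaps", gaps)

    def in_gap(self, day: date) -> bool:
        return any(a <= day < b for a, b in self.gaps)

    def contains(self, ts: datetime | date) -> bool:
        day = ts.date() if isinstance(ts, datetime) else ts
        return self.start <= day < self.end


_COLUMNS = [
    "id",
    "timestamp",
    "text",
    "lat",
    "lon",
    "user_location",
    "relevance",
    "verifiability",
]


def _parse_timestamp(raw: str, line: int) -> datetime:
    try:
        ts = datetime.fromisoformat(raw)
    except (ValueError, TypeError) as exc:
        raise TweetParseError(f"unparseable timestamp {raw!r}", line) from exc
    return ts if ts.tzinfo else ts.replace(tzinfo=timezone.utc)


def _record_from_mapping(obj: dict, line: int) -> TweetRecord:
    for key in ("id", "timestamp", "text"):
        if obj.get(key) in (None, ""):
            raise TweetParseError(f"missing required field {key!r}", line)
    lat, lon = obj.get("lat"), obj.get("lon")
    geotag = None
    if lat not in (None, "") and lon not in (None, ""):
        geotag = (float(lat), float(lon))
    try:
        return TweetRecord(
            id=str(obj["id"]),
            timestamp=_parse_timestamp(str(obj["timestamp"]), line),
            text=str(obj["text"]),
            geotag=geotag,
            user_location=obj.get("user_location") or None,
            relevance=obj.get("relevance") or None,
            verifiability=obj.get("verifiability") or None,
        )
    except ValueError as exc:
        raise TweetParseError(str(exc), line) from exc


def read_tweets(path: str | Path, format: str = "jsonl") -> list[TweetRecord]:
    """Read a tweet stream and return records sorted by timestamp.

    Malformed rows raise :class:`TweetParseError` with the offending line
    number; duplicate ids raise ``ValueError``.
    """
    path = Path(path)
    records: list[TweetRecord] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise TweetParseError(f"invalid JSON: {exc}", line_no) from exc
                records.append(_record_from_mapping(obj, line_no))
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for line_no, row in enumerate(reader, start=2):
                records.append(_record_from_mapping(row, line_no))
    else:
        raise ValueError(f"unknown format {format!r}")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate tweet id {rec.id!r}")
        seen.add(rec.id)
    records.sort(key=lambda r: (r.timestamp, r.id))
    return records


def _record_to_mapping(rec: TweetRecord) -> dict:
    return {
        "id": rec.id,
        "timestamp": rec.timestamp.isoformat(),
        "text": rec.text,
        "lat": rec.geotag[0] if rec.geotag else None,
        "lon": rec.geotag[1] if rec.geotag else None,
        "user_location": rec.user_location,
        "relevance": rec.relevance,
        "verifiability": rec.verifiability,
    }


def write_tweets(
    records: Iterable[TweetRecord], path: str | Path, format: str = "jsonl"
) -> None:
    """Write records so that :func:`read_tweets` round-trips them losslessly."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                obj = {k: v for k, v in _record_to_mapping(rec).items() if v is not None}
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_COLUMNS, quoting=csv.QUOTE_MINIMAL)
            writer.writeheader()
            for rec in records:
                row = _record_to_mapping(rec)
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
    else:
        raise ValueError(f"unknown format {format!r}")


def filter_period(
    records: Sequence[TweetRecord], start: date, end: date
) -> list[TweetRecord]:
    """Records with ``start <= timestamp.date() < end`` (half-open)."""
    if start > end:
        raise ValueError("start must not exceed end")
    return [r for r in records if start <= r.date < end]
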