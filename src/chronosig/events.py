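"""Event-stream ingestion and clock featurisation.

An *event stream* is one account's time-ordered posting record: absolute UTC
timestamps at one-second resolution plus a fixed per-account UTC offset in
minutes (the account's self-declared timezone; no DST database is consulted).
From a stream we derive the two timing features everything downstream runs on:

* the inter-event delay — seconds elapsed between consecutive events of the
  same account, floored at 1 s so that same-second events survive as a
  minimal positive gap; and
* the clock read-out — local hour of day (0-23) and ISO weekday (Mon=1) of
  each event, computed on ``t_utc + offset``.

Streams carry an optional class label (personal / managed / bot) used by the
classifier and the synthetic generator; unlabelled streams are legal inputs.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "TweetEvent",
    "EventStream",
    "DelaySeries",
    "ClockFeatures",
    "FilterReport",
    "ParseError",
    "MissingOffsetError",
    "parse_events",
    "write_events",
    "compute_delays",
    "clock_features",
    "filter_accounts",
]

LABELS = ("personal", "managed", "bot", "unlabelled")
#: maximum plausible timezone offset (UTC+14), minutes
MAX_OFFSET_MIN = 14 * 60
#: events retained per account (most recent), mirroring a typical crawl cap
DEFAULT_HISTORY_CAP = 800

SECONDS_PER_DAY = 86_400


class ParseError(ValueError):
    """A record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class MissingOffsetError(ValueError):
    """Raised when a clock feature is requested for an account without a
    known UTC offset; such accounts should be removed with
    :func:`filter_accounts` (``require_offset=True``)."""


@dataclass(frozen=True)
class TweetEvent:
    """A single timestamped post."""

    account_id: str
    t_utc: int  # POSIX seconds, integral (second resolution)
    utc_offset_min: int | None  # signed minutes, |offset| <= 840; None = unknown

    def __post_init__(self) -> None:
        if self.utc_offset_min is not None and abs(self.utc_offset_min) > MAX_OFFSET_MIN:
            raise ValueError(f"UTC offset {self.utc_offset_min} min outside +/-{MAX_OFFSET_MIN}")


@dataclass
class EventStream:
    """One account's ordered events plus its class label."""

    account_id: str
    label: str = "unlabelled"
    events: list[TweetEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        times = [e.t_utc for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("events must be sorted non-decreasing in t_utc")
        if any(e.account_id != self.account_id for e in self.events):
            raise ValueError("all events must share the stream's account_id")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def offset_missing(self) -> bool:
        return any(e.utc_offset_min is None for e in self.events)

    @property
    def times_utc(self) -> np.ndarray:
        return np.asarray([e.t_utc for e in self.events], dtype=np.int64)

    @property
    def offsets_min(self) -> np.ndarray:
        """Per-event offsets; raises if any is unknown."""
        if self.offset_missing:
            raise MissingOffsetError(
                f"account {self.account_id!r} has events without a UTC offset; "
                "drop it with filter_accounts(require_offset=True)"
            )
        return np.asarray([e.utc_offset_min for e in self.events], dtype=np.int64)


@dataclass
class DelaySeries:
    """Consecutive-event delays and the local hour preceding each delay."""

    delays: np.ndarray  # float seconds, >= 1
    preceding_hour: np.ndarray  # int 0-23, local hour of the earlier event

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.preceding_hour = np.asarray(self.preceding_hour, dtype=np.int64)
        if self.delays.shape != self.preceding_hour.shape:
            raise ValueError("delays and preceding_hour must be the same length")
        if len(self.delays) and self.delays.min() < 1:
            raise ValueError("delays must be >= 1 s (floor rule)")
        if len(self.preceding_hour) and (
            self.preceding_hour.min() < 0 or self.preceding_hour.max() > 23
        ):
            raise ValueError("preceding_hour must lie in [0, 23]")

    def __len__(self) -> int:
        return len(self.delays)


@dataclass
class ClockFeatures:
    """Per-event local-clock read-outs."""

    local_hour: np.ndarray  # int 0-23
    weekday: np.ndarray  # int 1-7, ISO (Monday=1)


@dataclass
class FilterReport:
    """Outcome of :func:`filter_accounts`."""

    kept: list[EventStream]
    discarded: dict[str, str]  # account_id -> reason


# ---------------------------------------------------------------------------
# parsing / writing

_COLUMNS = ("account_id", "label", "t_utc", "utc_offset_min")


def _parse_timestamp(raw, line: int) -> int:
    """ISO-8601 string or epoch number -> integral POSIX seconds."""
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        if float(raw) != int(raw):
            raise ParseError(f"timestamp {raw!r} not at second resolution", line)
        return int(raw)
    if isinstance(raw, str):
        text = raw.strip()
        try:
            return int(text)
        except ValueError:
            pass
        try:
            dt = datetime.fromisoformat(text.replace("Z", "+00:00"))
        except ValueError as exc:
            raise ParseError(f"malformed timestamp {raw!r}: {exc}", line) from None
        if dt.tzinfo is None:
            dt = dt.replace(tzinfo=timezone.utc)
        posix = dt.timestamp()
        if posix != int(posix):
            raise ParseError(f"timestamp {raw!r} not at second resolution", line)
        return int(posix)
    raise ParseError(f"malformed timestamp {raw!r}", line)


def _parse_offset(raw, line: int) -> int | None:
    if raw is None or raw == "" or (isinstance(raw, float) and np.isnan(raw)):
        return None
    try:
        value = int(raw)
    except (TypeError, ValueError):
        raise ParseError(f"malformed utc_offset_min {raw!r}", line) from None
    return value


def _iter_records(source, fmt: str | None) -> Iterator[tuple[int, dict]]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        if fmt is None:
            fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
        with open(path, newline="") as fh:
            if fmt == "csv":
                for i, row in enumerate(csv.DictReader(fh), start=2):
                    yield i, row
            else:
                for i, line in enumerate(fh, start=1):
                    if not line.strip():
                        continue
                    try:
                        yield i, json.loads(line)
                    except json.JSONDecodeError as exc:
                        raise ParseError(f"malformed JSON: {exc}", i) from None
    else:  # iterable of dicts
        for i, row in enumerate(source, start=1):
            yield i, row


def parse_events(
    source,
    fmt: str | None = None,
    history_cap: int | None = DEFAULT_HISTORY_CAP,
) -> list[EventStream]:
    """Read a cohort of event streams from JSON-lines, CSV, or dict records.

    Each record holds ``account_id``, ``t_utc`` (ISO-8601 or epoch seconds),
    ``utc_offset_min`` (may be null/empty) and an optional ``label``. Events
    are grouped by account and sorted by time; exact duplicate records are
    dropped with a warning; only the most recent ``history_cap`` events per
    account are retained.
    """
    by_account: dict[str, dict] = {}
    seen: set[tuple] = set()
    for line, rec in _iter_records(source, fmt):
        if "account_id" not in rec or rec["account_id"] in (None, ""):
            raise ParseError("missing account_id", line)
        if "t_utc" not in rec:
            raise ParseError("missing t_utc", line)
        account = str(rec["account_id"])
        t = _parse_timestamp(rec["t_utc"], line)
        offset = _parse_offset(rec.get("utc_offset_min"), line)
        label = rec.get("label") or "unlabelled"
        if label not in LABELS:
            raise ParseError(f"unknown label {label!r}", line)
        key = (account, t, offset, label)
        if key in seen:
            warnings.warn(f"duplicate record for account {account!r} at t={t} dropped")
            continue
        seen.add(key)
        entry = by_account.setdefault(account, {"label": label, "events": []})
        if label != "unlabelled":
            if entry["label"] not in ("unlabelled", label):
                raise ParseError(
                    f"conflicting labels for account {account!r}: "
                    f"{entry['label']} vs {label}",
                    line,
                )
            entry["label"] = label
        entry["events"].append(TweetEvent(account, t, offset))

    cohort = []
    for account, entry in by_account.items():
        events = sorted(entry["events"], key=lambda e: e.t_utc)
        if history_cap is not None and len(events) > history_cap:
            events = events[-history_cap:]
        cohort.append(EventStream(account, entry["label"], events))
    return cohort


def write_events(cohort: Sequence[EventStream], path, fmt: str | None = None) -> None:
    """Write a cohort back out, sorted by account_id then t_utc, in the same
    JSON-lines / CSV dialect :func:`parse_events` reads."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    rows = []
    for stream in sorted(cohort, key=lambda s: s.account_id):
        label = None if stream.label == "unlabelled" else stream.label
        for e in stream.events:
            rows.append(
                {
                    "account_id": stream.account_id,
                    "label": label,
                    "t_utc": datetime.fromtimestamp(e.t_utc, tz=timezone.utc).strftime(
                        "%Y-%m-%dT%H:%M:%S+00:00"
                    ),
                    "utc_offset_min": e.utc_offset_min,
                }
            )
    with open(path, "w", newline="") as fh:
        if fmt == "csv":
            writer = csv.DictWriter(fh, fieldnames=_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
        else:
            for row in rows:
                fh.write(json.dumps(row, sort_keys=False) + "\n")


# ---------------------------------------------------------------------------
# featurisation

def _local_seconds(stream: EventStream) -> np.ndarray:
    return stream.times_utc + 60 * stream.offsets_min


def compute_delays(stream: EventStream) -> DelaySeries:
    """Inter-event delays of one account, with the local hour of the event
    that *precedes* each delay.

    Zero gaps (same-second events) are floored to 1 s rather than dropped so
    the series keeps ``len(events) - 1`` entries.
    """
    if len(stream) < 2:
        raise ValueError(
            f"account {stream.account_id!r} has {len(stream)} event(s); "
            "need >= 2 to form a delay"
        )
    local = _local_seconds(stream)
    delays = np.maximum(np.diff(stream.times_utc).astype(float), 1.0)
    preceding_hour = (local[:-1] % SECONDS_PER_DAY) // 3600
    return DelaySeries(delays=delays, preceding_hour=preceding_hour)


def clock_features(stream: EventStream) -> ClockFeatures:
    """Local hour (0-23) and ISO weekday (Mon=1) per event."""
    local = _local_seconds(stream)  # raises MissingOffsetError if unknown
    hour = (local % SECONDS_PER_DAY) // 3600
    # POSIX day 0 (1970-01-01) was a Thursday, ISO weekday 4
    weekday = ((local // SECONDS_PER_DAY) + 3) % 7 + 1
    return ClockFeatures(local_hour=hour, weekday=weekday)


def filter_accounts(
    cohort: Iterable[EventStream],
    min_events: int = 2,
    require_offset: bool = True,
) -> FilterReport:
    """Drop accounts with too few events or (optionally) unknown timezone
    offsets, reporting which ids were discarded and why."""
    kept: list[EventStream] = []
    discarded: dict[str, str] = {}
    for stream in cohort:
        if len(stream) < min_events:
            discarded[stream.account_id] = f"fewer than {min_events} events"
        elif require_offset and (len(stream) == 0 or stream.offset_missing):
            discarded[stream.account_id] = "missing UTC offset"
        else:
            kept.append(stream)
    return FilterReport(kept=kept, discarded=discarded)
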