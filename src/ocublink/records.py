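"""Blink annotation data model and I/O.

A blink train is a sequence of timestamped events inside a fixed analysis
window (60 s by default), each flagged *complete* (cornea fully obscured at
blink completion, taken to renew and redistribute the tear film) or
*incomplete* (cornea partially visible, treated as not renewing it).

Two boundary policies are supported:

* ``pinned`` — the observed events themselves delimit the window; used for
  idealized patterns whose first and last blinks sit exactly at the window
  edges.
* ``assumed`` — a complete blink is assumed to occur 1 s before the window
  start and 1 s after its end (the −1 s / 61 s marks for a [0, 60] s
  window); realistic, since real first/last blinks rarely coincide with the
  segment edges.  The assumed delimiters bound interblink intervals and the
  exposure clock but are never counted as blinks, and because exposure is
  clipped to the window they can only *under*estimate exposure.

Event times are real-valued seconds; the per-second annotation grid
(:func:`grid_marks`) is a derived view, never the storage format.

File formats (UTF-8 text):

* annotation CSV — one row per blink event with columns
  ``participant_id, age_y, gender, condition, window_start_s,
  window_span_s, boundary_policy, time_s, complete``; a window with zero
  events is encoded by one sentinel row with empty ``time_s``/``complete``;
* annotation JSON — one object per recording with the same fields
  (schema shipped as ``data/annotation.schema.json``);
* TFBUT replicate CSV — ``participant_id, rep1_s, rep2_s, rep3_s``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .exposure import TearFilmParams

__all__ = [
    "ASSUMED_MARGIN_S",
    "AnnotationParseError",
    "ValidationError",
    "BoundaryPolicy",
    "Condition",
    "Gender",
    "BlinkEvent",
    "BlinkWindow",
    "Recording",
    "GridMarks",
    "read_annotations",
    "write_annotations",
    "read_tfbut_table",
    "write_tfbut_table",
    "select_analysis_window",
    "grid_marks",
    "annotation_schema",
]

#: Offset (s) of the assumed boundary blinks outside the analysis window.
ASSUMED_MARGIN_S = 1.0

_CSV_HEADER = [
    "participant_id",
    "age_y",
    "gender",
    "condition",
    "window_start_s",
    "window_span_s",
    "boundary_policy",
    "time_s",
    "complete",
]


class AnnotationParseError(ValueError):
    """A malformed annotation file row (message names the offending line)."""


class ValidationError(ValueError):
    """A structurally valid record violating a domain invariant."""


class BoundaryPolicy(str, Enum):
    PINNED = "pinned"
    ASSUMED = "assumed"


class Condition(str, Enum):
    BASELINE = "baseline"
    DISPLAY = "display"
    HARDCOPY = "hardcopy"


class Gender(str, Enum):
    M = "M"
    F = "F"


@dataclass(frozen=True, order=True)
class BlinkEvent:
    """A single blink: time in seconds plus a completeness flag."""

    time_s: float
    complete: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_s):
            raise ValidationError(f"blink time must be finite, got {self.time_s!r}")


@dataclass(frozen=True)
class BlinkWindow:
    """An analysis window with ordered blink events on its closed span.

    Events are counted on the CLOSED interval ``[start_s, end_s]``: a blink
    exactly at either edge belongs to the window.  Events must be strictly
    ascending in time; identical timestamps are rejected at ingest (lid
    twitches/tremors are an annotation-time exclusion, not a merge rule).
    """

    start_s: float = 0.0
    end_s: float = 60.0
    events: tuple[BlinkEvent, ...] = ()
    boundary_policy: BoundaryPolicy = BoundaryPolicy.ASSUMED

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "boundary_policy", BoundaryPolicy(self.boundary_policy))
        if not (math.isfinite(self.start_s) and math.isfinite(self.end_s)):
            raise ValidationError("window bounds must be finite")
        if self.end_s <= self.start_s:
            raise ValidationError(
                f"window span must be positive, got [{self.start_s}, {self.end_s}]"
            )
        prev = None
        for ev in self.events:
            if not isinstance(ev, BlinkEvent):
                raise ValidationError(f"expected BlinkEvent, got {type(ev).__name__}")
            if not (self.start_s <= ev.time_s <= self.end_s):
                raise ValidationError(
                    f"event at {ev.time_s} s outside window [{self.start_s}, {self.end_s}] s"
                )
            if prev is not None:
                if ev.time_s == prev:
                    raise ValidationError(f"duplicate event timestamp {ev.time_s} s")
                if ev.time_s < prev:
                    raise ValidationError("events must be sorted ascending by time")
            prev = ev.time_s

    @property
    def span_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def complete_times(self) -> tuple[float, ...]:
        return tuple(e.time_s for e in self.events if e.complete)

    @property
    def incomplete_times(self) -> tuple[float, ...]:
        return tuple(e.time_s for e in self.events if not e.complete)

    def shifted(self, offset_s: float) -> "BlinkWindow":
        """Translate the window and all events by ``offset_s``."""
        return replace(
            self,
            start_s=self.start_s + offset_s,
            end_s=self.end_s + offset_s,
            events=tuple(replace(e, time_s=e.time_s + offset_s) for e in self.events),
        )


@dataclass(frozen=True)
class Recording:
    """One participant/condition video capture with its annotated windows.

    ``duration_s`` defaults to the largest window end time.  ``tfbut``
    optionally references the participant's tear-film parameters.
    """

    participant_id: str
    condition: Condition
    windows: tuple[BlinkWindow, ...]
    age_y: int | None = None
    gender: Gender | None = None
    duration_s: float | None = None
    tfbut: "TearFilmParams | None" = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.gender is not None:
            object.__setattr__(self, "gender", Gender(self.gender))
        object.__setattr__(self, "windows", tuple(self.windows))
        if not self.windows:
            raise ValidationError("a recording needs at least one window")
        max_end = max(w.end_s for w in self.windows)
        if self.duration_s is None:
            object.__setattr__(self, "duration_s", max_end)
        elif self.duration_s < max(w.span_s for w in self.windows):
            raise ValidationError("recording shorter than one of its windows")


@dataclass(frozen=True)
class GridMarks:
    """Per-second annotation grid: (complete, incomplete) counts per square.

    Mirrors a manual counting grid in which a horizontal grating of 60
    one-second squares represents the minute and several blink events may be
    marked inside one square.  Purely a derived view of a
    :class:`BlinkWindow`.
    """

    bins: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", tuple((int(c), int(i)) for c, i in self.bins))
        if any(c < 0 or i < 0 for c, i in self.bins):
            raise ValidationError("grid counts must be non-negative")

    @property
    def total_complete(self) -> int:
        return sum(c for c, _ in self.bins)

    @property
    def total_incomplete(self) -> int:
        return sum(i for _, i in self.bins)


# ---------------------------------------------------------------------------
# Window selection and the per-second grid
# ---------------------------------------------------------------------------

def select_analysis_window(recording: Recording, span_s: float = 60.0) -> BlinkWindow:
    """Return the final ``span_s`` of a recording as the analysis window.

    The first part of each capture is discarded (it covers adaptation to the
    task); blinking is assessed on the last minute only.  Events are
    re-indexed to window-relative time, so the result always spans
    ``[0, span_s]``.  Events exactly on either cut are kept (closed span).
    """
    if recording.duration_s is None or recording.duration_s < span_s:
        raise ValidationError(
            f"recording too short: {recording.duration_s} s < {span_s} s"
        )
    cut = recording.duration_s - span_s
    events: list[BlinkEvent] = []
    policy = recording.windows[0].boundary_policy
    for w in recording.windows:
        events.extend(e for e in w.events if cut <= e.time_s <= recording.duration_s)
    events.sort(key=lambda e: e.time_s)
    return BlinkWindow(
        start_s=0.0,
        end_s=span_s,
        events=tuple(replace(e, time_s=e.time_s - cut) for e in events),
        boundary_policy=policy,
    )


def grid_marks(window: BlinkWindow, n_bins: int = 60) -> GridMarks:
    """Bin a 60 s window's events onto the per-second counting grid.

    Bin ``k`` collects events with ``floor(time_s - start_s) == k``; an
    event exactly at the closed upper edge goes to the last bin.
    """
    if not math.isclose(window.span_s, float(n_bins)):
        raise ValidationError(
            f"grid requires a {n_bins} s window, got span {window.span_s} s"
        )
    counts = [[0, 0] for _ in range(n_bins)]
    for ev in window.events:
        k = int(math.floor(ev.time_s - window.start_s))
        if k >= n_bins:  # closed upper edge
            k = n_bins - 1
        counts[k][0 if ev.complete else 1] += 1
    return GridMarks(bins=tuple((c, i) for c, i in counts))


# ---------------------------------------------------------------------------
# Annotation I/O (CSV and JSON)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # repr round-trips doubles exactly through float()
    return repr(float(x))


def read_annotations(path: str | Path) -> list[Recording]:
    """Read recordings from an annotation CSV or JSON file.

    The format is chosen by extension (``.json`` vs anything else = CSV).
    Events are validated and must be strictly increasing within each window;
    duplicate timestamps raise :class:`ValidationError`, malformed rows
    raise :class:`AnnotationParseError` naming the line.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_json(path)
    return _read_csv(path)


def write_annotations(recordings: Sequence[Recording], path: str | Path) -> Path:
    """Write recordings to CSV or JSON (by extension); returns the path.

    Round-trip identity: ``read_annotations(write_annotations(x))`` equals
    ``x`` for valid recordings (TFBUT references travel separately).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _write_json(recordings, path)
    return _write_csv(recordings, path)


def _read_csv(path: Path) -> list[Recording]:
    groups: dict[tuple, dict[tuple, list[BlinkEvent]]] = {}
    meta: dict[tuple, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise AnnotationParseError(f"{path}: empty file (header required)")
        missing = set(_CSV_HEADER) - set(reader.fieldnames)
        if missing:
            raise AnnotationParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                pid = row["participant_id"].strip()
                cond = Condition(row["condition"].strip())
                start = float(row["window_start_s"])
                span = float(row["window_span_s"])
                policy = BoundaryPolicy(row["boundary_policy"].strip())
                age = int(row["age_y"]) if row["age_y"].strip() else None
                gender = Gender(row["gender"].strip()) if row["gender"].strip() else None
            except (KeyError, ValueError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: malformed row ({exc})") from exc
            rkey = (pid, cond)
            wkey = (start, span, policy)
            meta.setdefault(rkey, {"age": age, "gender": gender})
            groups.setdefault(rkey, {}).setdefault(wkey, [])
            t_raw = row["time_s"].strip()
            if not t_raw:
                continue  # sentinel row: empty window
            try:
                t = float(t_raw)
                comp = {"1": True, "0": False}[row["complete"].strip()]
            except (KeyError, ValueError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if not (start <= t <= start + span):
                raise ValidationError(
                    f"{path}:{lineno}: event at {t} s outside window "
                    f"[{start}, {start + span}] s"
                )
            groups[rkey][wkey].append(BlinkEvent(time_s=t, complete=comp))
    recordings = []
    for rkey, windows in groups.items():
        pid, cond = rkey
        wins = []
        for (start, span, policy), events in windows.items():
            events.sort(key=lambda e: e.time_s)
            wins.append(
                BlinkWindow(
                    start_s=start, end_s=start + span,
                    events=tuple(events), boundary_policy=policy,
                )
            )
        recordings.append(
            Recording(
                participant_id=pid, condition=cond, windows=tuple(wins),
                age_y=meta[rkey]["age"], gender=meta[rkey]["gender"],
            )
        )
    return recordings


def _write_csv(recordings: Sequence[Recording], path: Path) -> Path:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for rec in recordings:
            base = [
                rec.participant_id,
                "" if rec.age_y is None else rec.age_y,
                "" if rec.gender is None else rec.gender.value,
                rec.condition.value,
            ]
            for w in rec.windows:
                wcols = [_fmt(w.start_s), _fmt(w.span_s), w.boundary_policy.value]
                if not w.events:
                    writer.writerow(base + wcols + ["", ""])
                for ev in w.events:
                    writer.writerow(base + wcols + [_fmt(ev.time_s), int(ev.complete)])
    return path


def _window_to_obj(w: BlinkWindow) -> dict:
    return {
        "start_s": w.start_s,
        "end_s": w.end_s,
        "boundary_policy": w.boundary_policy.value,
        "events": [{"time_s": e.time_s, "complete": e.complete} for e in w.events],
    }


def _write_json(recordings: Sequence[Recording], path: Path) -> Path:
    doc = {
        "recordings": [
            {
                "participant_id": r.participant_id,
                "age_y": r.age_y,
                "gender": None if r.gender is None else r.gender.value,
                "condition": r.condition.value,
                "duration_s": r.duration_s,
                "windows": [_window_to_obj(w) for w in r.windows],
            }
            for r in recordings
        ]
    }
    path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
    return path


def _read_json(path: Path) -> list[Recording]:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "recordings" not in doc:
        raise AnnotationParseError(f"{path}: top-level 'recordings' key required")
    recordings = []
    for i, obj in enumerate(doc["recordings"]):
        try:
            windows = tuple(
                BlinkWindow(
                    start_s=float(w["start_s"]),
                    end_s=float(w["end_s"]),
                    events=tuple(
                        BlinkEvent(time_s=float(e["time_s"]), complete=bool(e["complete"]))
                        for e in w["events"]
                    ),
                    boundary_policy=BoundaryPolicy(w["boundary_policy"]),
                )
                for w in obj["windows"]
            )
            recordings.append(
                Recording(
                    participant_id=str(obj["participant_id"]),
                    condition=Condition(obj["condition"]),
                    windows=windows,
                    age_y=obj.get("age_y"),
                    gender=None if obj.get("gender") is None else Gender(obj["gender"]),
                    duration_s=obj.get("duration_s"),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise AnnotationParseError(
                f"{path}: recordings[{i}] malformed ({exc})"
            ) from exc
    return recordings


def read_tfbut_table(path: str | Path) -> dict[str, tuple[float, float, float]]:
    """Read a TFBUT replicate CSV into ``{participant_id: (r1, r2, r3)}``."""
    path = Path(path)
    out: dict[str, tuple[float, float, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"participant_id", "rep1_s", "rep2_s", "rep3_s"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise AnnotationParseError(
                f"{path}: header must contain {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                out[row["participant_id"].strip()] = (
                    float(row["rep1_s"]), float(row["rep2_s"]), float(row["rep3_s"])
                )
            except (KeyError, ValueError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: malformed row ({exc})") from exc
    return out


def write_tfbut_table(
    replicates: Mapping[str, Iterable[float]], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "rep1_s", "rep2_s", "rep3_s"])
        for pid, reps in replicates.items():
            reps = list(reps)
            if len(reps) != 3:
                raise ValidationError(f"{pid}: exactly 3 TFBUT replicates required")
            writer.writerow([pid] + [_fmt(r) for r in reps])
    return path


def annotation_schema() -> dict:
    """Return the packaged JSON schema for the annotation document format."""
    schema_path = Path(__file__).parent / "data" / "annotation.schema.json"
    return json.loads(schema_path.read_text(encoding="utf-8"))
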