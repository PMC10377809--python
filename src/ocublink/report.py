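"""Participant/condition summary tables, condition deltas, timeline plots.

The summary layout mirrors the standard per-participant reporting format
for this kind of study: one row per participant carrying age, gender and
TFBUT, followed by a block of four metrics per experimental condition —
SEBR (blinks/min), incomplete blinks (%), blink regularity (CV of IBI, %)
and ocular exposure (% of window time, complete blinks only).  Percentages
are rounded to one decimal in emitted tables; full precision is retained
in the in-memory objects.

Condition comparison is descriptive only (per-participant and mean deltas,
reading − baseline); no hypothesis tests are computed.

A packaged reference pilot table (eight adults, three viewing conditions)
is shipped for regression-testing this layer.  Its metric values are
stored as printed in the original report — the underlying blink
timestamps were never published, so its exposure figures cannot be
recomputed from events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .records import (
    BlinkWindow,
    Condition,
    Gender,
    Recording,
    ValidationError,
    select_analysis_window,
)
from .metrics import blink_metrics
from .exposure import TearFilmParams, exposure_profile

__all__ = [
    "ConditionMetrics",
    "ConditionSummary",
    "summarize",
    "summaries_to_frame",
    "compare_conditions",
    "plot_timeline",
    "load_reference_pilot_table",
]

_METRIC_COLS = ("sebr", "incomplete_pct", "cv_pct", "exposure_pct")


@dataclass(frozen=True)
class ConditionMetrics:
    """The four reported metrics for one participant under one condition."""

    sebr: float
    incomplete_pct: float | None
    cv_pct: float | None
    exposure_pct: float | None


@dataclass(frozen=True)
class ConditionSummary:
    """One participant's summary row across experimental conditions."""

    participant_id: str
    age_y: int | None
    gender: Gender | None
    tfbut_s: float
    conditions: Mapping[Condition, ConditionMetrics]


def _analysis_window(recording: Recording) -> BlinkWindow:
    """The recording's 60 s analysis window (last minute if longer)."""
    if len(recording.windows) == 1 and math.isclose(recording.windows[0].span_s, 60.0):
        return recording.windows[0]
    return select_analysis_window(recording)


def summarize(
    recordings: Sequence[Recording],
    tfbut: Mapping[str, TearFilmParams],
) -> list[ConditionSummary]:
    """Per-participant summaries over all conditions present.

    Each recording contributes one condition block computed by running the
    blink metrics and the exposure model on its analysis window.  Every
    participant must have a TFBUT entry; a missing one raises an error
    naming the participant.  Undefined metrics (e.g. exposure for a pinned
    window with no complete blinks) propagate as ``None``.
    """
    by_pid: dict[str, dict] = {}
    for rec in recordings:
        if rec.participant_id not in tfbut:
            raise ValidationError(f"no TFBUT entry for participant {rec.participant_id!r}")
        tear = tfbut[rec.participant_id]
        window = _analysis_window(rec)
        m = blink_metrics(window)
        try:
            exp_pct = exposure_profile(window, tear).exposure_pct
        except ValidationError:
            exp_pct = None
        entry = by_pid.setdefault(
            rec.participant_id,
            {"age": rec.age_y, "gender": rec.gender, "tfbut": tear.tfbut_s, "conds": {}},
        )
        entry["conds"][rec.condition] = ConditionMetrics(
            sebr=m.sebr,
            incomplete_pct=m.incomplete_pct,
            cv_pct=m.cv_pct,
            exposure_pct=exp_pct,
        )
    return [
        ConditionSummary(
            participant_id=pid,
            age_y=e["age"],
            gender=e["gender"],
            tfbut_s=e["tfbut"],
            conditions=e["conds"],
        )
        for pid, e in by_pid.items()
    ]


def summaries_to_frame(
    summaries: Sequence[ConditionSummary], decimals: int = 1
) -> pd.DataFrame:
    """Flatten summaries to a wide table, percentages rounded to ``decimals``.

    Columns: ``participant_id, age_y, gender, tfbut_s`` then
    ``<condition>_<metric>`` for each condition present, metrics ordered
    SEBR, incomplete %, regularity CV %, exposure %.
    """
    conds = [c for c in Condition if any(c in s.conditions for s in summaries)]
    rows = []
    for s in summaries:
        row: dict = {
            "participant_id": s.participant_id,
            "age_y": s.age_y,
            "gender": None if s.gender is None else s.gender.value,
            "tfbut_s": s.tfbut_s,
        }
        for c in conds:
            cm = s.conditions.get(c)
            for col in _METRIC_COLS:
                val = None if cm is None else getattr(cm, col)
                if val is not None and col != "sebr":
                    val = round(val, decimals)
                row[f"{c.value}_{col}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def compare_conditions(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Descriptive deltas (reading condition − baseline) per participant.

    Returns a tidy frame with one row per participant × reading condition
    and columns ``d_sebr, d_incomplete_pct, d_cv_pct, d_exposure_pct``,
    plus one ``mean`` row per reading condition averaging the available
    per-participant deltas.  Raises when no participant has a baseline row.
    """
    have_baseline = [s for s in summaries if Condition.BASELINE in s.conditions]
    if not have_baseline:
        raise ValidationError("condition comparison needs at least one baseline row")
    rows = []
    for s in have_baseline:
        base = s.conditions[Condition.BASELINE]
        for cond in (Condition.DISPLAY, Condition.HARDCOPY):
            cm = s.conditions.get(cond)
            if cm is None:
                continue
            row = {"participant_id": s.participant_id, "condition": cond.value}
            for col in _METRIC_COLS:
                a, b = getattr(cm, col), getattr(base, col)
                row[f"d_{col}"] = None if a is None or b is None else a - b
            rows.append(row)
    if not rows:
        raise ValidationError("no reading-condition rows to compare against baseline")
    frame = pd.DataFrame(rows)
    means = (
        frame.drop(columns="participant_id")
        .groupby("condition", as_index=False)
        .mean(numeric_only=True)
    )
    means.insert(0, "participant_id", "mean")
    return pd.concat([frame, means], ignore_index=True)


def _draw_timeline(ax, window: BlinkWindow, tear: TearFilmParams) -> dict:
    """Draw marks and exposure shading onto ``ax``; return artist counts."""
    try:
        profile = exposure_profile(window, tear)
        spans = [
            (max(iv.from_s + tear.tfbut_s, window.start_s), min(iv.to_s, window.end_s))
            for iv in profile.intervals
            if iv.exposed_s > 0
        ]
    except ValidationError:
        spans = []
    for lo, hi in spans:
        ax.axvspan(lo, hi, color="0.82", zorder=0)
    for t in window.complete_times:
        ax.axvline(t, color="tab:blue", linestyle="-", lw=1.8, ymin=0.05, ymax=0.95)
    for t in window.incomplete_times:
        ax.axvline(t, color="tab:red", linestyle="--", lw=1.8, ymin=0.05, ymax=0.95)
    ax.set_xlim(window.start_s, window.end_s)
    ax.set_yticks([])
    ax.set_xlabel("time (s)")
    return {
        "complete_marks": len(window.complete_times),
        "incomplete_marks": len(window.incomplete_times),
        "shaded_spans": len(spans),
        "span_bounds": spans,
    }


def plot_timeline(
    window: BlinkWindow,
    tear: TearFilmParams,
    path: str | Path,
    title: str | None = None,
) -> Path:
    """Timeline figure: blink marks plus shaded ocular-exposure spans.

    Complete blinks are solid blue vertical segments, incomplete blinks
    dashed red ones; shaded grey bands mark the times when elapsed time
    since the last complete blink exceeds TFBUT.  Saved to ``path`` (format
    by extension).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 2.2))
    _draw_timeline(ax, window, tear)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    try:
        fig.savefig(path)
    finally:
        plt.close(fig)
    return path


def load_reference_pilot_table() -> pd.DataFrame:
    """The packaged reference pilot table (metrics stored as printed).

    Eight adults, three viewing conditions; per condition the columns are
    SEBR, incomplete %, regularity CV % and ocular exposure %.  Shipped for
    regression-testing the report layer only — the raw blink timestamps
    behind these rows were never published, so the exposure values are
    data, not something this package recomputes.  (One baseline cell
    records 0 incomplete blinks at 4 blinks/min; it is stored as printed.)
    """
    path = Path(__file__).parent / "data" / "pilot_reference_metrics.csv"
    return pd.read_csv(path)
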