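"""Synthetic blink trains and cohorts.

No public blink-annotation dataset exists for this kind of analysis (the
source recordings are videos of participants' eyes), so every pipeline
stage is exercised on generated event trains:

* the four canonical worked-example patterns (A–D) — regular/irregular ×
  complete/incomplete at fixed SEBR 6 blinks/min and mean IBI 12 s — as
  exact, deterministic fixtures;
* parametric generators for regular, jittered and clustered trains
  ("bursts and gaps" irregularity is modeled as bursts of tightly spaced
  blinks around uniformly drawn anchors, which is how irregular blinking
  presents in recordings: clusters of blinks separated by blink-free gaps);
* a cohort generator emulating a small reading study: per participant a
  TFBUT drawn once and shared across conditions (TFBUT is measured once at
  session start), and per condition a train whose rate, regularity and
  incomplete-blink probability are shifted by condition presets.  The
  default preset encodes the directions reading induces — lower SEBR,
  higher IBI variability — and a higher incomplete-blink probability on an
  electronic display than on hard copy; magnitudes are free parameters, not
  claims about any particular cohort.

All stochastic operations take an explicit seed; no global random state is
touched, and a fixed seed reproduces output exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .records import (
    BlinkEvent,
    BlinkWindow,
    BoundaryPolicy,
    Condition,
    Gender,
    Recording,
    ValidationError,
)

__all__ = [
    "TrainKind",
    "TrainSpec",
    "ConditionEffect",
    "CohortSpec",
    "default_condition_effects",
    "make_worked_examples",
    "generate_regular_train",
    "generate_jittered_train",
    "generate_clustered_train",
    "generate_train",
    "assign_completeness",
    "generate_cohort",
]

from enum import Enum


class TrainKind(str, Enum):
    REGULAR = "regular"
    JITTERED = "jittered"
    CLUSTERED = "clustered"


@dataclass(frozen=True)
class TrainSpec:
    """Parameters of one generated blink train.

    ``rate_bpm`` is the target event count per minute.  ``jitter_sd_s``
    applies to the jittered kind only; ``n_clusters`` and
    ``within_cluster_gap_s`` to the clustered kind only.
    """

    kind: TrainKind
    rate_bpm: float
    span_s: float = 60.0
    jitter_sd_s: float | None = None
    n_clusters: int | None = None
    within_cluster_gap_s: float | None = None
    incomplete_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", TrainKind(self.kind))
        if not 0.0 <= self.incomplete_prob <= 1.0:
            raise ValidationError("incomplete_prob must lie in [0, 1]")
        if self.span_s <= 0:
            raise ValidationError("span must be positive")


@dataclass(frozen=True)
class ConditionEffect:
    """How one experimental condition shifts the generated blink train."""

    rate_multiplier: float = 1.0
    incomplete_prob: float = 0.0
    cv_target_pct: float = 40.0

    def __post_init__(self) -> None:
        if self.rate_multiplier <= 0:
            raise ValidationError("rate multiplier must be positive")
        if not 0.0 <= self.incomplete_prob <= 1.0:
            raise ValidationError("incomplete_prob must lie in [0, 1]")
        if self.cv_target_pct < 0:
            raise ValidationError("CV target must be non-negative")


def default_condition_effects() -> dict[Condition, ConditionEffect]:
    """Default per-condition presets for the cohort generator.

    Directions follow what reading tasks do to blinking — roughly halved
    SEBR and noticeably higher IBI variability than quiet fixation — with
    electronic-display reading carrying a higher incomplete-blink
    probability than hard copy.  The baseline incomplete probability is set
    high (many people blink incompletely at rest); the magnitudes are
    package defaults, not population estimates.
    """
    return {
        Condition.BASELINE: ConditionEffect(1.0, incomplete_prob=0.38, cv_target_pct=55.0),
        Condition.DISPLAY: ConditionEffect(0.5, incomplete_prob=0.20, cv_target_pct=80.0),
        Condition.HARDCOPY: ConditionEffect(0.5, incomplete_prob=0.15, cv_target_pct=80.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """A simulated reading-study cohort.

    Defaults emulate a small adult pilot cohort: 8 participants aged
    29–74 y, baseline SEBR around 22 blinks/min (SD 8), TFBUT around 7 s
    (SD 3, one draw per participant), one 60 s assumed-policy window per
    condition.
    """

    n_participants: int = 8
    base_rate_mean_bpm: float = 22.0
    base_rate_sd_bpm: float = 8.0
    min_rate_bpm: float = 3.0
    tfbut_mean_s: float = 7.0
    tfbut_sd_s: float = 3.0
    min_tfbut_s: float = 1.0
    age_range_y: tuple[int, int] = (29, 74)
    span_s: float = 60.0
    effects: Mapping[Condition, ConditionEffect] = field(
        default_factory=default_condition_effects
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValidationError("n_participants must be non-negative")
        if self.base_rate_mean_bpm <= 0 or self.tfbut_mean_s <= 0:
            raise ValidationError("rate and TFBUT means must be positive")


# ---------------------------------------------------------------------------
# Fixed worked-example patterns
# ---------------------------------------------------------------------------

def make_worked_examples() -> dict[str, BlinkWindow]:
    """The four canonical 60 s blink patterns A–D (pinned policy).

    All four share SEBR = 6 blinks/min and mean IBI = 12 s:

    * **A** — regular, all complete: blinks at 0, 12, 24, 36, 48, 60 s;
    * **B** — as A, blinks at 24 s and 36 s incomplete;
    * **C** — irregular, all complete: blinks at 0, 6, 9, 51, 54, 60 s
      (IBIs 6, 3, 42, 3, 6 s);
    * **D** — as C, blinks at 9 s and 51 s incomplete
      (complete-only IBIs 6, 48, 6 s).
    """

    def win(times_incomplete: dict[float, bool]) -> BlinkWindow:
        return BlinkWindow(
            start_s=0.0,
            end_s=60.0,
            events=tuple(
                BlinkEvent(time_s=t, complete=not inc)
                for t, inc in sorted(times_incomplete.items())
            ),
            boundary_policy=BoundaryPolicy.PINNED,
        )

    regular = [0.0, 12.0, 24.0, 36.0, 48.0, 60.0]
    irregular = [0.0, 6.0, 9.0, 51.0, 54.0, 60.0]
    return {
        "A": win({t: False for t in regular}),
        "B": win({t: t in (24.0, 36.0) for t in regular}),
        "C": win({t: False for t in irregular}),
        "D": win({t: t in (9.0, 51.0) for t in irregular}),
    }


# ---------------------------------------------------------------------------
# Parametric generators
# ---------------------------------------------------------------------------

def generate_regular_train(rate_bpm: int, span_s: float = 60.0) -> BlinkWindow:
    """Deterministic pinned train: ``rate_bpm`` equally spaced complete blinks.

    Events sit at spacing ``span / (rate_bpm − 1)`` with the first at 0 and
    the last at ``span`` (so a 6 blinks/min train is the worked pattern A).
    """
    if int(rate_bpm) != rate_bpm or rate_bpm < 2:
        raise ValidationError("regular trains need an integer rate of at least 2")
    n = int(rate_bpm)
    times = np.linspace(0.0, span_s, n)
    return BlinkWindow(
        start_s=0.0,
        end_s=span_s,
        events=tuple(BlinkEvent(time_s=float(t)) for t in times),
        boundary_policy=BoundaryPolicy.PINNED,
    )


def _finalize_times(times: np.ndarray, span_s: float) -> tuple[float, ...]:
    """Sort, deduplicate and keep times inside [0, span]."""
    times = np.sort(times)
    times = times[(times >= 0.0) & (times <= span_s)]
    keep = np.concatenate(([True], np.diff(times) > 0))
    return tuple(float(t) for t in times[keep])


def generate_jittered_train(spec: TrainSpec) -> BlinkWindow:
    """Seeded quasi-regular train: an even grid plus Gaussian timing noise."""
    if spec.kind is not TrainKind.JITTERED:
        raise ValidationError(f"spec kind is {spec.kind.value}, expected jittered")
    if spec.jitter_sd_s is None or spec.jitter_sd_s < 0:
        raise ValidationError("jittered trains need a non-negative jitter_sd_s")
    if spec.seed is None:
        raise ValidationError("stochastic generators require a seed")
    n = max(2, round(spec.rate_bpm * spec.span_s / 60.0))
    rng = np.random.default_rng(spec.seed)
    grid = (np.arange(n) + 0.5) * spec.span_s / n
    times = grid + rng.normal(0.0, spec.jitter_sd_s, size=n)
    times = _finalize_times(times, spec.span_s)
    if len(times) < 1:
        raise ValidationError("jitter pushed every event outside the window")
    window = BlinkWindow(
        start_s=0.0,
        end_s=spec.span_s,
        events=tuple(BlinkEvent(time_s=t) for t in times),
        boundary_policy=BoundaryPolicy.ASSUMED,
    )
    return assign_completeness(window, spec.incomplete_prob, seed=rng)


def generate_clustered_train(spec: TrainSpec) -> BlinkWindow:
    """Seeded "bursts and gaps" train: clusters of tightly spaced blinks.

    ``n_clusters`` anchor times are drawn uniformly over the span; each
    cluster emits its share of the target event count as a burst at
    ``within_cluster_gap_s`` spacing starting at the anchor.  Events are
    sorted, deduplicated and restricted to the span.
    """
    if spec.kind is not TrainKind.CLUSTERED:
        raise ValidationError(f"spec kind is {spec.kind.value}, expected clustered")
    if spec.seed is None:
        raise ValidationError("stochastic generators require a seed")
    if not spec.n_clusters or spec.n_clusters < 1:
        raise ValidationError("clustered trains need n_clusters >= 1")
    gap = spec.within_cluster_gap_s
    if gap is None or gap <= 0:
        raise ValidationError("clustered trains need within_cluster_gap_s > 0")
    n_events = max(2, round(spec.rate_bpm * spec.span_s / 60.0))
    per, extra = divmod(n_events, spec.n_clusters)
    sizes = [per + (1 if k < extra else 0) for k in range(spec.n_clusters)]
    if (max(sizes) - 1) * gap > spec.span_s:
        raise ValidationError(
            "infeasible clustered spec: a single burst outlasts the window"
        )
    rng = np.random.default_rng(spec.seed)
    anchors = rng.uniform(0.0, spec.span_s, size=spec.n_clusters)
    times = np.concatenate(
        [a + gap * np.arange(size) for a, size in zip(anchors, sizes)]
    )
    times = _finalize_times(times, spec.span_s)
    if len(times) < 2:
        raise ValidationError("infeasible clustered spec: fewer than 2 resolvable events")
    window = BlinkWindow(
        start_s=0.0,
        end_s=spec.span_s,
        events=tuple(BlinkEvent(time_s=t) for t in times),
        boundary_policy=BoundaryPolicy.ASSUMED,
    )
    return assign_completeness(window, spec.incomplete_prob, seed=rng)


def generate_train(spec: TrainSpec) -> BlinkWindow:
    """Dispatch on ``spec.kind`` (regular trains ignore the seed)."""
    if spec.kind is TrainKind.REGULAR:
        window = generate_regular_train(int(spec.rate_bpm), spec.span_s)
        if spec.incomplete_prob:
            if spec.seed is None:
                raise ValidationError("incomplete labelling requires a seed")
            window = assign_completeness(window, spec.incomplete_prob, spec.seed)
        return window
    if spec.kind is TrainKind.JITTERED:
        return generate_jittered_train(spec)
    return generate_clustered_train(spec)


def assign_completeness(
    window: BlinkWindow,
    incomplete_prob: float,
    seed: int | np.random.Generator,
) -> BlinkWindow:
    """Independently flag each event incomplete with the given probability."""
    if not 0.0 <= incomplete_prob <= 1.0:
        raise ValidationError("incomplete_prob must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flags = rng.random(len(window.events)) >= incomplete_prob
    return replace(
        window,
        events=tuple(
            replace(e, complete=bool(f)) for e, f in zip(window.events, flags)
        ),
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    # redraw rather than clip, to avoid a point mass at the bound
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    return lower


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[Recording], dict[str, tuple[float, float, float]]]:
    """Simulate a reading-study cohort.

    Returns one :class:`Recording` per participant × condition (a single
    60 s assumed-policy window each) plus a TFBUT replicate table keyed by
    participant id.  TFBUT is drawn once per participant and shared across
    conditions; the three replicates are small perturbations around the
    participant's draw.  Per condition, the participant's base blink rate
    is scaled by the preset multiplier and the train is jittered to the
    preset CV target (jitter SD ≈ target × mean IBI / √2, the SD that a
    difference of two independent timing errors contributes per interval).
    """
    root = np.random.SeedSequence(spec.seed)
    recordings: list[Recording] = []
    tfbut_table: dict[str, tuple[float, float, float]] = {}
    conditions = list(spec.effects.keys())
    child_seeds = root.spawn(max(spec.n_participants, 1))
    for p in range(spec.n_participants):
        rng = np.random.default_rng(child_seeds[p])
        pid = f"S{p + 1:02d}"
        age = int(rng.integers(spec.age_range_y[0], spec.age_range_y[1] + 1))
        gender = Gender.M if rng.random() < 0.5 else Gender.F
        base_rate = _truncated_normal(
            rng, spec.base_rate_mean_bpm, spec.base_rate_sd_bpm, spec.min_rate_bpm
        )
        tfbut = _truncated_normal(rng, spec.tfbut_mean_s, spec.tfbut_sd_s, spec.min_tfbut_s)
        reps = tuple(
            float(max(spec.min_tfbut_s / 2, tfbut + rng.normal(0.0, 0.3)))
            for _ in range(3)
        )
        tfbut_table[pid] = reps  # type: ignore[assignment]
        for cond in conditions:
            eff = spec.effects[cond]
            rate = max(2.0, base_rate * eff.rate_multiplier)
            n = max(2, round(rate * spec.span_s / 60.0))
            mean_ibi = spec.span_s / n
            jitter = (eff.cv_target_pct / 100.0) * mean_ibi / math.sqrt(2.0)
            train = TrainSpec(
                kind=TrainKind.JITTERED,
                rate_bpm=rate,
                span_s=spec.span_s,
                jitter_sd_s=jitter,
                incomplete_prob=eff.incomplete_prob,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            window = generate_jittered_train(train)
            recordings.append(
                Recording(
                    participant_id=pid,
                    condition=cond,
                    windows=(window,),
                    age_y=age,
                    gender=gender,
                )
            )
    return recordings, tfbut_table
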