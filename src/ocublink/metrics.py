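"""Blink parameters from an analysis window.

Four quantities characterize a blink train:

* **SEBR** — spontaneous eyeblink rate, counted events per minute on the
  window's closed span (count × 60 / span);
* **incomplete-blink percentage** — 100 × incomplete / counted events;
* **interblink intervals (IBI)** — successive differences of the delimiting
  blink times under a stated *basis* (all blinks, or complete blinks only)
  and the window's boundary policy;
* **blink regularity** — the coefficient of variation of the IBI series,
  CV = 100 × SD/mean, with the *sample* (n−1) standard deviation.  CV below
  100 % denotes moderate-to-high regularity; 100 % and above denotes low
  regularity ("bursts and gaps" clustering).

Under the ``assumed`` boundary policy the IBI delimiters include the
synthetic complete blinks 1 s outside each window edge; those delimiters
never count toward SEBR or the incomplete percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence, Union

import numpy as np

from .records import ASSUMED_MARGIN_S, BlinkWindow, BoundaryPolicy, ValidationError

__all__ = [
    "Basis",
    "Regularity",
    "IBISeries",
    "BlinkMetrics",
    "count_sebr",
    "incomplete_fraction",
    "ibi_series",
    "regularity_cv",
    "classify_regularity",
    "blink_metrics",
]


class Basis(str, Enum):
    """Which blinks delimit interblink intervals."""

    ALL_BLINKS = "all_blinks"
    COMPLETE_ONLY = "complete_only"


class Regularity(str, Enum):
    REGULAR = "regular"
    IRREGULAR = "irregular"


@dataclass(frozen=True)
class IBISeries:
    """Ordered interblink intervals under a stated basis and boundary policy."""

    values_s: tuple[float, ...]
    basis: Basis
    boundary_policy: BoundaryPolicy

    def __post_init__(self) -> None:
        object.__setattr__(self, "values_s", tuple(float(v) for v in self.values_s))
        if any(v <= 0 for v in self.values_s):
            raise ValidationError("interblink intervals must be positive")

    def __len__(self) -> int:
        return len(self.values_s)

    @property
    def mean_s(self) -> float:
        if not self.values_s:
            raise ValidationError("mean IBI undefined for an empty series")
        return float(np.mean(self.values_s))


@dataclass(frozen=True)
class BlinkMetrics:
    """Bundle of per-window blink parameters (None = undefined, never 0)."""

    sebr: float
    incomplete_pct: float | None
    cv_pct: float | None
    mean_ibi_s: float | None


def delimiters(window: BlinkWindow, basis: Basis = Basis.ALL_BLINKS) -> tuple[float, ...]:
    """Blink times delimiting IBIs, including assumed boundary blinks.

    Under ``assumed`` policy the synthetic delimiters sit ``ASSUMED_MARGIN_S``
    outside the window edges and are always treated as complete, so they
    survive the ``complete_only`` filter.
    """
    basis = Basis(basis)
    if basis is Basis.COMPLETE_ONLY:
        times = list(window.complete_times)
    else:
        times = [e.time_s for e in window.events]
    if window.boundary_policy is BoundaryPolicy.ASSUMED:
        times = [window.start_s - ASSUMED_MARGIN_S, *times, window.end_s + ASSUMED_MARGIN_S]
    return tuple(times)


def count_sebr(window: BlinkWindow) -> float:
    """Spontaneous eyeblink rate: observed events per minute.

    Counts real annotated events on the closed span (a blink exactly at
    either window edge counts); assumed boundary blinks never count.  For
    non-60 s windows the count is rate-normalized to per-minute.
    """
    return len(window.events) * 60.0 / window.span_s


def incomplete_fraction(window: BlinkWindow) -> float:
    """Percentage of counted blinks that are incomplete (0–100).

    Undefined for a window with no events — raises rather than reporting 0,
    since "no blinks" and "all blinks complete" are different findings.
    """
    n = len(window.events)
    if n == 0:
        raise ValidationError("incomplete fraction undefined for an empty window")
    return 100.0 * len(window.incomplete_times) / n


def ibi_series(window: BlinkWindow, basis: Basis = Basis.ALL_BLINKS) -> IBISeries:
    """Interblink intervals: successive differences of the delimiting blinks."""
    basis = Basis(basis)
    delims = delimiters(window, basis)
    if len(delims) < 2:
        raise ValidationError(
            f"IBI undefined: fewer than 2 delimiting blinks under basis {basis.value}"
        )
    values = tuple(b - a for a, b in zip(delims, delims[1:]))
    return IBISeries(values_s=values, basis=basis, boundary_policy=window.boundary_policy)


def regularity_cv(ibis: Union[IBISeries, Sequence[float]]) -> float:
    """Blink regularity: CV of the IBI series in percent (sample SD, n−1)."""
    values = ibis.values_s if isinstance(ibis, IBISeries) else tuple(float(v) for v in ibis)
    if len(values) < 2:
        raise ValidationError("regularity CV requires at least 2 intervals")
    if any(v <= 0 for v in values):
        raise ValidationError("interblink intervals must be positive")
    arr = np.asarray(values, dtype=float)
    return 100.0 * float(np.std(arr, ddof=1)) / float(np.mean(arr))


def classify_regularity(cv_pct: float) -> Regularity:
    """Regular for CV < 100 %, irregular at 100 % and above."""
    if cv_pct < 0 or not math.isfinite(cv_pct):
        raise ValidationError(f"CV must be a finite non-negative percent, got {cv_pct}")
    return Regularity.REGULAR if cv_pct < 100.0 else Regularity.IRREGULAR


def blink_metrics(window: BlinkWindow) -> BlinkMetrics:
    """SEBR, incomplete %, regularity CV and mean IBI for one window.

    CV and mean IBI are computed on the all-blinks IBI series (regularity
    describes the timing of blink events regardless of amplitude).
    Components that are undefined for the window (too few events) are
    reported as ``None``, never silently as zeros.
    """
    sebr = count_sebr(window)
    try:
        inc = incomplete_fraction(window)
    except ValidationError:
        inc = None
    cv = mean_ibi = None
    try:
        series = ibi_series(window, Basis.ALL_BLINKS)
        mean_ibi = series.mean_s
        cv = regularity_cv(series)
    except ValidationError:
        pass
    return BlinkMetrics(sebr=sebr, incomplete_pct=inc, cv_pct=cv, mean_ibi_s=mean_ibi)
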