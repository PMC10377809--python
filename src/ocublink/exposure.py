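"""Ocular surface exposure from complete-blink intervals and TFBUT.

Model: a complete blink renews the tear film; after a complete blink at
time ``t`` the film holds for TFBUT seconds and the surface is *exposed*
from ``t + TFBUT`` until the next complete blink.  Incomplete blinks never
reset this clock.  TFBUT is taken as constant over the window.  Exposure is
accrued only inside the analysis window, so the assumed boundary blinks
(1 s outside each edge, under the ``assumed`` policy) can only shrink the
reported exposure, never inflate it.

Two protection indices are provided:

* ``OPI = TFBUT / <IBI>`` (dimensionless); values ≥ 1 indicate blinking
  outpaces tear-film break-up (a protected surface) — but the index is
  blind to blink regularity and completeness;
* ``OPI 2.0 = <% exposed ocular surface area> / <IBI>`` (%/s); the area
  series must be supplied by the caller (it requires fluorescein imaging),
  the package only evaluates the ratio.

TFBUT is measured in three replicates whose arithmetic mean is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .records import BlinkWindow, ValidationError
from .metrics import Basis, delimiters

__all__ = [
    "TearFilmParams",
    "ExposureInterval",
    "ExposureProfile",
    "OPIResult",
    "average_tfbut",
    "exposure_profile",
    "opi",
    "opi2",
]


@dataclass(frozen=True)
class TearFilmParams:
    """Tear film break-up time, optionally with its three replicates."""

    tfbut_s: float
    replicates_s: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tfbut_s) and self.tfbut_s > 0):
            raise ValidationError(f"TFBUT must be positive, got {self.tfbut_s}")
        if self.replicates_s is not None:
            reps = tuple(float(r) for r in self.replicates_s)
            object.__setattr__(self, "replicates_s", reps)
            if len(reps) != 3:
                raise ValidationError("exactly 3 TFBUT replicates required")
            if any(r <= 0 for r in reps):
                raise ValidationError("TFBUT replicates must be positive")
            if not math.isclose(self.tfbut_s, sum(reps) / 3.0, rel_tol=1e-9):
                raise ValidationError("tfbut_s must equal the replicate mean")


@dataclass(frozen=True)
class ExposureInterval:
    """Exposure accrued between two consecutive complete-blink delimiters."""

    from_s: float
    to_s: float
    exposed_s: float

    def __post_init__(self) -> None:
        if self.exposed_s < 0:
            raise ValidationError("exposure cannot be negative")
        if self.exposed_s > self.to_s - self.from_s + 1e-9:
            raise ValidationError("exposure exceeds its interval length")


@dataclass(frozen=True)
class ExposureProfile:
    """Per-interval and aggregate ocular surface exposure for one window."""

    intervals: tuple[ExposureInterval, ...]
    total_exposed_s: float
    exposure_pct: float
    window_span_s: float


@dataclass(frozen=True)
class OPIResult:
    """Ocular protection indices; ``opi2`` needs a user-supplied area mean."""

    opi: float
    opi2: float | None = None

    @property
    def protected(self) -> bool:
        """True when OPI ≥ 1: tear-film renewal outpaces break-up."""
        return self.opi >= 1.0


def average_tfbut(replicates_s: Sequence[float]) -> TearFilmParams:
    """Average three TFBUT replicate measurements (seconds)."""
    reps = tuple(float(r) for r in replicates_s)
    if len(reps) != 3:
        raise ValidationError(f"exactly 3 TFBUT replicates required, got {len(reps)}")
    if any(not math.isfinite(r) or r <= 0 for r in reps):
        raise ValidationError("TFBUT replicates must be positive and finite")
    return TearFilmParams(tfbut_s=sum(reps) / 3.0, replicates_s=reps)


def exposure_profile(window: BlinkWindow, tear: TearFilmParams) -> ExposureProfile:
    """Time-based ocular surface exposure over the analysis window.

    For each consecutive pair of complete-blink delimiters ``(t_i, t_{i+1})``
    — including the assumed −1 s / +1 s boundary delimiters under the
    ``assumed`` policy — exposure accrues over
    ``[t_i + TFBUT, t_{i+1}] ∩ [start, end]``.  ``exposure_pct`` is the
    accrued time as a percentage of the window span.
    """
    delims = delimiters(window, Basis.COMPLETE_ONLY)
    if len(delims) < 2:
        raise ValidationError(
            "exposure undefined: fewer than 2 complete-blink delimiters"
        )
    intervals = []
    total = 0.0
    for t0, t1 in zip(delims, delims[1:]):
        lo = max(t0 + tear.tfbut_s, window.start_s)
        hi = min(t1, window.end_s)
        exposed = max(0.0, hi - lo)
        total += exposed
        intervals.append(ExposureInterval(from_s=t0, to_s=t1, exposed_s=exposed))
    return ExposureProfile(
        intervals=tuple(intervals),
        total_exposed_s=total,
        exposure_pct=100.0 * total / window.span_s,
        window_span_s=window.span_s,
    )


def opi(tear: TearFilmParams, mean_ibi_s: float) -> float:
    """Ocular Protection Index: TFBUT / mean IBI (dimensionless)."""
    if not (math.isfinite(mean_ibi_s) and mean_ibi_s > 0):
        raise ValidationError(f"mean IBI must be positive, got {mean_ibi_s}")
    return tear.tfbut_s / mean_ibi_s


def opi2(mean_exposed_area_pct: float, mean_ibi_s: float) -> float:
    """OPI 2.0: mean exposed ocular-surface area (%) / mean IBI (s), in %/s.

    The exposed-area series comes from fluorescein imaging and must be
    supplied by the caller; only the ratio is evaluated here.
    """
    if not (0.0 <= mean_exposed_area_pct <= 100.0):
        raise ValidationError(
            f"exposed area must be a percentage in [0, 100], got {mean_exposed_area_pct}"
        )
    if not (math.isfinite(mean_ibi_s) and mean_ibi_s > 0):
        raise ValidationError(f"mean IBI must be positive, got {mean_ibi_s}")
    return mean_exposed_area_pct / mean_ibi_s
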