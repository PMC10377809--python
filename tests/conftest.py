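"""Shared fixtures: worked-example patterns, random windows, grid oracle."""

from __future__ import annotations

import numpy as np
import pytest

from ocublink import (
    ASSUMED_MARGIN_S,
    BlinkEvent,
    BlinkWindow,
    BoundaryPolicy,
    TearFilmParams,
    make_worked_examples,
)


@pytest.fixture(scope="session")
def patterns() -> dict[str, BlinkWindow]:
    """The four canonical worked-example blink patterns A–D."""
    return make_worked_examples()


@pytest.fixture(scope="session")
def tear10() -> TearFilmParams:
    return TearFilmParams(tfbut_s=10.0)


def random_assumed_window(rng: np.random.Generator, span_s: float = 60.0) -> BlinkWindow:
    """A random assumed-policy window with mixed complete/incomplete blinks."""
    n = int(rng.integers(0, 25))
    times = np.unique(np.round(rng.uniform(0.0, span_s, size=n), 4))
    complete = rng.random(len(times)) < 0.7
    return BlinkWindow(
        start_s=0.0,
        end_s=span_s,
        events=tuple(
            BlinkEvent(time_s=float(t), complete=bool(c))
            for t, c in zip(times, complete)
        ),
        boundary_policy=BoundaryPolicy.ASSUMED,
    )


def grid_exposure_s(window: BlinkWindow, tfbut_s: float, dt: float = 1e-3) -> float:
    """Brute-force exposure oracle on a uniform time grid.

    A grid midpoint counts as exposed iff the elapsed time since the last
    complete blink at or before it exceeds TFBUT.  This definition matches
    the interval model only under the ``assumed`` boundary policy (the
    assumed delimiters close off the region after the last observed blink),
    which is the policy every random test window uses.  Midpoint sampling
    makes the result exact up to one grid step per exposure-segment
    boundary.
    """
    comp = list(window.complete_times)
    if window.boundary_policy is BoundaryPolicy.ASSUMED:
        comp = [window.start_s - ASSUMED_MARGIN_S, *comp, window.end_s + ASSUMED_MARGIN_S]
    comp_arr = np.asarray(comp, dtype=float)
    n = int(round(window.span_s / dt))
    mids = window.start_s + dt * (np.arange(n) + 0.5)
    idx = np.searchsorted(comp_arr, mids, side="right") - 1
    exposed = np.zeros(n, dtype=bool)
    valid = idx >= 0
    exposed[valid] = (mids[valid] - comp_arr[idx[valid]]) > tfbut_s
    return float(dt * exposed.sum())
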