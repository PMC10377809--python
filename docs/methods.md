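# Methods

## The exposure model

`ocublink` treats the tear film as a binary covered/exposed clock. A
*complete* blink (cornea fully obscured at blink completion) renews the
tear film; TFBUT seconds later the film ruptures and the ocular surface is
exposed until the next complete blink. *Incomplete* blinks are transparent
to this clock — they are counted in the blink metrics but never reset
exposure. The possibility that an incomplete blink partially renews the
film over previously exposed cornea is deliberately not modeled, nor is
any growth law for the exposed *area* over time: exposure is a time
percentage, and OPI 2.0 is evaluated only as a ratio on a user-supplied
mean exposed-area percentage.

Assumptions worth stating explicitly:

- **TFBUT is constant over the window.** It is measured once per
  participant (three replicates, arithmetic mean) before the session and
  assumed stable and repeatable at every interblink interval.
- **Closed window span.** Events are counted on `[start, end]` inclusive:
  the idealized patterns place blinks at both the 0 s and 60 s marks and
  count 6 blinks, giving 5 intervals of 12 s. SEBR on a non-60 s window is
  rate-normalized to per-minute (count × 60 / span); this is an extension
  with a stated rule, since real analyses always use 60 s windows.
- **Assumed boundary blinks.** Under the `assumed` policy a complete blink
  is placed `ASSUMED_MARGIN_S = 1 s` outside each window edge (−1 s and
  61 s for a [0, 60] s window). These delimiters bound IBIs and the
  exposure clock but are never counted toward SEBR or the incomplete
  percentage. Because exposure only accrues inside the window, the
  assumption can only underestimate exposure — which is the conservative
  direction for a protection assessment, and requires the assumed blinks
  to be treated as complete (tear-film-resetting).
- **Regularity is computed on the all-blinks IBI series.** Regularity
  describes the *timing* of blink events regardless of amplitude; the
  irregular worked patterns have the same CV (140.3 %) whether or not two
  of their blinks are incomplete. The complete-only basis remains
  available through `ibi_series(window, Basis.COMPLETE_ONLY)` for
  sensitivity analyses.
- **Sample (n−1) standard deviation for the CV.** On the irregular
  worked-example series (6, 3, 42, 3, 6) s this yields 140.3 %; the
  population SD would yield 125.5 %. The sample convention is the one the
  140.3 % reference figure pins down, and tests enforce it.
- **CV = 100 % classifies as irregular.** "Under 100 %" defines the
  regular side; the boundary goes to the other class.
- Whether a real recording's published CV figures included the assumed
  boundary delimiters in the IBI series is not documented anywhere we
  know of; both variants are available (`boundary_policy`), and the
  default for real windows includes them.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| window span | s | 60 | analysis always on the last minute of a capture |
| `ASSUMED_MARGIN_S` | s | 1 | offset of the assumed boundary blinks |
| TFBUT | s | — | mean of exactly 3 positive replicates |
| regularity threshold | % | 100 | regular < 100 ≤ irregular |
| report rounding | — | 1 decimal (percentages), 2 (OPI) | full precision kept internally |

Annotation timestamps are arbitrary real seconds (60 fps video implies a
1/60 s granularity, but no grid is forced); the per-second counting grid
(`grid_marks`) is a derived view emulating a manual counting application,
never a storage format. Duplicate timestamps within a window are rejected
rather than merged — minor lid twitches are an annotation-time exclusion,
not a data-model state.

## Synthetic data

No raw blink-timestamp dataset is publicly available for this kind of
analysis, so the generators create what the pipeline needs:

- **Worked examples A–D** are exact fixtures (pinned policy): regular /
  regular-with-incomplete / clustered / clustered-with-incomplete at
  SEBR 6, ⟨IBI⟩ 12 s.
- **Regular trains**: `rate` equally spaced complete blinks pinned to the
  span; used for closed-form exposure checks and rate-recovery tests.
- **Jittered trains**: an even grid plus Gaussian timing noise (SD
  `jitter_sd_s`), sorted, deduplicated, restricted to the span; assumed
  policy.
- **Clustered trains**: "bursts and gaps" — `n_clusters` anchors drawn
  uniformly over the span, each emitting its share of the target event
  count at `within_cluster_gap_s` spacing. Chosen over a renewal process
  because irregular blinking presents in recordings as clusters separated
  by blink-free gaps, and these parameters are directly interpretable.
  The true distributional form of human IBI variability is unknown; this
  model is a stand-in for generating test conditions, not a claim about
  physiology.
- **Cohorts** (default: 8 participants aged 29–74, baseline SEBR
  ~N(22, 8²) blinks/min truncated at 3, TFBUT ~N(7, 3²) s truncated at 1,
  one 60 s assumed window per condition): TFBUT is drawn once per
  participant and shared across conditions, matching a design where TFBUT
  is measured once at session start. Condition presets encode effect
  *directions* — reading halves SEBR and raises the IBI CV target
  (55 → 80 %), with a higher incomplete-blink probability on an
  electronic display (0.20) than on hard copy (0.15) and a high baseline
  probability (0.38). Magnitudes are package defaults chosen to be
  realistic for small adult cohorts, not population estimates, and are
  all exposed on `CohortSpec`. The jitter SD for a CV target `c` is
  `c · ⟨IBI⟩ / √2`, since an IBI is a difference of two independent
  timing errors.

All stochastic operations require an explicit seed (numpy `default_rng` /
`SeedSequence.spawn`); no global state, and a fixed seed reproduces output
byte-identically.

What passing tests on synthetic data do **not** show: the generators
produce stationary, independently labelled trains. Real blinking is
non-stationary within a task, completeness is not independent of timing,
and examiner annotation carries its own error; results on real recordings
inherit those caveats.

## Numerical choices

- Exposure intervals are closed-form interval intersections (no
  discretization); the 1 ms time-grid simulation exists only as an
  independent test oracle, which agrees with the interval model up to one
  grid step per exposure-segment boundary.
- Undefined metrics propagate as missing (`None`), never as zeros: the
  incomplete percentage of an empty window and the CV of fewer than two
  intervals are undefined, and "no blinks" is a different finding from
  "all blinks complete".
- An event exactly at the closed upper window edge bins into the last grid
  square; grid binning conserves counts per completeness class.
- CSV round-trips write floats via `repr`, so annotations survive
  write→read bit-exactly.
- The packaged pilot reference table stores its metric values exactly as
  printed in the original report; they are regression data for the report
  layer, not recomputable (the underlying timestamps were never
  published). One of its baseline cells records 0 incomplete blinks at
  4 blinks/min and is stored as printed.

## Test and script problem sizes

The test suite runs the worked examples exactly, 500-window oracle
comparisons, an (n, L, TFBUT) closed-form grid, monotonicity sweeps, and
parameter recovery with a 10,000-event labelling and 50-participant
cohorts — sizes chosen so the whole suite completes in a few seconds while
keeping binomial error well inside the asserted tolerances.
`scripts/acceptance.py` is deterministic desk-scale arithmetic on the
worked examples.

## Known limitations

- Blink *durations* and waveforms are not modeled; amplitude is reduced to
  the binary complete/incomplete flag.
- No inferential statistics: condition comparisons are descriptive deltas.
- Exposure percentages at very low SEBR rest on few intervals; the
  incomplete percentage under strongly reduced SEBR should be interpreted
  with caution (small denominators), and no correction is applied.
- The OPI 2.0 area series must come from fluorescein imaging outside this
  package.
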