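# ocublink

Blink-train characterization and ocular surface exposure.

Blinking protects the eye by renewing and redistributing the tear film.
How well it protects depends on more than the **spontaneous eyeblink rate**
(SEBR, blinks/min): two blink trains with the same rate can leave the
ocular surface exposed for very different fractions of time depending on
how **regular** the blinking is and how many blinks are **incomplete**
(cornea still partly visible at blink completion, so the tear film is not
renewed). `ocublink` is for vision scientists and optometry researchers who
annotate blink events on one-minute video windows and want a complete,
reproducible characterization of that protection.

## Model

For an analysis window with blink times `t_1 < … < t_n` (each flagged
complete or incomplete) and a tear film break-up time `TFBUT` (mean of
three replicate measurements):

- **SEBR** = event count × 60 / window span (counted on the *closed* span,
  so blinks exactly at the window edges count);
- **incomplete blinks (%)** = 100 × incomplete / counted blinks;
- **interblink intervals (IBI)** = successive differences of the
  delimiting blinks under a chosen basis (all blinks, or complete only);
- **blink regularity** = CV of IBI = 100 × s / ⟨IBI⟩ with the sample
  (n−1) standard deviation `s`; CV < 100 % is classified *regular*,
  CV ≥ 100 % *irregular* (bursts-and-gaps blinking);
- **ocular surface exposure**: only a complete blink resets the tear-film
  clock; between consecutive complete-blink delimiters `(t_i, t_{i+1})`
  the surface is exposed over `[t_i + TFBUT, t_{i+1}]`, clipped to the
  window; exposure is reported as % of window time;
- **OPI** = TFBUT / ⟨IBI⟩ (≥ 1 ⇒ renewal outpaces break-up) and
  **OPI 2.0** = ⟨% exposed area⟩ / ⟨IBI⟩ (%/s) on a user-supplied
  exposed-area mean.

Real windows use the `assumed` boundary policy: a complete blink is
assumed 1 s before and after the window (the −1 s / 61 s marks), bounding
the IBIs without ever being counted as a blink; since exposure is clipped
to the window, the assumption can only *under*estimate exposure.

The package also ships a seeded synthetic generator (regular, jittered and
clustered trains; reading-study cohorts with condition presets), summary
and condition-delta tables, timeline plots, and a CLI.

## Worked example

The four canonical one-minute patterns A–D all share SEBR = 6 blinks/min,
⟨IBI⟩ = 12 s and TFBUT = 10 s — so the classical OPI cannot tell them
apart — yet their exposure differs almost four-fold:

```sh
ocublink examples --out-dir demo
cat demo/worked_examples_summary.csv
```

```text
pattern,tfbut_s,sebr,mean_ibi_s,opi,incomplete_pct,cv_pct,exposure_pct
A,10.0,6.0,12.0,0.83,0.0,0.0,16.7
B,10.0,6.0,12.0,0.83,33.3,0.0,50.0
C,10.0,6.0,12.0,0.83,0.0,140.3,53.3
D,10.0,6.0,12.0,0.83,33.3,140.3,63.3
```

A is regular and all-complete: the surface is exposed only for the last
2 s of each 12 s interval (16.7 % of the minute). B keeps the same timing
but two of six blinks are incomplete, stretching the complete-only
intervals to 12/36/12 s (50 % exposure). C blinks in bursts (IBIs
6, 3, 42, 3, 6 s; CV 140.3 %) and D combines both defects, the worst case
(63.3 %). The same pipeline is available from Python:

```python
import ocublink as ob

w = ob.make_worked_examples()["D"]
tear = ob.average_tfbut((10, 10, 10))
print(ob.blink_metrics(w))
print(ob.exposure_profile(w, tear).exposure_pct)   # 63.33…
```

Other subcommands: `metrics`, `exposure`, `report` and `plot` consume
annotation CSV/JSON plus a TFBUT replicate table (formats documented in
`ocublink.records`), and `simulate` generates a seeded synthetic cohort.

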