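# afdm — atrial-fibrillation driver mapping and outcome analysis

`afdm` is a tested, reusable implementation of the computational chain used
to characterize atrial-fibrillation (AF) drivers from multi-electrode
catheter electrograms and to link driver location to post-ablation outcome:

* **Rotational activity (RAc) detection.** Local activation times (LATs)
  are the instants of maximum negative slope of the unipolar electrograms.
  On the 5-spline × 4-electrode catheter the electrodes form four
  concentric rings; a rotation qualifies when the LATs of the rings form a
  monotone circular "staircase" whose span exceeds 50 % of the dominant
  cycle length (DCL), and ≥ 2 consecutive rotations of constant chirality
  make an RAc event. An automated surrogate of the expert review confirms
  an event when it has > 2 rotations and the electrical burden rises on an
  inner-ring bipole during the event.
* **Focal activity (FAc) detection.** A focal origin shows a monophasic
  negative (QS) unipolar morphology; the detector finds the earliest QS
  activation within a 10-mm radius and 50-ms window, and ≥ 2 consecutive
  beats from the same origin make an FAc event.
* **Electrical burden.** A fully unsupervised two-state Gaussian HMM on
  framed log-energy features scores each bipolar channel in [0, 1]: the
  fraction of the window decoded as electrically active.
* **Mesh atlas.** Patient left-atrial shells are centered at the origin,
  merged onto a reference shell by non-rigid ICP, voltage / cycle length /
  driver sites are projected onto the reference, the shell is segmented
  into 9 anatomical areas (LAA, PV antra at 1 cm of the ostia with the LAA
  ridge truncation, posterior, roof, lateral, septum, anterior, floor,
  mitral), and driver sites are classified inside/outside the wide-area
  circumferential PV isolation (WACPVI) line. Low-voltage area fractions
  use the 0.5 / 0.35 / 0.1 mV thresholds.
* **Cohort statistics.** Chi-square / Fisher contingency tests, Welch's
  t-test, proportion z-test, logistic odds ratios with Wald CIs, and
  1:1 greedy propensity-score matching with caliper and standardized-mean-
  difference diagnostics; recurrence is tabulated by RAc-location class
  (none / inside-only / outside the WACPVI).
* **Synthetic data.** Generators for catheter geometries, planar /
  rotational / focal activation fields, unipolar + bipolar electrograms,
  bursty bipolar channels with known activity duty cycle, synthetic left
  atria with planted regions / fibrosis patches / ablation lines, and
  confounded patient cohorts with a known recurrence odds ratio — every
  detector and statistic can be validated against ground truth.

The package is a library: import it from Python, or start from the
narrative scripts in `examples/`.

## Worked example

```python
import afdm

rotor = afdm.simulate_acquisition("rotational", seed=3, n_beats=6,
                                  cycle_length_ms=170, jitter_sd_ms=3,
                                  noise_sd_mv=0.05, duration_s=3.0)
lats = afdm.detect_lats(rotor)                 # max-negative-slope LATs
dcl = afdm.dominant_cycle_length(lats)         # median-of-medians DCL
events = afdm.detect_rac(rotor, lats, dcl)     # staircase-span rule
```

Running `python examples/01_simulate_and_detect_drivers.py` prints

```
rotor window: dominant cycle length 170.0 ms (generated 170.0)
RAc event: 6 rotations, chirality +1, duration 994 ms, rings (1, 2, 3, 4)
  confirmed: True (burden contrast 0.39)
FAc event: origin electrode 7, 6 beats, origin error 0.0 mm from the true source
planar window: 0 RAc events, 0 FAc events (both should be 0)
```

i.e. the detector recovers the generated rotor (6 rotations spanning
4/5 of each 170-ms cycle across all four rings, one event of ~6 cycles)
and the focal origin lands on the electrode over the source, while a plane
wave triggers neither detector. `examples/04_cohort_outcomes.py` reproduces
the outcome table of a published 85-patient persistent-AF cohort from its
printed counts:

```
AF/AT recurrence by RAc location (published cohort, n=79):
                n  recurrences  pct_display
none         29.0          9.0         31.0
inside_only   9.0          1.0         11.1
outside      41.0         26.0         63.4

RAc prevalence men vs women: chi-square 8.65, p = 0.003
```

Patients whose rotational drivers all sat inside the ablation line had the
lowest recurrence (11.1 %), and drivers outside the line carried the
highest (63.4 %).

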