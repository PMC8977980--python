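# Methods

This note documents the models and procedures implemented in `afdm`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show
about clinical recordings. Units are mm, ms and mV throughout; sample
indices are 0-based and times are reported in ms.

## Signal model and synthetic acquisitions

The mapping catheter has 5 equally spaced splines carrying 4 electrodes
each, forming 4 concentric rings (default radii 10/7/4/2 mm — nominal and
configurable, since the clinical catheter's exact spacing is not
standardized here). Unipolar electrograms are synthesized by placing one
deflection per activation:

* biphasic (RS) template: a derivative-of-Gaussian, positive then negative;
* QS template: a negative Gaussian, used on electrodes within a
  configurable radius (default 5 mm) of a focal source.

Both templates are positioned so their **maximum negative slope falls
exactly on the nominal LAT** (for the QS shape this means the nadir sits
one template-σ after the LAT). This is what makes the "detected LATs equal
generated LATs" invariant exact rather than offset by template internals.
Default template support is 10 ms (σ ≈ 1.7 ms), default sampling rate
1 kHz (clinical mapping-system convention), default additive white noise
0.05 mV against a 1-mV deflection. Bipolar channels are differences of
along-spline electrode pairs: external ring (1–2), (5–6), …, internal ring
(3–4), …, (19–20).

Activation fields:

* planar: `LAT = t0 + k·CL + (x·d̂)/v`
* focal: `LAT = t0 + k·CL + ‖x − s‖/v`
* rotational: `LAT = t0 + k·CL + ((χ·θ) mod 2π)/2π · CL`, θ the electrode
  azimuth about the core, χ = ±1 the chirality,

with i.i.d. Gaussian per-beat jitter and a refractory floor (default
50 ms) enforced per electrode. Fibrillatory irregularity is modeled by
this jitter only — no restitution or meander dynamics — so the rotors here
are *stationary and fully periodic*. Detector sensitivity measured on them
bounds what drifting clinical rotors would give from above.

The default focal source sits directly under a mid-catheter electrode
(electrode 7), the clinical acquisition geometry (catheter placed over the
focus). Sources between electrodes make "the" origin electrode ill-defined
at the electrode spacing.

## LAT detection and dominant cycle length

Candidate LATs are local minima of the first derivative (central
differences after a 15-sample moving average at 1 kHz) below an adaptive
negative floor, accepted greedily from the steepest down subject to a
refractory spacing (default 60 ms, below physiological atrial
refractoriness; ties broken by earlier time). Because smoothing flattens
the derivative minimum into a plateau, each accepted LAT is refined to the
steepest raw-derivative sample inside the smoothing window — this restores
±1-sample accuracy at the default noise level.

The slope floor is `k ×` a robust estimate of the derivative noise SD: the
median RMS over 50-ms frames of the derivative. The median is insensitive
to the minority of frames containing deflections and carries no selection
bias; `k = 4.5` covers the extreme-value growth of Gaussian noise over
10⁴–10⁵ samples per channel. Deflection slopes sit ≈ 18 σ above the noise
floor at default settings, so the margin costs no sensitivity; the
multiplier and an absolute floor are both configurable.

DCL is the median over electrodes of each electrode's median
inter-activation interval (electrodes with < 3 activations excluded, ≥ 3
electrodes required). The median-of-medians was chosen over a spectral
dominant-frequency estimate for robustness on short windows; the method
tag is recorded in the output.

## Rotational-activity detection

Beat windows are anchored on pooled external-ring LATs and span
`[anchor − 0.1·DCL, anchor + 0.9·DCL]`: a full rotation occupies at most
4/5 of the cycle, so each phase keeps a 0.1·DCL jitter margin to the
window edges while the neighbouring beats stay 0.2·DCL outside.

Per ring and beat, the five first-in-window LATs are ordered circularly;
a *staircase* requires the cyclic sequence to be monotone with exactly one
wrap (equivalently: exactly one cyclic descent), the monotone direction
giving the chirality. The span fraction is (max − min)/DCL. A rotation
qualifies when ≥ `rings_required` rings (default 4, the strictest reading
of the four-ring span rule; a pooled-LAT variant is available as a flagged
sensitivity alternative) are staircases of identical chirality with span
> 0.5. Maximal runs of ≥ 2 consecutive qualifying rotations with constant
chirality become events — a chirality reversal splits the event, because a
rotor has one handedness. Event boundaries run from the first LAT of the
first qualifying rotation to the last LAT of the last, so a noiseless
3-rotation rotor at CL 170 has duration 2·170 + 136 = 476 ms.

The expert visual confirmation of events is replaced by an automated
surrogate: confirmed iff > 2 rotations *and* the burden score inside the
event exceeds the outside-event score by ≥ 0.15 on at least one inner-ring
bipole (the "appearance of continuous activity" reviewers look for near a
pivot). Both raw and confirmed event sets are retained; an event whose
burden cannot be computed passes through flagged unconfirmed rather than
being dropped.

## Focal-activity detection

An activation is QS when, in a 40-ms window centered on the LAT, the
maximum positive excursion is strictly below 0.15 of the maximum negative
excursion (the morphology rule names no ratio; 0.15 cleanly separates the
two template families) and the negative excursion exceeds 5× the
MAD-estimated channel noise SD. A QS activation is an origin candidate if
no other QS activation within 10 mm precedes it by ≤ 50 ms. Candidates are
placed on a DCL-pitch beat grid; runs of ≥ 2 consecutive beats whose
origins drift ≤ 10 mm per beat form events (a missed intermediate beat
breaks the run — the strict reading of "consecutive"). The event origin is
the run's modal origin electrode, which is robust to single-beat timing
swaps among near-simultaneous neighbours.

## Electrical burden

Each bipolar channel is framed (50-ms frames, 25-ms hop — ≥ 3 frames per
AF cycle at ~170 ms) into `log(1e-12 + mean squared amplitude)` features.
A two-state Gaussian HMM is fitted by EM with 5 k-means-initialized
restarts (best final log-likelihood wins; persistent-state transition
prior 0.9; variances floored at 10⁻⁶ of the feature variance and flagged
when hit), the state path is decoded by Viterbi, and the score is the
fraction of frames in the higher-mean state. All of this is exposed as
configuration, and the result carries the fitted model for audit.

Two-state fits are meaningless on single-regime windows (all silence or
all activity): the state means collapse. When the fitted means are closer
than 1 nat the channel is classified whole by the **excess kurtosis of its
raw samples** (threshold 1.0): Gaussian noise has excess kurtosis ≈ 0
while an impulsive electrogram train is strongly heavy-tailed. This keeps
the score invariant to global amplitude rescaling — deliberately so, since
amplitude alone cannot distinguish quiet tissue from low-contact gain.

The burst generator lays out activity bursts (default 1 s) periodically to
hit a requested duty cycle; inside a burst, deflections arrive every
~30 ms so activity is effectively continuous at the frame scale, as in
fractionated driver-core electrograms. Its per-sample activity mask is the
oracle for the duty-cycle recovery experiments.

## Mesh atlas

Shells are pre-aligned by translating the vertex centroid to the origin.
Registration runs rigid Kabsch ICP first (closest-vertex correspondences),
then a non-rigid refinement: per iteration, every source vertex moves a
relaxed step (0.8) toward its closest point on the reference surface,
with the displacement field smoothed by a Gaussian kernel over the
original source vertices under a decreasing stiffness schedule (16, 8, 4,
2 mm; 5 iterations per stage). Wide kernels act almost rigidly, narrow
ones fit local shape; the schedule is configuration. Closest points on the
surface are computed exactly per triangle after a face-centroid KD-tree
preselection (k = 8). Residuals are RMS point-to-surface distances; the
registration reports per-stage RMS and a convergence flag.

Scalar projection maps each sample point to its nearest reference vertex,
averages multiple values per vertex, flags unobserved vertices and counts
points dropped beyond a maximum distance (default 10 mm) — so projection
conserves mass over accepted points by construction.

Geodesic distances are edge-graph shortest paths (Dijkstra), which
overestimate exact polyhedral geodesics by a few percent at these vertex
densities — acceptable for centimetre-scale anatomical rules, and declared
here rather than hidden. Segmentation assigns each vertex to the nearest
region seed set (the operator's landmark clicks) by geodesic distance,
then overrides the PV antra as the 1-cm geodesic band around the ostium
loops — geodesic, not Euclidean, because the rule lives on the surface —
except where the ridge toward the LAA truncates the left-superior antrum
(vertices geodesically closer to the LAA apex than to the LS ostium keep
their base label). The synthetic atrium plants its ground-truth regions
with the same rule *structure* but its own construction-side computation,
and stores the anchor clicks as landmarks; the recovery experiment
perturbs every click to a random neighbouring vertex and still requires
≥ 95 % vertex agreement. Manual segmentation is thus replaced by a
landmark-seeded automatic partition whose inputs a human can still
dictate.

Driver-location classification cuts the vertex graph along the ablation
line's vertices; components containing PV ostium vertices are "inside".
A site whose nearest vertex lies on the line counts as inside (on-line
tissue is presumed ablated), and a line that fails to separate the PVs
from the mitral rim is rejected as open. Patient-level classes are
none / inside-only / outside (outside if ≥ 1 site is outside).

Voltage metrics weight each vertex by one-third of its incident triangle
areas; low-voltage fractions are strictly-below at 0.5 / 0.35 / 0.1 mV
over observed area only.

## Synthetic atrium

An icosphere (the smallest subdivision meeting the requested vertex count:
642 / 2 562 / 10 242 vertices) scaled to a 35 × 28 × 25 mm ellipsoid, with
four tubular PV stubs (8 mm) on the postero-superior aspect, an LAA
protrusion (12 mm) antero-laterally and a mitral pole. Ostium loops are
the vertex bands at the stub bases; the WACPVI is attached as the two
boundary loops of vertex caps encircling the left and right PV pairs.
Fibrosis patches override the base voltage (default 1.0 mV) inside
spherical neighbourhoods; negative voltages are rejected.

## Synthetic cohorts and statistics

The cohort generator draws, per patient: gender (default 64 men /
21 women per draw unit), gender-specific confounders (age, hypertension,
CHA2DS2-VASc, BSA — women older, more hypertensive, higher score, smaller
BSA), atrial size, mean voltage and low-voltage fraction, RAc presence by
gender-specific prevalence (defaults 73.4 % / 38.1 %), an RAc-location
class (82 % of RAc patients have a site outside the line), and a binary
recurrence from an explicit logistic model

```
logit P = b0 + b_out·1[outside] + b_lvf·LVF + b_vol·(LAvol − 148)/39
```

with defaults b0 = −0.8, b_out = log 4, b_lvf = 1, b_vol = 0.3. Because
the coefficients are spec'd, odds-ratio recovery by the fitting stage is a
sharp test. Follow-up times average 357 days with a 5 % short-follow-up
fraction so the 90-day blanking exclusion (configurable) has something to
exclude.

Statistical conventions: Pearson chi-square without continuity correction
(this is what reproduces the printed p = 0.003 on the gender × RAc table;
the correction is reachable by configuration); Fisher's exact test for
2×2 tables with any expected cell < 5; Welch's t with
Welch–Satterthwaite df; pooled-SE proportion z-test; logistic ORs by
maximum likelihood with Wald 95 % CIs (the CI method is not dictated by
the problem; Wald is the default and separation is detected and reported,
with an L2-penalized fallback that declines to print a CI). Display
rounding is half-up to 1 decimal, matching printed-table conventions,
with full precision retained internally.

Propensity matching fits a logistic model of group membership, matches
1:1 greedy nearest-neighbour on the logit without replacement within a
caliper of 0.2 × SD(logit), processes treated in descending propensity
order, reports unmatched treated explicitly, and returns standardized mean
differences (SMD, pooled-SD denominator) before/after. A caveat the
experiments make explicit: with near-disjoint covariate support (the
defaults' BSA distributions are separated by ≈ 1.9 SMD, as in the
emulated population) *no* matching method can balance — half the treated
leave the common-support region unmatched and residual SMDs persist. The
balance experiment therefore uses a strongly confounded cohort with
overlapping support (pre-match SMDs 0.4–0.8), where the matched set's
SMDs fall below 0.1.

## Reference experiments and problem sizes

`afdm.evaluation` fixes the experiment conditions; the acceptance tests
and `scripts/acceptance.py` run them unchanged:

* **Printed-count statistics** — exact, from the encoded contingency
  counts of the published cohort (no simulation).
* **RAc detector** — 200 planar + 200 focal windows (10 beats, 2 s,
  default noise) for specificity; 200 rotors (4 beats, jitter SD 4 ms,
  alternating chirality) for sensitivity; 20 noiseless rotors (3–6
  rotations) for exact rotation counts. Windows are seconds long rather
  than the 30-s clinical default: the detectors are per-beat algorithms,
  so window length multiplies runtime without informing accuracy.
* **FAc origin** — 200 focal windows (6 beats, jitter SD 2 ms), recovery
  within one inter-electrode spacing (3 mm).
* **Burden** — duty cycles 0.1–0.9 × 20 seeds on 10-s channels (MAE vs
  the mask, monotone means), plus silence and continuous windows.
* **Registration** — 20 random smooth warps (≈ 4 mm) of a 642-vertex
  shell plus one random rigid transform.
* **Cohorts** — 100 draws of 640 patients with OR 4 (adjusted-fit CI
  coverage), one 10 000-patient confounded cohort for matching balance.

## Known limitations

* Rotors are stationary and periodic; no meander, wavebreak or
  electrogram fractionation beyond the optional core-activity overlay.
  Detector performance on synthetic data is an upper bound.
* The QS/RS dichotomy is a two-template world; intermediate clinical
  morphologies will land on the R/S-ratio threshold's slopes.
* Edge-graph geodesics and KD-tree closest-point preselection are
  approximate (few-percent distance inflation; k-nearest-face candidate
  sets), declared tolerances rather than exact geometry.
* The non-rigid ICP has no explicit topology or inversion guard; it is
  validated on smooth warps of the magnitude seen between centered atrial
  shells (≤ ~5 mm).
* The cohort generator draws independent covariates within gender; it
  emulates marginal structure and a known outcome model, not the joint
  correlation structure of a clinical population.
* Vendor export formats are not parsed; acquisition bundles use the
  package's documented open directory layout.
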