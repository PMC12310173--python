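# Methods

This note documents the models, detector rules, numerical choices and
limitations of `respiradar`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic world

### Breathing signal

Resting respiration is modeled as concatenated raised-cosine breaths:
breath *k* has period `T_k ~ N(60/rate, (jitter·60/rate)^2)` (clipped to
0.4–2.5× the mean) and peak displacement `A_k ~ N(A, (cv·A)^2)` clipped to
(0.05·A, 12 mm]; within the breath, `d(t) = A_k (1 − cos 2πu)/2`. The
raised cosine is smooth, strictly peak-detectable, and keeps displacement
inside the physiological 1–12 mm chest-excursion range. Defaults: 15
breaths/min, 5 mm, 5% rate and 10% amplitude coefficients of variation;
sampling 20 Hz (≥10× the breathing frequency — the hardware rate is not
public, so this is an assumption, not an inference).

### Events and periodic breathing

An apnea or hypopnea is a multiplicative gate on the breath envelope:
`depth` inside the event window (apnea ≤ 0.05, hypopnea 0.1–0.7; generator
defaults draw 0–0.04 and 0.25–0.55), with 2-s cosine tapers just inside
each edge so the detector sees no step discontinuities. Durations ≥ 10 s
by construction (the clinical scoring minimum).

A periodic-breathing episode of `n ≥ 3` cycles alternates an apneic phase
(residual envelope 2%, default 40% of the cycle) with a ventilatory
half-sine-squared hump peaking at 1.3× baseline — the hyperpneic overshoot
that defines crescendo–decrescendo breathing. The final hump is floored by
a linear rise back to baseline so the episode terminates in normal
breathing rather than silence (otherwise the tail mimics one extra
spurious hypopnea).

### Radar channel

CW radar phase is `φ(t) = 4π d(t)/λ + φ0` with `λ = 12.5 mm` (24 GHz);
I/Q are `cos φ, sin φ` plus independent white Gaussian noise (default sd
0.02) and a 0.02-Hz sinusoidal additive drift (default amplitude 0.05)
standing in for front-end baseline wander. The paper does not describe its
noise floor; these are conservative desk-scale choices.

### Nights

`NightSpec` assembles a full recording: epoch-aligned wake blocks
(irregular breathing — 40%/50% jitter — plus aperiodic band-limited motion
noise of 2.5 mm RMS), optional off-bed blocks (sensor noise only, 0.02 mm),
events placed in evenly-spaced jittered slots so the realized count equals
`round(rate × TST)`, and PB episodes placed away from isolated events.
Truth (event list, episode list, per-epoch stages) is returned verbatim.

What the generator does **not** emulate: body-position changes, two-person
or pet clutter, cardiac micro-motion (0.1–0.5 mm), RF multipath, and
obstructive-vs-central event morphology (the modeled radar cannot
distinguish them either). A green detection test therefore establishes
correctness of the algorithmic chain against this idealized world, not
clinical performance.

### Cohorts

Each patient carries latent RDI and PB cycle length drawn from per-group
distributions (impaired-LVEF group: RDI 44.13 ± 20.76 events/h; preserved:
31.91 ± 20.74; PB is zero-inflated with prevalence × mean-given-present =
33.21 s and 14.72 s respectively — the printed group means are far below
any physiological cycle length, which forces the zero-inflation reading).
Echo measures and NT-proBNP follow linear-Gaussian links whose
coefficients default to the reported adjusted effects; LVEF uses intercept
75, β_RDI = −0.22, β_PB = −0.21, small age/sex/BMI terms and noise sd 8,
giving a realistic mean near 55% and roughly one third of patients below
the 50% threshold.

Two deliberate structural choices:

* **Exposure independence.** RDI and PB group-components are assigned
  independently per patient, so their marginal association arises only
  through LVEF. The reference analysis fits one exposure at a time; had
  the generator correlated the exposures, those single-exposure fits
  would be biased by the omitted variable and could not recover the
  injected coefficients.
* **Two grouping modes.** Default: the group label is the generated LVEF
  thresholded at 50% (sizes 25/47 are mixture counts, so realized label
  counts fluctuate realistically). For odds-ratio recovery studies the
  `logistic` mode draws membership from a logit containing the RDI term
  (log 1.04 per event/h) plus age/sex/BMI; PB is excluded from that logit
  because an independent omitted PB term would attenuate the recovered
  RDI odds ratio through non-collapsibility.

NT-proBNP is generated for a configurable patient fraction (default 33/72)
to mirror subgroup-only biomarker availability; the Gaussian link can
produce negative concentrations, which are retained unclipped so that
coefficient recovery stays exact (a known unrealism).

## 2. Detection chain

### Demodulation and filtering

DC offsets of the I/Q constellation are removed with an algebraic (Kåsa)
least-squares circle fit — exact for noise-free arcs, and the standard
remedy when channel means are biased by partial-arc trajectories. Phase is
`unwrap(atan2)`, scaled by `λ/4π`; unwrapping matters because 12-mm
excursions approach λ/2 = 6.25 mm. Respiration is isolated with a
zero-phase 4th-order Butterworth band-pass, 0.1–0.8 Hz (6–48 breaths/min,
no phase distortion of envelope timing). Epochs are fixed 30-s windows;
a trailing partial epoch is dropped.

### Breath features

Peaks/valleys come from prominence (0.3 mm) and separation (1.5 s) gated
extremum detection with alternation enforced (the more extreme of two
same-type neighbours survives). Per-breath amplitude is peak minus the
mean of its flanking valleys, robust to residual drift. Sample entropy is
SampEn(m=2, r=0.2·sd), Chebyshev distance, matches `<= r`, self-matches
excluded; degenerate conventions — 0 for constant/short series or no
m-template match, `ln B` (the counting ceiling) when only the (m+1)-level
fails — keep every feature finite. Epochs with fewer than two breaths emit
an all-zero sentinel vector so the classifier input is total. The 9-column
feature schema is fixed in `FEATURE_NAMES`.

### Event rules

The scorer works on a smoothed Hilbert-magnitude envelope, block-averaged
to a 0.5-s grid, divided by a trailing 120-s median of provisionally
normal (≥ 70% of global median) envelope — events cannot drag their own
baseline down. Scoring: a run below 70% of baseline is an event core;
cores separated only by envelope below 90% merge (threshold flicker of
shallow hypopneas); a span qualifies if it spends ≥ 6 s below 70% and its
corrected duration is ≥ 10 s; it is an apnea when a sub-stretch below 10%
reaches 10 s after correction. Design notes:

* The envelope is Hilbert-based rather than interpolated per-breath
  amplitudes: inside an apnea there are no breaths, so amplitude
  interpolation bridges straight across the event and is blind to it.
* Threshold crossings on a cosine edge land `u* = (edge/π)·
  arccos(2(θ−depth)/(1−depth) − 1)` seconds inside the true boundary;
  detected boundaries are back-corrected by this amount (edge = 2 s for
  the 70% crossing; 4 s for the 10% crossing, where band-pass/Hilbert
  transition smear dominates). After correction, mean onset and duration
  errors on synthetic nights are below 0.5 s; individual errors up to one
  breath period (~4 s) remain — envelope scoring cannot localize a
  boundary more finely than the breath quantization, which is why the
  matching tests assert near-zero mean bias and ±4 s/±6 s worst-case
  rather than ±2 s per event.
* Thresholds are AASM-style flow-reduction rules transplanted to
  displacement, without a desaturation criterion (no oximeter).

The detector is exactly equivalent to an exhaustive window-scan oracle on
the same envelope-ratio grid (verified on 100 seeded signals).

### Sleep staging

Per epoch: off-bed if RMS < 0.08 mm; wake if breathing is continuous
(≥ 5 intervals, none > 8 s) but irregular (median absolute successive
interval difference > 15% of the epoch's median breath period) or if RMS
exceeds 1.5× the in-bed night median (gross motion). The continuity gate
is what keeps apnea epochs — whose signature is one long gap, not many
irregular intervals — scored as sleep. TST = 30 s × sleep epochs;
efficiency = 100 × TST / in-bed time; the three labels partition the
recording exactly. Events are counted toward the RDI only when their
midpoint lies in a sleep epoch, per scoring convention.

### DNDT classifier

The deep neural decision tree soft-bins each feature with a
temperature-softmax over learned cut-points (3 cuts → 4 bins, τ = 0.1),
forms leaf membership as the Kronecker product of bin memberships, and
maps leaves linearly to class logits. Because the full product over 9
features would have 4⁹ leaves, features are partitioned into groups of ≤ 3
with one soft tree per group and averaged logits — the same device the
DNDT literature uses for wide inputs. All parameters (cut-points, leaf
weights, bias) are trained jointly by full-batch Adam (lr 0.05, 500 steps)
on cross-entropy with hand-derived gradients; cut-points initialize at
within-feature quantiles; everything is deterministic under the seed and
serializes to a single JSON document. On the 5,000-epoch synthetic corpus
the held-out accuracy is recomputed by the acceptance script (well above
the 75% benchmark bound; the synthetic separation is easier than real
ward data, so that margin should not be read clinically).

### Periodic breathing

Consecutive events chain into an episode when each ventilatory gap passes
a crescendo–decrescendo test — after adaptive smoothing (window = gap/6,
capped at 5 s) a single interior maximum, near-monotone flanks (10%
tolerance), and edges below 85% of the peak — and is no longer than
min(90 s, 2× the flanking event durations): within periodic breathing the
ventilatory phase is short relative to its events, while isolated events
sit in long flat gaps. Chains need ≥ 3 cycles. Cycle *i* spans event *i*'s
onset to event *i+1*'s onset; because detected event boundaries swallow
the sub-70% hump flanks symmetrically, onset-to-onset differences recover
the injected cycle length almost exactly. Two corrections keep the ends
honest: the first event of an episode lacks the preceding-hump flank
advance, compensated by the interior-vs-first event-duration difference;
and the final cycle's ventilatory end (envelope trough after the last
hump, with a median-of-previous fallback) must respect the episode's own
periodicity (±50% of the median cycle), as must end cycles generally
(aperiodic end cycles are pruned as chained-on unrelated events).
Nightly index: mean cycle length over all cycles of all episodes, 0 when
none (config-switchable to per-episode means); patient index: arithmetic
mean over available nights.

## 3. Statistics

Numeric group comparisons use the Mann-Whitney U test — full permutation
enumeration with midranks when combined n ≤ 12, otherwise the normal
approximation with tie correction; categorical variables use Fisher's
exact test (tables wider than 2×2 are collapsed to top-level-vs-rest).
Associations are OLS with t-based 95% CIs and maximum-likelihood logistic
regression with Wald CIs on the log-odds scale, each adjusted for age, sex
(single male indicator; female is the reference level) and BMI, one
exposure at a time; complete or quasi-separation (unbounded Wald SE)
raises a structured error rather than an estimate. No multiple-testing
correction is applied, matching per-model reporting. The NT-proBNP
subgroup is the non-missing-biomarker subset, reported with its own n.

Monte-Carlo tolerances in the acceptance tests are 3 standard errors of
the replicate mean, computed from the replicates themselves.

## 4. Known limitations

* Synthetic wake/motion is far cleaner than real actigraphy; staging
  thresholds are calibrated to this world and config-exposed.
* Event-kind labels (apnea vs hypopnea) agree with truth ~90% of the
  time; short apneas whose deep-crossing correction still falls short of
  10 s are labeled hypopnea. The RDI counts both, so the indices are
  unaffected.
* The PB gap-to-event-duration constraint is tuned to envelope-detected
  boundaries; a detector with different boundary conventions would need
  the multiplier revisited.
* EDF I/O is not provided (no EDF library in the target environment);
  waveforms travel as 2-column CSV, radar I/Q as 3-column CSV, everything
  else as JSON/TSV.
* Logistic ML estimates carry the usual O(1/n) away-from-null bias;
  at n = 500 it is an order of magnitude below the Monte-Carlo tolerance.
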