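# Methods

## The measurement and the estimand

Transcranial Doppler insonation of the middle cerebral artery yields a
velocity envelope MCAv(t) in cm/s, a surrogate for cerebral blood flow under
the assumption of constant vessel diameter. During a continuous 7.5-min bout
(90 s seated rest, then 6 min of moderate-intensity exercise) the quantity of
interest per hemisphere is the cerebrovascular response

    CVR = mean MCAv over [180, 270) s  −  mean MCAv over [0, 90) s

together with its baseline-normalized form %ΔMCAv = 100·CVR/MCAv_rest.
The steady-state window is anchored to the *recording* clock (minutes 3–4.5
of the recording, i.e. 90–180 s into exercise); the alternative anchoring to
exercise time was rejected because the rest period is indexed as the first
90 s of the same continuous recording. Windows are half-open so no sample is
counted twice. Group inference compares subjects with HbA1c > 7% at the time
of acute stroke against those ≤ 7% (a value of exactly 7.0 goes to the
controlled group; the guideline split defines only "<7%" and ">7%" and the
boundary case is a documented convention).

## Preprocessing model

Analysis is per cardiac cycle. Beat onsets are an input channel (beat
detection from ECG is out of scope); each inter-onset interval contributes
its RR, time-averaged velocity, and peak velocity.

Censoring rules, both strict inequalities:

* **RR implausibility** — instantaneous cardiac frequency 1/RR > 5 Hz
  (RR < 0.2 s, i.e. > 300 bpm, physiologically impossible; the rule as
  usually printed, "RR intervals > 5 Hz", is dimensionally inconsistent and
  this reading is the only coherent one).
* **Velocity jump** — change in peak velocity > 10 cm/s within a single
  cardiac cycle. The comparison is against the most recent *accepted* peak:
  a censored cycle does not become the next cycle's reference. This makes a
  single spiked cycle censor exactly one cycle instead of two, at the cost
  that a genuine step change > 10 cm/s cascades until the acquisition is
  discarded — acceptable, since such steps are artifact by definition of the
  rule. The first cycle has no reference and is exempt.

If more than 15% of an acquisition's cycles are censored the whole
acquisition is discarded. Surviving cycle means, placed at cycle midpoints,
are linearly interpolated onto a uniform 2 Hz grid over [0, duration); grid
points outside the convex hull of surviving beats are missing. Interpolation
is linear — nothing in the pipeline benefits from higher order, and linear
bridging across censored gaps is transparent. The 2 Hz series is reduced to
non-overlapping 3 s block means (blocks anchored at t = 0; a final partial
block is dropped) and smoothed with a centered 3-block (9 s) sliding
average, edge blocks averaging the two available neighbours. Repeated bouts
are averaged pointwise (missing values excluded pairwise) before outcome
extraction; resting MCAv is therefore also a cross-bout average, consistent
with the signal-to-noise rationale for recording multiple bouts. A subject
whose every bout is discarded on either hemisphere is excluded (the
bilateral outcome cannot be formed).

## Statistics

Group comparisons of continuous outcomes use the Mann–Whitney U test
computed from midranks. Reported internals:

* U for the named group, U = R − n(n+1)/2; mean ranks per group.
* z = (U − n₁n₂/2)/σ with the tie-corrected
  σ² = (n₁n₂/12)·[(N+1) − Σ(t³−t)/(N(N−1))] and **no continuity
  correction** — the uncorrected formula reproduces the reference value
  z = −2.543 at U = 10, n = 6/13 exactly, while the corrected one gives
  −2.50.
* Exact two-sided p = min(1, 2·min tail), point mass included — the dominant
  convention in clinical statistics packages. Without ties the null
  distribution of U comes from the exact integer recursion
  c(a,b,u) = c(a−1,b,u−b) + c(a,b−1,u) (verified against brute-force
  enumeration for all group sizes ≤ 8); with ties, from complete enumeration
  of group assignments of the midranks when C(N, n₁) ≤ 2·10⁵, otherwise the
  exact p is reported as unavailable and the asymptotic p stands in. The
  exact path is kept for n₁n₂ ≤ 2500 (up to 50 per group), where exact and
  asymptotic p agree to < 0.01.

Categorical rows use Fisher's exact test: two-sided p as the sum of
hypergeometric point probabilities (margins fixed) over tables whose
probability does not exceed the observed one, computed in exact rational
arithmetic with a 1e−7 relative guard against ties in the point
probabilities; degenerate margins give p = 1. This convention reproduces the
reference values 1.000 / 0.605 / 0.517 for the 13-vs-6 demographic tables.
Correlations are Pearson's r with a two-sided p from
t = r·√((n−2)/(1−r²)) on n−2 df. α = 0.05 throughout; no multiplicity
adjustment and no multivariate modelling (out of scope at these sample
sizes).

## Synthetic cohort generator

No participant recordings are available, so the generator *defines* the
study conditions and provides ground truth for recovery testing. What it
emulates:

* **Cohort structure** — 13 controlled / 6 hyperglycemic subjects by
  default; HbA1c uniform on 5.0–6.8% (low) and 7.2–11.0% (high) — the
  distributional form within groups is unspecified in the source material,
  so a uniform spread over the plausibly observed range is used for
  grouping-logic purposes only. Demographics (age, sex, BMI, smoking,
  hypertension, T2DM) are drawn per group at the published rates/moments;
  beta-blocker use at 30% (not tabulated; a typical post-stroke rate).
* **Ground-truth outcomes** — per-hemisphere true CVR drawn Gaussian
  (Gaussian is an assumption; only mean ± SD are known): stroke-affected
  6.8 ± 5.0 vs 0.9 ± 3.7 cm/s, non-affected 7.7 ± 5.7 vs 0.1 ± 3.8 cm/s.
  Resting MCAv Gaussian 55 ± 15 cm/s per hemisphere (clipped at 25 cm/s),
  spanning the 51–75 cm/s range of reported group means. Hemispheres share a
  subject-level effect with correlation 0.7, a design choice mimicking the
  reported bilateral concordance and flagged for sensitivity testing.
* **Waveforms** — 450 s at 500 Hz. Beat onsets at RR = 60/HR_rest with 1%
  jitter. Cycle-mean velocity follows rest + A·(1 − exp(−(t−95)/τ)) with
  τ = 30 s and a 5 s onset delay; the kinetic form is a generator design
  choice (the source's dynamic-response model is not stated), so truth is
  defined kinetics-agnostically as the steady-state-window mean increment
  and A = CVR / f where f is the closed-form window mean of the exponential
  (f ≈ 0.9815 at the defaults). A systolic pulse waveform (default 20 cm/s
  excursion) is de-meaned *exactly* within each cycle so pulsatility cannot
  bias cycle means; white noise (default SD 2 cm/s, a realistic
  envelope-tracking noise level) is added per sample. MAP and end-tidal CO2
  channels carry analogous rest→exercise ramps (80→98 mmHg, 35→39 mmHg) as
  covariate plumbing only.
* **Artifacts** — Poisson-placed velocity spikes (default magnitude 15 cm/s,
  forced > 10 so each spike trips the jump rule) applied within one cycle at
  its systolic peak, and spurious beat markers 0.15 s after a real onset
  (6.7 Hz instantaneous frequency, tripping the RR rule). Every injection is
  logged so censoring can be audited event-by-event.
* **Determinism** — one root seed; every subject/bout/purpose draws from an
  RNG substream derived by stable (BLAKE2b) hashing of
  (seed, subject_id, purpose, bout), so enlarging a cohort never reshuffles
  existing subjects.

What it does **not** emulate: cerebral autoregulation and CO2-reactivity
dynamics, heart-rate kinetics during exercise (RR stays near resting),
device physics, probe drift, or non-Gaussian outcome tails. Passing recovery
tests therefore demonstrates correctness of the *pipeline arithmetic* under
controlled conditions, not robustness to every behaviour of real TCD data.

## Numerical and scale choices

* Noise-free recovery: end-to-end CVR error is < 0.01 cm/s at the defaults
  (tolerance 0.1 cm/s covers smoothing/interpolation bias at the window
  edges).
* Recovery and pipeline tests run 3–6 subjects, one bout, at 125–500 Hz;
  power simulations use 500 cohorts drawn at the outcome level (the rank
  test needs only the CVR values, not the waveforms). Calibration checks use
  2,000–20,000 subjects per group at the truth level. These sizes make the
  whole suite run in seconds while keeping Monte-Carlo error well inside the
  asserted bounds.
* At the calibrated effect size (n = 13 vs 6) the two-sided α = 0.05
  Mann–Whitney rejects in roughly 70% of simulated cohorts, and at the
  nominal rate under the matched null; the acceptance script reports both
  rates with the simulation count.
* The recording CSV writer quantizes beat-onset times to the sample grid
  (≤ 1 ms at 500 Hz), which is below any tolerance used downstream.

## Known limitations

* Tables 1-style group means/SDs of *real* participants are not reproducible
  here by construction — the generator is calibrated to those moments
  instead, and the calibration itself is what the tests check.
* The exact Mann–Whitney p under heavy ties falls back to the asymptotic
  value beyond the enumeration cap.
* Whether censoring should compare mean or peak cycle velocity jumps is
  ambiguous in the field; peak velocity is implemented, as printed in the
  protocol this pipeline follows. The 7.5-min bout length is adopted where
  source descriptions disagree (7.5 vs 8 min); resting data are the first
  90 s either way.
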