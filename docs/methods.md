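# Methods

This note records the models, measurement conventions, parameter defaults
and numerical choices behind each module, and what the synthetic-data
round trips do and do not demonstrate about real recordings.

## ECG delineation and intervals

A record is a single-lead voltage series (mV) at a fixed sampling rate.
Baseline wander is removed with a zero-phase high-pass: a 2nd-order
Butterworth applied forward and backward (effective 4th order, no phase
distortion), default cutoff 0.5 Hz. The output keeps the input length;
edge transients extend roughly one filter settling length (~1/cutoff) into
each end, and tests trim accordingly.

R peaks are local maxima above half of the largest positive excursion over
the record median, separated by a species-dependent refractory window
(40 ms mouse, 250 ms human). Delineation then works per beat on a lightly
smoothed copy (1 ms moving average; 2 ms for human):

- **Isoelectric level** — the median of a 10-ms window ending 5 ms before
  the P onset. A first pass uses a window just before the P search region,
  a second pass refines it once the P onset is known. The measurement rules
  do not define this level; the median window is this package's choice and
  is configurable.
- **P onset / Q onset** — walking back from the wave's extremum to where
  the deflection has fallen to 10% of the wave's own height, with linear
  interpolation between samples.
- **S end** — the first interpolated crossing of the isoelectric line after
  the S trough (the QRS interval runs Q onset → S end).
- **T end** — "90% of the decline" is operationalised as the first point
  after the T peak where the voltage has fallen to 10% of the T height
  above the isoelectric level, interpolated (QT = Q onset → T end).

Intervals are averaged arithmetically over every beat carrying the needed
fiducial pair; the per-interval beat counts are reported rather than
enforcing a fixed number of beats. RR is the mean R-to-R spacing and
HR = 60000/RR. All indices are 0-based; times are milliseconds internally.

QT correction:

- Bazett (human): QTc = QT/√(RR s) with RR derived from the heart rate
  (RR = 60/HR). The clinical fixture's separately printed RR column is
  inconsistent with its printed QTc for several subjects, while HR-derived
  RR reproduces all eight; the HR route is therefore the implementation.
- Hodges: QTc = QT + 1.75·(HR − 60).
- Murine normalisation: QTc = QT/√(RR/100 ms), the 100-ms-cycle analogue
  of Bazett's 1-s normalisation.

Integer reporting conventions are part of the fixture semantics and are
carried on the value: Bazett truncates toward zero (499.6 → 499,
489.9 → 489), Hodges rounds half up (461.25 → 461). Full precision is kept
internally; reporting is explicit and opt-in.

T-wave morphology: amplitude is the mean T-peak height above the
isoelectric level; area is the trapezoidal integral of (V − isoelectric)
from the S end to the T end, averaged over the first five complete beats
(all available beats, flagged, when fewer than five exist).

## QT variability

For a beat-to-beat QT series (n ≥ 2, mean QTm) and an aligned heart-rate
series (mean HRm, variance HRvar):

- QTvar = Σ(QTᵢ − QTm)²/(n−1) (unbiased), SDqt = √QTvar — enforced to
  machine precision as an invariant.
- STVqt = Σ|QTᵢ₊₁ − QTᵢ| / (n_d·√2). Only n−1 successive differences
  exist, so n_d = n−1 by default; a fixed n_d = 30 mode covers the
  conventional 30-beat-window denominator. Which denominator a given
  clinical report used is frequently ambiguous, hence the explicit mode.
- QTVN = QTvar/QTm²; QTVI = log₁₀(QTVN / (HRvar/HRm²)). A constant QT
  series gives QTVI = −∞ (flagged); constant HR makes the index undefined
  (error).
- RMSSDqt = √(Σ(QTᵢ₊₁ − QTᵢ)²/(n−1)), with the square root that the
  marker's name implies.

Series means are taken from the analysed series; an override exists for
replicating externally reported panels. For white-noise series,
E[RMSSD] → SD·√2; the suite checks this at n = 10⁵ within 2%, and checks
all six markers against an independent straight-loop implementation to
1e-9 relative on random series.

## Voltage-clamp analysis

Sweeps are uniformly sampled current traces with a defined pulse window.
Conventions, all configurable:

- **Blanking** — the first 0.3 ms of a pulse is excluded from peak
  searches (residual capacitive transient). Note an implication for very
  fast events: a peak occurring inside the blank window is invisible, so
  measured peak-referenced quantities then refer to the post-blank
  extremum.
- **End of pulse** — the mean over the last 5% of the pulse window
  (half-open: the first post-pulse sample is excluded).
- Peak amplitude is the pulse extremum minus the end-of-pulse level,
  signed; sustained amplitude is the end-of-pulse level minus the
  pre-pulse baseline. Densities divide by cell capacitance.

The I–V relation is fitted to I = (Vm − E_rev)·G_max·(1 + e^−(Vm−V_h)/k)⁻¹:
occupancy rises with depolarisation and k is reported positive, matching
the slope-factor convention of conductance–voltage tables (for
availability/inactivation curves the exponent sign flips and k is again
reported positive). Initialisation: E_rev from the zero crossing beyond
the I–V peak (linear extrapolation of the quasi-linear limb if no sign
change is sampled), V_h from the half-maximum crossing of the normalised
chord conductance, k from the 10–90% rise span divided by 4.4 (the exact
10–90 width of a Boltzmann in units of k), G_max from the largest chord
conductance; V_h is bounded ±50 mV around its initial guess. Fits use
least squares via lmfit; the RMSE is reported with every fit.

Chord conductance G = I/(Vm − E_rev) excludes points within 1 mV of E_rev
(singular) and is normalised to its maximum. Two independent routes to
(V_h, k) — the direct I–V fit, and the conductance transform followed by a
Boltzmann fit — agree within 1 mV / 0.5 mV on noiseless model data and are
tested against each other, not against a shared implementation.

Recovery from inactivation uses paired-pulse sweeps (identical P1 and P2
separated by a coupling interval); the P2/P1 peak ratio vs interval is
fitted with r(t) = plateau·(1 − e^−t/τ), plateau fixed at 1 by default
(optional free plateau for protocols where recovery saturates below 1).

Decay kinetics fit A·e^−t/τ + C or the two-exponential analogue from the
pulse peak to the pulse end; τ_fast < τ_slow is enforced by reordering
after the fit rather than by constrained optimisation. A biexponential fit
whose minor component carries under 2% of the decaying amplitude falls
back to the monoexponential, flagged; a flat trace is flagged degenerate
(τ unidentifiable). Late (persistent) current is the mean over the last
10% of the pulse as a percentage of the peak, same sign convention. Charge
is the trapezoidal integral of (I − I_end) from the peak to the pulse end,
in pC after division by 1000, per pF of capacitance — a purely sustained
current therefore carries zero charge by construction.

Action potentials (current-clamp traces) yield RMP (mean pre-stimulus
voltage), APA (peak − RMP; below 10 mV the trace is rejected as "no AP"),
and APD at 20/50/90% repolarisation measured from the peak by default
(upstroke half-amplitude reference available), with interpolated level
crossings. No liquid-junction-potential correction is applied anywhere,
matching the recording convention the package mirrors.

## Synthetic data

The generators define the conditions under which the pipeline is
validated. All are seeded (default 20250507) and bit-reproducible.

**ECG.** Each beat is a sum of Gaussian deflections (P, Q, R, S, a small
J-point hump, T). Widths scale with the programmed intervals
(σ_P = 0.12·PR; σ_Q, σ_R, σ_S = 0.07, 0.08, 0.10·QRS; σ_J = 0.15·QRS;
σ_T = 0.12·QT). Placement realises the programmed intervals under the
measurement definitions themselves: P and Q onsets sit where the bump
passes 10% of its height; the S centre is root-solved so the waveform's
isoelectric crossing lands exactly at Q onset + QRS; the T centre is
root-solved so the 90%-decline point lands exactly at Q onset + QT. The
J-point hump exists so that the S-end crossing has a usable slope — a pure
Gaussian tail approaches the baseline asymptotically, which no real ECG
does. Per-beat QT jitter (AR(0) Gaussian, default SD 1 ms) translates the
whole T wave; white noise (default 0.01 mV) and sinusoidal wander
(default 0.2 mV at 0.2 Hz) are added on top; the returned fiducials refer
to the noiseless construction. Mouse defaults (500 bpm, PR 40, QRS 10,
QT 45 ms, T 0.25 mV, 4 kHz) represent an anesthetized adult mouse; the
human preset (60 bpm, PR 160, QRS 90, QT 400 ms, 1 kHz) a resting adult.
Known limitation: the broad human T wave interacts with the 0.5-Hz
bidirectional high-pass, biasing the measured human QT by about 1% (~4 ms)
— visible in the tests' tolerances, and a faithful reflection of why
diagnostic-grade human ECG uses lower high-pass corners. What these round
trips do *not* show: robustness to ectopy, electrode motion artefacts,
biphasic or inverted T waves, or morphology change over time.

**QT/HR series.** Stationary AR(1) with exact stationary mean, SD and
lag-1 correlation — the simplest process exercising both the dispersion
markers (variance-based) and the successive-difference markers through a
controllable short-term structure. Real QT series carry respiratory and
circadian structure the AR(1) does not emulate.

**Voltage clamp.** A Hodgkin–Huxley-flavoured separable model:
I(t) = G_max·m∞(V)·(1 − e^−t/τ_act)·h(t)·(V − E_rev), with m∞ a rising
Boltzmann (V_h_act, k_act) and h a biexponential decay toward a late
fraction. Steady-state availability for prepulse protocols follows the
falling Boltzmann (V_h_inact, k_inact); paired-pulse recovery follows
1 − e^−Δt/τ_react. Protocol geometries (holding/test potentials, step
sizes, pulse durations, sampling rates) follow standard murine ventricular
practice: 50-ms sodium pulses at 50 kHz from −120 mV, 500-ms calcium and
outward-potassium pulses at 4 kHz, 250-ms inward-rectifier steps, 500-ms
availability prepulses, 0.05–500 ms coupling intervals. Presets carry
typical wildtype ventricular parameters (sodium: V_h_act −52.9 mV, k 4.0,
V_h_inact −86.9 mV, k 5.0, τ_f/τ_s 1.3/4.5 ms, τ_react 8.2 ms; calcium:
−11.1/6.4 and −33.5/5.2, τ_f/τ_s 20.1/72.2 ms; outward K⁺: −4.6/14.3,
τ_inact 156 ms with a 35% sustained fraction; inward rectifier: quasi-ohmic
with E_K −85 mV). Because activation and inactivation overlap in time, the
trace peak is smaller than G_max·m∞·(V−E_rev) by a voltage-independent
factor; V_h, k, E_rev and every time constant are unaffected, and the
generator returns the noiseless peak density per sweep as the truth for
amplitude checks. Decay-kinetics validation uses near-instant activation
(τ_act = 0.01 ms) so the fitted segment is exactly biexponential.

**Action potentials.** Flat RMP, a half-cosine upstroke (1.5 ms), then a
monotone piecewise-cubic (PCHIP) repolarisation through the programmed
20/50/90% crossing points — the APDs are exact by construction, which is
the point: AP metrics are tested against construction truth, not a fitted
model.

**Masks.** Rod-shaped cell cartoons on a tissue frame: rectangular cells
with N-Cadherin ICD bands at both ends and WGA membrane along ends and
sides. Cx43 pixels are randomly allocated inside the ICD to hit the
programmed ICD fraction, and inside the lateral membrane (WGA minus ICD)
to hit the programmed lateral/ICD ratio; PSR pixels are allocated inside
the tissue at the programmed fibrosis percentage. Fractions are exact up
to pixel rounding and the achieved values are returned as truth. The
"lateral membrane = WGA minus its ICD overlap" subtraction avoids counting
any pixel on both sides of the lateralization ratio; segmenting raw
fluorescence into masks is explicitly upstream of these metrics.

## Cohort fixtures and summaries

The two clinical tables ship as TSV fixtures with SHA-256 checksums and are
loaded verbatim. Group summaries use the unbiased sample SD and
SEM = SD/√n, with a round-half-up 1-decimal reporting mode for comparison
against printed mean±SD values. Inferential statistics (t-tests,
Mann–Whitney, ANOVA, mixed models) are deliberately out of scope: they are
off-the-shelf procedures, and the pipeline instead exports tidy tables for
whatever statistics package the user prefers. One known irreconcilable in
the variability fixture: its QTVN and QTVI columns cannot be reproduced
from the single per-subject QT/HR values of the ECG table (they require
the unpublished beat series, and plausibly a ×100 scale on QTVN); the
fixture stores them for reference and only the SDqt = √QTvar consistency
is asserted.

## Problem sizes and determinism

Round-trip validations use sizes chosen to keep estimator error well under
the asserted tolerances: 60–150 beats for ECG interval recovery (standard
error of the QT mean ≲ 0.1 ms at 1-ms jitter), 10⁵ beats for estimator
consistency checks, 100 replicates for noisy-fit medians, 256×256 masks.
Every stochastic path takes an explicit seed; identical spec + seed yields
bit-identical data, and the report pipeline is byte-deterministic for a
fixed config.

## Interfaces

All interchange formats are plain text (delimited series with comment
headers, JSON manifests for sweep bundles, PNG + JSON sidecar for masks),
chosen so fixtures stay inspectable and diffable; readers for
acquisition-native binary formats are out of scope. The `cardioqt` CLI is
a thin wrapper over the library — every command body is a few lines of
module calls.
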