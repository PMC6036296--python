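# Methods

This note records the models implemented in `granuflux`, the defaults they
ship with, and the reasoning behind the choices that were genuinely open.

## Assay model

A flux plate run is a set of per-well kinetic traces sharing one injection
schedule.  Measurement cycles are 1-based, matching instrument numbering,
and injections are anchored to "after cycle k" rather than clock time,
because the instrument queues port injections between cycles.  When a
source reports injection times in minutes (as figure legends usually do),
they are mapped to the last cycle completed at or before that time.

Window segmentation is purely index-based: the baseline window is
`[1, k₁]`, the window for injection i is `[kᵢ+1, kᵢ₊₁]`, and the last
window runs to the end of the assay.  Every cycle belongs to exactly one
window; two injections after the same cycle are rejected.

Stress-test parameters are computed per well and only then aggregated
(mean ± SEM over wells), never on group-mean traces; this keeps the SEM an
honest between-well statistic and allows well-level hypothesis tests.  The
pre-glucose reference (NGA) defaults to the single last baseline
measurement — the conventional reading of "measurement prior to glucose
injection" — with a baseline-mean option available but non-default.  No
parameter is floored at zero: under ambient hypoxia the uncoupled (FCCP)
rate legitimately falls below basal, giving negative spare capacity, and
clamping would bias group means.

An optional outlier rule (median absolute deviation, robust z > 3.5 on the
per-well trace mean) is evaluated and reported but **off** by default; no
well exclusions are assumed.

## Agonist responses

The headline statistic is the absolute peak rate after the stimulus (the
baseline-subtracted delta is always reported alongside, since "peak
height" is used both ways in the literature).  For primed schedules the
baseline is taken before the *first* injection of the primer+stimulus
pair; priming cytokines alone do not move baseline OCR, so this matches
the unprimed baseline while protecting against any primer drift.

Kinetic classification thresholds are package conventions, configurable
and deliberately relative so the class is invariant under uniform
rescaling of rates: *biphasic* needs two local maxima ≥60% of the delta
above baseline separated by ≥3 cycles; *sustained* needs the final
measurement ≥50% of the delta above baseline with the trace extending
≥90 min past the stimulus; anything else with a detectable delta is
*transient*; deltas below 1 rate unit are *none*.

## Hypoxia: calibration and rate estimation

Within a measure phase the transient microchamber obeys

    dC/dt = k_d (C_amb − C) − r(t) / (V α)

with C the chamber oxygen tension (kPa), k_d the back-diffusion constant
(min⁻¹), V the chamber volume (µl) and α an effective oxygen capacity
(pmol µl⁻¹ kPa⁻¹) that absorbs solubility and sensor-geometry factors.
Each mix phase re-equilibrates the chamber to ambient.

Calibration is a two-anchor affine map from raw sensor signal to kPa: the
ambient anchor is the pre-assay plateau of the cell-free sulfite wells,
the zero anchor the pooled median signal over their last three
post-sulfite measure phases (sodium sulfite chemically scavenges all
dissolved oxygen).  Rate estimation fits an ordinary least-squares line to
the calibrated levels over the **first half** of each measure phase —
early samples minimize back-diffusion curvature while keeping ≥3 points at
the default cadence — and inverts the chamber model:

    r̂ = V α (k_d (C_amb − C̄) − slope)

Equivalence with any proprietary hypoxia-rate software is not claimed;
what is demonstrated (in tests) is unbiased recovery on the package's own
microchamber simulations and the failure mode the sulfite wells exist to
prevent: analysing hypoxic data against a normoxic ambient anchor inflates
rate estimates many-fold.

Oxygen is carried in kPa internally; % O₂ converts at 101.325 kPa
barometric (configurable).  The hypoxic presets use an 0.8% O₂ atmosphere
(≈0.81 kPa).

## The simulator

**What it emulates.**  Per-well continuous-time rate kinetics with
injection-triggered responses; measure/mix cycle structure (3 min + 3 min
by default, one rate per cycle attributed to the middle of the measure
phase, three cycles per condition segment — the cadence of typical
granulocyte runs); multiplicative per-well effects (lognormal, mean 1,
CV 5%) and additive measurement noise (SD = 2% of signal + 0.5 rate
units), chosen once so simulated SEMs at n ≈ 6 wells are of the order of
published granulocyte SEMs — a calibration of plausibility, not a claim
about any instrument; linear scaling of rates with seeded cells per well
(reference 150 × 10³/well); raw level mode with the microchamber ODE above
(defaults: V = 2.28 µl, k_d = 0.05 min⁻¹, α = 22 pmol µl⁻¹ kPa⁻¹,
10 samples per measure phase, affine sensor with gain 40 signal/kPa —
invented, documented, configurable); and sulfite wells whose tension
decays chemically to zero (τ = 0.5 min) and is not restored by mixing.

**Response kinetics.**  Step-exponential responses relax toward a new
target with time constant τ (τ = 0 switches instantly; the reference
presets use this for bit-exact recovery checks).  Transient responses add
`A (1 − e^(−t/τ_r)) e^(−t/τ_d)` on top of the pre-injection rate.  A
biphasic burst is the sum of two transients; the second component carries
an onset delay, because two summed zero-delay transients merge into a
single broad hump rather than the two separated maxima seen in sustained
eosinophil bursts.

**Presets.**  Each library preset encodes published group-mean rates for
human eosinophil/neutrophil assays as its ground truth (post-glucose ECAR
peaks at 1 and 10 mM glucose, the oligomycin-suppressible glucose-derived
OCR rise, PMA and primed-agonist peak heights, normoxic/hypoxic post-FCCP
rates).  Step targets equal the published value directly; transient
amplitudes are scaled so the noiseless model *sampled at the default
cadence* peaks exactly at the published value, since published peaks are
themselves instrument-sampled.  Trace levels the sources do not print —
baselines before glucose, the oligomycin-suppressed plateau, hypoxic
baselines, post-2-DG levels — were fixed once at physiologically
reasonable values and are part of the preset definitions; they are
documented truth for the simulator, not claims about the original cells.

**What it does not emulate.**  Sensor photophysics and drift, pH-side
(buffer-capacity) chemistry, CO₂-derived acidification, substrate
depletion, cell death or detachment during long runs, edge effects and
spatial plate gradients, or correlated well noise.  Passing recovery tests
therefore demonstrates that the analysis inverts the stated generative
model — not that it is robust to every artefact of real plates.

**Numerics.**  Level mode integrates with fixed-step classical
Runge–Kutta at 0.01 min (the dynamics are non-stiff; a fixed step keeps
results bit-reproducible across platforms); with k_d = 0 the integrator
matches the linear closed form to better than 10⁻⁶ relative.  Well
randomness is keyed by (seed, well position), so a plate is identical
under the same seed and wells are unaffected by plate size.

## Morphometry

Contours are simple polygons in pixel units; areas use the shoelace
formula and hulls the Andrew monotone chain with collinear boundary points
dropped.  Self-intersecting contours are rejected, not repaired — silent
repair would bias the area ratio.  No sub-pixel smoothing is applied; the
upstream imaging pipeline is out of scope.  The synthetic generator draws
radial polygons `r(θ) = R (1 + a sin(fθ + φ) + smooth noise)` with 64
vertices; such star-shaped outlines cannot self-intersect, and the
protrusion amplitude `a` tunes how far a population departs from
convexity.  Population summaries report both median and mean ratio (the
preferred per-donor aggregate is a matter of convention) and flag
populations below the conventional 5000-event acquisition minimum.

## Statistics

The gate is per comparison: every group is screened with Shapiro–Wilk at
α = 0.05 and the comparison is parametric only if *all* groups pass — the
conservative reading of a normality-gated workflow.  Groups with n < 3
cannot be screened and fall back to nonparametric with a warning.  All
tests are two-sided at α = 0.05.  Test internals (Shapiro–Wilk, t,
Mann–Whitney, ANOVA, Tukey HSD) are delegated to scipy; the module owns
gating, orchestration and reporting.  The Tukey table also carries
unadjusted pooled-variance pairwise p-values, which bound the adjusted
ones from below.  Both the ANOVA+Tukey route and the plain two-group route
are exposed, and results record which was used.

## Problem sizes

Default verification runs use 6 wells × 20 seeds per preset (120 wells per
benchmark quantity), 100–200 randomized traces for property checks, and
2000 replicates for the type-I-error simulation; these sizes give
Monte-Carlo SEMs comfortably inside the stated tolerances while keeping
the full suite's runtime in seconds.

## Known limitations

- Proton-efflux-rate conversion and ATP-production-rate modelling from
  combined ECAR/OCR are out of scope (they need a buffer factor the
  package does not assume).
- The hypoxia estimator assumes the consumption rate is constant within a
  fit window; strongly varying rates within a single measure phase bias
  the estimate toward the window average.
- Kinetic-class thresholds are conventions; borderline sustained/biphasic
  traces near the 60%/50% boundaries are sensitive to noise.
- The simulator's noise model is independent across cycles; real
  instruments show serial correlation that would widen true SEMs.
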