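# Methods

## Scope and intent

`vasoloop` implements a rule-based closed-loop critical-care controller for
vasodilatory shock, the synthetic patient needed to exercise it end to end,
the standard ischemia–reperfusion experiment choreography, and the
time-in-range metrics used to judge runs. The controller and metrics encode
a published protocol; the patient model is this package's own construction —
a test harness with documented parameters, not a physiological claim.

## Controller

**Inputs.** Proximal MAP and CVP, reduced to trailing 1-min averages; the
current NE rate and bolus count are controller state. Units are fixed
throughout the decision logic (mmHg, mcg/kg/min, mL, s); conversions happen
only at I/O boundaries.

**Zones.** MAP < 50 severe hypotension; 50–59 (inclusive) moderate; 60–70
(inclusive) normotension; > 70 hypertension. The band edges 60 and 70 are
normotensive, matching the band definitions used by the metrics layer.

**Titration.** The protocol names the ingredients of the titration function
— distance from the 65 mmHg target, square root of the current NE rate, an
integer branch scale, and the constant 0.0072 — without printing their
composition. We use the simplest composition consistent with all four:

    Δ = s · 0.0072 · |MAP − 65| · sqrt(max(NE, 0.02))   [mcg/kg/min]

The sqrt floor of 0.02 mcg/kg/min (the baseline background infusion) keeps
the controller live from NE = 0; without it the product is zero and the
pressor could never escalate once fully weaned. The sign is applied by the
branch (increase in hypotension, decrease in hypertension) and the result is
clamped to [ne_min, ne_max] = [0, 1] mcg/kg/min. The branch scales are 2
for severe-hypotension increases and 1 for moderate increases and all
decreases: a larger correction for the larger deviation. "Maximum pressors"
for the pressor-resistance rule is ne_max itself; 1.0 mcg/kg/min sits well
above the protocol's "large dose" marker of 0.5 and is configurable.

**Normotension corner.** The protocol states the exception condition
(NE > 0.5 mcg/kg/min and CVP < 6 mmHg during normotension) but not the
action. We emit a weight-based fluid bolus: restoring preload is what
enables the subsequent pressor wean, which is the evident intent of the
rule. In hypertension with NE already at the floor nothing happens — fluids
are never withdrawn.

**Responsiveness bookkeeping.** A test bolus zeroes the
interventions-since-test counter and stamps the test time; every other
emitting decision tick increments the counter by one, so the
severe-hypotension combined action (bolus + NE increase) counts as a single
decision event for the 4-intervention reset while still contributing one
bolus and one titration to the intervention statistics. Whether NE
*decreases* count in the reported intervention rate is not stated in the
protocol; we count them (every titration, up or down, is an actuated
decision).

**Cadence and lockout.** Decisions are evaluated every 60 s — the natural
granularity of 1-min averaging. No new decision is taken while a bolus is
infusing; after any bolus the next decision waits until the assessment
window closes (bolus end + 60 s). Responsiveness windows are symmetric and
native to the controller: baseline = the 1-min average immediately before
the test bolus, post = the 1-min average ending 60 s after bolus
completion. The first 60 s of any stream are warm-up and produce no
decisions; non-finite or negative pressures invalidate their tick, which is
logged and skipped, never imputed.

`decide` itself is a pure function of (window, state, config); the lockout
and assessment plumbing live in `ControlLoop` so replays are exactly
reproducible.

## Synthetic patient

A lumped-parameter model with four slow states, stepped explicitly at
dt ≤ 1 s (default 0.1 s, vitals at 10 Hz; 1000 Hz is available by setting
dt = 0.001 at proportional cost):

* **Volume** V (mL). dV/dt = infusions − hemorrhage − leak. The leak drains
  volume in excess of a reference volume at `leak_rate_per_min` (default
  0.03/min); a fraction `bolus_retention` (default 0.4) of every
  crystalloid mL permanently raises the reference, and blood counts fully,
  so a crystalloid bolus decays toward 40% retained — capillary leak
  without breaking exact volume bookkeeping (conservation holds to machine
  precision and is asserted after every run).
* **CVP** from venous capacitance: CVP = (V − V_u)/C_v, floored at 0, with
  unstressed volume V_u = 50% of estimated blood volume (EBV, 60 mL/kg) and
  C_v = 3.75 mL/mmHg per kg — baseline CVP ≈ 8 mmHg at full volume, and the
  "low CVP" branch threshold of 6 mmHg discriminates hypovolemia.
* **Cardiac output** saturating in preload: CO = CO_max · CVP/(CVP + 4.5),
  CO_max = 8 L/min at 70 kg. The saturation is what makes the ≥ 5 mmHg
  bolus-response criterion discriminating: a 5 mL/kg bolus raises the 1-min
  MAP average by ≥ 5 mmHg below ~85% EBV and by < 5 mmHg at ≥ 100% EBV
  (verified by direct simulation in the test suite).
* **Tone and NE effect.** MAP = CO · SVR with
  SVR = SVR₀ · tone · (1 + E_max · e), where e lags a first-order Hill
  response h(NE) = NE/(NE + EC₅₀) with τ = 60 s, E_max = 1.5, EC₅₀ = 0.08
  mcg/kg/min. SVR₀ is calibrated at construction so the model starts at
  equilibrium: baseline MAP 63 mmHg at full volume, tone 1 and the 0.02
  mcg/kg/min background infusion. Aortic occlusion multiplies proximal
  afterload by (1 + 1.2·f) and collapses distal mean pressure toward a
  12 mmHg stump (mean pressures only — no pulse waveform is modeled, so
  "absent distal pulse pressure" is represented by that collapse).

**Injury.** Occlusion charges an ischemic burden pool (full after 30 min of
complete occlusion, worth `injury_tone_drop` = 0.40 of tone); after
reperfusion the pool is expressed as vasodilation with τ = 240 s and decays
with τ = 9000 s. The result is the intended phenotype: untreated (NE fixed
at 0.02), the patient spends well over half of the 255-min critical-care
phase below 60 mmHg, while the closed loop restores the band within the
first ~15 min and holds it.

**Noise.** Additive Gaussian measurement noise on the emitted pressures
(σ = 2 mmHg arterial, 0.5 mmHg CVP) plus a slow Ornstein–Uhlenbeck drift on
tone (σ = 0.02, τ = 300 s) that provides the between-seed variability; all
draws come from one seeded generator, so identical seeds give bit-identical
streams.

**Calibration stance.** The injury severity, NE pharmacodynamics and leak
parameters were chosen once to satisfy the model's stated contracts —
untreated majority-hypotension, discriminating bolus response, monotone NE
dose response, and a closed loop that can hold the band — and are not
otherwise fit to any animal data. What a green design-goal test establishes
is therefore that the *controller logic* achieves its target on a patient
with these properties; it says nothing quantitative about real swine, whose
first post-reperfusion hour is substantially more unstable than this
model's.

## Choreography

T0 hemorrhage of 0.30 × EBV over 30 min; T30 complete occlusion for 30 min;
T45 calcium gluconate over 20 min, modeled as a schedulable no-op (logged,
no hemodynamic effect); T55 transfusion of 0.25 × EBV over 18 min (returning
the subject from 70% to 95% of EBV — the schedule reconciles exactly);
T60 linear balloon wean over 15 min (the wean profile is not specified
anywhere; linear is the least-structured choice); T75–T330 critical care
(255 min, ending 5.5 h from start). Transfusion targets 95% of *estimated*
blood volume, not of measured pre-hemorrhage volume. A fixed 5 mL/kg/h
crystalloid maintenance infusion runs throughout. The controller is active
only inside the critical-care window; one actuator may not run two
overlapping scheduled actions.

## Metrics

High-rate MAP is averaged into consecutive 1-min bins (samples are
end-of-interval timestamped; the trailing partial bin is dropped — the
source protocol is silent on partial bins and dropping is the conservative
choice). Bands: hypotension < 60, normotension 60–70 inclusive,
hypertension > 70, sub-divided at 80. A bin of exactly 70 mmHg is
normotensive, so the 70–80 sub-band is effectively (70, 80]; this is forced
by requiring the sub-bands to partition the hypertensive band and all bands
to sum to 100%.

Cohort roll-ups are medians with IQR using linear-interpolation order
statistics (quantile type 7; for n = 5 the quartiles are the 2nd and 4th
order statistics). This convention is pinned because published roll-ups of
such cohorts are ambiguous between conventions; the bundled five-subject
reference cohort reproduces median 15.3% (IQR 8.6–16.9%) hypotension under
it. Display rounding is one decimal, half-up.

Exclusion screens mirror clinical practice: expiration (MAP < 20 mmHg for
5 contiguous minutes at any point), excessive setup pressor support
(NE > 0.1 mcg/kg/min for > 10 min cumulative during setup), and baseline
pressor dependence (NE > 0.06 mcg/kg/min at time zero). A white-cell-count
screen would need laboratory inputs and is out of scope.

## Known limitations

* The patient model has no baroreflex, no heart-rate state, no oxygen
  transport or lactate kinetics, and CVP depends on volume only (real
  vasodilation also drops CVP at fixed volume).
* Intervention rates on the synthetic patient (~3–4/h) are lower than the
  ~8.5/h observed in live experiments: the model's first post-reperfusion
  hour is milder and less labile than a real animal's, so fewer corrections
  are needed. The rate is reported, not asserted.
* Fluid responsiveness is a binary MAP-change classifier by construction;
  the model's monotone volume→CO curve makes it better behaved than the
  real-world equivalent.
* The calcium event is a no-op: citrate–calcium physiology is not modeled.
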