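# vasoloop

Closed-loop critical care for vasodilatory shock, in software: a rule-based
controller that titrates a norepinephrine (NE) infusion and delivers
weight-based crystalloid boluses from two physiologic inputs — the 1-min
trailing averages of proximal mean arterial pressure (MAP) and central
venous pressure (CVP) — plus a synthetic swine ischemia–reperfusion patient
to exercise it against, an experiment choreographer, and time-in-range
metrics.

It is aimed at people studying physiological closed-loop control: the
package lets the full loop (injury → monitoring → decision → actuation →
hemodynamic response) be run, replayed and measured deterministically,
without animals or pump hardware.

## The controller

The target band is MAP 60–70 mmHg (inclusive), around a target of 65 mmHg.
Each decision tick (every 60 s) classifies the 1-min MAP average:

| zone | MAP (mmHg) | action |
|---|---|---|
| severe hypotension | < 50 | 5 mL/kg bolus **and** simultaneous NE increase |
| moderate hypotension | 50–59 | gated on fluid responsiveness (below) |
| normotension | 60–70 | none — unless NE > 0.5 mcg/kg/min and CVP < 6 mmHg, then a bolus so the pressor can be weaned |
| hypertension | > 70 | NE decrease (never below 0; fluids are not withdrawn) |

NE titration magnitude, in mcg/kg/min:

```
Δ = s · 0.0072 · |MAP − 65| · sqrt(max(NE, 0.02))
```

with branch scale factor `s` (2 for severe hypotension, 1 otherwise) and the
resulting rate clamped to [0, 1] mcg/kg/min.

Moderate hypotension uses a binary fluid-responsiveness classifier: with the
state unknown, a 5 mL/kg test bolus is given over 2 min and the subject is
"responsive" if MAP rises ≥ 5 mmHg (1-min averages before the bolus vs
ending 60 s after it). Responsive subjects get fluid-avid treatment
(boluses); non-responsive subjects get NE increases, except with low CVP
(< 6 mmHg → bolus, breaking cyclic NE escalation) or at maximum NE (bolus,
"pressor resistance"). The state resets to unknown every four interventions
or one hour after the last test bolus.

## The synthetic patient

A deliberately minimal lumped-parameter model (see `docs/methods.md`):
blood volume with capillary leak, venous capacitance CVP, a saturating
preload→cardiac-output curve, and SVR driven by vascular tone and a Hill
NE dose–response. Aortic occlusion accrues an ischemic burden that is
expressed as vasodilation after reperfusion, so the untreated patient drops
below MAP 60 mmHg for most of the critical-care phase; the controller's
interventions are both necessary and sufficient to restore the band.

The standard choreographed experiment: 30% estimated-blood-volume (60 mL/kg)
hemorrhage over 30 min → 30 min complete aortic occlusion (calcium infusion
scheduled as a logged no-op at T45) → transfusion back to 95% EBV over
18 min → linear balloon wean over 15 min → 255 min of closed-loop critical
care.

## Worked example

A 70-kg subject gets 5 mL/kg = 350 mL boluses over 2 min (10.5 L/h):

```python
>>> from vasoloop import ControllerConfig
>>> cfg = ControllerConfig(weight_kg=70)
>>> cfg.bolus_volume_ml, cfg.bolus_rate_l_per_h
(350.0, 10.5)
```

Run one full experiment and read the time-in-range report:

```
$ vasoloop simulate --seed 1 --out runs/
seed 1: <60 3.9%  60-70 92.9%  >70 3.1%  interventions/h 3.53
$ vasoloop metrics runs/run_seed1
{
  "pct_lt60": 3.9215686274509802,
  "pct_60_70": 92.94117647058823,
  ...
  "n_bins": 255,
  "interventions_per_hour": 3.5294117647058822,
  ...
}
```

Of the 255 one-minute critical-care bins, 3.9% were hypotensive
(MAP < 60 mmHg), 92.9% in the 60–70 band and 3.1% hypertensive — the
controller meets the design goal of ≥ 90% time not hypotensive with < 20%
hypertension on this synthetic patient. Interventions averaged 3.5/h.

The packaged five-subject reference cohort of time-at-range percentages
rolls up with median/IQR (type-7 quantiles):

```
$ vasoloop metrics --bundled-cohort
           median   q1   q3   n
pct_lt60     15.3  8.6 16.9 5.0
pct_60_70    77.3 76.5 80.8 5.0
...
```

The controller can also be audited over recorded vitals with no simulator
in the loop: `vasoloop replay vitals.csv --out events.jsonl` (CSV columns
`time_s,pap_mmHg,cvp_mmHg` at ≥ 1 Hz).

## Acceptance script

`scripts/acceptance.py` recomputes the design-goal metrics from scratch: it
runs the full choreographed experiment on the default synthetic patient for
20 seeds derived from `--seed`, bins each run's critical-care MAP into 1-min
blocks, and writes the across-seed medians of the percentage of bins not
hypotensive (MAP ≥ 60) and hypertensive (MAP > 70) as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is about half a minute on one CPU at the default 0.1 s step.
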