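"""Experiment choreography: the injury timeline and the closed loop.

The standard ischemia–reperfusion experiment, with T in minutes from start:

====== ======================= =============================================
phase  window                  action
====== ======================= =============================================
T0–30  [0, 1800) s             controlled hemorrhage of 30% of estimated
                               blood volume (EBV, 60 mL/kg) at constant rate
T30–60 [1800, 3600) s          complete aortic balloon occlusion
T45–65 [2700, 3900) s          calcium gluconate infusion — scheduled no-op
                               (logged; no hemodynamic effect modeled)
T55–73 [3300, 4380) s          transfusion back to 95% EBV (0.25 x EBV)
T60–75 [3600, 4500) s          linear balloon wean, occlusion 1 -> 0
T75–   [4500, 19800) s         closed-loop critical care, 255 min
====== ======================= =============================================

A fixed crystalloid maintenance infusion of 5 mL/kg/h runs throughout.
``run_experiment`` steps the patient model at ``dt`` (default 0.1 s,
vitals at 10 Hz), lets the controller evaluate 1-min trailing averages
once per decision period inside the critical-care window only, and bundles
the vitals stream, decision event log, time-in-range report and a replay
manifest into a :class:`RunResult`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import ControllerConfig
from .controller import ControlLoop, ControllerState, InterventionKind, TickRecord, VitalsWindow
from .metrics import TimeInRangeReport, bin_one_minute, intervention_stats, time_in_range
from .patient import PatientModel, PatientParams

__all__ = ["ScheduledAction", "ExperimentSchedule", "build_schedule",
           "run_experiment", "RunResult", "load_run"]

ACTIONS = ("hemorrhage", "occlude", "calcium", "transfuse", "wean_balloon", "critical_care")


@dataclass(frozen=True)
class ScheduledAction:
    start_s: float
    end_s: float
    action: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if not self.end_s > self.start_s:
            raise ValueError(f"{self.action}: end must be after start")


# one actuator per physical channel; same-actuator actions must not overlap
_ACTUATOR = {
    "hemorrhage": "hemorrhage_pump",
    "transfuse": "blood_pump",
    "calcium": "drug_pump",
    "occlude": "balloon",
    "wean_balloon": "balloon",
    "critical_care": "controller",
}


@dataclass
class ExperimentSchedule:
    weight_kg: float
    ebv_ml_per_kg: float
    actions: list[ScheduledAction]
    maintenance_ml_kg_h: float = 5.0

    def __post_init__(self) -> None:
        by_actuator: dict[str, list[ScheduledAction]] = {}
        for a in self.actions:
            by_actuator.setdefault(_ACTUATOR[a.action], []).append(a)
        for actuator, acts in by_actuator.items():
            acts = sorted(acts, key=lambda a: a.start_s)
            for prev, nxt in zip(acts, acts[1:]):
                if nxt.start_s < prev.end_s:
                    raise ValueError(
                        f"actuator conflict on {actuator}: {prev.action} and {nxt.action} overlap"
                    )

    @property
    def ebv_ml(self) -> float:
        return self.ebv_ml_per_kg * self.weight_kg

    def _get(self, action: str) -> ScheduledAction:
        for a in self.actions:
            if a.action == action:
                return a
        raise KeyError(action)

    @property
    def critical_care_window(self) -> tuple[float, float]:
        a = self._get("critical_care")
        return a.start_s, a.end_s

    @property
    def end_s(self) -> float:
        return max(a.end_s for a in self.actions)

    @property
    def total_hemorrhage_ml(self) -> float:
        a = self._get("hemorrhage")
        return a.params["rate_ml_min"] * (a.end_s - a.start_s) / 60.0

    @property
    def total_transfusion_ml(self) -> float:
        a = self._get("transfuse")
        return a.params["rate_ml_min"] * (a.end_s - a.start_s) / 60.0

    @property
    def maintenance_ml_min(self) -> float:
        return self.maintenance_ml_kg_h * self.weight_kg / 60.0

    # -- per-step actuation lookups ----------------------------------------

    def occlusion_at(self, t_s: float) -> float:
        for a in self.actions:
            if a.action == "occlude" and a.start_s <= t_s < a.end_s:
                return 1.0
            if a.action == "wean_balloon" and a.start_s <= t_s < a.end_s:
                return (a.end_s - t_s) / (a.end_s - a.start_s)
        return 0.0

    def hemorrhage_rate_at(self, t_s: float) -> float:
        a = self._get("hemorrhage")
        return a.params["rate_ml_min"] if a.start_s <= t_s < a.end_s else 0.0

    def blood_rate_at(self, t_s: float) -> float:
        a = self._get("transfuse")
        return a.params["rate_ml_min"] if a.start_s <= t_s < a.end_s else 0.0

    def summary(self) -> dict:
        return {
            "weight_kg": self.weight_kg,
            "ebv_ml": self.ebv_ml,
            "maintenance_ml_kg_h": self.maintenance_ml_kg_h,
            "actions": [asdict(a) for a in self.actions],
        }


def build_schedule(
    weight_kg: float,
    ebv_ml_per_kg: float = 60.0,
    maintenance_ml_kg_h: float = 5.0,
) -> ExperimentSchedule:
    """Standard injury timeline scaled to the subject's weight.

    Hemorrhage removes 0.30 x EBV over 30 min; transfusion returns
    0.25 x EBV (70% back to 95% of EBV) over 18 min.
    """
    if not weight_kg > 0:
        raise ValueError(f"weight_kg must be positive, got {weight_kg}")
    ebv = ebv_ml_per_kg * weight_kg
    hem_ml = 0.30 * ebv
    tx_ml = (0.95 - 0.70) * ebv
    actions = [
        ScheduledAction(0.0, 1800.0, "hemorrhage", {"rate_ml_min": hem_ml / 30.0}),
        ScheduledAction(1800.0, 3600.0, "occlude", {"fraction": 1.0}),
        ScheduledAction(2700.0, 3900.0, "calcium", {"dose_mg": 200.0}),  # logged no-op
        ScheduledAction(3300.0, 4380.0, "transfuse", {"rate_ml_min": tx_ml / 18.0}),
        ScheduledAction(3600.0, 4500.0, "wean_balloon", {"profile": "linear"}),
        ScheduledAction(4500.0, 19800.0, "critical_care", {}),
    ]
    return ExperimentSchedule(weight_kg, ebv_ml_per_kg, actions, maintenance_ml_kg_h)


@dataclass
class RunResult:
    """Replayable artifact bundle of one choreographed run."""

    vitals: pd.DataFrame                # time_s, pap_mmHg, dap_mmHg, cvp_mmHg
    events: list[TickRecord]
    report: TimeInRangeReport
    seed: int
    config: ControllerConfig
    params: PatientParams
    schedule: ExperimentSchedule
    controller_enabled: bool
    dt_s: float

    @property
    def manifest(self) -> dict:
        doc = {
            "controller": self.config.to_dict(),
            "patient": asdict(self.params),
            "schedule": self.schedule.summary(),
            "seed": self.seed,
            "dt_s": self.dt_s,
            "controller_enabled": self.controller_enabled,
        }
        digest = hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()
        return {
            **doc,
            "config_hash": digest,
            "version": __version__,
            "artifacts": {
                "vitals": "vitals.csv",
                "events": "events.jsonl",
                "report": "report.json",
            },
        }

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.vitals.to_csv(out / "vitals.csv", index=False, float_format="%.3f")
        with open(out / "events.jsonl", "w") as fh:
            for rec in self.events:
                fh.write(json.dumps(rec.to_json_dict()) + "\n")
        self.report.to_json(out / "report.json")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)
        return out


def run_experiment(
    params: PatientParams | None = None,
    config: ControllerConfig | None = None,
    schedule: ExperimentSchedule | None = None,
    seed: int = 0,
    controller_enabled: bool = True,
    dt_s: float = 0.1,
    ne_background: float = 0.02,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Run the full choreographed experiment against the synthetic patient.

    The controller is active only inside the critical-care window; during
    the injury phases actuation follows the schedule with the background
    norepinephrine infusion fixed at ``ne_background``.  Deterministic
    given ``seed``.
    """
    params = params if params is not None else PatientParams()
    config = config if config is not None else ControllerConfig(weight_kg=params.weight_kg)
    schedule = schedule if schedule is not None else build_schedule(
        params.weight_kg, params.ebv_ml_per_kg
    )
    if not (
        abs(params.weight_kg - config.weight_kg) < 1e-9
        and abs(params.weight_kg - schedule.weight_kg) < 1e-9
    ):
        raise ValueError("params, config and schedule must agree on subject weight")

    n_steps = int(round(schedule.end_s / dt_s))
    win_len = max(1, int(round(60.0 / dt_s)))       # samples per 1-min window
    cc_start, cc_end = schedule.critical_care_window
    maintenance = schedule.maintenance_ml_min

    # schedule actuation is precomputed; controller actuation is dynamic
    t_grid = np.arange(n_steps) * dt_s              # step start times
    occ = np.array([schedule.occlusion_at(t) for t in t_grid])
    hem = np.array([schedule.hemorrhage_rate_at(t) for t in t_grid])
    blood = np.array([schedule.blood_rate_at(t) for t in t_grid])

    model = PatientModel(params, seed=seed)
    loop = ControlLoop(config, ControllerState(ne_rate=ne_background))

    t_out = np.empty(n_steps)
    pap = np.empty(n_steps)
    dap = np.empty(n_steps)
    cvp = np.empty(n_steps)
    events: list[TickRecord] = []

    step = model.step
    bolus_rate = 0.0
    bolus_end = -1.0
    next_decision = cc_start
    period = config.decision_period_s
    v0 = model.volume_ml

    for k in range(n_steps):
        t = t_grid[k]
        in_cc = cc_start <= t < cc_end
        ne = loop.state.ne_rate if (controller_enabled and t >= cc_start) else ne_background
        fluid = maintenance + (bolus_rate if t < bolus_end else 0.0)
        s_pap, s_dap, s_cvp = step(
            dt_s,
            ne_rate=ne,
            fluid_rate_ml_min=fluid,
            blood_rate_ml_min=blood[k],
            hemorrhage_rate_ml_min=hem[k],
            occlusion_fraction=occ[k],
        )
        now = model.t_s                              # sample end time
        t_out[k] = now
        pap[k] = s_pap
        dap[k] = s_dap
        cvp[k] = s_cvp

        if controller_enabled and in_cc and now >= next_decision:
            lo = max(0, k + 1 - win_len)
            window = VitalsWindow(
                time_s=now,
                map_avg=float(pap[lo : k + 1].mean()),
                cvp_avg=float(cvp[lo : k + 1].mean()),
                warm_up=(k + 1) < win_len,
            )
            rec = loop.tick(window)
            events.append(rec)
            for iv in rec.interventions:
                if iv.kind in (InterventionKind.FLUID_BOLUS, InterventionKind.TEST_BOLUS):
                    bolus_rate = iv.magnitude / config.bolus_duration_s * 60.0
                    bolus_end = now + config.bolus_duration_s
            next_decision += period

    assert model.volume_balance_error_ml(v0) < 1e-6 * max(1.0, model.cum_in_ml)

    vitals = pd.DataFrame(
        {"time_s": t_out, "pap_mmHg": pap, "dap_mmHg": dap, "cvp_mmHg": cvp}
    )
    cc_mask = (t_out > cc_start) & (t_out <= cc_end)
    bins = bin_one_minute(t_out[cc_mask], pap[cc_mask], start_s=cc_start)
    all_interventions = [iv for rec in events for iv in rec.interventions]
    stats = intervention_stats(all_interventions, (cc_start, cc_end))
    report = time_in_range(bins, stats)

    result = RunResult(
        vitals=vitals, events=events, report=report, seed=seed,
        config=config, params=params, schedule=schedule,
        controller_enabled=controller_enabled, dt_s=dt_s,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def load_run(run_dir: str | Path) -> tuple[pd.DataFrame, list[dict], dict]:
    """Read back the (vitals, events, manifest) artifacts of a run directory."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    vitals = pd.read_csv(run_dir / manifest["artifacts"]["vitals"])
    events: list[dict] = []
    with open(run_dir / manifest["artifacts"]["events"]) as fh:
        for line in fh:
            if line.strip():
                events.append(json.loads(line))
    return vitals, events, manifest
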