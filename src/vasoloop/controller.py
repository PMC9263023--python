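"""Rule-based closed-loop critical-care decision engine.

The controller watches 1-min trailing averages of proximal mean arterial
pressure (MAP) and central venous pressure (CVP) and decides, once per
decision period, whether to give a weight-based crystalloid bolus, titrate
the norepinephrine (NE) infusion, or do nothing.  The decision tree:

* normotension (60–70 mmHg inclusive): no intervention, unless the subject
  is on a large NE dose (> 0.5 mcg/kg/min) with a low CVP (< 6 mmHg), in
  which case a fluid bolus is given so the pressor can subsequently be
  weaned ("normotension corner");
* hypertension (> 70): wean NE by the titration formula, floored at ne_min;
* severe hypotension (< 50): fluid bolus and a simultaneous NE increase;
* moderate hypotension (50–59 inclusive): gated on fluid-responsiveness —
  unknown state fires a 5 mL/kg test bolus; a responsive subject gets
  fluid-avid treatment (bolus); a non-responsive subject gets an NE
  increase, except when CVP is low (bolus instead, to break cyclic NE
  escalation) or NE is already maxed (bolus, "pressor resistance").

Titration magnitude is ``scale x 0.0072 x |MAP - 65| x sqrt(NE)`` with the
NE inside the sqrt floored at the baseline infusion rate so the controller
cannot lock at zero.  Responsiveness resets to unknown every four
interventions or one hour after the last test bolus.

``decide`` is a pure function of (window, state, config); the stateful
plumbing — bolus lockouts, deferred responsiveness assessment — lives in
:class:`ControlLoop`, which drives ``decide`` against a vitals stream.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .config import ControllerConfig

__all__ = [
    "MapZone", "Responsiveness", "InterventionKind",
    "VitalsWindow", "ActiveTest", "ControllerState", "Intervention",
    "TickRecord", "ControlLoop",
    "classify_map", "titration_delta", "assess_responsiveness",
    "maybe_reset_responsiveness", "decide",
]

log = logging.getLogger(__name__)


class MapZone(str, enum.Enum):
    SEVERE_HYPO = "severe_hypo"
    MODERATE_HYPO = "moderate_hypo"
    NORMO = "normo"
    HYPER = "hyper"


class Responsiveness(str, enum.Enum):
    UNKNOWN = "unknown"
    RESPONSIVE = "responsive"
    NON_RESPONSIVE = "non_responsive"


class InterventionKind(str, enum.Enum):
    FLUID_BOLUS = "fluid_bolus"
    TEST_BOLUS = "test_bolus"
    NE_INCREASE = "ne_increase"
    NE_DECREASE = "ne_decrease"
    NONE = "none"


@dataclass(frozen=True)
class VitalsWindow:
    """Trailing 1-min averages the controller acts on.

    ``warm_up`` flags windows computed from less than 60 s of data (the
    first minute of a stream); the controller never decides on them.
    """

    time_s: float
    map_avg: float
    cvp_avg: float
    warm_up: bool = False

    @property
    def valid(self) -> bool:
        return (
            not self.warm_up
            and math.isfinite(self.map_avg)
            and math.isfinite(self.cvp_avg)
            and self.map_avg >= 0.0
        )


@dataclass(frozen=True)
class ActiveTest:
    """Bookkeeping for a fluid-responsiveness test bolus in flight."""

    baseline_map: float
    start_s: float


@dataclass(frozen=True)
class ControllerState:
    ne_rate: float = 0.02
    bolus_count: int = 0
    responsiveness: Responsiveness = Responsiveness.UNKNOWN
    interventions_since_test: int = 0
    last_test_time_s: Optional[float] = None
    active_test: Optional[ActiveTest] = None
    last_intervention_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ne_rate < 0 or not math.isfinite(self.ne_rate):
            raise ValueError(f"ne_rate must be finite and >= 0, got {self.ne_rate}")
        if self.bolus_count < 0 or self.interventions_since_test < 0:
            raise ValueError("counters must be non-negative")


@dataclass(frozen=True)
class Intervention:
    """One actuated decision.

    ``magnitude`` is mL for boluses and the mcg/kg/min delta (always
    positive) for NE titrations; the kind carries the sign.
    """

    kind: InterventionKind
    magnitude: float
    branch: str
    time_s: float

    def __post_init__(self) -> None:
        if self.kind is not InterventionKind.NONE and not self.magnitude > 0:
            raise ValueError(f"{self.kind.value} requires magnitude > 0")

    @property
    def is_bolus(self) -> bool:
        return self.kind in (InterventionKind.FLUID_BOLUS, InterventionKind.TEST_BOLUS)

    @property
    def is_titration(self) -> bool:
        return self.kind in (InterventionKind.NE_INCREASE, InterventionKind.NE_DECREASE)


# ---------------------------------------------------------------------------
# Pure decision operations
# ---------------------------------------------------------------------------

def classify_map(map_avg: float, config: ControllerConfig) -> MapZone:
    """Assign a 1-min MAP average to exactly one pressure zone.

    Boundaries: < 50 severe, [50, 60) moderate, [60, 70] normotensive
    (both ends inclusive), > 70 hypertensive.
    """
    if not math.isfinite(map_avg) or map_avg < 0:
        raise ValueError(f"map_avg must be finite and >= 0, got {map_avg}")
    if map_avg < config.map_severe:
        return MapZone.SEVERE_HYPO
    if map_avg < config.map_low:
        return MapZone.MODERATE_HYPO
    if map_avg <= config.map_high:
        return MapZone.NORMO
    return MapZone.HYPER


def titration_delta(
    map_avg: float, ne_rate: float, branch_scale: int, config: ControllerConfig
) -> float:
    """Unsigned NE titration step (mcg/kg/min).

    delta = scale x 0.0072 x |MAP - 65| x sqrt(max(NE, floor)).  The caller
    applies the sign (increase in hypotension, decrease in hypertension) and
    clamps the resulting rate to [ne_min, ne_max].
    """
    if ne_rate < 0:
        raise ValueError(f"ne_rate must be >= 0, got {ne_rate}")
    if branch_scale < 1:
        raise ValueError(f"branch_scale must be >= 1, got {branch_scale}")
    return (
        branch_scale
        * config.scaling_constant
        * abs(map_avg - config.map_target)
        * math.sqrt(max(ne_rate, config.ne_sqrt_floor))
    )


def assess_responsiveness(
    baseline_map: float, post_map: float, config: ControllerConfig
) -> Responsiveness:
    """Classify a test bolus: responsive iff MAP rose by >= 5 mmHg."""
    if not (math.isfinite(baseline_map) and math.isfinite(post_map)):
        raise ValueError("MAP averages must be finite")
    if post_map - baseline_map >= config.responsiveness_delta:
        return Responsiveness.RESPONSIVE
    return Responsiveness.NON_RESPONSIVE


def maybe_reset_responsiveness(
    state: ControllerState, now_s: float, config: ControllerConfig
) -> ControllerState:
    """Reset the fluid-responsiveness state to unknown when stale.

    Fires after four interventions since the last test bolus, or an hour
    since the last test bolus.  Counters are left untouched: the next test
    bolus zeroes them.
    """
    stale = state.interventions_since_test >= config.reset_after_interventions
    if state.last_test_time_s is not None:
        stale = stale or (now_s - state.last_test_time_s) >= config.reset_after_s
    if stale and state.responsiveness is not Responsiveness.UNKNOWN:
        return replace(state, responsiveness=Responsiveness.UNKNOWN)
    return state


def _clamped_ne(ne_rate: float, delta: float, config: ControllerConfig) -> float:
    return min(max(ne_rate + delta, config.ne_min), config.ne_max)


def decide(
    window: VitalsWindow, state: ControllerState, config: ControllerConfig
) -> tuple[list[Intervention], ControllerState]:
    """One tick of the decision tree; pure in (window, state, config).

    Returns the interventions to actuate this tick plus the updated state.
    A tick with a test bolus in flight is deferred (no decision); boluses do
    not appear here while infusing because :class:`ControlLoop` enforces the
    lockout cadence.
    """
    if not window.valid:
        raise ValueError(f"invalid vitals window at t={window.time_s}")
    if state.active_test is not None:
        log.warning("decide called with a test bolus in flight at t=%s; deferred", window.time_s)
        return [], state

    now = window.time_s
    state = maybe_reset_responsiveness(state, now, config)
    zone = classify_map(window.map_avg, config)
    bolus_ml = config.bolus_volume_ml
    actions: list[Intervention] = []
    new = state

    def bolus(branch: str, kind: InterventionKind = InterventionKind.FLUID_BOLUS) -> None:
        actions.append(Intervention(kind, bolus_ml, branch, now))

    if zone is MapZone.NORMO:
        if state.ne_rate > config.high_ne_threshold and window.cvp_avg < config.low_cvp_threshold:
            bolus("normotension_corner")

    elif zone is MapZone.HYPER:
        branch = "hypertension_wean"
        step = titration_delta(window.map_avg, state.ne_rate, config.branch_scale(branch), config)
        target = _clamped_ne(state.ne_rate, -step, config)
        applied = state.ne_rate - target
        if applied > 0:
            actions.append(Intervention(InterventionKind.NE_DECREASE, applied, branch, now))
            new = replace(new, ne_rate=target)
        # already at the NE floor: fluids are never withdrawn, so no action

    elif zone is MapZone.SEVERE_HYPO:
        branch = "severe_hypotension"
        bolus(branch)
        step = titration_delta(window.map_avg, state.ne_rate, config.branch_scale(branch), config)
        target = _clamped_ne(state.ne_rate, step, config)
        applied = target - state.ne_rate
        if applied > 0:
            actions.append(Intervention(InterventionKind.NE_INCREASE, applied, branch, now))
            new = replace(new, ne_rate=target)

    else:  # moderate hypotension
        if state.responsiveness is Responsiveness.UNKNOWN:
            branch = "moderate_hypotension_test"
            actions.append(Intervention(InterventionKind.TEST_BOLUS, bolus_ml, branch, now))
            new = replace(
                new,
                active_test=ActiveTest(baseline_map=window.map_avg, start_s=now),
                last_test_time_s=now,
                interventions_since_test=0,
            )
        elif state.responsiveness is Responsiveness.RESPONSIVE:
            bolus("moderate_hypotension_responsive")
        else:  # non-responsive: vasopressor-avid, with two fluid corner cases
            if window.cvp_avg < config.low_cvp_threshold:
                bolus("cvp_based_fluid_bolus")
            elif state.ne_rate >= config.ne_max:
                bolus("pressor_resistance")
            else:
                branch = "moderate_hypotension_pressor"
                step = titration_delta(
                    window.map_avg, state.ne_rate, config.branch_scale(branch), config
                )
                target = _clamped_ne(state.ne_rate, step, config)
                applied = target - state.ne_rate
                if applied > 0:
                    actions.append(Intervention(InterventionKind.NE_INCREASE, applied, branch, now))
                    new = replace(new, ne_rate=target)

    if actions:
        test = any(a.kind is InterventionKind.TEST_BOLUS for a in actions)
        n_boluses = sum(a.kind is InterventionKind.FLUID_BOLUS for a in actions)
        new = replace(
            new,
            bolus_count=new.bolus_count + n_boluses,
            last_intervention_time_s=now,
            # one decision event for the reset counter, however many actions;
            # the test bolus itself restarts the count at zero
            interventions_since_test=(
                new.interventions_since_test if test else new.interventions_since_test + 1
            ),
        )
    return actions, new


# ---------------------------------------------------------------------------
# Stateful loop driver
# ---------------------------------------------------------------------------

@dataclass
class TickRecord:
    """One evaluated decision tick, as written to the event log."""

    time_s: float
    map_avg: float
    cvp_avg: float
    zone: Optional[str]
    branch: Optional[str]
    interventions: list[Intervention] = field(default_factory=list)
    ne_rate_after: float = 0.0
    responsiveness: str = Responsiveness.UNKNOWN.value
    status: str = "ok"  # ok | deferred | invalid | warm_up

    def to_json_dict(self) -> dict:
        return {
            "time_s": self.time_s,
            "map_avg": self.map_avg,
            "cvp_avg": self.cvp_avg,
            "zone": self.zone,
            "branch": self.branch,
            "interventions": [
                {"kind": iv.kind.value, "magnitude": iv.magnitude,
                 "branch": iv.branch, "time_s": iv.time_s}
                for iv in self.interventions
            ],
            "ne_rate_after": self.ne_rate_after,
            "responsiveness": self.responsiveness,
            "status": self.status,
        }


class ControlLoop:
    """Drives ``decide`` against a stream of vitals windows.

    Owns the non-pure bookkeeping the spec of the decision function keeps
    out of ``decide``: the bolus lockout (no new decision while a bolus is
    infusing or its assessment window is open) and the completion of
    fluid-responsiveness tests.  Feed it one :class:`VitalsWindow` per
    decision period via :meth:`tick`; read pump commands off the returned
    interventions and the NE rate off ``state.ne_rate``.
    """

    def __init__(self, config: ControllerConfig, state: ControllerState | None = None):
        self.config = config
        self.state = state if state is not None else ControllerState()
        self.busy_until_s: float = -math.inf
        self._assess_due_s: Optional[float] = None

    def tick(self, window: VitalsWindow) -> TickRecord:
        rec = TickRecord(
            time_s=window.time_s,
            map_avg=window.map_avg,
            cvp_avg=window.cvp_avg,
            zone=None,
            branch=None,
            ne_rate_after=self.state.ne_rate,
            responsiveness=self.state.responsiveness.value,
        )
        if window.warm_up:
            rec.status = "warm_up"
            return rec
        if not window.valid:
            log.warning("invalid vitals at t=%s (map=%s cvp=%s); tick skipped",
                        window.time_s, window.map_avg, window.cvp_avg)
            rec.status = "invalid"
            return rec

        # close an open responsiveness assessment first, so the same tick
        # can act on the fresh classification
        if (
            self.state.active_test is not None
            and self._assess_due_s is not None
            and window.time_s >= self._assess_due_s
        ):
            verdict = assess_responsiveness(
                self.state.active_test.baseline_map, window.map_avg, self.config
            )
            self.state = replace(self.state, responsiveness=verdict, active_test=None)
            self._assess_due_s = None

        if window.time_s < self.busy_until_s or self.state.active_test is not None:
            rec.status = "deferred"
            rec.responsiveness = self.state.responsiveness.value
            return rec

        interventions, self.state = decide(window, self.state, self.config)
        rec.zone = classify_map(window.map_avg, self.config).value
        rec.interventions = interventions
        rec.branch = interventions[0].branch if interventions else None
        rec.ne_rate_after = self.state.ne_rate
        rec.responsiveness = self.state.responsiveness.value

        for iv in interventions:
            if iv.is_bolus:
                # lockout until the bolus has run in and settled
                self.busy_until_s = max(
                    self.busy_until_s,
                    window.time_s + self.config.bolus_duration_s + self.config.assess_lag_s,
                )
            if iv.kind is InterventionKind.TEST_BOLUS:
                self._assess_due_s = (
                    window.time_s + self.config.bolus_duration_s + self.config.assess_lag_s
                )
        return rec
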