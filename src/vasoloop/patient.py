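"""Synthetic swine hemodynamics: a lumped-parameter ischemia–reperfusion model.

This module is the stand-in for the animal.  It is deliberately minimal — a
test harness for the controller, not a physiological claim — and collapses
the circulation to four slow states:

* **blood volume** ``V`` (mL), driven by infusions, hemorrhage and a
  capillary leak that drains volume in excess of a reference volume; a
  fraction ``bolus_retention`` of every crystalloid mL permanently raises
  that reference (interstitial re-equilibration), so a bolus decays toward
  ``bolus_retention x bolus_ml`` retained;
* **vascular tone** (0–1]: ischemic burden accrues during aortic occlusion
  and converts to vasodilation after reperfusion with time constant
  ``injury_tau_s``, then recovers with ``recovery_tau_s`` — this is the
  post-reperfusion vasodilatory shock the controller must treat;
* **norepinephrine effect**: first-order lag toward a Hill function of the
  infusion rate, multiplying systemic vascular resistance (SVR);
* a slow Ornstein–Uhlenbeck drift on tone plus white measurement noise on
  the emitted pressures, both seed-controlled.

Pressures derive algebraically: CVP from venous capacitance
(``(V - V_unstressed)/C_v``), cardiac output from a saturating
preload→output (Starling) curve, and MAP = CO x SVR(tone, NE), with
proximal MAP amplified and distal MAP collapsed to a small stump pressure
under balloon occlusion.  Mean pressures only — no pulse waveform.

``svr_baseline`` is calibrated at construction so the model starts at
equilibrium: baseline MAP at full volume, full tone and the 0.02 mcg/kg/min
background norepinephrine infusion.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["PatientParams", "PatientState", "PatientModel", "BolusResponse",
           "apply_bolus_kinetics"]


@dataclass
class PatientParams:
    """Parameters of the synthetic patient (defaults: ~70 kg adult swine)."""

    weight_kg: float = 70.0
    ebv_ml_per_kg: float = 60.0          # estimated blood volume, mL per kg
    baseline_map: float = 63.0           # equilibrium proximal MAP, mmHg
    unstressed_frac: float = 0.5         # fraction of EBV exerting no venous pressure
    venous_compliance: Optional[float] = None   # mL/mmHg; default 3.75 x weight
    co_max_l_min: Optional[float] = None        # L/min; default 8/70 x weight
    cvp_half_mmhg: float = 4.5           # CVP at half-maximal cardiac output
    svr_baseline: Optional[float] = None # mmHg·min/L; calibrated if None
    ne_emax: float = 1.5                 # max fractional SVR gain from NE
    ne_ec50: float = 0.08                # mcg/kg/min at half-maximal NE effect
    ne_tau_s: float = 60.0               # NE effect-site time constant
    injury_tone_drop: float = 0.40       # tone lost after a full 30-min occlusion
    injury_tau_s: float = 240.0          # vasodilation onset after reperfusion
    recovery_tau_s: float = 9000.0       # slow recovery of vascular tone
    occlusion_charge_s: float = 1800.0   # full-occlusion time to accrue full injury
    occ_prox_gain: float = 1.2           # proximal afterload gain at full occlusion
    distal_stump_mmhg: float = 12.0      # distal mean pressure under full occlusion
    leak_rate_per_min: float = 0.03      # fraction of excess volume lost per min
    bolus_retention: float = 0.4         # crystalloid fraction retained at steady state
    noise_sd: float = 2.0                # measurement noise on pressures, mmHg
    cvp_noise_sd: float = 0.5            # measurement noise on CVP, mmHg
    tone_drift_sd: float = 0.02          # OU drift sd on tone
    tone_drift_tau_s: float = 300.0      # OU drift time constant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.venous_compliance is None:
            self.venous_compliance = 3.75 * self.weight_kg
        if self.co_max_l_min is None:
            self.co_max_l_min = 8.0 / 70.0 * self.weight_kg
        for name in ("weight_kg", "ebv_ml_per_kg", "baseline_map", "venous_compliance",
                     "co_max_l_min", "cvp_half_mmhg", "ne_ec50", "ne_tau_s",
                     "injury_tau_s", "recovery_tau_s", "occlusion_charge_s",
                     "tone_drift_tau_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.bolus_retention <= 1:
            raise ValueError("bolus_retention must be in (0, 1]")
        if not 0 <= self.injury_tone_drop < 1:
            raise ValueError("injury_tone_drop must be in [0, 1)")
        if self.leak_rate_per_min < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be non-negative")
        if self.svr_baseline is None:
            self.svr_baseline = self._calibrate_svr()

    @property
    def ebv_ml(self) -> float:
        return self.ebv_ml_per_kg * self.weight_kg

    def _hill(self, ne_rate: float) -> float:
        return ne_rate / (ne_rate + self.ne_ec50)

    def _cardiac_output(self, cvp: float) -> float:
        cvp = max(cvp, 0.0)
        return self.co_max_l_min * cvp / (cvp + self.cvp_half_mmhg)

    def _cvp_of_volume(self, volume_ml: float) -> float:
        return max(0.0, (volume_ml - self.unstressed_frac * self.ebv_ml) / self.venous_compliance)

    def _calibrate_svr(self) -> float:
        """SVR such that MAP = baseline_map at equilibrium (full volume,
        tone 1, background NE of 0.02 mcg/kg/min)."""
        co = self._cardiac_output(self._cvp_of_volume(self.ebv_ml))
        ne_factor = 1.0 + self.ne_emax * self._hill(0.02)
        return self.baseline_map / (co * ne_factor)


@dataclass(frozen=True)
class PatientState:
    """Snapshot of the model, including the noisy measured pressures."""

    t_s: float
    blood_volume_ml: float
    vascular_tone: float
    ne_effect: float
    map_mmHg: float
    map_distal_mmHg: float
    cvp_mmHg: float


class PatientModel:
    """Steps the lumped-parameter model forward; deterministic given seed."""

    def __init__(
        self,
        params: PatientParams | None = None,
        seed: int | None = None,
        initial_volume_frac: float = 1.0,
        initial_ne: float = 0.02,
    ):
        self.params = params if params is not None else PatientParams()
        p = self.params
        self._rng = np.random.default_rng(p.seed if seed is None else seed)
        self._nbuf = np.empty(0)
        self._nidx = 0

        self.t_s = 0.0
        self.volume_ml = initial_volume_frac * p.ebv_ml
        self.v_ref_ml = self.volume_ml       # leak reference volume
        self.injury_pool = 0.0               # accrued ischemic burden (tone units)
        self.injury_active = 0.0             # currently expressed vasodilation
        self.tone_drift = 0.0                # OU perturbation on tone
        self.ne_effect = p._hill(initial_ne)
        # conservation bookkeeping (exact, mL)
        self.cum_in_ml = 0.0
        self.cum_out_ml = 0.0
        self.cum_leak_ml = 0.0
        self._last_sample = (p.baseline_map, p.baseline_map, p._cvp_of_volume(self.volume_ml))

    # -- internals ----------------------------------------------------------

    def _randn(self) -> float:
        if self._nidx >= self._nbuf.size:
            self._nbuf = self._rng.standard_normal(8192)
            self._nidx = 0
        v = self._nbuf[self._nidx]
        self._nidx += 1
        return float(v)

    @property
    def tone(self) -> float:
        return min(1.0, max(0.05, 1.0 - self.injury_active + self.tone_drift))

    def core_pressures(self, occlusion_fraction: float = 0.0) -> tuple[float, float, float]:
        """Noise-free (proximal MAP, distal MAP, CVP) at the current state."""
        p = self.params
        cvp = p._cvp_of_volume(self.volume_ml)
        co = p._cardiac_output(cvp)
        svr = p.svr_baseline * self.tone * (1.0 + p.ne_emax * self.ne_effect)
        map_core = co * svr * (1.0 + p.occ_prox_gain * occlusion_fraction)
        dap_core = (1.0 - occlusion_fraction) * map_core + occlusion_fraction * p.distal_stump_mmhg
        return map_core, dap_core, cvp

    # -- stepping -----------------------------------------------------------

    def step(
        self,
        dt_s: float,
        ne_rate: float = 0.02,
        fluid_rate_ml_min: float = 0.0,
        blood_rate_ml_min: float = 0.0,
        hemorrhage_rate_ml_min: float = 0.0,
        occlusion_fraction: float = 0.0,
    ) -> tuple[float, float, float]:
        """Advance one step; returns the measured (pap, dap, cvp) sample in mmHg."""
        if not 0.0 < dt_s <= 1.0:
            raise ValueError(f"dt_s must be in (0, 1], got {dt_s}")
        if min(ne_rate, fluid_rate_ml_min, blood_rate_ml_min, hemorrhage_rate_ml_min) < 0:
            raise ValueError("actuation rates must be non-negative")
        if not 0.0 <= occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must be in [0, 1]")
        p = self.params

        # volume balance (mL over this step); leak only drains excess over v_ref
        inflow = (fluid_rate_ml_min + blood_rate_ml_min) / 60.0 * dt_s
        outflow = hemorrhage_rate_ml_min / 60.0 * dt_s
        leak = p.leak_rate_per_min / 60.0 * max(0.0, self.volume_ml - self.v_ref_ml) * dt_s
        drained = outflow + leak
        available = self.volume_ml + inflow
        if drained > available:             # cannot drain below empty
            scale = available / drained if drained > 0 else 0.0
            outflow *= scale
            leak *= scale
        self.volume_ml += inflow - outflow - leak
        self.cum_in_ml += inflow
        self.cum_out_ml += outflow
        self.cum_leak_ml += leak
        self.v_ref_ml += p.bolus_retention * fluid_rate_ml_min / 60.0 * dt_s \
            + blood_rate_ml_min / 60.0 * dt_s - outflow

        # ischemic burden charges under occlusion, releases as vasodilation
        if occlusion_fraction > 0.0:
            self.injury_pool = min(
                p.injury_tone_drop,
                self.injury_pool
                + p.injury_tone_drop * occlusion_fraction / p.occlusion_charge_s * dt_s,
            )
        reperfused = 1.0 - occlusion_fraction
        self.injury_pool -= self.injury_pool / p.recovery_tau_s * reperfused * dt_s
        self.injury_active += (
            (self.injury_pool * reperfused - self.injury_active) / p.injury_tau_s * dt_s
        )

        # OU drift on tone (seeded variability between runs)
        tau = p.tone_drift_tau_s
        self.tone_drift += (-self.tone_drift / tau) * dt_s \
            + p.tone_drift_sd * math.sqrt(2.0 * dt_s / tau) * self._randn()

        # NE effect-site lag toward the Hill response
        self.ne_effect += (p._hill(ne_rate) - self.ne_effect) / p.ne_tau_s * dt_s

        self.t_s += dt_s
        map_core, dap_core, cvp_core = self.core_pressures(occlusion_fraction)
        pap = max(0.0, map_core + p.noise_sd * self._randn())
        dap = max(0.0, dap_core + p.noise_sd * self._randn())
        cvp = max(0.0, cvp_core + p.cvp_noise_sd * self._randn())
        self._last_sample = (pap, dap, cvp)
        return pap, dap, cvp

    def snapshot(self) -> PatientState:
        pap, dap, cvp = self._last_sample
        return PatientState(
            t_s=self.t_s,
            blood_volume_ml=self.volume_ml,
            vascular_tone=self.tone,
            ne_effect=self.ne_effect,
            map_mmHg=pap,
            map_distal_mmHg=dap,
            cvp_mmHg=cvp,
        )

    def volume_balance_error_ml(self, initial_volume_ml: float) -> float:
        """|V - (V0 + inflows - hemorrhage - leak)|; ~machine precision."""
        return abs(
            self.volume_ml - (initial_volume_ml + self.cum_in_ml
                              - self.cum_out_ml - self.cum_leak_ml)
        )


@dataclass
class BolusResponse:
    """Trajectory of a bolus challenge plus its 1-min-average MAP change."""

    t_s: np.ndarray
    volume_ml: np.ndarray
    map_mmHg: np.ndarray
    baseline_map: float
    post_map: float

    @property
    def delta_map(self) -> float:
        return self.post_map - self.baseline_map


def apply_bolus_kinetics(
    model: PatientModel,
    bolus_ml: float,
    duration_s: float = 120.0,
    ne_rate: float = 0.02,
    observe_s: float = 240.0,
    dt_s: float = 0.1,
) -> BolusResponse:
    """Run a crystalloid bolus challenge on a copy of ``model``.

    Simulates 60 s of baseline, the bolus over ``duration_s``, and an
    observation tail; the reported MAP change is the difference between the
    1-min average ending 60 s after bolus completion and the 1-min average
    immediately preceding the bolus — the same windows the controller's
    fluid-responsiveness test uses.  A zero bolus leaves the state unchanged
    and reports a trivial trajectory.
    """
    if bolus_ml < 0:
        raise ValueError("bolus_ml must be >= 0")
    if bolus_ml == 0:
        snap = model.snapshot()
        return BolusResponse(
            t_s=np.array([snap.t_s]), volume_ml=np.array([model.volume_ml]),
            map_mmHg=np.array([snap.map_mmHg]),
            baseline_map=snap.map_mmHg, post_map=snap.map_mmHg,
        )
    sim = copy.deepcopy(model)
    rate = bolus_ml / duration_s * 60.0  # mL/min
    segments = [(60.0, 0.0), (duration_s, rate), (observe_s, 0.0)]
    ts, vols, maps = [], [], []
    for seg_len, fluid in segments:
        for _ in range(int(round(seg_len / dt_s))):
            pap, _, _ = sim.step(dt_s, ne_rate=ne_rate, fluid_rate_ml_min=fluid)
            ts.append(sim.t_s)
            vols.append(sim.volume_ml)
            maps.append(pap)
    t = np.asarray(ts)
    m = np.asarray(maps)
    t0 = t[0] + 60.0                      # bolus start
    t_post = t0 + duration_s + 60.0       # assessment window close
    baseline = float(m[(t > t0 - 60.0) & (t <= t0)].mean())
    post = float(m[(t > t_post - 60.0) & (t <= t_post)].mean())
    return BolusResponse(
        t_s=t, volume_ml=np.asarray(vols), map_mmHg=m,
        baseline_map=baseline, post_map=post,
    )
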