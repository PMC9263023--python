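"""Controller configuration.

All pressure thresholds are in mmHg, norepinephrine (NE) rates in
mcg/kg/min, volumes in mL, and times in seconds.  Unit conversions happen
only at I/O boundaries (CSV/YAML), never inside the decision logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ControllerConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration document is malformed or inconsistent."""


#: Closed set of decision-tree leaves an Intervention may be tagged with.
BRANCHES = (
    "severe_hypotension",
    "moderate_hypotension_test",
    "moderate_hypotension_responsive",
    "moderate_hypotension_pressor",
    "cvp_based_fluid_bolus",
    "pressor_resistance",
    "hypertension_wean",
    "normotension_corner",
)


def _default_branch_scales() -> dict[str, int]:
    # Larger corrective step for the larger deviation: severe hypotension
    # titrates with scale 2, all other titrating branches with scale 1.
    return {
        "severe_hypotension": 2,
        "moderate_hypotension_pressor": 1,
        "hypertension_wean": 1,
    }


@dataclass
class ControllerConfig:
    """Parameters of the rule-based pressure controller.

    The defaults encode the published protocol: keep the 1-min mean arterial
    pressure (MAP) in the inclusive 60–70 mmHg band around a 65 mmHg target,
    treat MAP < 50 as severe hypotension, give weight-based crystalloid
    boluses of 5 mL/kg over 2 min, call a test bolus "responsive" when MAP
    rises by at least 5 mmHg, and reset the fluid-responsiveness state every
    four interventions or one hour after the last test bolus.
    """

    weight_kg: float = 70.0
    map_low: float = 60.0
    map_high: float = 70.0
    map_severe: float = 50.0
    map_target: float = 65.0
    scaling_constant: float = 0.0072
    branch_scale_factors: dict[str, int] = field(default_factory=_default_branch_scales)
    bolus_dose_ml_kg: float = 5.0
    bolus_duration_s: float = 120.0
    responsiveness_delta: float = 5.0
    high_ne_threshold: float = 0.5
    low_cvp_threshold: float = 6.0
    ne_max: float = 1.0
    ne_min: float = 0.0
    #: Floor inside the sqrt of the titration formula so the controller can
    #: escalate from NE = 0; equals the baseline background infusion rate.
    ne_sqrt_floor: float = 0.02
    reset_after_interventions: int = 4
    reset_after_s: float = 3600.0
    decision_period_s: float = 60.0
    #: Post-bolus settling time before the responsiveness window closes.
    assess_lag_s: float = 60.0

    def __post_init__(self) -> None:
        if not (self.map_severe < self.map_low <= self.map_target <= self.map_high):
            raise ConfigError(
                "require map_severe < map_low <= map_target <= map_high, got "
                f"{self.map_severe}/{self.map_low}/{self.map_target}/{self.map_high}"
            )
        for name in (
            "weight_kg", "map_low", "map_high", "map_severe", "map_target",
            "scaling_constant", "bolus_dose_ml_kg", "bolus_duration_s",
            "responsiveness_delta", "high_ne_threshold", "low_cvp_threshold",
            "reset_after_s", "decision_period_s",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ConfigError(f"{name} must be a positive finite number, got {v!r}")
        if not self.ne_min < self.ne_max:
            raise ConfigError(f"ne_min ({self.ne_min}) must be < ne_max ({self.ne_max})")
        if self.ne_min < 0:
            raise ConfigError("ne_min must be >= 0")
        if self.reset_after_interventions < 1:
            raise ConfigError("reset_after_interventions must be >= 1")
        unknown = set(self.branch_scale_factors) - set(BRANCHES)
        if unknown:
            raise ConfigError(f"unknown branch labels in scale factors: {sorted(unknown)}")
        for branch, scale in self.branch_scale_factors.items():
            if not (isinstance(scale, int) and scale >= 1):
                raise ConfigError(f"branch scale for {branch} must be an integer >= 1")

    # -- derived quantities -------------------------------------------------

    @property
    def bolus_volume_ml(self) -> float:
        """Weight-based bolus volume (mL): dose [mL/kg] x weight [kg]."""
        return self.bolus_dose_ml_kg * self.weight_kg

    @property
    def bolus_rate_l_per_h(self) -> float:
        """Bolus infusion rate in L/h (350 mL over 2 min -> 10.5 L/h)."""
        return self.bolus_volume_ml / self.bolus_duration_s * 3.6

    def branch_scale(self, branch: str) -> int:
        return self.branch_scale_factors.get(branch, 1)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path) -> ControllerConfig:
    """Load a ControllerConfig from a YAML document.

    The document may either be a flat mapping of ControllerConfig fields or
    contain them under a ``controller:`` key (the layout used by the
    simulator configs, which also carry a ``patient:`` namespace).
    """
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if doc is None:
        return ControllerConfig()
    if not isinstance(doc, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    section = doc.get("controller", doc)
    if not isinstance(section, Mapping):
        raise ConfigError("'controller' section must be a mapping")
    known = set(ControllerConfig.__dataclass_fields__)
    fields = {k: v for k, v in section.items() if k in known}
    unknown = set(section) - known
    if section is doc:
        unknown -= {"patient", "schedule", "run"}
    if unknown:
        raise ConfigError(f"unknown controller config keys: {sorted(unknown)}")
    try:
        return ControllerConfig(**fields)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: ControllerConfig, path: str | Path) -> None:
    """Write a config back out as a flat YAML mapping."""
    with open(path, "w") as fh:
        yaml.safe_dump({"controller": config.to_dict()}, fh, sort_keys=False)
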