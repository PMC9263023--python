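"""Controller-only replay of recorded or external vitals.

Runs the decision engine over a CSV vitals stream with no simulator in the
loop: the controller's decisions are logged but nothing feeds back into the
pressures.  Useful for auditing the decision tree against recorded data and
for deterministic regression of controller behavior.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, ControllerConfig
from .controller import ControlLoop, ControllerState, TickRecord, VitalsWindow

__all__ = ["replay_vitals", "write_event_log"]

REQUIRED_COLUMNS = ("time_s", "pap_mmHg", "cvp_mmHg")


def replay_vitals(
    vitals: pd.DataFrame | str | Path,
    config: ControllerConfig | None = None,
    initial_state: ControllerState | None = None,
) -> list[TickRecord]:
    """Tick the controller over a vitals stream at its decision cadence.

    ``vitals`` is a DataFrame or CSV path with columns
    ``time_s, pap_mmHg, cvp_mmHg`` at any sample rate >= 1 Hz.  The first
    60 s are warm-up (no decisions); windows containing non-finite samples
    invalidate their tick, which is flagged and skipped, never imputed.
    """
    if not isinstance(vitals, pd.DataFrame):
        vitals = pd.read_csv(vitals)
    missing = [c for c in REQUIRED_COLUMNS if c not in vitals.columns]
    if missing:
        raise ConfigError(f"vitals CSV missing required columns: {missing}")
    if len(vitals) == 0:
        return []
    config = config if config is not None else ControllerConfig()

    t = vitals["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ConfigError("vitals samples must be time-ordered")
    pap = vitals["pap_mmHg"].to_numpy(dtype=float)
    cvp = vitals["cvp_mmHg"].to_numpy(dtype=float)

    loop = ControlLoop(config, initial_state)
    records: list[TickRecord] = []
    t0 = t[0]
    period = config.decision_period_s
    tick_time = t0 + period
    while tick_time <= t[-1] + 1e-9:
        mask = (t > tick_time - 60.0) & (t <= tick_time + 1e-9)
        if mask.any():
            m_win = pap[mask]
            c_win = cvp[mask]
            map_avg = float(np.mean(m_win))        # NaN if any sample is NaN
            cvp_avg = float(np.mean(c_win))
            if not (math.isfinite(map_avg) and math.isfinite(cvp_avg)):
                map_avg = map_avg if math.isfinite(map_avg) else float("nan")
                cvp_avg = cvp_avg if math.isfinite(cvp_avg) else float("nan")
            window = VitalsWindow(
                time_s=tick_time,
                map_avg=map_avg,
                cvp_avg=cvp_avg,
                warm_up=(tick_time - t0) < 60.0,
            )
            records.append(loop.tick(window))
        tick_time += period
    return records


def write_event_log(records: list[TickRecord], path: str | Path) -> None:
    """Write decision ticks as JSON-lines, one record per tick."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json_dict()) + "\n")
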