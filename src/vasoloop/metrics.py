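"""Time-in-range metrics, intervention statistics and cohort summaries.

High-rate pressure data are reduced to 1-min bins (arithmetic mean per
bin, trailing partial bin dropped), classified into pressure bands —
hypotension < 60 mmHg, normotension 60–70 mmHg inclusive, hypertension
> 70 mmHg, with hypertension subdivided at 80 mmHg — and summarized per
run as percentages of bins.  Cohorts are rolled up as medians with
interquartile ranges using linear-interpolation (type-7) order statistics.

A bin of exactly 70 mmHg is normotensive; the 70–80 sub-band therefore
covers (70, 80] so that the sub-bands partition the hypertensive band and
all bands sum to 100%.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .controller import Intervention, InterventionKind

__all__ = [
    "TimeInRangeReport", "InterventionStats",
    "bin_one_minute", "time_in_range", "intervention_stats",
    "cohort_summary", "exclusion_screen", "reference_cohort",
]

BAND_FIELDS = ("pct_lt60", "pct_60_70", "pct_70_80", "pct_gt80", "pct_gt70")


@dataclass
class InterventionStats:
    per_hour: float
    pct_boluses: Optional[float]     # None when no interventions (mix undefined)
    pct_titrations: Optional[float]
    n_interventions: int
    n_boluses: int
    n_titrations: int


@dataclass
class TimeInRangeReport:
    """Per-run proportions of 1-min bins in each pressure band."""

    pct_lt60: float
    pct_60_70: float
    pct_70_80: float
    pct_gt80: float
    pct_gt70: float
    n_bins: int
    interventions_per_hour: Optional[float] = None
    pct_boluses: Optional[float] = None
    pct_titrations: Optional[float] = None
    n_interventions: Optional[int] = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def bin_one_minute(
    time_s: Sequence[float] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    start_s: float | None = None,
    bin_s: float = 60.0,
) -> np.ndarray:
    """Mean of ``values`` over consecutive, non-overlapping 1-min bins.

    Samples are timestamped at the end of their acquisition interval, so a
    sample at exactly ``start + 60`` closes the first bin.  The trailing
    partial bin is dropped.  Any sample rate is accepted; an empty stream
    yields an empty array.
    """
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        return np.empty(0)
    if t.size != v.size:
        raise ValueError("time and value arrays must have equal length")
    if np.any(np.diff(t) < 0):
        raise ValueError("samples must be time-ordered")
    if start_s is None:
        # samples are stamped at interval end: the stream starts one sample
        # interval before the first timestamp
        dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
        t0 = float(t[0]) - dt
    else:
        t0 = float(start_s)
    rel = t - t0
    keep = rel > 0
    rel, v = rel[keep], v[keep]
    if rel.size == 0:
        return np.empty(0)
    idx = np.ceil(rel / bin_s).astype(np.int64) - 1
    n_bins = int(np.floor(rel[-1] / bin_s + 1e-9))
    full = idx < n_bins
    idx, v = idx[full], v[full]
    if n_bins == 0:
        return np.empty(0)
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        return sums / counts


def time_in_range(
    bins: Sequence[float] | np.ndarray,
    stats: InterventionStats | None = None,
) -> TimeInRangeReport:
    """Band percentages over 1-min MAP bins (inclusive 60–70 normotension)."""
    b = np.asarray(bins, dtype=float)
    if b.size == 0:
        raise ValueError("time_in_range requires at least one bin")
    pct = lambda mask: float(np.count_nonzero(mask)) / b.size * 100.0
    rep = TimeInRangeReport(
        pct_lt60=pct(b < 60.0),
        pct_60_70=pct((b >= 60.0) & (b <= 70.0)),
        pct_70_80=pct((b > 70.0) & (b <= 80.0)),
        pct_gt80=pct(b > 80.0),
        pct_gt70=pct(b > 70.0),
        n_bins=int(b.size),
    )
    if stats is not None:
        rep.interventions_per_hour = stats.per_hour
        rep.pct_boluses = stats.pct_boluses
        rep.pct_titrations = stats.pct_titrations
        rep.n_interventions = stats.n_interventions
    return rep


def intervention_stats(
    interventions: Iterable[Intervention],
    window_s: tuple[float, float],
) -> InterventionStats:
    """Intervention rate and bolus/titration mix over a phase window.

    Test boluses count as boluses; every NE change, up or down, counts as
    one titration.  The severe-hypotension combined action therefore
    contributes one bolus and one titration here even though it is a single
    decision event for the responsiveness-reset counter.
    """
    start, end = window_s
    if not end > start:
        raise ValueError("window end must be after start")
    inside = [iv for iv in interventions if start <= iv.time_s < end]
    n_bol = sum(iv.is_bolus for iv in inside)
    n_tit = sum(iv.is_titration for iv in inside)
    n = n_bol + n_tit
    hours = (end - start) / 3600.0
    if n == 0:
        return InterventionStats(0.0, None, None, 0, 0, 0)
    return InterventionStats(
        per_hour=n / hours,
        pct_boluses=n_bol / n * 100.0,
        pct_titrations=n_tit / n * 100.0,
        n_interventions=n,
        n_boluses=n_bol,
        n_titrations=n_tit,
    )


def cohort_summary(reports: Sequence[TimeInRangeReport] | pd.DataFrame) -> pd.DataFrame:
    """Median and IQR per report field across a cohort of runs.

    Quantiles use linear interpolation between order statistics (numpy's
    default, quantile type 7): for n = 5 the quartiles are exactly the 2nd
    and 4th order statistics.
    """
    if isinstance(reports, pd.DataFrame):
        df = reports.copy()
    else:
        if len(reports) == 0:
            raise ValueError("cohort_summary requires at least one report")
        df = pd.DataFrame([r.to_dict() for r in reports])
    df = df.select_dtypes("number").dropna(axis=1, how="all")
    out = {}
    for col in df.columns:
        vals = df[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
        out[col] = {"median": med, "q1": q1, "q3": q3, "n": vals.size}
    return pd.DataFrame(out).T[["median", "q1", "q3", "n"]]


def exclusion_screen(
    time_s: Sequence[float] | np.ndarray,
    map_mmhg: Sequence[float] | np.ndarray,
    ne_rate: Sequence[float] | np.ndarray,
    *,
    setup_window: tuple[float, float],
    t_zero: float,
) -> list[str]:
    """Hemodynamic exclusion flags for one subject's record.

    * ``expiration`` — MAP < 20 mmHg sustained for 5 contiguous minutes at
      any time;
    * ``setup_pressor`` — NE > 0.1 mcg/kg/min for more than 10 min
      cumulative during the setup window;
    * ``baseline_pressor`` — NE > 0.06 mcg/kg/min at time zero.

    The white-cell-count criterion of the source protocol needs laboratory
    input and is intentionally not implemented.
    """
    t = np.asarray(time_s, dtype=float)
    m = np.asarray(map_mmhg, dtype=float)
    ne = np.asarray(ne_rate, dtype=float)
    if not (t.size == m.size == ne.size and t.size > 1):
        raise ValueError("time, MAP and NE arrays must align and have >= 2 samples")
    if setup_window is None or not setup_window[1] > setup_window[0]:
        raise ValueError("setup_window must be an increasing (start, end) pair")
    dt = float(np.median(np.diff(t)))
    flags: list[str] = []

    low = (m < 20.0).astype(np.int64)
    if low.any():
        # longest contiguous run of sub-20 samples, in seconds
        padded = np.concatenate([[0], low, [0]])
        edges = np.flatnonzero(np.diff(padded))
        run_lengths = edges[1::2] - edges[0::2]
        if run_lengths.size and run_lengths.max() * dt >= 300.0:
            flags.append("expiration")

    in_setup = (t >= setup_window[0]) & (t < setup_window[1])
    if float(np.count_nonzero(in_setup & (ne > 0.1))) * dt > 600.0:
        flags.append("setup_pressor")

    if ne[np.argmin(np.abs(t - t_zero))] > 0.06:
        flags.append("baseline_pressor")
    return flags


def reference_cohort() -> pd.DataFrame:
    """Bundled five-subject reference cohort of time-at-range percentages.

    Per-subject percentages of 1-min bins in each pressure band over a
    255-min critical-care phase, used as the fixture for cohort-statistics
    checks (its < 60 mmHg column has median 15.3%, IQR 8.6–16.9%).
    """
    with resources.files("vasoloop.data").joinpath("cohort_reference.csv").open() as fh:
        df = pd.read_csv(fh)
    df["pct_gt70"] = df["pct_70_80"] + df["pct_gt80"]
    return df


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Display rounding: one decimal, half away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def write_cohort_csv(summary: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort summary as CSV with one-decimal half-up display rounding."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["field", "median", "q1", "q3", "n"])
        for field, row in summary.iterrows():
            writer.writerow([
                field,
                round_half_up(row["median"]), round_half_up(row["q1"]),
                round_half_up(row["q3"]), int(row["n"]),
            ])
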