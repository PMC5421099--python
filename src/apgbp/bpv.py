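"""24-hour blood-pressure variability analytics.

Implements the ambulatory-monitoring summaries a BP-tracking
application surfaces: nocturnal dipping-pattern classification, daily
and per-weekday statistics, and BP histograms.

Daytime is the local-clock window [06:00, 22:00) and nighttime
[22:00, 06:00); a reading stamped exactly 22:00 is nocturnal.  The
dipping label follows the standard clinical convention on the
percentage nocturnal decline of mean systolic pressure:

* decline < 0%        -> riser
* 0% <= decline < 10% -> nondipper
* 10% <= decline < 20% -> dipper
* decline >= 20%      -> extreme-dipper

The verbal definitions in common use overlap at exactly 10% and 20%;
the half-open intervals above resolve the boundary so that exactly one
label applies to any input (10% -> dipper, 20% -> extreme-dipper).
The diastolic decline is computed and reported but the label is always
the systolic one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientCoverageError

__all__ = [
    "BPSeries",
    "DippingResult",
    "day_night_means",
    "classify_dipping",
    "dipping_from_series",
    "daily_stats",
    "bp_histogram",
    "weekly_stats",
    "bmi",
    "calories_from_steps",
    "plot_bpv",
]

PATTERNS = ("riser", "nondipper", "dipper", "extreme-dipper")
_PATTERN_ALIASES = {"extreme": "extreme-dipper"}


class BPSeries:
    """Timestamped SBP/DBP readings (mmHg) with strictly increasing times."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = {"time", "sbp", "dbp"} - set(frame.columns)
        if missing:
            raise InputError(f"BP series missing columns: {sorted(missing)}")
        frame["time"] = pd.to_datetime(frame["time"])
        if len(frame) == 0:
            raise InputError("BP series is empty")
        if not frame["time"].is_monotonic_increasing or frame["time"].duplicated().any():
            raise InputError("timestamps must be strictly increasing")
        if not (frame["sbp"] > frame["dbp"]).all():
            raise InputError("every reading must satisfy SBP > DBP")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path) -> "BPSeries":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class DippingResult:
    day_mean_sbp: float
    night_mean_sbp: float
    day_mean_dbp: float
    night_mean_dbp: float
    decline_pct: float        # systolic, 100 * (day - night) / day
    dbp_decline_pct: float
    pattern: str


def _day_mask(times: pd.Series) -> np.ndarray:
    hours = pd.DatetimeIndex(times).hour
    return (hours >= 6) & (hours < 22)


def day_night_means(series: BPSeries):
    """Arithmetic SBP/DBP means over the daytime and nighttime windows."""
    day = _day_mask(series.frame["time"])
    if not day.any():
        raise InsufficientCoverageError("daytime")
    if day.all():
        raise InsufficientCoverageError("nighttime")
    f = series.frame
    day_means = (float(f.loc[day, "sbp"].mean()), float(f.loc[day, "dbp"].mean()))
    night_means = (float(f.loc[~day, "sbp"].mean()), float(f.loc[~day, "dbp"].mean()))
    return day_means, night_means


def classify_dipping(day_mean_sbp: float, night_mean_sbp: float,
                     day_mean_dbp: float = float("nan"),
                     night_mean_dbp: float = float("nan")) -> DippingResult:
    """Label the nocturnal SBP decline with exactly one dipping pattern."""
    if not day_mean_sbp > 0:
        raise InputError("day mean SBP must be positive")
    decline = 100.0 * (day_mean_sbp - night_mean_sbp) / day_mean_sbp
    if day_mean_dbp and day_mean_dbp > 0:
        dbp_decline = 100.0 * (day_mean_dbp - night_mean_dbp) / day_mean_dbp
    else:
        dbp_decline = float("nan")
    if decline < 0:
        pattern = "riser"
    elif decline < 10:
        pattern = "nondipper"
    elif decline < 20:
        pattern = "dipper"
    else:
        pattern = "extreme-dipper"
    return DippingResult(day_mean_sbp, night_mean_sbp, day_mean_dbp,
                         night_mean_dbp, decline, dbp_decline, pattern)


def dipping_from_series(series: BPSeries) -> DippingResult:
    (ds, dd), (ns, nd) = day_night_means(series)
    return classify_dipping(ds, ns, dd, nd)


def matches_pattern(result: DippingResult, requested: str) -> bool:
    return result.pattern == _PATTERN_ALIASES.get(requested, requested)


def daily_stats(series: BPSeries, date) -> dict:
    """Mean SBP, mean DBP, max SBP and min DBP for one calendar day."""
    date = pd.Timestamp(date).date()
    f = series.frame
    day = f[f["time"].dt.date == date]
    if len(day) == 0:
        raise InputError(f"no readings on {date}")
    return {
        "mean_sbp": float(day["sbp"].mean()),
        "mean_dbp": float(day["dbp"].mean()),
        "max_sbp": float(day["sbp"].max()),
        "min_dbp": float(day["dbp"].min()),
    }


def bp_histogram(series: BPSeries, bin_width: float, range_: tuple,
                 which: str = "sbp"):
    """Histogram with half-open, lower-edge-inclusive bins [lo, lo+w).

    Returns ``(edges, counts)``; counts sum to the number of readings
    falling inside ``range_`` (a value exactly at the upper limit is
    outside).
    """
    if bin_width <= 0:
        raise InputError("bin width must be positive")
    lo, hi = range_
    if not lo < hi:
        raise InputError("empty histogram range")
    values = series.frame[which].to_numpy(dtype=float)
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.floor((values - lo) / bin_width).astype(int)
    in_range = (values >= lo) & (values < hi)
    counts = np.bincount(idx[in_range], minlength=n_bins)[:n_bins]
    return edges, counts


def weekly_stats(series: BPSeries) -> pd.DataFrame:
    """Max SBP and min DBP per weekday, keyed Monday-first.

    Multiple occurrences of the same weekday in the series pool
    together; only weekdays present appear.
    """
    f = series.frame
    names = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday",
             "Saturday", "Sunday"]
    grouped = f.groupby(f["time"].dt.dayofweek).agg(
        max_sbp=("sbp", "max"), min_dbp=("dbp", "min"))
    grouped.index = [names[i] for i in grouped.index]
    order = [n for n in names if n in grouped.index]
    return grouped.loc[order]


def bmi(weight: float, height: float) -> float:
    """Body-mass index, kg/m^2."""
    if height <= 0:
        raise InputError("height must be positive")
    return weight / height ** 2


def calories_from_steps(steps: float, kcal_per_step: float = 0.04) -> float:
    """Walking energy expenditure from a step count (configurable factor)."""
    if steps < 0:
        raise InputError("step count must be nonnegative")
    return steps * kcal_per_step


def plot_bpv(series: BPSeries, out_line, out_hist, bin_width: float = 5.0) -> None:
    """Write the day-profile line graph and SBP histogram as image files."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f = series.frame
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(f["time"], f["sbp"], label="SBP", color="tab:red")
    ax.plot(f["time"], f["dbp"], label="DBP", color="tab:blue")
    ax.set_ylabel("mmHg")
    ax.legend(loc="upper right")
    fig.autofmt_xdate()
    fig.savefig(out_line, dpi=100, bbox_inches="tight")
    plt.close(fig)

    lo = float(np.floor(f["sbp"].min() / bin_width) * bin_width)
    hi = float(np.ceil(f["sbp"].max() / bin_width) * bin_width) + bin_width
    edges, counts = bp_histogram(series, bin_width, (lo, hi))
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(edges[:-1], counts, width=bin_width, align="edge", edgecolor="k")
    ax.set_xlabel("SBP [mmHg]")
    ax.set_ylabel("readings")
    fig.savefig(out_hist, dpi=100, bbox_inches="tight")
    plt.close(fig)
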