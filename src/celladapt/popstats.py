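"""Cohort-level fate statistics and growth-curve summaries.

Fate fractions are reported the way the live-cell experiments were: cells
are pooled into 3-4 groups of wells and the mean +/- sample SD across
groups is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tracekit import CellTrace, EventRecord, FateCall

__all__ = [
    "FateSummary",
    "GrowthCurve",
    "fate_fractions",
    "division_events_per_interval",
    "growth_curve",
    "doubling_time_from_counts",
]

_FATES = ("dead", "arrested", "adapted")


@dataclass
class FateSummary:
    group_fractions: pd.DataFrame  # one row per group, columns per fate
    mean: dict
    sd: dict
    group_sizes: list[int]

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


@dataclass
class GrowthCurve:
    times: np.ndarray
    counts: np.ndarray
    normalization: float  # initial-count basis

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def normalized(self) -> np.ndarray:
        return self.counts / self.normalization


def _round_robin_groups(n: int, n_groups: int) -> np.ndarray:
    return np.arange(n) % n_groups


def fate_fractions(
    calls: Sequence[FateCall],
    grouping: Optional[Sequence] = None,
    n_groups: int = 4,
) -> FateSummary:
    """Per-group fate fractions with across-group mean +/- sample SD.

    ``grouping`` supplies explicit group labels; otherwise cells are
    assigned round-robin to ``n_groups`` groups.
    """
    fates = [c.fate for c in calls]
    if grouping is None:
        grouping = _round_robin_groups(len(fates), n_groups)
    df = pd.DataFrame({"fate": fates, "group": list(grouping)})
    if df.empty:
        raise ValueError("no calls supplied")
    sizes = df.groupby("group").size()
    if (sizes < 1).any():
        raise ValueError("empty group")

    frac = (
        df.groupby("group")["fate"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(_FATES), fill_value=0.0)
    )
    frac["surviving"] = frac["arrested"] + frac["adapted"]
    mean = frac.mean().to_dict()
    sd = frac.std(ddof=1).fillna(0.0).to_dict() if len(frac) > 1 else {
        k: 0.0 for k in frac.columns
    }
    return FateSummary(
        group_fractions=frac.reset_index(),
        mean=mean,
        sd=sd,
        group_sizes=sizes.tolist(),
    )


def division_events_per_interval(
    events: Sequence[EventRecord],
    intervals: Sequence[tuple[float, float]],
    grouping: Optional[Sequence] = None,
    n_groups: int = 4,
) -> pd.DataFrame:
    """Percentage of cells with >= 1 division in each half-open interval.

    Returns one row per interval with grouped mean and sample SD of the
    percentage.
    """
    ordered = sorted(intervals)
    for (a0, b0), (a1, _) in zip(ordered, ordered[1:]):
        if a1 < b0:
            raise ValueError("overlapping intervals")
    if grouping is None:
        grouping = _round_robin_groups(len(events), n_groups)
    grouping = np.asarray(list(grouping))

    rows = []
    for (a, b) in intervals:
        hit = np.array(
            [any(a <= t < b for t in ev.divisions) for ev in events], dtype=float
        )
        per_group = [
            100.0 * hit[grouping == g].mean() for g in np.unique(grouping)
        ]
        rows.append(
            {
                "start_h": a,
                "end_h": b,
                "mean_pct": float(np.mean(per_group)),
                "sd_pct": float(np.std(per_group, ddof=1)) if len(per_group) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def growth_curve(
    source, interval_min: float = 45.0, normalize: bool = True
) -> GrowthCurve:
    """Live-cell counts over time, normalized to the t=0 count.

    ``source`` is either a sequence of :class:`CellTrace` (counts are sums
    of per-cell alive indicators, resampled at ``interval_min``) or a tidy
    counts DataFrame with ``time_h`` and ``count`` columns (averaged over
    replicates if a ``replicate`` column is present).
    """
    if isinstance(source, pd.DataFrame):
        df = source
        if "replicate" in df.columns:
            df = df.groupby("time_h", as_index=False)["count"].mean()
        df = df.sort_values("time_h")
        times = df["time_h"].to_numpy(float)
        counts = df["count"].to_numpy(float)
    else:
        traces: list[CellTrace] = list(source)
        if not traces:
            raise ValueError("empty panel")
        grid = traces[0].times
        alive = np.sum([t.alive for t in traces], axis=0).astype(float)
        step = max(int(round((interval_min / 60.0) / (traces[0].dt_h or 1.0))), 1)
        times = grid[::step]
        counts = alive[::step]
    norm = counts[0] if (normalize and counts[0] > 0) else 1.0
    return GrowthCurve(times=times, counts=counts, normalization=norm)


def doubling_time_from_counts(
    curve: GrowthCurve, fit_window: Optional[tuple[float, float]] = None
) -> tuple[float, dict]:
    """Doubling time from a log-linear least-squares fit of counts vs time.

    Returns ``(hours, diagnostics)``; a non-positive growth slope yields
    ``inf`` with ``diagnostics["non_growing"]`` set.
    """
    times, counts = curve.times, curve.counts
    if fit_window is not None:
        a, b = fit_window
        mask = (times >= a) & (times <= b)
        times, counts = times[mask], counts[mask]
    if len(times) < 3:
        raise ValueError("need at least 3 points in the fit window")
    if np.any(counts <= 0):
        raise ValueError("counts must be positive for a log-linear fit")
    slope, intercept = np.polyfit(times, np.log(counts), 1)
    diag = {"slope_per_h": float(slope), "log_intercept": float(intercept), "non_growing": False}
    if slope <= 0:
        diag["non_growing"] = True
        return float("inf"), diag
    return float(np.log(2.0) / slope), diag
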