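"""Per-cell geminin trace analysis.

Converts single-cell geminin reporter traces into cell-cycle phase
segmentations, division/death event records, phase lengths, minimum
doubling times, and a three-way fate call (dead / arrested / adapted).

The geminin reporter is absent in G0/G1, accumulates through S/G2/M and
is destroyed abruptly at division, so S/G2 onset is called by a smoothed
signal crossing a fixed threshold and division by a sharp drop from a
sustained high level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellTrace",
    "PhaseSegmentation",
    "EventRecord",
    "FateCall",
    "MinDoublingResult",
    "smooth_geminin",
    "call_phases",
    "detect_events",
    "phase_lengths",
    "min_doubling_time",
    "classify_fate",
    "analyze_trace",
    "analyze_panel",
    "read_trace_csv",
    "write_trace_csv",
]


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class CellTrace:
    """One cell's sampled geminin signal on a uniform time grid.

    ``annotated_events`` holds curated ``(time_h, kind)`` pairs with kind in
    ``{"division", "death"}``; when present they take precedence over
    automated event detection.
    """

    cell_id: str
    times: np.ndarray
    geminin: np.ndarray
    alive: np.ndarray
    annotated_events: Optional[list[tuple[float, str]]] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.geminin = np.asarray(self.geminin, dtype=float)
        self.alive = np.asarray(self.alive, dtype=bool)
        n = len(self.times)
        if n == 0:
            raise ValueError("empty trace")
        if len(self.geminin) != n or len(self.alive) != n:
            raise ValueError("times, geminin and alive must have equal length")
        if n > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must lie on a uniform grid")
        # no resurrection: alive is monotone non-increasing
        if np.any(np.diff(self.alive.astype(int)) > 0):
            raise ValueError("alive series must be monotone non-increasing")

    @property
    def dt_h(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class PhaseSegmentation:
    """Alternating G0/G1 and S/G2 intervals covering the observed lifetime."""

    intervals: list[tuple[float, float, str]]
    threshold_used: float
    window_frames: int
    censored_terminal: bool = True

    def __post_init__(self) -> None:
        for (a, b, phase) in self.intervals:
            if b <= a:
                raise ValueError(f"degenerate interval ({a}, {b})")
            if phase not in ("G0G1", "SG2"):
                raise ValueError(f"unknown phase {phase!r}")
        for (_, b0, p0), (a1, _, p1) in zip(self.intervals, self.intervals[1:]):
            if not np.isclose(b0, a1):
                raise ValueError("intervals must be contiguous")
            if p0 == p1:
                raise ValueError("phases must alternate")

    @property
    def sg2_onsets(self) -> list[float]:
        return [a for (a, _, p) in self.intervals if p == "SG2"]


@dataclass
class EventRecord:
    """Division times and (optional) death time for one cell."""

    divisions: list[float]
    death: Optional[float]
    censored_at: float

    def __post_init__(self) -> None:
        self.divisions = sorted(float(t) for t in self.divisions)
        for t in self.divisions:
            if t < 0 or t > self.censored_at:
                raise ValueError("division outside observed support")
            if self.death is not None and t >= self.death:
                raise ValueError("division recorded after death")
        if self.death is not None and self.death > self.censored_at:
            raise ValueError("death after censoring time")


@dataclass
class FateCall:
    fate: str  # dead | arrested | adapted
    support: Optional[float] = None  # death time or first re-entry time (h)


@dataclass
class MinDoublingResult:
    hours: float
    is_lower_bound: bool = False

    def __float__(self) -> float:
        return self.hours


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def smooth_geminin(trace, window_frames: int = 40) -> np.ndarray:
    """Centered moving average of the geminin signal.

    Accepts a :class:`CellTrace` or a raw 1-D array.  Even windows use the
    classical centered convention (half weight on the two end taps); the
    boundary is handled by half-sample symmetric reflection, which makes the
    smoothing operator doubly stochastic so the series mean is preserved
    exactly.
    """
    x = trace.geminin if isinstance(trace, CellTrace) else np.asarray(trace, float)
    n = len(x)
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if window_frames > n:
        raise ValueError(f"window ({window_frames}) longer than trace ({n})")
    if window_frames == 1:
        return x.astype(float).copy()
    w = window_frames
    if w % 2 == 1:
        kernel = np.full(w, 1.0 / w)
        half = w // 2
    else:
        kernel = np.full(w + 1, 1.0 / w)
        kernel[0] = kernel[-1] = 0.5 / w
        half = w // 2
    padded = np.pad(x, half, mode="symmetric")
    return np.convolve(padded, kernel, mode="valid")


def _true_runs(mask: np.ndarray, min_run: int = 1) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True, discarding runs < min_run."""
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        if stop - start >= min_run:
            runs.append((int(start), int(stop)))
    return runs


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------


def detect_events(
    trace: CellTrace,
    drop_fraction: float = 0.5,
    drop_frames: int = 2,
    high_level: float = 2.0,
    min_run: int = 5,
) -> EventRecord:
    """Detect division and death events.

    Division: the raw geminin signal, after at least ``min_run`` consecutive
    frames above ``high_level``, falls by at least ``drop_fraction`` of its
    last high value within ``drop_frames`` frames.  Death: first frame where
    the alive flag is False.  Annotated events on the trace override
    automated division calls.
    """
    if trace.n_frames == 0:
        raise ValueError("empty trace")
    times = trace.times
    dead_idx = np.flatnonzero(~trace.alive)
    death = float(times[dead_idx[0]]) if dead_idx.size else None
    censored_at = death if death is not None else float(times[-1])

    annotated = trace.annotated_events
    if annotated:
        divisions = sorted(t for (t, kind) in annotated if kind == "division")
        ann_deaths = [t for (t, kind) in annotated if kind == "death"]
        if ann_deaths:
            death = float(min(ann_deaths))
            censored_at = death
        return EventRecord(divisions=divisions, death=death, censored_at=censored_at)

    g = trace.geminin
    n = trace.n_frames
    last_obs = dead_idx[0] if dead_idx.size else n  # frames at/after death excluded
    divisions: list[float] = []
    above = (g > high_level) & (np.arange(n) < last_obs)
    for start, stop in _true_runs(above, min_run=min_run):
        end = stop - 1  # last frame above level
        lo = g[end + 1 : min(end + 1 + drop_frames, last_obs)]
        if lo.size == 0:
            continue  # run censored by movie end or death
        hit = np.flatnonzero(lo <= (1.0 - drop_fraction) * g[end])
        if hit.size:
            divisions.append(float(times[end + 1 + hit[0]]))
    return EventRecord(divisions=divisions, death=death, censored_at=censored_at)


# ---------------------------------------------------------------------------
# phase segmentation
# ---------------------------------------------------------------------------


def call_phases(
    trace: CellTrace,
    threshold: float,
    window_frames: int = 40,
    min_run: int = 5,
    events: Optional[EventRecord] = None,
) -> PhaseSegmentation:
    """Segment a trace into alternating G0/G1 and S/G2 intervals.

    S/G2 starts at the first sustained crossing of the smoothed geminin
    signal above ``threshold`` within each inter-division segment, and ends
    at the closing division (or at censoring).  A run that begins exactly at
    a division boundary is attributed to smoothing carry-over from the
    previous cycle and ignored.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if trace.n_frames == 0:
        raise ValueError("empty trace")
    if events is None:
        events = detect_events(trace, high_level=threshold, min_run=min_run)

    smoothed = smooth_geminin(trace, window_frames)
    times = trace.times
    dt = trace.dt_h or 1.0
    end_time = events.censored_at
    end_idx = int(round((end_time - times[0]) / dt))
    above = smoothed > threshold
    runs = _true_runs(above, min_run=min_run)

    div_idx = [int(round((t - times[0]) / dt)) for t in events.divisions]
    boundaries = [0] + div_idx + [end_idx]

    intervals: list[tuple[float, float, str]] = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if b <= a:
            continue
        onset = None
        for (rs, _) in runs:
            if rs >= b:
                break
            if rs < a or (rs == a and a > 0):
                continue  # carry-over from before this segment
            onset = rs
            break
        if onset is None or onset >= b:
            intervals.append((times[a], times[b] if b < len(times) else end_time, "G0G1"))
        else:
            t_b = times[b] if b < len(times) else end_time
            if onset > a:
                intervals.append((times[a], times[onset], "G0G1"))
            intervals.append((times[onset], t_b, "SG2"))

    if not intervals:  # degenerate single-frame observation
        intervals = [(times[0], max(end_time, times[0] + dt), "G0G1")]

    # a division whose S/G2 run went undetected leaves two adjacent G0/G1
    # intervals; merge same-phase neighbours so phases alternate
    merged: list[tuple[float, float, str]] = [intervals[0]]
    for (a, b, phase) in intervals[1:]:
        pa, pb, pphase = merged[-1]
        if phase == pphase:
            merged[-1] = (pa, b, phase)
        else:
            merged.append((a, b, phase))
    intervals = merged

    censored = events.death is None and (
        not events.divisions or events.divisions[-1] < end_time
    )
    return PhaseSegmentation(
        intervals=intervals,
        threshold_used=threshold,
        window_frames=window_frames,
        censored_terminal=censored,
    )


def phase_lengths(seg: PhaseSegmentation) -> pd.DataFrame:
    """Durations of each phase interval; terminal interval flagged if censored."""
    rows = []
    for i, (a, b, phase) in enumerate(seg.intervals):
        rows.append(
            {
                "start_h": a,
                "end_h": b,
                "phase": phase,
                "duration_h": b - a,
                "censored": seg.censored_terminal and i == len(seg.intervals) - 1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# doubling-time lower bound and fate call
# ---------------------------------------------------------------------------


def min_doubling_time(
    events: EventRecord, observation_window: tuple[float, float]
) -> MinDoublingResult:
    """Longest interval before, between, or after divisions in a window.

    With no division in the window the window length itself is returned and
    flagged as a lower bound on the cell's doubling time.
    """
    a, b = observation_window
    if b <= a:
        raise ValueError("empty observation window")
    divs = [t for t in events.divisions if a <= t <= b]
    if not divs:
        return MinDoublingResult(hours=b - a, is_lower_bound=True)
    pts = [a] + divs + [b]
    gaps = [q - p for p, q in zip(pts[:-1], pts[1:])]
    return MinDoublingResult(hours=max(gaps), is_lower_bound=False)


def classify_fate(
    events: EventRecord,
    seg: PhaseSegmentation,
    movie_length_h: float,
    arrest_min_h: float = 36.0,
) -> FateCall:
    """Three-way fate call: dead, arrested, or adapted.

    A surviving cell is adapted if it shows an S/G2 onset or a division
    after ``arrest_min_h`` (separating initial drug-induced arrest from
    adaptive cell-cycle re-entry); otherwise it is arrested.
    """
    if events.death is not None:
        return FateCall(fate="dead", support=events.death)
    late_onsets = [t for t in seg.sg2_onsets if t > arrest_min_h]
    late_divs = [t for t in events.divisions if t > arrest_min_h]
    candidates = late_onsets + late_divs
    if candidates:
        return FateCall(fate="adapted", support=min(candidates))
    return FateCall(fate="arrested", support=None)


# ---------------------------------------------------------------------------
# panel-level driver and I/O
# ---------------------------------------------------------------------------


def analyze_trace(
    trace: CellTrace,
    threshold: float = 2.0,
    window_frames: int = 40,
    arrest_min_h: float = 36.0,
    min_run: int = 5,
) -> dict:
    """Run the full per-cell pipeline; returns a flat record."""
    events = detect_events(trace, high_level=threshold, min_run=min_run)
    seg = call_phases(
        trace, threshold, window_frames=window_frames, min_run=min_run, events=events
    )
    fate = classify_fate(events, seg, trace.times[-1], arrest_min_h=arrest_min_h)
    mdt = min_doubling_time(events, (float(trace.times[0]), float(trace.times[-1])))
    onsets = seg.sg2_onsets
    return {
        "cell_id": trace.cell_id,
        "fate": fate.fate,
        "n_divisions": len(events.divisions),
        "death_h": events.death,
        "first_reentry_h": fate.support if fate.fate == "adapted" else None,
        "first_sg2_onset_h": onsets[0] if onsets else None,
        "min_doubling_h": mdt.hours,
        "min_doubling_lower_bound": mdt.is_lower_bound,
        "division_times": ";".join(f"{t:.3f}" for t in events.divisions),
        "censored_at_h": events.censored_at,
    }


def analyze_panel(traces: Sequence[CellTrace], **kwargs) -> pd.DataFrame:
    return pd.DataFrame([analyze_trace(t, **kwargs) for t in traces])


def write_trace_csv(traces: Sequence[CellTrace], path) -> None:
    """Long-format trace table: cell_id, frame, time_h, geminin, alive, event."""
    frames = []
    for tr in traces:
        event = np.array(["none"] * tr.n_frames, dtype=object)
        if tr.annotated_events:
            dt = tr.dt_h or 1.0
            for (t, kind) in tr.annotated_events:
                idx = int(round((t - tr.times[0]) / dt))
                if 0 <= idx < tr.n_frames:
                    event[idx] = kind
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "frame": np.arange(tr.n_frames),
                    "time_h": tr.times,
                    "geminin": tr.geminin,
                    "alive": tr.alive.astype(int),
                    "event": event,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_csv(path) -> list[CellTrace]:
    df = pd.read_csv(path)
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("frame")
        events = [
            (float(r.time_h), str(r.event))
            for r in sub.itertuples()
            if r.event in ("division", "death")
        ]
        traces.append(
            CellTrace(
                cell_id=str(cell_id),
                times=sub["time_h"].to_numpy(),
                geminin=sub["geminin"].to_numpy(),
                alive=sub["alive"].to_numpy().astype(bool),
                annotated_events=events or None,
            )
        )
    return traces
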