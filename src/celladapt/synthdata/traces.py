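"""Trace-cohort generators.

Cells draw a fate (death / arrest / adaptation) and a per-cell event
schedule; the geminin waveform is reconstructed deterministically from the
schedule (zero in G0/G1, linear rise over the S/G2 duration to amplitude
10, instantaneous drop at division) and pointwise Gaussian noise is added.
Event times are snapped to the sampling grid so that noiseless traces are
exactly reconstructible from their schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ..tracekit import CellTrace
from .params import FateModelParams

GEMININ_AMPLITUDE = 10.0

FATE_DEAD = "dead"
FATE_ARRESTED = "arrested"
FATE_ADAPTED = "adapted"


@dataclass
class CellSchedule:
    """Ground-truth event schedule for one simulated cell (grid-snapped)."""

    cell_id: str
    fate: str
    death_h: Optional[float] = None
    reentry_h: Optional[float] = None
    division_times_h: list[float] = field(default_factory=list)


@dataclass
class TraceCohort:
    """A panel of simulated traces plus ground truth and provenance."""

    traces: list[CellTrace]
    schedules: list[CellSchedule]
    params: FateModelParams
    seed: int
    kind: str  # "treated" or "untreated"

    @property
    def labels(self) -> list[str]:
        return [s.fate for s in self.schedules]

    def label_counts(self) -> dict:
        out = {FATE_DEAD: 0, FATE_ARRESTED: 0, FATE_ADAPTED: 0}
        for s in self.schedules:
            out[s.fate] += 1
        return out

    def schedule_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [s.cell_id for s in self.schedules],
                "fate": [s.fate for s in self.schedules],
                "death_h": [s.death_h for s in self.schedules],
                "reentry_h": [s.reentry_h for s in self.schedules],
                "division_times_h": [
                    ";".join(f"{t:.3f}" for t in s.division_times_h)
                    for s in self.schedules
                ],
            }
        )

    def metadata(self) -> dict:
        return {"seed": self.seed, "kind": self.kind, "params": self.params.to_dict()}


def _grid(params: FateModelParams) -> np.ndarray:
    dt = params.sampling_interval_min / 60.0
    n = int(round(params.movie_length_h / dt)) + 1
    return np.arange(n) * dt


def _snap(t: float, dt: float) -> float:
    return round(t / dt) * dt


def _waveform(times: np.ndarray, divisions: list[float], s_g2: float) -> np.ndarray:
    """Noiseless geminin signal implied by a division schedule."""
    g = np.zeros_like(times)
    prev = -np.inf
    for d in divisions:
        start = max(d - s_g2, prev, 0.0)
        in_rise = (times >= start) & (times < d)
        g[in_rise] = GEMININ_AMPLITUDE * (times[in_rise] - (d - s_g2)) / s_g2
        prev = d
    np.clip(g, 0.0, GEMININ_AMPLITUDE, out=g)
    return g


def _partial_rise(
    times: np.ndarray, g: np.ndarray, next_division: float, s_g2: float, last_full: float
) -> None:
    """Add the censored rise toward a division beyond the movie end."""
    start = max(next_division - s_g2, last_full, 0.0)
    in_rise = (times >= start) & (times < next_division)
    g[in_rise] = np.clip(
        GEMININ_AMPLITUDE * (times[in_rise] - (next_division - s_g2)) / s_g2,
        0.0,
        GEMININ_AMPLITUDE,
    )


def _draw_death_time(params: FateModelParams, rng: np.random.Generator) -> float:
    lo, hi = params.death_window_h
    if params.death_time_dist == "uniform":
        return float(rng.uniform(lo, hi))
    # truncated lognormal with mode near the window midpoint
    mode = 0.5 * (lo + hi)
    sigma = 0.25
    mu = np.log(mode) + sigma**2
    for _ in range(1000):
        t = float(rng.lognormal(mu, sigma))
        if lo < t < hi:
            return t
    return float(rng.uniform(lo, hi))  # pragma: no cover - fallback


def _lognormal_interval(mean: float, cv: float, rng: np.random.Generator) -> float:
    if cv <= 0:
        return mean
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def simulate_fate_cohort(
    params: FateModelParams, n_cells: int, seed: int, annotate: bool = False
) -> TraceCohort:
    """Simulate a drug-treated cohort with a three-way fate mixture.

    Dying cells remain in G0/G1 until a death time drawn inside the death
    window; arrested cells emit near-zero geminin throughout; adapted cells
    stay arrested until an S-phase re-entry time drawn uniformly in the
    re-entry window, divide one S/G2 duration later, and then cycle with
    lognormal intermitotic times whose extra length (relative to S/G2) is
    spent in G0/G1.

    With ``annotate=True`` traces carry their true division/death events as
    annotations (curated-track emulation); by default they do not, so the
    event detector is actually exercised.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if params.movie_length_h < params.death_window_h[0]:
        raise ValueError("movie shorter than the death window start")
    rng = np.random.default_rng(seed)
    times = _grid(params)
    dt = times[1] - times[0]
    fates = rng.choice(
        [FATE_DEAD, FATE_ARRESTED, FATE_ADAPTED],
        size=n_cells,
        p=[params.p_death, params.p_arrest, params.p_adapt],
    )

    traces: list[CellTrace] = []
    schedules: list[CellSchedule] = []
    for i, fate in enumerate(fates):
        cell_id = f"c{i:04d}"
        sched = CellSchedule(cell_id=cell_id, fate=str(fate))
        g = np.zeros_like(times)
        alive = np.ones_like(times, dtype=bool)

        if fate == FATE_DEAD:
            t_death = _snap(_draw_death_time(params, rng), dt)
            sched.death_h = t_death
            alive[times >= t_death - dt / 2] = False
        elif fate == FATE_ADAPTED:
            t_r = float(rng.uniform(*params.reentry_window_h))
            sched.reentry_h = t_r
            divisions = []
            d = t_r + params.s_g2_duration_h
            while d <= params.movie_length_h:
                divisions.append(_snap(d, dt))
                d += _lognormal_interval(
                    params.intermitotic_mean_h, params.intermitotic_cv, rng
                )
            sched.division_times_h = divisions
            g = _waveform(times, divisions, params.s_g2_duration_h)
            last_full = divisions[-1] if divisions else 0.0
            _partial_rise(times, g, d, params.s_g2_duration_h, last_full)
            if not divisions:
                # re-entry rise censored by the movie end
                start = max(t_r, 0.0)
                in_rise = times >= start
                g[in_rise] = np.clip(
                    GEMININ_AMPLITUDE
                    * (times[in_rise] - t_r)
                    / params.s_g2_duration_h,
                    0.0,
                    GEMININ_AMPLITUDE,
                )

        if params.noise_sd > 0:
            noise = rng.normal(0.0, params.noise_sd, size=len(times))
            g = np.where(alive, g + noise, 0.0)
        else:
            g = np.where(alive, g, 0.0)

        annotated = None
        if annotate:
            annotated = [(t, "division") for t in sched.division_times_h]
            if sched.death_h is not None:
                annotated.append((sched.death_h, "death"))
        traces.append(
            CellTrace(
                cell_id=cell_id,
                times=times.copy(),
                geminin=g,
                alive=alive,
                annotated_events=annotated,
            )
        )
        schedules.append(sched)
    return TraceCohort(traces=traces, schedules=schedules, params=params, seed=seed, kind="treated")


def simulate_untreated_cohort(
    params: FateModelParams, n_cells: int, seed: int, annotate: bool = False
) -> TraceCohort:
    """Simulate a freely cycling (DMSO) cohort; no deaths.

    Every cell cycles with mean intermitotic time ``untreated_doubling_h``;
    the first division falls at a uniform phase offset within the first
    drawn cycle, so the population is asynchronous.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    times = _grid(params)
    dt = times[1] - times[0]

    traces: list[CellTrace] = []
    schedules: list[CellSchedule] = []
    for i in range(n_cells):
        cell_id = f"u{i:04d}"
        tau0 = _lognormal_interval(
            params.untreated_doubling_h, params.intermitotic_cv, rng
        )
        d = float(rng.uniform(0.0, tau0))
        divisions = []
        while d <= params.movie_length_h:
            divisions.append(_snap(d, dt))
            d += _lognormal_interval(
                params.untreated_doubling_h, params.intermitotic_cv, rng
            )
        g = _waveform(times, divisions, params.s_g2_duration_h)
        last_full = divisions[-1] if divisions else 0.0
        _partial_rise(times, g, d, params.s_g2_duration_h, last_full)
        alive = np.ones_like(times, dtype=bool)
        if params.noise_sd > 0:
            g = g + rng.normal(0.0, params.noise_sd, size=len(times))
        annotated = [(t, "division") for t in divisions] if annotate else None
        traces.append(
            CellTrace(
                cell_id=cell_id,
                times=times.copy(),
                geminin=g,
                alive=alive,
                annotated_events=annotated,
            )
        )
        schedules.append(
            CellSchedule(cell_id=cell_id, fate=FATE_ADAPTED, division_times_h=divisions)
        )
    return TraceCohort(
        traces=traces, schedules=schedules, params=params, seed=seed, kind="untreated"
    )
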