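"""Preset parameter types for the synthetic generators.

Each dataclass validates its own invariants on construction; generators
accept either an instance or a plain mapping (converted via ``from_dict``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Optional


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be a probability, got {p}")


@dataclass
class FateModelParams:
    """Generative fate-mixture and timing parameters for a trace cohort."""

    p_death: float
    p_arrest: float
    p_adapt: float
    death_window_h: tuple[float, float]
    reentry_window_h: tuple[float, float]
    intermitotic_mean_h: float
    intermitotic_cv: float
    s_g2_duration_h: float
    untreated_doubling_h: float
    noise_sd: float
    sampling_interval_min: float = 6.0
    movie_length_h: float = 84.0
    death_time_dist: str = "lognormal"  # or "uniform"

    def __post_init__(self) -> None:
        for name in ("p_death", "p_arrest", "p_adapt"):
            _check_prob(name, getattr(self, name))
        if abs(self.p_death + self.p_arrest + self.p_adapt - 1.0) > 1e-9:
            raise ValueError("fate probabilities must sum to 1")
        for name in (
            "intermitotic_mean_h",
            "s_g2_duration_h",
            "untreated_doubling_h",
            "sampling_interval_min",
            "movie_length_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.intermitotic_cv < 0:
            raise ValueError("noise_sd and intermitotic_cv must be non-negative")
        self.death_window_h = tuple(self.death_window_h)  # type: ignore[assignment]
        self.reentry_window_h = tuple(self.reentry_window_h)  # type: ignore[assignment]
        for name in ("death_window_h", "reentry_window_h"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= self.movie_length_h):
                raise ValueError(
                    f"{name} must satisfy 0 <= lo < hi <= movie_length_h, got {(lo, hi)}"
                )
        if self.death_time_dist not in ("lognormal", "uniform"):
            raise ValueError("death_time_dist must be 'lognormal' or 'uniform'")

    @classmethod
    def from_dict(cls, d: dict) -> "FateModelParams":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "FateModelParams":
        d = self.to_dict()
        d.update(kwargs)
        return FateModelParams(**d)


@dataclass
class PlatePreset:
    """Dose–response plate generator parameters."""

    doses: list[float]
    true_ec50: float
    true_hill: float
    true_emax: float
    initial_count: int
    control_doublings: float
    apoptosis_background: float
    replicate_cv: float
    n_replicates: int = 4
    # bell-shaped protection from sub-IC50 pre-treatment (fold of 1 = none)
    protection_fold: float = 1.0
    protection_peak_um: float = 0.1
    protection_width_log10: float = 0.5

    def __post_init__(self) -> None:
        self.doses = sorted(float(d) for d in self.doses)
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if not (0.0 <= self.true_emax <= 1.0):
            raise ValueError("true_emax must be in [0, 1]")
        if self.initial_count <= 0:
            raise ValueError("initial_count must be positive")
        if self.true_ec50 <= 0 or self.true_hill <= 0:
            raise ValueError("true_ec50 and true_hill must be positive")
        if self.protection_fold < 1.0:
            raise ValueError("protection_fold must be >= 1")
        _check_prob("apoptosis_background", self.apoptosis_background)

    @classmethod
    def from_dict(cls, d: dict) -> "PlatePreset":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExpressionPreset:
    """Two-line expression-table generator parameters."""

    n_genes: int
    n_planted_up: int
    n_planted_down: int
    planted_log2ratio: float
    fpkm_floor: float
    q_signal: float
    q_null: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.n_planted_up + self.n_planted_down > self.n_genes:
            raise ValueError("planted counts exceed n_genes")
        if not (self.q_signal < 0.01 <= self.q_null):
            raise ValueError("require q_signal < 0.01 <= q_null")
        if self.dispersion < 0 or self.fpkm_floor < 0:
            raise ValueError("dispersion and fpkm_floor must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "ExpressionPreset":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScreenPreset:
    """Compound-screen plate generator parameters."""

    n_compounds: int = 41
    n_doses: int = 3
    n_lines: int = 3
    suppressor_ids: list[int] = field(default_factory=list)
    suppression_log2: float = 1.5
    noise_sd: float = 0.15
    n_replicates: int = 2
    doses_um: list[float] = field(default_factory=lambda: [0.11, 0.53, 2.67])

    def __post_init__(self) -> None:
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if any(not (0 <= i < self.n_compounds) for i in self.suppressor_ids):
            raise ValueError("suppressor_ids must index valid compounds")
        if len(self.doses_um) != self.n_doses:
            self.doses_um = list(self.doses_um)[: self.n_doses] or [1.0] * self.n_doses

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenPreset":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BiopsyPreset:
    """Per-cell two-marker biopsy table generator parameters."""

    n_cells: int
    frac_marker_high: dict  # e.g. {"ngfr": 0.30, "ki67": 0.40}
    high_low_separation: float
    background_frac: float
    background_boost: float
    low_mean_log: float = 2.0
    component_sd_log: float = 0.35

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for marker, frac in self.frac_marker_high.items():
            _check_prob(f"frac_marker_high[{marker}]", frac)
        _check_prob("background_frac", self.background_frac)

    @property
    def background_threshold(self) -> float:
        """Prestain cutoff separating boosted regions from clean tissue."""
        return 1.0 + self.background_boost / 2.0

    @classmethod
    def from_dict(cls, d: dict) -> "BiopsyPreset":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GrowthPreset:
    """Exponential outgrowth trajectory parameters (sorted-pool assays)."""

    doubling_h: float
    initial_count: int = 1000
    n_replicates: int = 4
    replicate_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.doubling_h <= 0:
            raise ValueError("doubling_h must be positive")
        if self.initial_count <= 0:
            raise ValueError("initial_count must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthPreset":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)
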