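"""Screen hit selection and per-cell tissue gating.

Hit selection averages compound readouts across doses and replicates per
line, z-scores across compounds within each line, and keeps compounds in
the k lowest ranks in every line.  Tissue gating excludes high-background
cells via a prestain channel and thresholds marker intensities (fixed,
reference-quantile or Otsu).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = ["HitList", "GateResult", "screen_hits", "exclude_background", "gate_high"]


@dataclass
class HitList:
    hits: list[str]
    zscores: pd.DataFrame  # compound x line
    ranks: pd.DataFrame
    k_lowest: int
    tie_flag: bool = False


@dataclass
class GateResult:
    thresholds: dict  # marker -> threshold
    fractions_high: dict  # marker -> fraction strictly above threshold
    quadrant_counts: Optional[dict]  # joint 2x2 counts for two markers
    n_used: int
    n_excluded: int
    degenerate: dict = field(default_factory=dict)


def screen_hits(
    plate: pd.DataFrame,
    k_lowest: int = 5,
    value_col: str = "ngfr_log2",
) -> HitList:
    """Compounds within the k lowest z-scores in every line.

    ``plate`` is tidy with ``compound``, ``line``, ``dose_um``,
    ``replicate`` and a readout column.  Ties at the k-th value are
    included and flagged.
    """
    required = {"compound", "line", value_col}
    if not required <= set(plate.columns):
        raise ValueError(f"plate must have columns {sorted(required)}")
    means = (
        plate.groupby(["line", "compound"])[value_col].mean().unstack("line")
    )
    if means.isna().any().any():
        raise ValueError("missing compound x line cells in the screen design")
    if len(means) < k_lowest:
        raise ValueError("fewer compounds than k_lowest")
    z = (means - means.mean()) / means.std(ddof=1)
    ranks = z.rank(method="min", ascending=True)

    tie_flag = False
    per_line_hits = []
    for line in z.columns:
        vals = z[line]
        kth = np.sort(vals.to_numpy())[k_lowest - 1]
        strict = set(vals.index[vals < kth])
        tied = set(vals.index[vals == kth])
        selected = strict | tied
        if len(selected) > k_lowest:
            tie_flag = True
            # a tie group straddling rank k is included (borderline hits are
            # not silently dropped) unless it is degenerately large, e.g. a
            # noiseless null plate where most compounds share one value
            if len(selected) > 2 * k_lowest:
                selected = strict
        per_line_hits.append(selected)
    hits = sorted(set.intersection(*per_line_hits))
    return HitList(hits=hits, zscores=z, ranks=ranks, k_lowest=k_lowest, tie_flag=tie_flag)


def exclude_background(
    cells: pd.DataFrame,
    bg_threshold: float,
    prestain_col: str = "prestain",
) -> tuple[pd.DataFrame, int]:
    """Drop cells whose prestain intensity exceeds the background threshold."""
    if prestain_col not in cells.columns:
        raise ValueError(f"missing {prestain_col} column")
    keep = cells[cells[prestain_col] <= bg_threshold].copy()
    return keep, int(len(cells) - len(keep))


def _threshold(
    values: np.ndarray,
    method: str,
    fixed: Optional[float],
    reference: Optional[np.ndarray],
    quantile: float,
) -> tuple[float, bool]:
    if method == "fixed":
        if fixed is None:
            raise ValueError("fixed method requires a threshold value")
        return float(fixed), False
    if method == "quantile-of-reference":
        ref = values if reference is None else np.asarray(reference, float)
        return float(np.quantile(ref, quantile)), False
    if method == "otsu":
        if np.ptp(values) < 1e-12:
            return float(values[0]), True
        return float(threshold_otsu(values)), False
    raise ValueError(f"unknown gating method {method!r}")


def gate_high(
    cells: pd.DataFrame,
    markers: Sequence[str] = ("ngfr_log",),
    method: str = "otsu",
    fixed_thresholds: Optional[dict] = None,
    reference: Optional[pd.DataFrame] = None,
    quantile: float = 0.95,
    n_excluded: int = 0,
) -> GateResult:
    """Fraction of marker-high cells per marker (and jointly for two markers).

    The threshold per marker comes from the chosen method; cells strictly
    above it are high.  With two markers, 2x2 quadrant counts mirror the
    covariate scatter analyses.
    """
    if len(cells) < 10:
        raise ValueError("need >= 10 cells to gate")
    thresholds: dict = {}
    fractions: dict = {}
    degenerate: dict = {}
    highs: dict = {}
    for m in markers:
        vals = cells[m].to_numpy(float)
        fixed = (fixed_thresholds or {}).get(m)
        ref = reference[m].to_numpy(float) if reference is not None else None
        thr, degen = _threshold(vals, method, fixed, ref, quantile)
        high = vals > thr
        if degen:
            high = np.zeros(len(vals), dtype=bool)
        thresholds[m] = thr
        fractions[m] = float(high.mean())
        degenerate[m] = degen
        highs[m] = high

    quadrants = None
    if len(markers) == 2:
        m1, m2 = markers
        quadrants = {
            "high_high": int((highs[m1] & highs[m2]).sum()),
            "high_low": int((highs[m1] & ~highs[m2]).sum()),
            "low_high": int((~highs[m1] & highs[m2]).sum()),
            "low_low": int((~highs[m1] & ~highs[m2]).sum()),
        }
    return GateResult(
        thresholds=thresholds,
        fractions_high=fractions,
        quadrant_counts=quadrants,
        n_used=len(cells),
        n_excluded=n_excluded,
        degenerate=degenerate,
    )
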