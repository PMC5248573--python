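"""Endpoint plate pharmacology.

Apoptosis spot scoring, relative viability, the growth-rate-inhibition
(GR) metric, four-parameter-free Hill dose-response fitting (residual
floor E_max, Hill slope, EC50, log-dose AUC) and sequential-dosing
protection summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

__all__ = [
    "GRResult",
    "DoseResponseFit",
    "score_apoptosis",
    "relative_viability",
    "gr_value",
    "auc_log_dose",
    "fit_dose_response",
    "sequential_dosing_summary",
]


@dataclass
class GRResult:
    x_c: float
    x_0: float
    x_ctrl: float
    gr: float


@dataclass
class DoseResponseFit:
    e_max: float
    hill: float
    ec50: float
    auc: float
    residuals: np.ndarray
    converged: bool = True
    degenerate: bool = False
    at_bounds: bool = False
    message: str = ""


def score_apoptosis(
    cells: pd.DataFrame, spot_threshold: Optional[float] = None
) -> tuple[np.ndarray, float]:
    """Flag apoptotic cells by caspase spot brightness per unit nucleus area.

    ``cells`` needs ``spot_intensity`` and ``nucleus_area`` columns.  A cell
    is apoptotic iff intensity/area exceeds ``spot_threshold``; when the
    threshold is omitted, an Otsu split of the pooled intensity/area
    distribution is used.
    """
    areas = cells["nucleus_area"].to_numpy(float)
    if np.any(areas <= 0):
        raise ValueError("zero or negative nucleus area")
    ratio = cells["spot_intensity"].to_numpy(float) / areas
    if spot_threshold is None:
        spot_threshold = float(threshold_otsu(ratio))
    elif spot_threshold <= 0:
        raise ValueError("spot_threshold must be positive")
    flags = ratio > spot_threshold
    return flags, float(flags.mean())


def relative_viability(
    treated: pd.DataFrame, control: pd.DataFrame
) -> pd.DataFrame:
    """(total - apoptotic) per treated well, normalized to mean control viable.

    Both tables need ``total_cells`` and ``apoptotic_count`` columns.
    """
    ctrl_viable = (control["total_cells"] - control["apoptotic_count"]).mean()
    if ctrl_viable <= 0:
        raise ValueError("control viable count must be positive")
    out = treated.copy()
    out["viable"] = out["total_cells"] - out["apoptotic_count"]
    out["relative_viability"] = out["viable"] / ctrl_viable
    return out


def gr_value(x_c: float, x_0: float, x_ctrl: float) -> GRResult:
    """Growth-rate-inhibition value: 1 = no effect, 0 = stasis, <0 = killing."""
    if x_0 <= 0 or x_c <= 0:
        raise ValueError("cell counts must be positive")
    if x_ctrl <= x_0:
        raise ValueError("control must grow (x_ctrl > x_0) for GR normalization")
    gr = 2.0 ** (np.log2(x_c / x_0) / np.log2(x_ctrl / x_0)) - 1.0
    return GRResult(x_c=x_c, x_0=x_0, x_ctrl=x_ctrl, gr=float(gr))


def _hill(d: np.ndarray, e_max: float, log10_ec50: float, hill: float) -> np.ndarray:
    ec50 = 10.0**log10_ec50
    with np.errstate(divide="ignore"):
        term = np.where(d > 0, (d / ec50) ** hill, 0.0)
    return e_max + (1.0 - e_max) / (1.0 + term)


def auc_log_dose(doses: Sequence[float], responses: Sequence[float]) -> float:
    """Trapezoid AUC of the response over log10 dose.

    Dose 0 is mapped one decade below the lowest nonzero dose so the
    control anchors the left edge of the integration range.
    """
    d = np.asarray(doses, float)
    r = np.asarray(responses, float)
    order = np.argsort(d)
    d, r = d[order], r[order]
    pos = d[d > 0]
    if pos.size == 0:
        raise ValueError("need at least one positive dose")
    d = np.where(d > 0, d, pos.min() / 10.0)
    return float(np.trapezoid(r, np.log10(d)))


def fit_dose_response(
    doses: Sequence[float], responses: Sequence[float]
) -> DoseResponseFit:
    """Least-squares descending-Hill fit of a viability-fraction curve.

    Model: r(d) = e_max + (1 - e_max) / (1 + (d / ec50)^hill), with
    0 <= e_max <= 1 and positive slope.  Degenerate flat inputs are flagged
    rather than fit.
    """
    d = np.asarray(doses, float)
    r = np.asarray(responses, float)
    if len(np.unique(d)) < 4 or 0.0 not in d:
        raise ValueError("need >= 4 distinct doses including 0")
    if d.min() < 0:
        raise ValueError("negative dose")
    pos = d[d > 0]
    auc = auc_log_dose(d, r)

    if np.ptp(r) < 1e-9:
        return DoseResponseFit(
            e_max=float(np.clip(r.mean(), 0.0, 1.0)),
            hill=0.0,
            ec50=float(np.exp(np.mean(np.log(pos)))),
            auc=auc,
            residuals=np.zeros_like(r),
            converged=False,
            degenerate=True,
            message="flat response; no dose dependence",
        )

    e0 = float(np.clip(r.min(), 0.0, 1.0))
    mid = (1.0 + e0) / 2.0
    ec50_guess = float(pos[np.argmin(np.abs(r[d > 0] - mid))])
    lo = [0.0, np.log10(pos.min()) - 2.0, 0.05]
    hi = [1.0, np.log10(pos.max()) + 2.0, 10.0]
    p0 = [e0, np.clip(np.log10(ec50_guess), lo[1], hi[1]), 1.5]
    try:
        popt, _ = curve_fit(
            _hill, d, r, p0=p0, bounds=(lo, hi), maxfev=20000, xtol=1e-14, ftol=1e-14
        )
        converged, message = True, ""
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        popt, converged, message = p0, False, str(exc)
    e_max, log_ec50, hill = popt
    at_bounds = bool(
        np.any(np.isclose(popt, lo, atol=1e-9)) or np.any(np.isclose(popt, hi, atol=1e-9))
    )
    residuals = r - _hill(d, *popt)
    return DoseResponseFit(
        e_max=float(e_max),
        hill=float(hill),
        ec50=float(10.0**log_ec50),
        auc=auc,
        residuals=residuals,
        converged=converged,
        at_bounds=at_bounds,
        message=message,
    )


def sequential_dosing_summary(plate: pd.DataFrame) -> pd.DataFrame:
    """Fold-change in surviving cells vs the DMSO-pretreat arm.

    ``plate`` needs ``pretreat_dose_um``, ``replicate`` and ``viable_count``
    columns; the arm with pretreat dose 0 is the DMSO reference.  Returns
    one row per pretreat dose with the ratio mean +/- SD over replicates.
    """
    if "pretreat_dose_um" not in plate.columns:
        raise ValueError("missing pretreat_dose_um column")
    dmso = plate.loc[plate["pretreat_dose_um"] == 0, "viable_count"]
    if dmso.empty:
        raise ValueError("missing DMSO-pretreat arm")
    ref = dmso.mean()
    rows = []
    for pre, sub in plate.groupby("pretreat_dose_um"):
        ratios = sub["viable_count"] / ref
        rows.append(
            {
                "pretreat_dose_um": pre,
                "fold_change_mean": float(ratios.mean()),
                "fold_change_sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
                "n_replicates": len(ratios),
            }
        )
    return pd.DataFrame(rows).sort_values("pretreat_dose_um", ignore_index=True)
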