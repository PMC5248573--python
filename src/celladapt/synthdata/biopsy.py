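"""Biopsy-like per-cell marker table generator (two-component mixtures)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import BiopsyPreset


def simulate_biopsy_table(preset: BiopsyPreset, seed: int = 0) -> pd.DataFrame:
    """Per-cell table with log NGFR / Ki-67 intensities and a prestain channel.

    Each marker follows a two-component normal mixture in log space with
    component separation ``high_low_separation``; a ``background_frac``
    subset of cells sits in high-background regions where the prestain and
    both marker channels are inflated by ``background_boost``.
    """
    rng = np.random.default_rng(seed)
    n = preset.n_cells
    is_bg = rng.random(n) < preset.background_frac

    cols = {"cell_id": [f"b{i:05d}" for i in range(n)]}
    truth = {}
    for marker in ("ngfr", "ki67"):
        frac_high = preset.frac_marker_high.get(marker, 0.0)
        high = rng.random(n) < frac_high
        mean = np.where(
            high, preset.low_mean_log + preset.high_low_separation, preset.low_mean_log
        )
        vals = rng.normal(mean, preset.component_sd_log)
        vals = np.where(is_bg, vals + preset.background_boost, vals)
        cols[f"{marker}_log"] = vals
        truth[marker] = high
    cols["prestain"] = np.where(
        is_bg,
        rng.normal(1.0 + preset.background_boost, 0.3, size=n),
        rng.normal(1.0, 0.3, size=n),
    )
    cols["is_background_region"] = is_bg

    df = pd.DataFrame(cols)
    df.attrs["preset"] = preset.to_dict()
    df.attrs["seed"] = seed
    df.attrs["background_threshold"] = preset.background_threshold
    for marker, high in truth.items():
        df.attrs[f"true_high_{marker}"] = high
    return df
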