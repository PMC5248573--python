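"""Two-cell-line expression table generator with planted differential genes."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import ExpressionPreset

LINES = ("A", "B")
CONDITIONS = ("DMSO", "drug24h", "drug48h")
_PLANTED_BASE_MIN = 10.0  # keep planted genes safely above the FPKM filter


def simulate_expression_table(preset: ExpressionPreset, seed: int = 0) -> pd.DataFrame:
    """Long gene table: (gene, line, condition, fpkm, q).

    Planted up/down genes change in line A relative to line B by
    ``planted_log2ratio`` (in log2 of the cross-line fold-change ratio) with
    significant q in line A; null genes fluctuate with the preset dispersion
    and carry non-significant q everywhere.
    """
    rng = np.random.default_rng(seed)
    n = preset.n_genes
    genes = np.array([f"g{i:05d}" for i in range(n)])
    up = set(range(preset.n_planted_up))
    down = set(range(preset.n_planted_up, preset.n_planted_up + preset.n_planted_down))

    base = np.exp(rng.normal(np.log(20.0), 1.0, size=n))
    base = np.maximum(base, preset.fpkm_floor)
    planted = np.array([i in up or i in down for i in range(n)])
    base[planted] = np.maximum(base[planted], _PLANTED_BASE_MIN)

    rows = []
    for i in range(n):
        sign = 1.0 if i in up else (-1.0 if i in down else 0.0)
        for line in LINES:
            dmso = base[i] * np.exp(rng.normal(0.0, preset.dispersion))
            rows.append((genes[i], line, "DMSO", dmso, 1.0))
            for cond in CONDITIONS[1:]:
                if sign != 0.0 and line == "A":
                    fc = 2.0 ** (sign * preset.planted_log2ratio)
                    q = preset.q_signal
                elif sign != 0.0:
                    fc = 1.0
                    q = preset.q_null
                else:
                    fc = 2.0 ** rng.normal(0.0, preset.dispersion)
                    q = preset.q_null
                rows.append((genes[i], line, cond, dmso * fc, q))
    df = pd.DataFrame(rows, columns=["gene", "line", "condition", "fpkm", "q"])
    df.attrs["preset"] = preset.to_dict()
    df.attrs["seed"] = seed
    df.attrs["planted_up"] = [genes[i] for i in sorted(up)]
    df.attrs["planted_down"] = [genes[i] for i in sorted(down)]
    return df
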