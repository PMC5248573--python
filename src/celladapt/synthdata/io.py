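"""Disk output helpers: CSV tables plus JSON sidecars with preset + seed."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ..tracekit import write_trace_csv
from .traces import TraceCohort


def _write_sidecar(path: Path, meta: dict) -> None:
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def write_cohort(cohort: TraceCohort, path, with_truth: bool = False) -> None:
    """Write the long-format trace CSV (+ sidecar; optional ground-truth CSV)."""
    path = Path(path)
    write_trace_csv(cohort.traces, path)
    _write_sidecar(path, cohort.metadata())
    if with_truth:
        cohort.schedule_frame().to_csv(
            path.with_name(path.stem + "_truth.csv"), index=False
        )


def write_table(df: pd.DataFrame, path) -> None:
    """Write any generated table with its preset/seed sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta = {k: v for k, v in df.attrs.items() if not isinstance(v, pd.DataFrame)}
    meta = {
        k: (list(v) if hasattr(v, "tolist") else v) for k, v in meta.items()
    }
    _write_sidecar(path, meta)
    cells = df.attrs.get("cells")
    if isinstance(cells, pd.DataFrame):
        cells.to_csv(path.with_name(path.stem + "_cells.csv"), index=False)
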