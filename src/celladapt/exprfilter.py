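"""Expression-level rules.

Cross-line differential selection, fold-change classification,
Chebyshev-distance clustering preparation, z-scored two-marker condition
landscapes, and AUC-based marker correlation across cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .pharm import auc_log_dose

__all__ = [
    "DifferentialSelection",
    "select_differential_genes",
    "classify_fold_change",
    "prepare_cluster_matrix",
    "linkage_to_newick",
    "zscore_landscape",
    "auc_correlation",
]


@dataclass
class DifferentialSelection:
    up: dict  # timepoint -> list of gene ids (up in line A relative to B)
    down: dict
    q_cut: float
    fpkm_min: float
    log2ratio_min: float
    excluded: list = field(default_factory=list)  # genes with undefined fold-change

    def all_selected(self) -> list:
        out = set()
        for ids in list(self.up.values()) + list(self.down.values()):
            out.update(ids)
        return sorted(out)


def select_differential_genes(
    table: pd.DataFrame,
    q_cut: float = 0.01,
    fpkm_min: float = 1.0,
    log2ratio_min: float = 1.0,
    stabilize: bool = True,
    fpkm_rule: str = "eligible_line",
) -> DifferentialSelection:
    """Cross-line differential gene selection.

    At each treated timepoint a gene is *eligible* if q < ``q_cut`` in at
    least one line; it is *selected* if the treated FPKM passes
    ``fpkm_min`` and the cross-line fold-change ratio satisfies
    |log2(FC_A / FC_B)| >= ``log2ratio_min``, where FC is the
    treated-vs-DMSO fold-change per line.  The ratio sign assigns up vs
    down in line A relative to line B.

    ``stabilize`` computes fold-changes on (FPKM + 1); the raw-ratio mode
    excludes genes with zero DMSO FPKM as undefined.  ``fpkm_rule``
    controls where FPKM >= ``fpkm_min`` must hold: ``"eligible_line"``
    (a line driving eligibility) or ``"max"`` (the larger treated FPKM).
    """
    if fpkm_rule not in ("eligible_line", "max"):
        raise ValueError("fpkm_rule must be 'eligible_line' or 'max'")
    timepoints = sorted(set(table["condition"]) - {"DMSO"})
    fpkm = table.pivot_table(index="gene", columns=["line", "condition"], values="fpkm")
    q = table.pivot_table(index="gene", columns=["line", "condition"], values="q")
    genes = fpkm.index
    up: dict = {t: [] for t in timepoints}
    down: dict = {t: [] for t in timepoints}
    excluded: list = []

    for t in timepoints:
        fa, fb = fpkm[("A", t)], fpkm[("B", t)]
        f0a, f0b = fpkm[("A", "DMSO")], fpkm[("B", "DMSO")]
        qa, qb = q[("A", t)], q[("B", t)]
        missing = fa.isna() | fb.isna() | f0a.isna() | f0b.isna()
        if stabilize:
            fc_a = (fa + 1.0) / (f0a + 1.0)
            fc_b = (fb + 1.0) / (f0b + 1.0)
            undefined = missing
        else:
            undefined = missing | (f0a <= 0) | (f0b <= 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                fc_a = fa / f0a
                fc_b = fb / f0b
        excluded.extend((g, t) for g in genes[undefined])

        eligible_a = qa < q_cut
        eligible_b = qb < q_cut
        eligible = eligible_a | eligible_b
        if fpkm_rule == "max":
            fpkm_ok = np.maximum(fa, fb) >= fpkm_min
        else:
            fpkm_ok = (eligible_a & (fa >= fpkm_min)) | (eligible_b & (fb >= fpkm_min))
        with np.errstate(divide="ignore", invalid="ignore"):
            log2ratio = np.log2(fc_a / fc_b)
        passed = (
            ~undefined & eligible & fpkm_ok & (np.abs(log2ratio) >= log2ratio_min)
        )
        up[t] = sorted(genes[passed & (log2ratio > 0)])
        down[t] = sorted(genes[passed & (log2ratio < 0)])
    return DifferentialSelection(
        up=up,
        down=down,
        q_cut=q_cut,
        fpkm_min=fpkm_min,
        log2ratio_min=log2ratio_min,
        excluded=excluded,
    )


def classify_fold_change(log2fc: float, cut: float = 0.5) -> str:
    """Three-way call: increase (> cut), decrease (< -cut), else no_change."""
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if log2fc > cut:
        return "increase"
    if log2fc < -cut:
        return "decrease"
    return "no_change"


def prepare_cluster_matrix(
    table: pd.DataFrame,
    genes: Optional[Sequence] = None,
    method: str = "average",
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Build the log2((FPKM+1)/DMSO) matrix, Chebyshev distances and a dendrogram.

    Rows are genes, columns are (line, treated condition) pairs.  Returns
    (matrix, square distance DataFrame, Newick string of the average-linkage
    dendrogram).
    """
    df = table if genes is None else table[table["gene"].isin(genes)]
    wide = df.pivot_table(index="gene", columns=["line", "condition"], values="fpkm")
    if not any(c[1] == "DMSO" for c in wide.columns):
        raise ValueError("DMSO column required for normalization")
    mat = {}
    for (line, cond) in wide.columns:
        if cond == "DMSO":
            continue
        mat[f"{line}:{cond}"] = np.log2(
            (wide[(line, cond)] + 1.0) / (wide[(line, "DMSO")] + 1.0)
        )
    matrix = pd.DataFrame(mat)
    dist = pdist(matrix.to_numpy(), metric="chebyshev")
    dist_df = pd.DataFrame(
        squareform(dist), index=matrix.index, columns=matrix.index
    )
    if len(matrix) > 1:
        Z = linkage(dist, method=method)
        newick = linkage_to_newick(Z, list(matrix.index))
    else:
        newick = f"({matrix.index[0]});"
    return matrix, dist_df, newick


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Convert a SciPy linkage matrix to a Newick string with branch lengths."""
    tree = to_tree(Z)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"


def zscore_landscape(
    measurements: pd.DataFrame,
    markers: Sequence[str] = ("ngfr", "ki67"),
    log_transform: bool = True,
) -> pd.DataFrame:
    """Condition-level marker landscape: replicate mean -> log -> z-score.

    ``measurements`` is a tidy table with a ``condition`` column and one
    column per marker (one row per replicate measurement).  z-scores use the
    sample SD across conditions; a degenerate (zero-SD) marker is flagged
    and its z-scores set to 0.
    """
    conditions = measurements["condition"].unique()
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions for z-scoring")
    means = measurements.groupby("condition")[list(markers)].mean()
    out = pd.DataFrame(index=means.index)
    for m in markers:
        vals = means[m].to_numpy(float)
        if log_transform:
            if np.any(vals <= 0):
                raise ValueError(f"non-positive mean for marker {m}; cannot log")
            vals = np.log(vals)
        out[f"{m}_log_mean"] = vals
        sd = vals.std(ddof=1)
        if sd < 1e-12:
            out[f"{m}_z"] = 0.0
            out[f"{m}_degenerate"] = True
        else:
            out[f"{m}_z"] = (vals - vals.mean()) / sd
            out[f"{m}_degenerate"] = False
    return out.reset_index()


def auc_correlation(
    dose_response: pd.DataFrame,
    marker_cols: Sequence[str] = ("marker1", "marker2"),
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of per-line dose-response AUC z-scores.

    ``dose_response`` is tidy with ``line``, ``dose_um`` and two marker
    response columns.  Per line and marker the log-dose AUC is computed,
    z-scored across lines, and the two z-score vectors correlated.
    Returns (r, p, per-line AUC/z table).
    """
    m1, m2 = marker_cols
    lines = dose_response["line"].unique()
    if len(lines) < 3:
        raise ValueError("need >= 3 lines")
    rows = []
    for line, sub in dose_response.groupby("line"):
        sub = sub.sort_values("dose_um")
        rows.append(
            {
                "line": line,
                f"auc_{m1}": auc_log_dose(sub["dose_um"], sub[m1]),
                f"auc_{m2}": auc_log_dose(sub["dose_um"], sub[m2]),
            }
        )
    aucs = pd.DataFrame(rows)
    for m in (m1, m2):
        col = aucs[f"auc_{m}"]
        sd = col.std(ddof=1)
        if sd < 1e-12:
            raise ValueError(f"constant AUCs for {m}; correlation undefined")
        aucs[f"z_{m}"] = (col - col.mean()) / sd
    r, p = pearsonr(aucs[f"z_{m1}"], aucs[f"z_{m2}"])
    return float(r), float(p), aucs
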