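# celladapt

Quantitative pipeline for characterizing adaptive drug resistance in
BRAF-mutant melanoma cell populations: single-cell cell-cycle/fate calling
from geminin reporter traces, population fate statistics, viability/GR
dose-response pharmacology, cross-line differential-expression filtering,
marker landscapes, and compound-screen / biopsy scoring. Every input the
pipeline consumes can be generated by a seeded synthetic-data module, so the
whole analysis is testable offline.

## Modules

| Module | Purpose |
| --- | --- |
| `celladapt.synthdata` | Seeded generators: trace cohorts, endpoint/sequential plates, expression tables, 41-compound screen plates, biopsy-like per-cell tables, outgrowth trajectories. Named presets live in a YAML registry (`colo858_vem`, `mmacsf_vem`, `colo858_dmso`, ...). |
| `celladapt.tracekit` | Per-cell analysis: 40-frame moving-average smoothing, S/G2 onset calling (threshold 2.0/1.5), division/death event detection, phase lengths, minimum-doubling-time estimator, dead/arrested/adapted fate call. |
| `celladapt.popstats` | Grouped fate fractions (mean +/- SD over 3-4 groups), division events per interval, growth curves, log-linear doubling times. |
| `celladapt.pharm` | Apoptosis spot scoring, relative viability, GR metric, descending-Hill dose-response fits (E_max, Hill, EC50, log-dose AUC), sequential-dosing protection summaries. |
| `celladapt.exprfilter` | Cross-line DE selection (q < 0.01, FPKM >= 1, \|log2 ratio\| >= 1), fold-change classification, Chebyshev-distance clustering prep, z-scored marker landscapes, AUC-based marker correlation. |
| `celladapt.screenpath` | Screen hit rule (k lowest z-scores in every line), background exclusion, marker-high gating (fixed / quantile / Otsu). |

## CLI

The `celladapt` entry point exposes one subcommand per pipeline stage:

```bash
# simulate a drug-treated cohort and call fates
celladapt simulate-traces --preset colo858_vem --n-cells 300 --seed 1 --out traces.csv
celladapt analyze-traces --traces traces.csv --threshold 2.0 --window 40 --out calls.csv
celladapt fate-stats --calls calls.csv --out stats.json

# pharmacology
celladapt gr --x-c 200 --x-0 100 --x-ctrl 400
celladapt fit-dr --table plate.csv --out fit.json
celladapt seq-dose --plate seq_plate.csv --out summary.csv

# expression and screening
celladapt de-filter --genes genes.csv --out selection.json
celladapt landscape --table markers.csv --out landscape.csv
celladapt auc-corr --table dose_response.csv
celladapt screen-hits --plate screen.csv --k 5 --out hits.json
celladapt gate --cells cells.csv --method otsu --bg-threshold 2.5 --out gate.json
```

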