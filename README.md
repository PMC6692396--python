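# qpcrsig

A tested, reusable pipeline for RT-qPCR host-transcript classification of
viral versus bacterial infection from threshold-cycle (Ct) data:

- **`ct_data`** — replicate-level Ct parsing (long/wide CSV), the
  replicate-SD quality rule (SD > 0.5 masked by default), aggregation into a
  sample × gene Ct table with group labels.
- **`refgene_stability`** — four reference-gene stability algorithms
  (pairwise-ratio M values with iterative exclusion, model-based
  intra/intergroup variance decomposition, descriptive Ct dispersion with a
  geometric-mean index, comparative delta-Ct), combined by a geometric mean
  of ranks into a comprehensive ranking.
- **`normalization`** — delta Ct against single or multiple reference genes
  (target − mean reference Ct) and 2^−ΔΔCt fold change against a calibrator
  group.
- **`drs_score`** — two-transcript (`log(dCt_FAM89A+10) − log(dCt_IFI44L+10)`)
  and one-transcript (`−log(dCt_IFI44L+10)`) disease risk scores, plus
  intensity-scale variants for log-expression matrices.
- **`performance_eval`** — ROC/AUC (trapezoid ≡ tie-corrected Mann-Whitney),
  Youden cut-point, stratified-bootstrap confidence intervals, predictive
  values, and an assumption-driven group-comparison decision tree
  (Shapiro-Wilk → F test / Breusch-Pagan → t/Welch/ANOVA/Kruskal-Wallis with
  Tukey or Games-Howell post hoc).
- **`power_analysis`** — exact noncentral-t two-sample power and fractional
  per-group sample size.
- **`synthetic_data`** — a calibrated synthetic cohort generator (group
  means, per-gene biological SD, per-sample global offset, triplicate
  technical noise, cycle-cap censoring) so the whole pipeline is testable
  without any external data.
- **`pipeline`** / **`cli`** — deterministic end-to-end orchestration with a
  manifest, plus a click CLI.

## CLI

```sh
qpcrsig simulate --seed 1 --out-prefix scratch/sim
qpcrsig qc --ct-file scratch/sim_ct_long.csv --out scratch/qc
qpcrsig stability --ct-file scratch/sim_ct_long.csv --out scratch/stability.csv
qpcrsig normalize --ct-file scratch/sim_ct_long.csv --target IFI44L \
    --refs GUSB,PGK1,TBP --out scratch/norm.csv
qpcrsig drs --ct-file scratch/sim_ct_long.csv --refs GUSB,PGK1,TBP \
    --variant two_transcript --out scratch/drs.csv
qpcrsig evaluate --scores-file scratch/drs_scores.csv --out scratch/perf.json
qpcrsig power --delta 0.69 --sd 0.47 --power 0.8
qpcrsig run-all --ct-file scratch/sim_ct_long.csv --out-dir scratch/run
```

`run-all` executes QC → stability ranking → top-3 reference selection →
delta Ct → fold change vs controls → both risk-score variants → ROC/Youden/
bootstrap evaluation → cross-reference-option stability, writing CSV/JSON
reports, a Markdown summary, and a manifest. Identical config + seed
reproduces byte-identical outputs.

## Conventions

- Delta Ct is target minus reference, so higher delta Ct = lower
  expression; qPCR risk scores are higher in viral samples, and the
  intensity-scale scores are higher in bacterial samples.
- ROC curves are drawn viral-positive; a bacterial call is a score below
  the Youden cut-point.
- The +10 shift in the risk scores is fixed (published cut-points assume
  it); the log base is configurable and provably irrelevant to
  classification.
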