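# chromodyn

Pipeline for classifying time-course chromatin accessibility dynamics and
integrating them with cross-system differential expression and
factor-binding peak sets.

Given per-sample called-peak files over an ordered time axis anchored by a
somatic start state (MEF) and a pluripotent end state (ESC), chromodyn:

- merges all samples into a disjoint **union peak atlas** and calls each
  interval open/closed per sample (`genomic_intervals` / interval algebra in
  `chromodyn.intervals`);
- classifies every union interval by its anchor states — **PO** (open at
  both anchors), **OC** (open→closed), **CO** (closed→open), plus an **NE**
  catch-all for intervals closed at both anchors — and, for OC/CO, assigns a
  **timing submodule 1–K**: the earliest time point from which the interval
  adopts and maintains the end-anchor state (`chromodyn.dynamics`);
- produces per-condition module count tables and cross-condition Venn
  partitions of module membership;
- implements the cross-system expression-module scheme: per-timepoint
  up/down/ns calls under p and |log2FC| thresholds, within-system
  consistency filtering, common / pairwise / system-specific categories,
  MEF/ESC anchor-expression binning, and peak-timepoint ranking
  (`chromodyn.expression`);
- annotates peaks to genomic features (promoter / exon / intron / distal,
  ±3 kb TSS windows by default), links peaks to genes, scores gene-set
  overlaps with a hypergeometric upper-tail test, and computes binding-peak
  occupancy per accessibility class with region-count normalization
  (`chromodyn.integration`);
- generates fully seeded synthetic studies with planted ground truth —
  module structure with per-call flicker noise, planted DE categories,
  class-specific binding rates — used as recovery oracles throughout the
  test suite (`chromodyn.simulate`).

Coordinates are 0-based half-open (BED) everywhere; narrowPeak q-values are
read as −log10(q).

## CLI

The `chromodyn` entry point exposes one subcommand per analysis block. A
typical synthetic end-to-end run:

```bash
# write a study config
python - <<'EOF'
import yaml
from chromodyn.simulate import study_config
yaml.safe_dump(study_config(seed=1).to_dict(), open("study.yaml", "w"))
EOF

chromodyn simulate      --config study.yaml              --out run/sim
chromodyn classify-atac --config run/sim/classify_atac.yaml --out run/atac
chromodyn classify-deg  --config run/sim/classify_deg.yaml  --out run/deg
chromodyn integrate     --config run/sim/integrate.yaml     --out run/integrate \
                        --atac-dir run/atac --deg-dir run/deg
chromodyn report        --run-dir run
```

Thresholds (`--q-max`, `--p-max`, `--lfc-min`, `--min-overlap`,
`--promoter-window`, `--require-detection`) override the config and are
recorded in each stage's `manifest.json`. Re-running any stage with the
same config reproduces byte-identical data outputs; wall-clock timestamps
live only in `run.log`.

For real data, point `classify_atac.yaml` at your own BED3/narrowPeak files
(one entry per condition × timepoint plus the two shared anchor samples)
and `classify_deg.yaml` at TSV tables with columns
`gene  system  timepoint  log2fc  pvalue`.

## Layout

```
src/chromodyn/
  intervals.py    peak I/O + merge/overlap/subtract/union algebra
  dynamics.py     state matrix, PO/OC/CO/NE classifier, counts, Venn
  expression.py   direction calls, consistency filter, categories, ranking
  integration.py  feature annotation, gene-set overlap, occupancy metrics
  simulate.py     seeded synthetic studies with planted truth
  cli.py          subcommands + manifests
tests/            unit, property (hypothesis) and acceptance suites;
                  tests/_oracles.py holds the independent brute-force oracles
scripts/acceptance.py
```
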