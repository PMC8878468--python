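# cytogate

Live-cell high-content screening analysis: from multi-channel plate
images to segmented cells, hierarchically gated phenotypes, per-well
population kinetics, time-resolved IC50 fitting, growth rates and
per-compound flagging certificates. A synthetic image/plate generator
with exact ground truth makes every stage verifiable without archived
screen data.

## Modules

| module | what it does |
| --- | --- |
| `cytogate.synth` | Synthetic generator: cell/artifact ground truth types, multi-channel z-stack field rendering (Gaussian primitives + Poisson-Gaussian noise), discrete-time plate kinetics (division, Hill-hazard death routes, FUCCI occupancy drift), and labeled feature datasets produced through the full pipeline. |
| `cytogate.segmentation` | Maximum-intensity projection, digital phase contrast (slices 3–5, level 0.003), nuclei segmentation (smooth → threshold → watershed split → size filter), seeded-watershed cell bodies with disk fallback. |
| `cytogate.features` | Versioned per-cell feature sets: 13 nucleus features and 19 cell-body features (shape, per-channel cytoplasmic intensities, Annexin membrane ring, bright-field texture); nuclear-fragment grouping by body/proximity. |
| `cytogate.gating` | Trainable hierarchical gating tree: high-intensity-object filter → nuclear morphology (healthy/pyknosed/fragmented) → mitotic/apoptotic resolution, five-class viability, tubulin/mito/membrane phenotypes (healthy-nucleus cells only; mito only in Annexin-negative cells), FUCCI red/green/yellow. Rule-based fallbacks for HIO/Annexin/FUCCI; seeded random-forest nodes otherwise. |
| `cytogate.quantify` | Per-well fractions, DMSO normalization, normalized growth rate, 4-parameter-logistic IC50 per timepoint, threshold-based compound flagging (all-cell-lines rule), tidy heat-map tables. |
| `cytogate.io_cli` | TIFF field I/O (`{well}_{t}h_{channel}_z{k}.tif`), YAML plate designs/kinetics/configs, end-to-end pipeline with audit logs, CLI. |

## CLI

```bash
# simulate a plate (truth tables + TIFF stacks)
cytogate simulate --design design.yaml --kinetics kinetics.yaml --seed 1 --out sim/

# train a gating model on generator data
cytogate train --mode multiplex --seed 1 --out model.joblib

# end-to-end: segment, gate, quantify, certify
cytogate run --config run.yaml
```

A run config looks like:

```yaml
mode: multiplex
images_dir: sim/images
design_file: sim/design.yaml
out_dir: out
model_file: model.joblib   # optional; trains a default model if absent
seed: 1
min_count: 50
```

Outputs: `cells.csv` (per-cell labels + posteriors), `wells.csv`
(per-well fractions, DMSO-normalized healthy counts, growth rates),
`certificates.json` (per-compound flags), `audit.json` (per-gate object
counts), `resolved_config.yaml`.

Design file (`design.yaml`):

```yaml
mode: multiplex
timepoints: [0, 12, 24]
wells:
  B02: {role: dmso_control, cell_line: u2os}
  B03: {role: dmso_control, cell_line: u2os}
  B04: {compound: cmpdA, concentration: 1.0, role: treatment, cell_line: u2os}
```

Kinetics file (`kinetics.yaml`):

```yaml
cmpdA: {ic50: 1.0, hill: 1.5, kinetic_class: rapid, cell_cycle_action: none}
```

## Conventions

- Coordinates are 0-based pixels, origin top-left, `(x, y)` = (column, row).
- Intensities are raw counts; features are background-subtracted at the
  field's 5th percentile per channel.
- Fractions over a gating partition always sum to 1 over that
  partition's classes; FUCCI fractions exclude unlabeled cells.
- All randomness flows through explicit integer seeds; identical inputs
  and seeds give bit-identical images, truth tables and CSVs.
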