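# msquant

Automated quantitative analysis of ion-trap MS² fragment windows:

- **synthetic spectra** — a simulator for labeled analyte / internal-standard
  fragment-ion window pairs with the pathologies seen on miniature ion-trap
  instruments (Gaussian, tailed, and split peaks; baseline drift; additive
  noise; shared vs. independent per-acquisition amplitude factors),
- **1-D U-net segmentation** — a three-down / three-up encoder-decoder with
  skip connections that marks the peak region of each 400-point window
  (implemented directly on numpy: explicit forward, backward, and Adam, so
  training is deterministic and dependency-light),
- **quantification** — masked rectangle-rule peak areas
  (`S = (x · y) × Δm`, Δm = 0.01 m/z), analyte/IS area ratios, ordinary
  least-squares calibration curves, back-calculation, and process efficiency,
- **validation statistics** — precision (RSD), accuracy (bias), Pearson
  correlation, and Bland–Altman limits of agreement,
- **a CLI pipeline** — simulate → train → evaluate → calibrate → quantify →
  report, restartable per stage from serialized intermediates.

Windows are 400 intensities on a uniform 0.01 m/z grid spanning
`[center − 2, center + 2)` (left-closed, right-open). Truth labels mark the
contiguous region where the noiseless peak exceeds 1% of its apex. Peak areas
are always computed on raw intensities; per-window max scaling is applied only
at the network input.

## CLI

```bash
# full workflow with defaults into runs/demo
msquant all --seed 1 --out runs/demo

# re-run one stage from the serialized intermediates
msquant calibrate --out runs/demo

# custom configuration
msquant all --config run.yaml --seed 7 --out runs/custom
```

`msquant all` writes, under `--out`: the dataset run directories
(`data/train`, `data/test` with per-window TSV files, JSON label sidecars,
and a seed-bearing manifest), the trained model checkpoint (`model.npz`),
segmentation metrics, per-drug calibration curves, a quantification table for
simulated unknowns, precision/accuracy reports, a simulated two-chain
method-comparison (Pearson + Bland–Altman), and a human-readable
`summary.txt`. A YAML config (see `RunConfig.to_yaml`) overrides any default;
`--seed` overrides the master seed, from which every stage seed is derived.

## Layout

| module | contents |
| --- | --- |
| `msquant.windows` | window grid, resampling, annotation → label vectors |
| `msquant.simulate` | peak-shape model, noise model, dataset / calibration-run generators |
| `msquant.unet` | numpy 1-D U-net, training loop, mask prediction |
| `msquant.metrics` | confusion counts, sensitivity/specificity/accuracy, area deviation |
| `msquant.quantify` | Eq.-style peak area, ratios, calibration fit, back-calculation |
| `msquant.valstats` | RSD/bias, Pearson, Bland–Altman |
| `msquant.runio` | run-directory and results-table serialization |
| `msquant.config` / `msquant.pipeline` / `msquant.cli` | run configuration and orchestration |
| `msquant.experiments` | canned desk-scale experiments used by the acceptance checks |

The bundled fragment m/z values for the four example drugs are placeholders
(the instrument transition table is not public); window position does not
affect any computed statistic.
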