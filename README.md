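# gutcount

Quantification pipeline for 3D confocal z-stacks of epithelial tissue:
nuclear segmentation (threshold + anisotropy-aware watershed), per-nucleus
volume and intensity measurement, size- and clone-classification with
per-image threshold optimisation, depth filtering, tissue-level readouts
(cell counts, clone ratios, marker-positive cell ratios, positive-volume
ratios, spot counts) and group-comparison statistics (ANOVA/Tukey,
Kruskal–Wallis/Dunn). A ground-truthed synthetic stack generator makes the
whole pipeline testable without real microscopy data.

## Package layout

| module | contents |
| --- | --- |
| `gutcount.core` | `ImageStack` (C,Z,Y,X voxels + µm geometry), `LabelMap` |
| `gutcount.synthetic` | ellipsoid nucleus placement, channel rendering (blur + noise), fused touching pairs, area phantoms, exact truth tables |
| `gutcount.io` | multi-page TIFF stacks/label maps (geometry in the ImageDescription tag), CSV records |
| `gutcount.segmentation` | Otsu/manual threshold, h-maxima-seeded watershed on the physical distance transform, per-nucleus measurement |
| `gutcount.classification` | 1-D threshold optimisers (brute-force Otsu, deterministic 2-means), size/clone assignment, coverslip-half depth filter |
| `gutcount.quantification` | counts, clone/marker/volume ratios, spot counting |
| `gutcount.stats` | mean±s.e.m., ANOVA + Tukey HSD, Kruskal–Wallis + Dunn (Holm), significance stars |
| `gutcount.pipeline` / `gutcount.cli` | YAML-configured orchestration and the `gutcount` CLI |

## CLI

```sh
gutcount simulate --config sim.yaml --out DIR --seed N    # synthetic stacks + truth
gutcount segment STACK.tif --out labels.tif [--voxel-size Z Y X]
gutcount quantify --config run.yaml --out DIR             # nuclei + summaries CSVs
gutcount compare summaries.csv --metric clone_cell_ratio --mode auto
gutcount all --config full.yaml --out DIR --seed N        # simulate→quantify→compare
```

A simulate config lists `defaults` (any `SimulationParams` field) and
`images` (`id`, `group`, per-image `overrides`); a quantify config lists
`images` (`id`, `path`, `group`), channel roles and `segmentation` /
`classification` parameter blocks. Every run writes a frozen
`config_resolved.yaml` and a `run_log.txt` recording each per-image
auto-chosen threshold. Reruns with the same config and seed are
byte-identical.

## Conventions

- Voxel order is (channel, z, y, x); physical units are µm throughout; the
  centre of voxel *i* sits at (i + 0.5)·spacing.
- Thresholds are strict (`intensity > t`); classification ties go upward
  (volume ≥ cut → big, green mean ≥ cut → clone).
- z index 0 is the coverslip-proximal slice by default (`coverslip_end`
  configurable); the depth filter keeps centroids in the coverslip-proximal
  half of the physical z extent, midplane excluded.
- Undefined ratios (zero denominators) propagate as missing values, never 0.

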