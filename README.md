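# bacmap

Construction and anchoring of BAC-fingerprint physical maps, built around
the workflow used for wheat chromosome-arm maps:

- **simdata** — synthetic chromosome arms, BAC libraries (insert ≈ 143 kb,
  configurable purity), noisy HICF-style band fingerprints, planted
  markers/gene islands, and full ground truth for every generated entity.
- **fingerprint_io** — a minimal plain-text band-file dialect, plus the
  50–500 bp range filter and poor-quality profile rejection.
- **assembly** — Sulston-score overlap nets (binomial tail in log space),
  Q-clone/Q-overlap removal, adaptive clustering from 10⁻¹⁵ to 10⁻³³ in six
  steps with a linear-topology check, clone seriation and contig layout.
- **mtp_pools** — greedy minimum-tiling-path selection, weak-junction
  reinforcement, Q-clone bookkeeping, and 16-row/24-column/plate 3D pools.
- **deconvolution** — simulated PCR and dye-swap microarray screening of the
  pools, C-value/t-test scoring at three confidence tiers, and address
  intersection with an overlap-consistency rule.
- **binmap** — deletion-line bin inference, contig-to-bin assignment with
  conflict flags, coverage-corrected bin sizes, ortholog-rank ordering with
  duplication/split-location reports, supercontig elongation, AGP v2.1
  export.
- **genespace** — gene-island classification, per-bin gene count/density
  tables, and density-gradient Pearson correlations.
- **stats / cli / pipeline** — N50/L50 map statistics and a click CLI
  driving the restartable end-to-end pipeline.

## CLI

```bash
bacmap --seed 1 --outdir out run-all            # full pipeline, defaults
bacmap --config cfg.yaml --outdir out simulate  # individual stages...
bacmap --config cfg.yaml --outdir out assemble  # ...restartable from files
bacmap --outdir out stats
```

Stages: `simulate`, `assemble`, `mtp`, `pools`, `deconvolve`, `binmap`,
`genespace`, `stats`, `run-all`. Every stage writes TSV artifacts (plus a
band file, an AGP export and a log) into `--outdir` and can resume from the
files a previous stage left there. Configuration is YAML; see
`bacmap.config.PipelineConfig` for the keys and defaults.

```yaml
# cfg.yaml
seed: 1
sim:
  arm_length_kb: 11500
  n_clones: 1000
  purity: 0.88
  noise: {band_miss_rate: 0.05, spurious_rate: 2, size_jitter: 1}
assembly:
  net_cutoff: 1.0e-15
  final_cutoff: 1.0e-33
```

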