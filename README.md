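# autoquant

Quantification toolkit for autophagy/lysosome microscopy readouts:

- **Equal-area concentric-ring analysis** of lysosome positioning: each cell is
  divided into four concentric rings of equal area, boundaries scaled from the
  cell outline about the nucleus centroid, and the per-ring intensity density
  is normalized to the whole-cell density (`autoquant.radial_rings`). Includes
  rolling-ball background subtraction (grayscale opening by a ball, default
  radius 30 px) and maximum-intensity projection.
- **Tandem mCherry–GFP reporter scoring**: Laplacian-of-Gaussian punctum
  detection, greedy red↔green matching; red puncta = autophagic vacuoles (AV),
  matched = autophagosomes (APG), red-only = autolysosomes (AL = flux)
  (`autoquant.tandem_puncta`).
- **EM vacuole morphometry**: the ≥2-of-4-criteria autophagosome rule with a
  0.5 µm size gate, per-cell counts, area fractions and maturation percentages
  (`autoquant.em_morphometry`).
- **Densitometry & statistics**: loading-control ratios, fold changes,
  compartment percentages, two-sided unpaired t-test (pooled or Welch) and
  one-way ANOVA with Šidák-adjusted pairwise comparisons
  (`autoquant.quant_stats`).
- **Synthetic scenes with ground truth** (`autoquant.scene_sim`): single cells
  with nucleus, puncta placed with a controllable radial bias or red/green
  composition, smooth backgrounds, Poisson/Gaussian noise, plus vacuole and
  band tables — everything the other stages need for verification, no real
  data required.

## CLI

```sh
# simulate a seeded lysosome scene, then profile it
autoquant simulate --kind lysosome --seed 1 --n-scenes 5 --out scenes/
autoquant rings --input scenes/ --out results/

# tandem-reporter flux counts
autoquant simulate --kind tandem --seed 1 --out tandem/
autoquant puncta --input tandem/ --out results/

# EM vacuole tables and densitometry statistics
autoquant simulate --kind vacuoles --seed 1 --out em/
autoquant morpho --vacuoles em/vacuoles.csv --cells em/cells.csv --out results/
autoquant simulate --kind bands --seed 1 --out blot/
autoquant stats --bands blot/bands.csv --test t --control control --out results/
```

All stage parameters (ring count, rolling-ball radius, detection scale,
match radius, size gate, …) live in a YAML config passed with `--config`;
unknown keys are rejected. Defaults follow the published protocol.

Scene parameters for `simulate` are a separate YAML (fields of
`scene_sim.SceneParams`, e.g. `n_puncta`, `ring_weights`, `apg_fraction`).

## Conventions

- Arrays are indexed `(channel, z, row, col)`; coordinates are `(row, col)`,
  0-based, pixel centers at integers; areas in px² (and µm² when the pixel
  size is known).
- Ring 1 is the peripheral ring, ring 4 the perinuclear ring.
- CSV outputs carry a header row and one row per analysis unit.
- Fixed seeds make every pipeline stage byte-reproducible.
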