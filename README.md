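# corticowalk

Simulation and analysis toolkit for radial cortical neuron migration:

- **`corticowalk.sim`** — a 2D force-based biased persistent-random-walk
  migration model.  Each cell generates a force per timestep (pial-ward with
  probability `rho`, scaled by `alpha`); motion is overdamped against a
  piecewise-constant tissue-resistance field, and forces too weak to overcome
  the local stall threshold are retained as a spring-like store.  Includes
  mixed control/mutant populations with linear coupling of `rho`/`alpha` to
  the control-cell fraction, velocity-profile extraction, profile
  classification, and a mutant-abundance transition sweep.
- **`corticowalk.trackstats`** — per-track statistics for tracked-neuron
  tables (total/net distance, mean straight-line speed, directionality
  index), upper/lower-zone grouping by the any-frame rule, sub-track
  splitting at zone crossings, top-N ranking, and start/end zone occupancy.
- **`corticowalk.laminar`** — relative radial depth of marked neurons
  between two boundary polylines (`d1 / (d1 + d2)`), equal-zone binning, and
  arcsin-sqrt + two-way ANOVA + Tukey distribution comparisons.
- **`corticowalk.undrift`** — non-linear drift correction for time-lapse
  movies: dense pairwise optical flow, spatio-temporal Gaussian smoothing,
  temporal flow integration, and unwarping.
- **`corticowalk.synthdata`** — seeded generators for laminar mark sets,
  track tables and drift movies with known ground truth.
- **`corticowalk.io` / `corticowalk.cli`** — CSV/JSON/TIFF I/O with
  provenance blocks and the umbrella command line.

## Command line

All commands are subcommands of `corticowalk` (exit codes: 0 ok, 2 input
error, 3 invariant violation):

```sh
# population simulation and velocity profile
corticowalk simulate --config config.json --seed 1 --out out/

# mutant-abundance transition sweep
corticowalk sweep --config config.json --seed 1 --out sweep/

# velocity profile of an existing track table
corticowalk profile --tracks tracks.csv --height 200 --out prof/

# per-track statistics, zone occupancy, top-15 ranking
corticowalk analyze-tracks --tracks tracks.csv --y-mid 100 --frame-interval 15 --out stats/

# laminar zone distributions of marked neurons
corticowalk laminar --marks marks.csv --boundaries boundaries.json --zones 10 --out lam/

# drift correction of a multi-page TIFF
corticowalk undrift --in movie.tif --out corrected.tif --sigma-xy 25.6 --sigma-t 1

# synthetic fixtures
corticowalk synth marks --preset control-like --seed 1 --out synth/
```

Configuration is JSON with sections `model.control`, `model.ko`,
`field.control`, `field.ko`, `population`, `sweep` and `seed`; unknown keys
are rejected.  Every `ModelParams`/`ResistanceField` field is addressable;
a seed is required via config or `--seed`.

The optical-flow backend is pluggable: Farnebäck (via OpenCV) is used when
`cv2` is importable, otherwise the scikit-image iterative Lucas-Kanade
estimator (`--backend ilk|tvl1|farneback`).

## Notes

- Directionality biases (65% control, 51% KO) follow the experimental
  anchors; force scale, spring retention and resistance magnitudes are
  calibrated stand-ins chosen to reproduce the qualitative profile
  signatures and the abrupt mosaic-to-KO transition between 5% and 6%
  mutant abundance.
- All randomness flows from explicit seeds; identical config + seed gives
  hash-identical outputs.
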