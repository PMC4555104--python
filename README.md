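# ccPALM

A single-molecule localization microscopy (PALM) analysis pipeline:

* **GLRT spot detection** — per-frame generalized likelihood ratio test for a
  PSF-shaped spot over flat background (σ = 1.8 px default), followed by
  8-way connected-component particle finding;
* **sub-pixel localization** — least-squares fitting of a pixel-integrated
  2D Gaussian, with Thompson-style per-localization precision and SNR;
* **marker-free drift correction** — time-batched 2D localization histograms,
  phase correlation between consecutive batches with sub-pixel Gaussian peak
  refinement, polynomial interpolation, subtraction;
* **blinking consolidation** — consecutive-frame linking plus dark-time
  (t_d, default 10 s) tolerant merging, and the dark-time diagnostic curve
  with its biphasic fit;
* **density filtering** — retain points with ≥ 4 neighbors within 50 nm
  (plus their neighbors);
* **cluster morphometry** — freely rotating anisotropic 2D Gaussian fit per
  contoured cluster; FWHM thickness/length, the 25 nm resolution discard
  rule, and population summaries (logarithmic thickness/length vs content);
* **rendering** — Gaussian-spot (width = FWHM, e.g. 214 nm ≡ 2 px at
  107 nm/px) and histogram modes;
* **synthetic data** — a blinking-emitter movie generator (clusters along a
  curved cord + background molecules, uniform-in-time photoconversion,
  geometric on-times, exponential blink dark times, EMCCD-like noise) with
  ground truth written alongside, so every stage is testable end to end.

## CLI

```sh
ccpalm init-config config.yaml          # write the default configuration
ccpalm run --config config.yaml --seed 1 --out runs/demo
```

`run` executes simulate (unless an input movie/localization table is
configured) → detect → localize → drift → merge → filter → clusters → render,
writing each stage's table (CSV), the drift trajectory, ROI polygons (JSON),
rendered images (TIFF) and a `run_log.json` with parameters, seeds and
per-stage record counts.

Individual stages:

```sh
ccpalm simulate --out sim --seed 1 --n-frames 4000
ccpalm detect   sim/movie.tiff --sensitivity 25 --out det.csv
ccpalm localize sim/movie.tiff det.csv --out locs.csv
ccpalm drift    locs.csv --batch-size 1000 --bin-size-nm 107   # --no-correction to only estimate
ccpalm merge    localizations_corrected.csv --t-d 10           # or --off-gap-frames 200
ccpalm filter   molecules.csv --radius-nm 50 --min-neighbors 4 --keep-neighbors
ccpalm clusters molecules_filtered.csv --resolution-nm 25
ccpalm render   molecules_filtered.csv --spot-width-nm 214 --pixel-nm 10
```

Localization tables are plain CSV (`frame, x_nm, y_nm, amplitude, background,
photons, precision_nm, snr, fit_ok`); ThunderSTORM-style column names
(`x [nm]`, `uncertainty [nm]`, …) are accepted on input.

## Conventions

* Coordinates are continuous nanometres; the origin is the centre of camera
  pixel (0, 0) and pixel (i, j) spans `[i−0.5, i+0.5) × pixel_size`.
* Rendered "spot width" always means FWHM.
* All randomness flows through explicit integer seeds; identical seeds give
  byte-identical tables.
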