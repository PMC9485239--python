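# granuletrack

Region-resolved analysis of live-cell single-molecule tracking movies, for
experiments that follow the mobility of a nucleocytoplasmic protein (for
example an RNA-binding protein such as TDP-43) while cells form stress
granules.  The package takes two-channel time-lapse movies — a sparse
photoactivated tracking channel plus a periodic granule-marker control
channel — and produces region-resolved diffusion estimates, super-resolved
localization maps, and kinetic statistics.  A full synthetic-movie
simulator with known ground truth makes every stage testable without
microscope data.

## What it computes

* **Detection, localization, linking** — band-pass spot detection with a
  robust noise threshold, 2-D Gaussian sub-pixel fitting, and
  nearest-neighbour linking (5 px radius, one gap frame, minimum track
  length 3, ≥ 2 localizations before a gap).
* **Regions** — static cell/nucleus polygons plus dynamic stress-granule
  masks thresholded from the control channel (2-frame moving average,
  optional 2 px blur); tracks are split at region borders and the crossing
  jump belongs to neither region.
* **Jump-distance diffusion** — the cumulative distribution of
  frame-to-frame jump distances r (first 5 jumps per track, 1 nm bins) is
  fitted with a multi-exponential Brownian mixture

      P(r ≤ R) = 1 − Σᵢ Fᵢ · exp(−R² / (4 Dᵢ Δt)),   Σᵢ Fᵢ = 1,

  giving slow/medium/fast coefficients D₁ ≤ D₂ ≤ D₃ with fractions Fᵢ and
  the effective coefficient **D_eff = Σᵢ Fᵢ Dᵢ**; movies with < 30 jumps
  or a 95 %-CI error above 5× the group median are discarded before
  movie-wise aggregation.
* **TALM & diffusion maps** — detections binned on a 43 nm grid (×3
  up-scaled); squared jumps averaged over 3 × 3 bins give a local
  D = X/(4 Δt) map; slow patches are D < 2 µm²/s areas of ≥ 50 px with
  morphological closing (disk r = 3) and enclosed-pixel filling;
  localization clusters are ≥ 80 connected lower-quartile Voronoi cells.
* **Kinetics** — a 2-state Rayleigh-emission HMM separates bound from
  free links; turning angles of free jumps > 0.13 µm give the
  fold-anisotropy f₁₈₀/₀ = N(180°±30°)/N(0°±30°) with 50 half-data
  resamplings; free tracks crossing a granule border count as
  entering/leaving shuttling events.

## Worked example

`examples/02_jump_distance_fit.py` draws 10,000 jumps from a known
three-component mixture and fits 1–3 component models:

```
jumps collected: 10000
1-component fit: D = 1.731 µm²/s, F = 1.00, D_eff = 1.73 µm²/s, adj. R² = 0.88164
2-component fit: D = 0.169/4.424 µm²/s, F = 0.43/0.57, D_eff = 2.58 µm²/s, adj. R² = 0.99733
3-component fit: D = 0.045/0.485/4.983 µm²/s, F = 0.20/0.30/0.50, D_eff = 2.66 µm²/s, adj. R² = 0.99999
truth           : D = 0.050/0.500/5.000 µm²/s, F = 0.20/0.30/0.50, D_eff = 2.66 µm²/s
```

The 3-component model wins on adjusted R² and recovers the generating
coefficients to a few percent; D_eff is their fraction-weighted mean.
The other example scripts simulate and track a full movie
(`01_simulate_and_track.py`), render maps and segment the planted slow
patch (`03_maps_and_patches.py`, ~97 % area overlap), and compare the
anisotropy of free vs confined motion and count shuttling events
(`04_anisotropy_and_shuttling.py`).

A complete movie analysis is one call:

```python
import granuletrack as gt

bundle = gt.run_pipeline(
    gt.PipelineConfig(movie_id="cell01"),
    tracking_stack=tracking,        # (n_frames, ny, nx) array
    control_stack=control,          # granule-marker channel
    control_frames=control_frames,  # 0-based frame indices
    cell_polygon=cell, nucleus_polygon=nucleus,  # µm polygons (optional)
    out_dir="results/cell01",
)
print(gt.pipeline.report(bundle))
```

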