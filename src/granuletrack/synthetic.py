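"""Synthetic two-channel single-molecule movies with known ground truth.

The simulator emulates the statistical structure of a photoactivation
tracking experiment on a stressed cell: an elliptical cell containing a
nucleus, slowly drifting bright stress granules visible in a control
channel, and sparse photoactivated emitters in the tracking channel whose
motion mixes three Brownian populations, immobile binding hotspots and
slow-diffusivity cytoplasmic patches.  Every stochastic operation takes an
explicit seed; there is no hidden global random state.

Units: positions in µm, diffusion coefficients in µm²/s, times in seconds.
Pixel (i, j) of a raster covers the half-open square
[j·p, (j+1)·p) × [i·p, (i+1)·p) with p the pixel size in µm; x runs along
columns and y along rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "SceneConfig",
    "SceneGeometry",
    "MotionModel",
    "CameraModel",
    "GroundTruth",
    "make_geometry",
    "simulate_emitters",
    "simulate_free_tracks",
    "simulate_two_state_tracks",
    "render_movie",
    "write_fixture",
]


def _ellipse_polygon(center: np.ndarray, axes: np.ndarray, n: int = 64) -> np.ndarray:
    """Closed polygon approximating an axis-aligned ellipse (first vertex not repeated)."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + axes[0] * np.cos(t), center[1] + axes[1] * np.sin(t)]
    )


@dataclass
class SceneConfig:
    """Parameters of the simulated cell geometry.

    Defaults produce a mid-sized adherent cell (~160 µm² cytoplasm) in a
    160 × 160 px field of view at 130 nm pixels, decorated with a few
    stress granules, one slow-diffusivity cytoplasmic patch and two
    binding hotspots.
    """

    frame_size: tuple[int, int] = (160, 160)  # (rows, cols) px
    pixel_size: float = 0.130  # µm
    cell_axes: tuple[float, float] = (8.5, 6.0)  # semi-axes, µm
    nucleus_axes: tuple[float, float] = (3.8, 2.9)
    nucleus_offset: tuple[float, float] = (-1.8, 0.0)  # relative to cell center
    n_granules: int = 4
    granule_radius: tuple[float, float] = (0.45, 0.8)  # min, max µm
    granule_drift_sigma: float = 2e-4  # µm per frame, per axis
    n_patches: int = 1
    patch_radius: float = 1.0  # µm
    patch_D: float = 0.1  # µm²/s inside patches
    n_hotspots: int = 2
    hotspot_radius: float = 0.05  # µm
    hotspot_binding_prob: float = 0.5  # per visit

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if min(self.cell_axes) <= 0 or min(self.nucleus_axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if not (self.cell_axes[0] > self.nucleus_axes[0] and self.cell_axes[1] > self.nucleus_axes[1]):
            raise ValueError("cell must be larger than nucleus")
        if self.n_granules and (min(self.granule_radius) <= 0):
            raise ValueError("granule radii must be positive")


@dataclass
class SceneGeometry:
    """Ground-truth geometry of one simulated cell.

    ``granules`` rows are (cx, cy, radius, vx, vy) with the drift velocity
    in µm/frame; granule centers at frame ``t`` are ``(cx + vx·t, cy + vy·t)``.
    ``patches`` are disks (cx, cy, radius) with per-patch diffusivity in
    ``patch_D``; ``hotspots`` rows are (cx, cy, radius, binding_prob).
    """

    cell_center: np.ndarray
    cell_axes: np.ndarray
    nucleus_center: np.ndarray
    nucleus_axes: np.ndarray
    granules: np.ndarray  # (n, 5)
    patches: np.ndarray  # (n, 3)
    patch_D: np.ndarray  # (n,)
    hotspots: np.ndarray  # (n, 4)
    frame_size: tuple[int, int]
    pixel_size: float

    @property
    def cell_outline(self) -> np.ndarray:
        return _ellipse_polygon(self.cell_center, self.cell_axes)

    @property
    def nucleus_outline(self) -> np.ndarray:
        return _ellipse_polygon(self.nucleus_center, self.nucleus_axes)

    def elliptic_radius(self, xy: np.ndarray, which: str = "cell") -> np.ndarray:
        """Normalized elliptic radius (1.0 on the outline) of points (n, 2)."""
        c, a = (
            (self.cell_center, self.cell_axes)
            if which == "cell"
            else (self.nucleus_center, self.nucleus_axes)
        )
        u = (np.atleast_2d(xy) - c) / a
        return np.hypot(u[:, 0], u[:, 1])

    def in_cell(self, xy: np.ndarray) -> np.ndarray:
        return self.elliptic_radius(xy, "cell") <= 1.0

    def in_nucleus(self, xy: np.ndarray) -> np.ndarray:
        return self.elliptic_radius(xy, "nucleus") <= 1.0

    def granule_centers(self, frame: int) -> np.ndarray:
        if len(self.granules) == 0:
            return np.empty((0, 2))
        return self.granules[:, :2] + self.granules[:, 3:5] * frame

    def in_granule(self, xy: np.ndarray, frame: int) -> np.ndarray:
        xy = np.atleast_2d(xy)
        hit = np.zeros(len(xy), dtype=bool)
        centers = self.granule_centers(frame)
        for c, r in zip(centers, self.granules[:, 2]):
            hit |= np.hypot(xy[:, 0] - c[0], xy[:, 1] - c[1]) <= r
        return hit

    def patch_index(self, xy: np.ndarray) -> np.ndarray:
        """Index of the patch containing each point, or -1."""
        xy = np.atleast_2d(xy)
        idx = np.full(len(xy), -1, dtype=int)
        for k, (cx, cy, r) in enumerate(self.patches):
            inside = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) <= r
            idx[inside & (idx < 0)] = k
        return idx

    def granule_mask(self, frame: int) -> np.ndarray:
        """Rasterized boolean granule mask for one frame (movie pixel grid)."""
        ny, nx = self.frame_size
        p = self.pixel_size
        yy, xx = np.mgrid[0:ny, 0:nx]
        px = (xx + 0.5) * p
        py = (yy + 0.5) * p
        mask = np.zeros((ny, nx), dtype=bool)
        for c, r in zip(self.granule_centers(frame), self.granules[:, 2]):
            mask |= (px - c[0]) ** 2 + (py - c[1]) ** 2 <= r**2
        return mask

    def reflect_into_cell(self, xy: np.ndarray) -> np.ndarray:
        """Reflect points at the cell outline (radially in elliptic coordinates)."""
        xy = np.array(np.atleast_2d(xy), dtype=float)
        u = (xy - self.cell_center) / self.cell_axes
        r = np.hypot(u[:, 0], u[:, 1])
        out = r > 1.0
        if np.any(out):
            r_out = r[out]
            # fold r -> 2 - r repeatedly until inside; steps are small so one fold suffices
            r_new = np.abs(2.0 - r_out)
            r_new = np.where(r_new > 1.0, np.abs(2.0 - r_new), r_new)
            scale = r_new / r_out
            u[out] *= scale[:, None]
            xy = u * self.cell_axes + self.cell_center
        return xy


@dataclass
class MotionModel:
    """Brownian mixture motion law of the tracked molecules.

    Three diffusing populations (D1 < D2 < D3 with occupancy fractions
    summing to one) move with per-axis Gaussian steps of variance
    2·D·frame_cycle.  Emitters inside a slow patch take the patch
    diffusivity; emitters visiting a binding hotspot may immobilize.  An
    optional 2-state transition matrix adds global bound/free switching.
    """

    D_components: tuple[float, float, float] = (0.05, 0.5, 5.0)
    fractions: tuple[float, float, float] = (0.2, 0.3, 0.5)
    frame_cycle: float = 0.006742  # s
    localization_sigma: float = 0.02  # µm, applied to observed positions only
    switching: np.ndarray | None = None  # rows: from-state (free, bound)
    bound_D: float = 0.0
    bleach_prob: float = 0.1  # per-frame bleaching; mean track lifetime 10 frames
    activation_rate: float = 1.5  # expected new emitters per frame
    hotspot_release_prob: float = 0.1  # per-frame unbinding from a hotspot

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(d < 0 for d in self.D_components):
            raise ValueError("diffusion coefficients must be non-negative")
        if self.frame_cycle <= 0:
            raise ValueError("frame_cycle must be positive")
        if self.switching is not None:
            sw = np.asarray(self.switching, dtype=float)
            if sw.shape != (2, 2) or not np.allclose(sw.sum(axis=1), 1.0):
                raise ValueError("switching must be a 2x2 row-stochastic matrix")
            self.switching = sw


@dataclass
class CameraModel:
    """Rendering parameters for the EMCCD-like camera model."""

    psf_sigma_px: float = 1.0
    amplitude_photons: float = 200.0  # peak photons of one emitter PSF
    background_photons: float = 20.0  # photons per pixel per frame
    read_noise: float = 2.0  # ADU, Gaussian
    offset: float = 100.0  # ADU
    control_interval: int = 200  # frames between control-channel images
    control_cyto_photons: float = 60.0
    control_nucleus_photons: float = 30.0
    control_granule_photons: float = 600.0

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0 or self.amplitude_photons <= 0 or self.background_photons < 0:
            raise ValueError("PSF sigma and photon counts must be positive")
        if self.control_interval < 1:
            raise ValueError("control_interval must be >= 1")


@dataclass
class GroundTruth:
    """Per-emitter, per-frame ground truth of a simulated movie.

    ``frames`` columns: emitter_id, frame, x_um, y_um, population (0/1/2,
    -1 while hotspot-bound origin unknown), state ('free'/'bound'),
    in_granule, in_patch.
    """

    frames: pd.DataFrame
    emitters: pd.DataFrame  # emitter_id, population, t_on, t_off
    geometry: SceneGeometry
    motion: MotionModel
    n_frames: int
    seed: int

    def observed_positions(self, seed: int | None = None) -> pd.DataFrame:
        """Ground-truth table with localization noise added to positions."""
        rng = np.random.default_rng(self.seed + 7919 if seed is None else seed)
        out = self.frames.copy()
        s = self.motion.localization_sigma
        if s > 0:
            out["x_um"] = out["x_um"] + rng.normal(0.0, s, len(out))
            out["y_um"] = out["y_um"] + rng.normal(0.0, s, len(out))
        return out


def make_geometry(seed: int, config: SceneConfig | None = None) -> SceneGeometry:
    """Place cell, nucleus, granules, patches and hotspots; deterministic per seed.

    Granules and patches are placed by rejection sampling fully inside the
    cytoplasm (cell minus nucleus).  Raises ``RuntimeError`` naming the
    object type if no feasible placement is found within bounded retries.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    ny, nx = cfg.frame_size
    center = np.array([nx * cfg.pixel_size / 2.0, ny * cfg.pixel_size / 2.0])
    extent = np.array([nx * cfg.pixel_size, ny * cfg.pixel_size])
    if cfg.cell_axes[0] * 2 > extent[0] or cfg.cell_axes[1] * 2 > extent[1]:
        raise ValueError("cell does not fit into the field of view")
    nuc_center = center + np.asarray(cfg.nucleus_offset)

    cell = shapely.Polygon(_ellipse_polygon(center, np.asarray(cfg.cell_axes)))
    nucleus = shapely.Polygon(_ellipse_polygon(nuc_center, np.asarray(cfg.nucleus_axes)))
    if not nucleus.within(cell):
        raise ValueError("nucleus placement: nucleus must lie strictly inside the cell")
    cytoplasm = cell.difference(nucleus)

    def place_disks(n: int, radii: np.ndarray, what: str) -> np.ndarray:
        placed = []
        for r in radii:
            for _ in range(400):
                xy = rng.uniform([cell.bounds[0], cell.bounds[1]], [cell.bounds[2], cell.bounds[3]])
                disk = shapely.Point(xy).buffer(float(r), quad_segs=16)
                if disk.within(cytoplasm) and all(
                    np.hypot(xy[0] - p[0], xy[1] - p[1]) > r + p[2] for p in placed
                ):
                    placed.append([xy[0], xy[1], float(r)])
                    break
            else:
                raise RuntimeError(
                    f"could not place {what} of radius {r:.2f} µm inside the cytoplasm"
                )
        return np.asarray(placed).reshape(-1, 3)

    gr_radii = rng.uniform(*cfg.granule_radius, size=cfg.n_granules)
    granule_disks = place_disks(cfg.n_granules, gr_radii, "granule")
    drift = rng.normal(0.0, cfg.granule_drift_sigma, size=(cfg.n_granules, 2))
    granules = (
        np.column_stack([granule_disks, drift]) if cfg.n_granules else np.empty((0, 5))
    )

    patches = place_disks(cfg.n_patches, np.full(cfg.n_patches, cfg.patch_radius), "patch")
    patch_D = np.full(cfg.n_patches, cfg.patch_D)

    hotspot_disks = place_disks(
        cfg.n_hotspots, np.full(cfg.n_hotspots, cfg.hotspot_radius), "hotspot"
    )
    hotspots = (
        np.column_stack([hotspot_disks, np.full(cfg.n_hotspots, cfg.hotspot_binding_prob)])
        if cfg.n_hotspots
        else np.empty((0, 4))
    )

    return SceneGeometry(
        cell_center=center,
        cell_axes=np.asarray(cfg.cell_axes, dtype=float),
        nucleus_center=nuc_center,
        nucleus_axes=np.asarray(cfg.nucleus_axes, dtype=float),
        granules=granules,
        patches=patches,
        patch_D=patch_D,
        hotspots=hotspots,
        frame_size=cfg.frame_size,
        pixel_size=cfg.pixel_size,
    )


def simulate_emitters(
    geometry: SceneGeometry,
    motion: MotionModel,
    n_frames: int,
    seed: int,
) -> GroundTruth:
    """Simulate photoactivated emitters through ``n_frames`` frames.

    New emitters appear as a Poisson process (``activation_rate`` per
    frame), uniformly in the cell, drawn from the three Brownian
    populations; they bleach after a geometric lifetime.  Free emitters
    take isotropic Gaussian steps of per-axis variance 2·D·Δt with D the
    population coefficient, or the patch coefficient while inside a slow
    patch; steps reflect at the cell outline.  Visits to a hotspot disk
    immobilize the emitter with the hotspot's binding probability until a
    geometric release.  With a ``switching`` matrix, emitters additionally
    alternate between free motion and an immobile bound state.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    D = np.asarray(motion.D_components, dtype=float)
    dt = motion.frame_cycle

    rows: list[tuple] = []
    emitters: list[tuple] = []
    # active emitter state (parallel lists -> arrays each frame)
    pos: list[np.ndarray] = []
    pop: list[int] = []
    state: list[int] = []  # 0 free, 1 hotspot-bound, 2 switching-bound
    t_off: list[int] = []
    ids: list[int] = []
    next_id = 0

    hot = geometry.hotspots

    for t in range(n_frames):
        # propagate existing emitters
        keep_pos, keep_pop, keep_state, keep_toff, keep_ids = [], [], [], [], []
        for i in range(len(pos)):
            if t >= t_off[i]:
                continue
            p = pos[i]
            st = state[i]
            if st == 1:  # hotspot-bound
                if rng.random() < motion.hotspot_release_prob:
                    st = 0
            elif st == 2:  # switching-bound
                if motion.bound_D > 0:
                    p = p + rng.normal(0.0, np.sqrt(2 * motion.bound_D * dt), 2)
                if rng.random() < motion.switching[1, 0]:
                    st = 0
            else:
                k = geometry.patch_index(p)[0]
                d_local = geometry.patch_D[k] if k >= 0 else D[pop[i]]
                p = p + rng.normal(0.0, np.sqrt(2 * d_local * dt), 2)
                p = geometry.reflect_into_cell(p)[0]
                # hotspot binding on visit
                if len(hot) and st == 0:
                    dists = np.hypot(hot[:, 0] - p[0], hot[:, 1] - p[1])
                    j = int(np.argmin(dists))
                    if dists[j] <= hot[j, 2] and rng.random() < hot[j, 3]:
                        st = 1
                        p = hot[j, :2] + rng.normal(0.0, hot[j, 2] / 3.0, 2)
                # global bound/free switching
                if motion.switching is not None and st == 0:
                    if rng.random() < motion.switching[0, 1]:
                        st = 2
            keep_pos.append(p)
            keep_pop.append(pop[i])
            keep_state.append(st)
            keep_toff.append(t_off[i])
            keep_ids.append(ids[i])
        pos, pop, state, t_off, ids = keep_pos, keep_pop, keep_state, keep_toff, keep_ids

        # activate new emitters
        n_new = rng.poisson(motion.activation_rate)
        for _ in range(n_new):
            for _ in range(200):
                xy = geometry.cell_center + rng.uniform(-1, 1, 2) * geometry.cell_axes
                if geometry.in_cell(xy)[0]:
                    break
            else:  # pragma: no cover - cell fills most of its bbox
                continue
            k = int(rng.choice(3, p=motion.fractions))
            life = int(rng.geometric(motion.bleach_prob))
            st0 = 0
            if motion.switching is not None:
                # start from the stationary distribution of the switching chain
                p01, p10 = motion.switching[0, 1], motion.switching[1, 0]
                pb = p01 / (p01 + p10) if (p01 + p10) > 0 else 0.0
                st0 = 2 if rng.random() < pb else 0
            pos.append(np.asarray(xy))
            pop.append(k)
            state.append(st0)
            t_off.append(t + life)
            ids.append(next_id)
            emitters.append((next_id, k, t, min(t + life, n_frames)))
            next_id += 1

        if pos:
            xy_arr = np.asarray(pos)
            in_gr = geometry.in_granule(xy_arr, t)
            in_pa = geometry.patch_index(xy_arr) >= 0
            for i in range(len(pos)):
                rows.append(
                    (
                        ids[i],
                        t,
                        pos[i][0],
                        pos[i][1],
                        pop[i],
                        "bound" if state[i] != 0 else "free",
                        bool(in_gr[i]),
                        bool(in_pa[i]),
                    )
                )

    frames = pd.DataFrame(
        rows,
        columns=["emitter_id", "frame", "x_um", "y_um", "population", "state", "in_granule", "in_patch"],
    )
    if frames.empty:
        warnings.warn("no active emitters over the whole movie", stacklevel=2)
    em = pd.DataFrame(emitters, columns=["emitter_id", "population", "t_on", "t_off"])
    return GroundTruth(
        frames=frames, emitters=em, geometry=geometry, motion=motion, n_frames=n_frames, seed=seed
    )


def simulate_free_tracks(
    n_tracks: int,
    n_steps: int,
    D: float,
    frame_cycle: float = 0.006742,
    localization_sigma: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Unbounded 2-D Brownian tracks (n_steps jumps each), as (n_steps+1, 2) arrays."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * D * frame_cycle)
    steps = rng.normal(0.0, sigma, size=(n_tracks, n_steps, 2))
    tracks = np.concatenate([np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    if localization_sigma > 0:
        tracks = tracks + rng.normal(0.0, localization_sigma, size=tracks.shape)
    return [t for t in tracks]


def simulate_two_state_tracks(
    n_tracks: int,
    n_steps: int,
    D_bound: float,
    D_free: float,
    stay_prob: float = 0.95,
    frame_cycle: float = 0.006742,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Two-state Brownian tracks; returns (tracks, per-jump state labels 0=bound/1=free)."""
    rng = np.random.default_rng(seed)
    tracks, labels = [], []
    for _ in range(n_tracks):
        st = int(rng.random() < 0.5)
        xy = np.zeros((n_steps + 1, 2))
        lab = np.zeros(n_steps, dtype=int)
        for j in range(n_steps):
            lab[j] = st
            d = D_free if st == 1 else D_bound
            xy[j + 1] = xy[j] + rng.normal(0.0, np.sqrt(2 * d * frame_cycle), 2)
            if rng.random() > stay_prob:
                st = 1 - st
        tracks.append(xy)
        labels.append(lab)
    return tracks, labels


def _render_spots(image: np.ndarray, xy_px: np.ndarray, amp: float, sigma: float) -> None:
    """Add Gaussian PSFs (in place, photon units) at sub-pixel positions (x, y) in px."""
    ny, nx = image.shape
    half = max(3, int(np.ceil(4 * sigma)))
    for x, y in np.atleast_2d(xy_px):
        i0, j0 = int(np.floor(y)), int(np.floor(x))
        i_lo, i_hi = max(0, i0 - half), min(ny, i0 + half + 1)
        j_lo, j_hi = max(0, j0 - half), min(nx, j0 + half + 1)
        if i_lo >= i_hi or j_lo >= j_hi:
            continue
        ii, jj = np.mgrid[i_lo:i_hi, j_lo:j_hi]
        image[i_lo:i_hi, j_lo:j_hi] += amp * np.exp(
            -(((jj + 0.5 - x) ** 2) + ((ii + 0.5 - y) ** 2)) / (2 * sigma**2)
        )


def render_movie(
    truth: GroundTruth,
    geometry: SceneGeometry,
    camera: CameraModel | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render the tracking channel (every frame) and control channel.

    Returns ``(tracking_stack, control_stack, control_frames)``; the
    control channel images the granule marker every ``control_interval``
    frames starting at frame 0.  Emitters are rendered as 2-D Gaussian
    PSFs over a flat background, with Poisson shot noise and Gaussian read
    noise, as uint16 with a fixed offset.
    """
    cam = camera or CameraModel()
    rng = np.random.default_rng(seed)
    ny, nx = geometry.frame_size
    p = geometry.pixel_size
    n_frames = truth.n_frames
    if cam.amplitude_photons < 3.0 * np.sqrt(max(cam.background_photons, 1.0)):
        warnings.warn("emitter brightness below background noise: spots may be undetectable", stacklevel=2)

    by_frame = {t: g for t, g in truth.frames.groupby("frame")}
    tracking = np.empty((n_frames, ny, nx), dtype=np.uint16)
    for t in range(n_frames):
        img = np.full((ny, nx), cam.background_photons, dtype=float)
        g = by_frame.get(t)
        if g is not None and len(g):
            xy_px = g[["x_um", "y_um"]].to_numpy() / p
            _render_spots(img, xy_px, cam.amplitude_photons, cam.psf_sigma_px)
        img = rng.poisson(img).astype(float)
        img += rng.normal(0.0, cam.read_noise, img.shape) + cam.offset
        tracking[t] = np.clip(img, 0, 65535).astype(np.uint16)

    control_frames = np.arange(0, n_frames, cam.control_interval)
    yy, xx = np.mgrid[0:ny, 0:nx]
    px = (xx + 0.5) * p
    py = (yy + 0.5) * p
    pts = np.column_stack([px.ravel(), py.ravel()])
    cell_m = geometry.in_cell(pts).reshape(ny, nx)
    nuc_m = geometry.in_nucleus(pts).reshape(ny, nx)
    control = np.empty((len(control_frames), ny, nx), dtype=np.uint16)
    for k, t in enumerate(control_frames):
        img = np.full((ny, nx), cam.background_photons, dtype=float)
        img[cell_m] += cam.control_cyto_photons
        img[nuc_m] += cam.control_nucleus_photons - cam.control_cyto_photons
        gmask = geometry.granule_mask(int(t))
        img[gmask] += cam.control_granule_photons
        img = rng.poisson(img).astype(float)
        img += rng.normal(0.0, cam.read_noise, img.shape) + cam.offset
        control[k] = np.clip(img, 0, 65535).astype(np.uint16)

    return tracking, control, control_frames


def write_fixture(
    truth: GroundTruth,
    movies: tuple[np.ndarray, np.ndarray, np.ndarray],
    path,
    manifest_extra: dict | None = None,
) -> dict:
    """Write a fixture bundle (TIFF stacks, truth CSV, geometry/manifest JSON).

    Returns the manifest dictionary.  The bundle round-trips through
    :mod:`granuletrack.io` readers.
    """
    import json
    from pathlib import Path

    import tifffile

    tracking, control, control_frames = movies
    if tracking.shape[0] == 0:
        raise ValueError("fixture with 0 frames rejected")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "tracking.tif", tracking, photometric="minisblack")
    tifffile.imwrite(path / "control.tif", control, photometric="minisblack")
    truth.frames.to_csv(path / "ground_truth_tracks.csv", index=False)
    geom = truth.geometry
    geo_json = {
        "cell": geom.cell_outline.tolist(),
        "nucleus": geom.nucleus_outline.tolist(),
        "granules": geom.granules.tolist(),
        "patches": geom.patches.tolist(),
        "patch_D": geom.patch_D.tolist(),
        "hotspots": geom.hotspots.tolist(),
        "pixel_size": geom.pixel_size,
        "frame_size": list(geom.frame_size),
    }
    (path / "geometry.json").write_text(json.dumps(geo_json, indent=1))
    manifest = {
        "n_frames": truth.n_frames,
        "seed": truth.seed,
        "control_frames": np.asarray(control_frames).tolist(),
        "motion": {
            "D_components": list(truth.motion.D_components),
            "fractions": list(truth.motion.fractions),
            "frame_cycle": truth.motion.frame_cycle,
            "localization_sigma": truth.motion.localization_sigma,
            "bleach_prob": truth.motion.bleach_prob,
            "activation_rate": truth.motion.activation_rate,
        },
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
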