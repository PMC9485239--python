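"""Configuration and end-to-end orchestration of the tracking analysis.

``run_pipeline`` executes the stages in order: ingest (or simulate) the
movie, detect and localize spots, link tracks, build region masks, split
tracks by region, fit jump-distance mixtures with QC, render TALM and
diffusion maps with patch/cluster quantification, and run the kinetics
analyses (bound/free segmentation, anisotropy, shuttling).  Each stage is
skippable by supplying its input table directly (a pre-computed track CSV
bypasses detection and linking).  All defaults match the reference
acquisition: 130 nm pixels, 6.742 ms frame cycle, a control image every
200 frames, 5 px tracking radius, one gap frame, minimum track length 3,
first 5 jumps, 1 nm histogram bins, a 30-jump movie minimum, a 5× CI
error filter, 2 µm²/s patch threshold, 50 px minimum patch size, radius-3
closing disk, lower-quartile Voronoi cells, 80-cell clusters, 0.13 µm
minimum angle jump, ±30° windows and 50 half-data resamplings.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from granuletrack import diffusion, io, kinetics, maps, regions as regions_mod, tracking

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    """All parameters of one pipeline run; defaults are the reference values."""

    # acquisition
    pixel_size: float = 0.130  # µm
    frame_cycle: float = 0.006742  # s
    control_interval: int = 200  # frames
    time_slot_minutes: float = 20.0
    # detection / localization
    threshold_factor: float = 2.0
    dog_sigmas: tuple[float, float] = (1.0, 2.5)
    fit_window: int = 7
    psf_sigma_px: float = 1.0
    # linking
    radius_px: float = 5.0
    max_gap: int = 1
    min_track_length: int = 3
    min_len_before_gap: int = 2
    # regions
    granule_threshold_mode: str = "quantile"
    granule_threshold_value: float = 0.995
    moving_average_frames: int = 2
    granule_blur_sigma_px: float = 2.0  # applied for TALM/DM-style data
    granule_min_area_px: int = 4
    granule_dilate_px: int = 0
    # jump-distance fitting
    first_n_jumps: int = 5
    use_all_jumps: bool = False
    n_components: int = 3
    bin_nm: float = 1.0
    min_jumps: int = 30
    ci_factor: float = 5.0
    # maps
    upscale_factor: int = 3
    map_window: int = 3
    patch_d_threshold: float = 2.0  # µm²/s
    patch_min_pixels: int = 50
    patch_closing_radius_px: int = 3
    cluster_area_quantile: float = 0.25
    cluster_min_cells: int = 80
    # kinetics
    min_jump_um: float = 0.13
    anisotropy_half_window_deg: float = 30.0
    n_resamples: int = 50
    resample_fraction: float = 0.5
    # misc
    seed: int = 0
    movie_id: str = "movie"
    display_d_max: float = 6.0  # µm²/s color clamp for rendered maps

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dog_sigmas"] = list(d["dog_sigmas"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "dog_sigmas" in d:
            d["dog_sigmas"] = tuple(d["dog_sigmas"])
        return cls(**d)


@dataclass
class ResultsBundle:
    """All tables and maps produced by one pipeline run."""

    config: PipelineConfig
    track_table: pd.DataFrame
    tracks: list
    region_set: regions_mod.RegionSet
    assignment: regions_mod.RegionAssignment
    fits: list
    qc_log: pd.DataFrame
    fit_table: pd.DataFrame
    aggregate_table: pd.DataFrame
    region_area_table: pd.DataFrame
    talm: maps.RasterMap
    dmap: maps.RasterMap
    patches: list
    patch_summary: dict
    clusters: list
    cluster_table: pd.DataFrame
    anisotropy: dict
    shuttling_events: list
    shuttling_summary: dict


def detect_and_link(stack: np.ndarray, cfg: PipelineConfig) -> list[tracking.Track]:
    """Detection, sub-pixel localization and linking over a whole stack."""
    per_frame: dict[int, list[tracking.Localization]] = {}
    for t in range(stack.shape[0]):
        cands = tracking.detect_spots(stack[t], cfg.threshold_factor, cfg.dog_sigmas)
        locs = tracking.localize_subpixel(
            stack[t], cands, pixel_size=cfg.pixel_size, frame=t,
            window=cfg.fit_window, psf_sigma_px=cfg.psf_sigma_px,
        )
        if locs:
            per_frame[t] = locs
    return tracking.link_tracks(
        per_frame,
        radius_px=cfg.radius_px,
        max_gap=cfg.max_gap,
        min_track_length=cfg.min_track_length,
        min_len_before_gap=cfg.min_len_before_gap,
        pixel_size=cfg.pixel_size,
    )


def build_regions(
    control_stack: np.ndarray,
    control_frames: np.ndarray,
    cfg: PipelineConfig,
    cell_polygon: np.ndarray | None = None,
    nucleus_polygon: np.ndarray | None = None,
) -> regions_mod.RegionSet:
    """Granule segmentation plus static outlines (supplied or auto-estimated)."""
    if cell_polygon is None or nucleus_polygon is None:
        cell_polygon, nucleus_polygon = regions_mod.estimate_outlines(
            control_stack, cfg.pixel_size
        )
    import shapely

    ny, nx = control_stack.shape[1:]
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.column_stack(
        [((xx + 0.5) * cfg.pixel_size).ravel(), ((yy + 0.5) * cfg.pixel_size).ravel()]
    )
    cell_mask = shapely.intersects(shapely.Polygon(cell_polygon), shapely.points(pts)).reshape(ny, nx)
    masks = regions_mod.segment_granules(
        control_stack,
        moving_average_frames=cfg.moving_average_frames,
        gaussian_sigma_px=cfg.granule_blur_sigma_px,
        threshold_mode=cfg.granule_threshold_mode,
        threshold_value=cfg.granule_threshold_value,
        min_area_px=cfg.granule_min_area_px,
        dilate_px=cfg.granule_dilate_px,
        cell_mask=cell_mask,
    )
    return regions_mod.RegionSet(
        cell_polygon=cell_polygon,
        nucleus_polygon=nucleus_polygon,
        granule_masks=masks,
        control_frames=control_frames,
        pixel_size=cfg.pixel_size,
    )


def fit_table(fits: list) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {
            "movie_id": f.movie_id,
            "region": f.region,
            "n_jumps": f.n_jumps,
            "n_components": f.n_components,
            "D_eff": f.D_eff,
            "sse": f.sse,
            "adj_r2": f.adjusted_r2,
            "ci_error": f.ci_error,
            "valid": f.valid,
        }
        for c in range(f.n_components):
            row[f"D{c + 1}"] = f.D[c]
            row[f"F{c + 1}"] = f.F[c]
            row[f"ci95_D{c + 1}"] = f.ci95_halfwidth_D[c]
            row[f"ci95_F{c + 1}"] = f.ci95_halfwidth_F[c]
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    tracking_stack: np.ndarray | None = None,
    control_stack: np.ndarray | None = None,
    control_frames: np.ndarray | None = None,
    track_table: pd.DataFrame | None = None,
    cell_polygon: np.ndarray | None = None,
    nucleus_polygon: np.ndarray | None = None,
    frame_size: tuple[int, int] | None = None,
    out_dir=None,
) -> ResultsBundle:
    """Run the full analysis on one movie.

    Inputs may be in-memory arrays or a pre-computed ``track_table``
    (skipping detection and linking).  ``control_stack`` and
    ``control_frames`` are required for region-resolved results; without
    them all tracks are treated as one 'cytoplasm' pool over an empty
    granule set.  When ``out_dir`` is given, all tables and maps are
    written beneath it.
    """
    cfg = config
    # --- detection + linking (skippable) ---
    if track_table is not None:
        tracks = io.tracks_from_table(track_table)
        if frame_size is None and tracking_stack is None and control_stack is None:
            ext = float(max(track_table.x_um.max(), track_table.y_um.max()))
            n = int(np.ceil(ext / cfg.pixel_size)) + 1
            frame_size = (n, n)
    else:
        if tracking_stack is None:
            raise ValueError("either a tracking stack or a track table is required")
        tracks = detect_and_link(tracking_stack, cfg)
    if tracking_stack is not None:
        frame_size = tracking_stack.shape[1:]
    elif control_stack is not None:
        frame_size = control_stack.shape[1:]
    logger.info("stage linking: %d tracks", len(tracks))
    ttable = tracking.track_table(tracks)

    # --- regions ---
    if control_stack is not None:
        if control_frames is None:
            n_frames = int(ttable.frame.max()) + 1 if len(ttable) else control_stack.shape[0]
            control_frames = np.arange(control_stack.shape[0]) * cfg.control_interval
        rset = build_regions(control_stack, control_frames, cfg, cell_polygon, nucleus_polygon)
    else:
        # fallback: whole field of view is 'cytoplasm', no granules, tiny nucleus stub
        ny, nx = frame_size
        ex, ey = nx * cfg.pixel_size, ny * cfg.pixel_size
        eps = min(ex, ey) * 1e-4
        cell = np.array([[0.0, 0.0], [ex, 0.0], [ex, ey], [0.0, ey]]) if cell_polygon is None else cell_polygon
        nuc = (
            np.array([[eps, eps], [2 * eps, eps], [2 * eps, 2 * eps], [eps, 2 * eps]])
            if nucleus_polygon is None
            else nucleus_polygon
        )
        rset = regions_mod.RegionSet(
            cell_polygon=cell,
            nucleus_polygon=nuc,
            granule_masks=np.zeros((1, ny, nx), dtype=bool),
            control_frames=np.array([0]),
            pixel_size=cfg.pixel_size,
        )
    assignment = regions_mod.assign_and_split(tracks, rset)
    area_table = regions_mod.region_areas(rset)

    # --- jump-distance fitting per region ---
    samples = diffusion.collect_jumps(
        assignment, first_n=cfg.first_n_jumps, use_all=cfg.use_all_jumps, movie_id=cfg.movie_id
    )
    fits = []
    for lab, sample in sorted(samples.items()):
        if sample.n_jumps < max(cfg.n_components * 4, 8):
            logger.info("region %s: too few jumps (%d) for a fit", lab, sample.n_jumps)
            continue
        cdf = diffusion.empirical_cdf(sample, bin_nm=cfg.bin_nm)
        f = diffusion.fit_mixture(
            cdf, n_components=cfg.n_components, frame_cycle=cfg.frame_cycle,
            n_jumps=sample.n_jumps, seed=cfg.seed + 12345, region=lab, movie_id=cfg.movie_id,
        )
        diffusion.effective_diffusion(f)
        fits.append(f)
    kept, qc_log = diffusion.qc_filter(fits, min_jumps=cfg.min_jumps, ci_factor=cfg.ci_factor)
    agg = diffusion.aggregate(kept) if kept else pd.DataFrame()
    ftable = fit_table(fits)

    # --- maps ---
    all_xy = ttable[["x_um", "y_um"]].to_numpy() if len(ttable) else np.empty((0, 2))
    talm = maps.render_talm(all_xy, frame_size, cfg.pixel_size, cfg.upscale_factor)
    try:
        dmap = maps.render_diffusion_map(
            tracks, frame_size, cfg.pixel_size, cfg.upscale_factor, cfg.map_window, cfg.frame_cycle
        )
        patches = maps.segment_patches(
            dmap, cfg.patch_d_threshold, cfg.patch_min_pixels, cfg.patch_closing_radius_px
        )
        patch_summary = maps.quantify_patches(patches, rset, dmap)
    except ValueError:
        dmap = maps.RasterMap("diffusion", np.full((1, 1), np.nan), cfg.pixel_size / cfg.upscale_factor)
        patches, patch_summary = [], {"coverage_percent": np.nan, "n_patches": 0, "mean_patch_area_um2": np.nan}
    mean_len = float(ttable.groupby("track_id").size().mean()) if len(ttable) else np.nan
    try:
        clusters = maps.voronoi_clusters(all_xy, cfg.cluster_area_quantile, cfg.cluster_min_cells)
        cluster_table = maps.quantify_clusters(clusters, rset, mean_track_length=mean_len)
    except ValueError:
        clusters, cluster_table = [], pd.DataFrame()

    # --- kinetics ---
    anis: dict[str, kinetics.AnisotropyResult] = {}
    events: list = []
    shut: dict = {}
    try:
        seg = kinetics.segment_states(tracks)
        angles = kinetics.compute_angles(tracks, cfg.min_jump_um, regions=rset)
        for lab, g in angles.groupby("region"):
            if len(g):
                anis[str(lab)] = kinetics.fold_anisotropy(
                    g.angle_deg.to_numpy(),
                    cfg.anisotropy_half_window_deg,
                    cfg.n_resamples,
                    cfg.resample_fraction,
                    seed=cfg.seed + 77,
                    region=str(lab),
                )
        events = kinetics.classify_shuttling(seg, rset)
        shut = kinetics.shuttling_stats(events, rset)
    except ValueError as exc:
        logger.info("kinetics stage skipped: %s", exc)

    bundle = ResultsBundle(
        config=cfg,
        track_table=ttable,
        tracks=tracks,
        region_set=rset,
        assignment=assignment,
        fits=fits,
        qc_log=qc_log,
        fit_table=ftable,
        aggregate_table=agg,
        region_area_table=area_table,
        talm=talm,
        dmap=dmap,
        patches=patches,
        patch_summary=patch_summary,
        clusters=clusters,
        cluster_table=cluster_table,
        anisotropy=anis,
        shuttling_events=events,
        shuttling_summary=shut,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: ResultsBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    io.write_track_csv(out / "tracks.csv", bundle.track_table)
    bundle.fit_table.to_csv(out / "fits.csv", index=False)
    bundle.qc_log.to_csv(out / "qc_log.csv", index=False)
    if len(bundle.aggregate_table):
        bundle.aggregate_table.to_csv(out / "aggregate.csv", index=False)
    bundle.region_area_table.to_csv(out / "region_areas.csv", index=False)
    io.write_masks(out / "granule_masks.tif", bundle.region_set.granule_masks)
    io.write_stack(out / "talm.tif", bundle.talm.grid.astype(np.float32))
    io.write_stack(out / "diffusion_map.tif", bundle.dmap.grid.astype(np.float32))
    if len(bundle.cluster_table):
        bundle.cluster_table.to_csv(out / "clusters.csv", index=False)
    pd.DataFrame([bundle.patch_summary]).to_csv(out / "patches.csv", index=False)
    io.write_polygons(
        out / "outlines.json",
        {"cell": bundle.region_set.cell_polygon, "nucleus": bundle.region_set.nucleus_polygon},
    )
    io.write_config_yaml(out / "config.yaml", bundle.config.to_dict())
    (out / "report.txt").write_text(report(bundle))


def report(bundle: ResultsBundle) -> str:
    """Human-readable run summary; numbers identical to the underlying tables."""
    lines = ["# Region-resolved single-molecule tracking summary", ""]
    lines.append(f"movie: {bundle.config.movie_id}")
    lines.append(f"tracks: {bundle.track_table.track_id.nunique() if len(bundle.track_table) else 0}")
    lines.append(f"localizations: {len(bundle.track_table)}")
    lines.append("")
    lines.append("## Effective diffusion per region (µm²/s)")
    if len(bundle.fit_table):
        for _, r in bundle.fit_table.iterrows():
            lines.append(
                f"  {r.region:<10} D_eff={r.D_eff:7.3f}  n_jumps={int(r.n_jumps):6d}  adjR2={r.adj_r2:.4f}"
            )
    else:
        lines.append("  (no fits)")
    lines.append("")
    lines.append("## Cytoplasmic patches")
    ps = bundle.patch_summary
    lines.append(
        f"  n={ps.get('n_patches', 0)}  coverage={ps.get('coverage_percent', float('nan')):.2f}% "
        f" mean_area={ps.get('mean_patch_area_um2', float('nan')):.3f} µm²"
    )
    lines.append("")
    lines.append("## Localization clusters")
    if len(bundle.cluster_table):
        for _, r in bundle.cluster_table.iterrows():
            if r.n_clusters:
                lines.append(
                    f"  {r.region:<10} n={int(r.n_clusters)}  density={r.density_per_um2:.3f}/µm²  "
                    f"diameter={r.equivalent_diameter_nm:.0f} nm"
                )
    lines.append("")
    lines.append("## Anisotropy (f_180/0)")
    for lab, a in bundle.anisotropy.items():
        lines.append(
            f"  {lab:<10} f={a.f_180_0:.3f}  resample {a.resample_mean:.3f} ± {a.resample_std:.3f}  (n={a.n_angles})"
        )
    lines.append("")
    lines.append("## Shuttling")
    s = bundle.shuttling_summary
    if s:
        lines.append(
            f"  enter={s['n_enter']}  leave={s['n_leave']}  per µm² granule={s['events_per_um2']:.3f}  "
            f"entering fraction={s['fraction_entering'] if s['n_total'] else float('nan'):.3f}"
            if s["n_total"]
            else "  no events"
        )
    return "\n".join(lines) + "\n"


def render_figures(bundle: ResultsBundle, out_dir) -> list[str]:
    """Write TALM and diffusion-map figures (diffusion clamped at the display max)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(np.log1p(bundle.talm.grid), cmap="gray", origin="upper")
    ax.set_title("TALM (log counts)")
    ax.axis("off")
    p = out / "talm.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(str(p))
    fig, ax = plt.subplots(figsize=(5, 5))
    d = np.clip(bundle.dmap.grid, 0, bundle.config.display_d_max)
    im = ax.imshow(d, cmap="RdYlBu", vmin=0, vmax=bundle.config.display_d_max, origin="upper")
    fig.colorbar(im, ax=ax, label="D (µm²/s), clamped")
    ax.set_title("Diffusion map")
    ax.axis("off")
    p = out / "diffusion_map.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(str(p))
    return written
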