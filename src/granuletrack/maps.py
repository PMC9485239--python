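"""TALM images, pixel-wise diffusion maps, patch and cluster quantification.

TALM (tracking and localization microscopy) images bin the sub-pixel
detections of all tracked molecules onto an up-scaled grid (43 × 43 nm²,
three times finer than the camera pixels), so bright bins mark repeated
localization at one site.  Diffusion maps bin the squared consecutive-
frame jump distances onto the same grid, average over a 3 × 3 bin window
and convert to a local coefficient D = X / (4 Δt).  Patches of slow
diffusivity are segmented from the map by thresholding, size filtering,
morphological closing and enclosed-pixel filling; localization clusters
(binding hotspots) are found as connected groups of small Voronoi cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import Voronoi
from skimage import morphology

from granuletrack.regions import RegionSet
from granuletrack.tracking import Track

__all__ = [
    "RasterMap",
    "Patch",
    "LocalizationCluster",
    "render_talm",
    "render_diffusion_map",
    "segment_patches",
    "quantify_patches",
    "voronoi_clusters",
    "quantify_clusters",
]

DEFAULT_BIN_UM = 0.130 / 3  # 43 nm analysis grid


@dataclass
class RasterMap:
    """A TALM count grid or diffusion-coefficient grid on the up-scaled lattice.

    ``grid`` uses NaN as the no-data marker for diffusion maps.  Bin
    (i, j) covers [j·b, (j+1)·b) × [i·b, (i+1)·b) µm from the image-frame
    origin.
    """

    kind: str  # 'talm' | 'diffusion'
    grid: np.ndarray
    bin_size: float  # µm
    upscale_factor: int = 3
    origin: tuple[float, float] = (0.0, 0.0)


@dataclass
class Patch:
    """Connected slow-diffusivity area of a diffusion map."""

    pixels: np.ndarray  # (n, 2) row, col on the map grid
    area_um2: float
    mean_D: float
    centroid_um: tuple[float, float]


@dataclass
class LocalizationCluster:
    """Connected group of small Voronoi cells marking a binding hotspot."""

    point_indices: np.ndarray
    n_detections: int
    area_um2: float
    centroid_um: tuple[float, float]
    region: str = ""

    @property
    def equivalent_diameter_nm(self) -> float:
        return 2.0 * np.sqrt(self.area_um2 / np.pi) * 1e3


def _grid_shape(frame_size: tuple[int, int], pixel_size: float, bin_size: float) -> tuple[int, int]:
    ny, nx = frame_size
    return (int(np.ceil(ny * pixel_size / bin_size)), int(np.ceil(nx * pixel_size / bin_size)))


def render_talm(
    xy_um: np.ndarray,
    frame_size: tuple[int, int],
    pixel_size: float = 0.130,
    upscale_factor: int = 3,
) -> RasterMap:
    """Bin tracked detections onto the up-scaled grid; Σ grid = n detections.

    Detections are assigned to the bin containing their half-open square,
    so a position exactly on a bin boundary belongs to the bin to its
    lower-right in index terms.
    """
    bin_size = pixel_size / upscale_factor
    shape = _grid_shape(frame_size, pixel_size, bin_size)
    grid = np.zeros(shape, dtype=np.int64)
    xy = np.atleast_2d(xy_um)
    if len(xy):
        jj = np.floor(xy[:, 0] / bin_size).astype(int)
        ii = np.floor(xy[:, 1] / bin_size).astype(int)
        ok = (ii >= 0) & (ii < shape[0]) & (jj >= 0) & (jj < shape[1])
        np.add.at(grid, (ii[ok], jj[ok]), 1)
    return RasterMap(kind="talm", grid=grid, bin_size=bin_size, upscale_factor=upscale_factor)


def _jump_entries(tracks: list[Track]) -> tuple[np.ndarray, np.ndarray]:
    """Start positions and squared lengths of all consecutive-frame jumps."""
    starts, sq = [], []
    for tr in tracks:
        if len(tr) < 2:
            continue
        keep = ~tr.gap_after
        d = np.diff(tr.xy, axis=0)
        sq.append((d[keep] ** 2).sum(axis=1))
        starts.append(tr.xy[:-1][keep])
    if not starts:
        return np.empty((0, 2)), np.empty(0)
    return np.concatenate(starts), np.concatenate(sq)


def render_diffusion_map(
    tracks: list[Track],
    frame_size: tuple[int, int],
    pixel_size: float = 0.130,
    upscale_factor: int = 3,
    window: int = 3,
    frame_cycle: float = 0.006742,
) -> RasterMap:
    """Pixel-wise diffusion map D = X / (4 Δt) from binned squared jumps.

    Squared consecutive-frame jump distances are binned at the jump's
    start position; X at a pixel is the mean of all entries in the
    ``window`` × ``window`` neighbourhood; pixels whose window holds no
    entry are NaN (no data).
    """
    bin_size = pixel_size / upscale_factor
    shape = _grid_shape(frame_size, pixel_size, bin_size)
    ssum = np.zeros(shape)
    cnt = np.zeros(shape)
    starts, sq = _jump_entries(tracks)
    if len(sq) == 0:
        raise ValueError("tracks contain no consecutive-frame jumps")
    jj = np.floor(starts[:, 0] / bin_size).astype(int)
    ii = np.floor(starts[:, 1] / bin_size).astype(int)
    ok = (ii >= 0) & (ii < shape[0]) & (jj >= 0) & (jj < shape[1])
    np.add.at(ssum, (ii[ok], jj[ok]), sq[ok])
    np.add.at(cnt, (ii[ok], jj[ok]), 1)
    ker = np.ones((window, window))
    wsum = ndimage.convolve(ssum, ker, mode="constant")
    wcnt = ndimage.convolve(cnt, ker, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(wcnt > 0, wsum / wcnt, np.nan)
    D = X / (4.0 * frame_cycle)
    return RasterMap(kind="diffusion", grid=D, bin_size=bin_size, upscale_factor=upscale_factor)


def segment_patches(
    dmap: RasterMap,
    d_threshold: float = 2.0,
    min_pixels: int = 50,
    closing_radius_px: int = 3,
) -> list[Patch]:
    """Segment slow-diffusivity patches from a diffusion map.

    Steps in order: threshold (D < ``d_threshold`` on data pixels),
    8-connected component size filter (≥ ``min_pixels``), morphological
    closing with a disk of radius ``closing_radius_px``, and assignment of
    enclosed faster pixels to the patch (hole filling).
    """
    if dmap.kind != "diffusion":
        raise ValueError("patch segmentation requires a diffusion map")
    D = dmap.grid
    slow = np.isfinite(D) & (D < d_threshold)
    lab, n = ndimage.label(slow, structure=np.ones((3, 3)))
    sizes = np.bincount(lab.ravel())
    keep = np.zeros_like(slow)
    for k in range(1, n + 1):
        if sizes[k] >= min_pixels:
            keep |= lab == k
    closed = morphology.closing(keep, morphology.disk(closing_radius_px))
    filled = ndimage.binary_fill_holes(closed)
    lab2, n2 = ndimage.label(filled, structure=np.ones((3, 3)))
    patches = []
    b = dmap.bin_size
    for k in range(1, n2 + 1):
        px = np.argwhere(lab2 == k)
        vals = D[px[:, 0], px[:, 1]]
        patches.append(
            Patch(
                pixels=px,
                area_um2=len(px) * b * b,
                mean_D=float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan,
                centroid_um=((px[:, 1].mean() + 0.5) * b, (px[:, 0].mean() + 0.5) * b),
            )
        )
    return patches


def patch_mask(patches: list[Patch], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for p in patches:
        mask[p.pixels[:, 0], p.pixels[:, 1]] = True
    return mask


def quantify_patches(
    patches: list[Patch],
    regions: RegionSet,
    dmap: RasterMap,
) -> dict:
    """Patch coverage of the granule-free cytoplasm and mean patch size.

    Coverage (%) = Σ (patch ∩ cytoplasm area) / (cytoplasm − granules)
    × 100, using the time-averaged granule mask; patch pixels inside
    granules or the nucleus are excluded from the numerator.
    """
    area_df = _region_area_table(regions)
    cyto_excl = float(area_df["cytoplasm_excl_granule_um2"].mean())
    if cyto_excl <= 0:
        raise ValueError("cytoplasm area excluding granules is zero")
    b = dmap.bin_size
    shape = dmap.grid.shape
    cell = shapely.Polygon(regions.cell_polygon)
    nucleus = shapely.Polygon(regions.nucleus_polygon)
    # granule occupancy on the map grid: any-control-frame union (conservative)
    gr_any = regions.granule_masks.any(axis=0)
    covered = 0.0
    for p in patches:
        xy = np.column_stack(
            [(p.pixels[:, 1] + 0.5) * b, (p.pixels[:, 0] + 0.5) * b]
        )
        in_cell = shapely.intersects(cell, shapely.points(xy))
        in_nuc = shapely.intersects(nucleus, shapely.points(xy))
        jj = np.floor(xy[:, 0] / regions.pixel_size).astype(int)
        ii = np.floor(xy[:, 1] / regions.pixel_size).astype(int)
        ny, nx = gr_any.shape
        ok = (ii >= 0) & (ii < ny) & (jj >= 0) & (jj < nx)
        in_gr = np.zeros(len(xy), dtype=bool)
        in_gr[ok] = gr_any[ii[ok], jj[ok]]
        covered += float(np.sum(in_cell & ~in_nuc & ~in_gr)) * b * b
    mean_size = float(np.mean([p.area_um2 for p in patches])) if patches else 0.0
    return {
        "coverage_percent": 100.0 * covered / cyto_excl,
        "mean_patch_area_um2": mean_size,
        "n_patches": len(patches),
        "cytoplasm_excl_granule_um2": cyto_excl,
    }


def _region_area_table(regions: RegionSet):
    from granuletrack.regions import region_areas

    return region_areas(regions)


def _voronoi_cells(points: np.ndarray) -> tuple[np.ndarray, list[list[int]], Voronoi]:
    """Finite Voronoi cell areas (NaN for unbounded cells) and adjacency."""
    vor = Voronoi(points)
    n = len(points)
    areas = np.full(n, np.nan)
    for i in range(n):
        reg = vor.regions[vor.point_region[i]]
        if not reg or -1 in reg:
            continue
        poly = vor.vertices[reg]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    adjacency: list[list[int]] = [[] for _ in range(n)]
    for (a, b) in vor.ridge_points:
        adjacency[a].append(int(b))
        adjacency[b].append(int(a))
    return areas, adjacency, vor


def voronoi_clusters(
    xy_um: np.ndarray,
    area_quantile: float = 0.25,
    min_cells: int = 80,
) -> list[LocalizationCluster]:
    """Detect localization clusters as connected groups of small Voronoi cells.

    The detections are Voronoi-tessellated; only cells with an area in the
    lower ``area_quantile`` fraction are kept (unbounded hull cells are
    excluded before the quantile is taken); kept cells sharing a Voronoi
    edge are grouped, and groups of at least ``min_cells`` cells become
    clusters.  Cluster area is the summed member-cell area.
    """
    xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
    if len(xy) < 4:
        raise ValueError("at least 4 localizations required for a Voronoi tessellation")
    try:
        areas, adjacency, _ = _voronoi_cells(xy)
    except Exception as exc:  # qhull failures on degenerate input
        raise ValueError(f"Voronoi tessellation failed (degenerate geometry): {exc}") from exc
    finite = np.isfinite(areas)
    if not finite.any():
        return []
    cut = np.quantile(areas[finite], area_quantile)
    kept = finite & (areas <= cut)
    # connected components over kept cells (iterative DFS)
    comp = np.full(len(xy), -1)
    cid = 0
    for s in np.flatnonzero(kept):
        if comp[s] >= 0:
            continue
        stack = [s]
        comp[s] = cid
        while stack:
            u = stack.pop()
            for v in adjacency[u]:
                if kept[v] and comp[v] < 0:
                    comp[v] = cid
                    stack.append(v)
        cid += 1
    clusters = []
    for k in range(cid):
        members = np.flatnonzero(comp == k)
        if len(members) < min_cells:
            continue
        clusters.append(
            LocalizationCluster(
                point_indices=members,
                n_detections=len(members),
                area_um2=float(np.sum(areas[members])),
                centroid_um=(float(xy[members, 0].mean()), float(xy[members, 1].mean())),
            )
        )
    return clusters


def quantify_clusters(
    clusters: list[LocalizationCluster],
    regions: RegionSet,
    mean_track_length: float | None = None,
) -> pd.DataFrame:
    """Per-region cluster statistics: density, detections, size, diameter.

    A cluster belongs to the region containing its centroid
    ('granule' or 'cytoplasm').  Density is clusters per µm² of the
    region's (time-averaged) area; the equivalent circle diameter is
    2·√(mean area / π).  When ``mean_track_length`` is given, the mean
    number of binding events per cluster (detections / track length) is
    reported as well.
    """
    area_df = _region_area_table(regions)
    region_area = {
        "granule": float(area_df["granule_um2"].mean()),
        "cytoplasm": float(area_df["cytoplasm_excl_granule_um2"].mean()),
        "nucleus": float(area_df["nucleus_um2"].mean()),
    }
    for cl in clusters:
        labs = regions.label_points(
            np.array([cl.centroid_um]), np.array([int(regions.control_frames[0])])
        )
        cl.region = str(labs[0])
    rows = []
    for reg in ("granule", "cytoplasm", "nucleus"):
        cls = [c for c in clusters if c.region == reg]
        area = region_area[reg]
        mean_area = float(np.mean([c.area_um2 for c in cls])) if cls else np.nan
        row = {
            "region": reg,
            "n_clusters": len(cls),
            "density_per_um2": (len(cls) / area) if area > 0 else np.nan,
            "detections_per_cluster": float(np.mean([c.n_detections for c in cls])) if cls else np.nan,
            "mean_cluster_area_um2": mean_area,
            "equivalent_diameter_nm": 2.0 * np.sqrt(mean_area / np.pi) * 1e3 if cls else np.nan,
        }
        if mean_track_length and cls:
            row["binding_events_per_cluster"] = row["detections_per_cluster"] / mean_track_length
        rows.append(row)
    return pd.DataFrame(rows)
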