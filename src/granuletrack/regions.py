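"""Region masks (cell, nucleus, stress granules) and region-wise track splitting.

Stress granules are segmented from the intensity of the control channel:
each control frame is averaged with its predecessor (a two-frame moving
average against blinking/fluctuations), optionally Gaussian-blurred, then
thresholded.  Cell and nucleus are static polygons, supplied by the user
or estimated automatically from the time-averaged control channel (Otsu).
Each localization is labeled using the granule mask of the
nearest-in-time control frame; tracks crossing a region border are split
at the border, and the crossing link belongs to neither single-region
sub-track's jump pool.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from skimage import filters, measure, morphology

from granuletrack.tracking import Track

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSet",
    "RegionAssignment",
    "segment_granules",
    "assign_and_split",
    "region_areas",
    "estimate_outlines",
]

LABELS = ("nucleus", "cytoplasm", "granule", "outside")


@dataclass
class RegionSet:
    """Static cell/nucleus polygons plus per-control-frame granule masks."""

    cell_polygon: np.ndarray  # (n, 2) µm, closed (first vertex not repeated)
    nucleus_polygon: np.ndarray
    granule_masks: np.ndarray  # (n_control, ny, nx) bool
    control_frames: np.ndarray  # (n_control,) 0-based frame indices
    pixel_size: float

    _cell: shapely.Polygon = field(init=False, repr=False)
    _nucleus: shapely.Polygon = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.control_frames = np.asarray(self.control_frames, dtype=int)
        if not np.all(np.diff(self.control_frames) > 0):
            raise ValueError("control_frames must be strictly increasing")
        self.granule_masks = np.asarray(self.granule_masks, dtype=bool)
        if self.granule_masks.shape[0] != len(self.control_frames):
            raise ValueError("one granule mask per control frame required")
        self._cell = shapely.Polygon(self.cell_polygon)
        self._nucleus = shapely.Polygon(self.nucleus_polygon)
        if not self._nucleus.within(self._cell):
            raise ValueError("nucleus polygon must lie inside the cell polygon")

    def nearest_control_index(self, frame: int | np.ndarray) -> np.ndarray:
        """Index of the nearest-in-time control frame (ties -> earlier)."""
        cf = self.control_frames
        frame = np.atleast_1d(frame)
        pos = np.searchsorted(cf, frame)
        pos = np.clip(pos, 0, len(cf) - 1)
        prev = np.clip(pos - 1, 0, len(cf) - 1)
        d_next = np.abs(cf[pos] - frame)
        d_prev = np.abs(frame - cf[prev])
        return np.where(d_prev <= d_next, prev, pos)

    def label_points(self, xy: np.ndarray, frames: np.ndarray) -> np.ndarray:
        """Region label per point: granule > nucleus > cytoplasm > outside.

        Points exactly on a polygon boundary belong to the inner region
        (polygons are closed sets).
        """
        xy = np.atleast_2d(xy)
        frames = np.atleast_1d(frames)
        labels = np.full(len(xy), "outside", dtype=object)
        in_cell = shapely.intersects(self._cell, shapely.points(xy))
        labels[in_cell] = "cytoplasm"
        in_nuc = shapely.intersects(self._nucleus, shapely.points(xy))
        labels[in_nuc] = "nucleus"
        ny, nx = self.granule_masks.shape[1:]
        ci = self.nearest_control_index(frames)
        jj = np.floor(xy[:, 0] / self.pixel_size).astype(int)
        ii = np.floor(xy[:, 1] / self.pixel_size).astype(int)
        ok = (ii >= 0) & (ii < ny) & (jj >= 0) & (jj < nx)
        gr = np.zeros(len(xy), dtype=bool)
        gr[ok] = self.granule_masks[ci[ok], ii[ok], jj[ok]]
        labels[gr & in_cell] = "granule"
        n_out = int((labels == "outside").sum())
        if n_out:
            logger.info("%d localizations outside the cell polygon", n_out)
        return labels


@dataclass
class RegionAssignment:
    """Per-localization region labels and maximal single-region sub-tracks."""

    tracks: list[Track]  # parent tracks with region_labels filled
    subtracks: list[Track]  # each with .region_label set
    n_crossing_links: int


def segment_granules(
    control_stack: np.ndarray,
    control_frames: np.ndarray | None = None,
    moving_average_frames: int = 2,
    gaussian_sigma_px: float = 0.0,
    threshold_mode: str = "quantile",
    threshold_value: float = 0.995,
    min_area_px: int = 4,
    dilate_px: int = 0,
    cell_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Intensity-threshold granule masks from the control channel.

    Each control frame is averaged with its predecessor (the first frame
    is used as is), optionally blurred with a Gaussian, then thresholded
    either at an absolute intensity or at a quantile of the smoothed frame
    (restricted to ``cell_mask`` when given).  Connected components
    smaller than ``min_area_px`` are removed; ``dilate_px`` > 0 slightly
    overestimates outlines to keep granule-edge signal out of the
    cytoplasm pool.
    """
    stack = np.asarray(control_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] < 1:
        raise ValueError("at least one control frame required")
    n = stack.shape[0]
    masks = np.zeros(stack.shape, dtype=bool)
    for k in range(n):
        lo = max(0, k - (moving_average_frames - 1))
        img = stack[lo : k + 1].mean(axis=0)
        if gaussian_sigma_px > 0:
            img = ndimage.gaussian_filter(img, gaussian_sigma_px)
        if threshold_mode == "quantile":
            ref = img[cell_mask] if cell_mask is not None else img
            thr = np.quantile(ref, threshold_value)
        elif threshold_mode == "absolute":
            thr = threshold_value
        else:
            raise ValueError(f"unknown threshold mode {threshold_mode!r}")
        if thr >= img.max():
            warnings.warn(f"granule threshold above control frame {k} maximum: empty mask", stacklevel=2)
            continue
        m = img > thr
        if cell_mask is not None:
            m &= cell_mask
        lab, nlab = ndimage.label(m)
        if nlab:
            sizes = np.bincount(lab.ravel())
            good = np.flatnonzero(sizes >= min_area_px)
            m = np.isin(lab, good[good != 0])
        if dilate_px > 0:
            m = morphology.binary_dilation(m, morphology.disk(dilate_px))
        masks[k] = m
    return masks


def estimate_outlines(
    control_stack: np.ndarray, pixel_size: float, smooth_sigma_px: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Automatic cell/nucleus polygon fallback from the time-averaged control channel.

    Not part of the reference procedure (outlines there are drawn by
    hand): Otsu on the smoothed average yields the cell; a second Otsu
    inside the cell separates the dimmer nuclear interior.  Returns
    (cell_polygon, nucleus_polygon) in µm.
    """
    avg = ndimage.gaussian_filter(np.asarray(control_stack, dtype=float).mean(axis=0), smooth_sigma_px)
    cell_mask = avg > filters.threshold_otsu(avg)
    cell_mask = ndimage.binary_fill_holes(morphology.remove_small_objects(cell_mask, 64))
    inside = avg[cell_mask]
    nuc_mask = cell_mask & (avg < filters.threshold_otsu(inside))
    nuc_mask = ndimage.binary_fill_holes(morphology.remove_small_objects(nuc_mask, 64))

    def biggest_contour(mask: np.ndarray) -> np.ndarray:
        cs = measure.find_contours(mask.astype(float), 0.5)
        if not cs:
            raise ValueError("no contour found for outline estimation")
        c = max(cs, key=len)
        # contours are (row, col); convert to (x, y) µm at pixel centers
        return np.column_stack([(c[:, 1] + 0.5) * pixel_size, (c[:, 0] + 0.5) * pixel_size])

    return biggest_contour(cell_mask), biggest_contour(nuc_mask)


def assign_and_split(tracks: list[Track], regions: RegionSet) -> RegionAssignment:
    """Label localizations by region and split tracks at region borders.

    Each localization gets the label of the granule mask at the
    nearest-in-time control frame, else nucleus, else cytoplasm, else
    outside.  A parent track is cut wherever consecutive localizations
    carry different labels; the crossing link is assigned to neither
    single-region sub-track.  Sub-tracks keep their per-link gap flags.
    """
    subtracks: list[Track] = []
    n_cross = 0
    next_id = 0
    for tr in tracks:
        labels = regions.label_points(tr.xy, tr.frames)
        tr.region_labels = labels
        # maximal runs of constant label
        start = 0
        for k in range(1, len(tr) + 1):
            if k == len(tr) or labels[k] != labels[start]:
                sub = Track(
                    track_id=next_id,
                    frames=tr.frames[start:k],
                    xy=tr.xy[start:k],
                    intensity=None if tr.intensity is None else tr.intensity[start:k],
                    gap_after=tr.gap_after[start : k - 1],
                    region_label=str(labels[start]),
                )
                sub.parent_id = tr.track_id  # type: ignore[attr-defined]
                subtracks.append(sub)
                next_id += 1
                if k < len(tr):
                    n_cross += 1
                start = k
    return RegionAssignment(tracks=tracks, subtracks=subtracks, n_crossing_links=n_cross)


def region_areas(regions: RegionSet) -> "pd.DataFrame":
    """Per-control-frame areas (µm²) of granules, cytoplasm excluding granules, nucleus.

    Granule areas are pixel counts × pixel_size²; cell and nucleus areas
    come from the exact polygon (shoelace) formula.  Granule pixels inside
    the nucleus polygon are not subtracted (granules live in the
    cytoplasm by construction).
    """
    import pandas as pd

    p = regions.pixel_size
    cell_area = shapely.Polygon(regions.cell_polygon).area
    nuc_area = shapely.Polygon(regions.nucleus_polygon).area
    rows = []
    for k, f in enumerate(regions.control_frames):
        gr = float(regions.granule_masks[k].sum()) * p * p
        rows.append((int(f), gr, cell_area - nuc_area - gr, nuc_area))
    return pd.DataFrame(rows, columns=["control_frame", "granule_um2", "cytoplasm_excl_granule_um2", "nucleus_um2"])
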