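"""Bound/free segmentation, angular anisotropy and granule shuttling.

Track links are classified into a bound (small displacements) and a free
(large displacements) state with a 2-state hidden Markov model whose
emissions are Rayleigh distributed jump magnitudes — the magnitude of an
isotropic Gaussian step.  The model is trained by expectation-
maximization over all tracks of a movie and decoded with the
most-probable (Viterbi) path; the bound state is, by convention, the one
with the smaller emission scale.

Angular anisotropy quantifies deviations from Brownian motion: for
consecutive free jumps longer than a minimum distance, the turning angle
between the two displacement vectors is computed, and the
fold-anisotropy f_180/0 is the count ratio of backward (180° ± 30°) to
forward (0° ± 30°) angles — 1 for pure Brownian motion, above 1 for
confined or trapped molecules.  Shuttling events are free tracks whose
first and last localization lie on opposite sides of a stress-granule
boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from granuletrack.regions import RegionSet
from granuletrack.tracking import Track

logger = logging.getLogger(__name__)

__all__ = [
    "StateSegmentation",
    "AnisotropyResult",
    "ShuttlingEvent",
    "segment_states",
    "compute_angles",
    "turning_angles",
    "fold_anisotropy",
    "classify_shuttling",
    "shuttling_stats",
]


@dataclass
class StateSegmentation:
    """Per-link bound/free labels plus the fitted 2-state HMM parameters."""

    tracks: list[Track]  # state_labels filled per link
    sigma: np.ndarray  # Rayleigh emission scales, ascending (bound first)
    transition: np.ndarray  # 2x2 row-stochastic
    initial: np.ndarray
    log_likelihood: float
    converged: bool = True


@dataclass
class AnisotropyResult:
    """Fold-anisotropy with half-data resampling error."""

    f_180_0: float
    n_angles: int
    resample_mean: float
    resample_std: float
    region: str = ""
    histogram: tuple[np.ndarray, np.ndarray] | None = None  # (bin edges deg, counts)


@dataclass
class ShuttlingEvent:
    track_id: int
    direction: str  # 'enter' | 'leave'
    granule_id: int
    frame_start: int
    frame_end: int


def _rayleigh_logpdf(r: np.ndarray, sigma: float) -> np.ndarray:
    r = np.maximum(r, 1e-12)
    return np.log(r) - 2 * np.log(sigma) - r**2 / (2 * sigma**2)


def _track_sequences(tracks: list[Track]) -> list[np.ndarray]:
    """Per-track jump-magnitude sequences, broken at gap links."""
    seqs = []
    for tr in tracks:
        if len(tr) < 2:
            continue
        mags = tr.jumps
        gaps = tr.gap_after
        start = 0
        for k in range(len(mags) + 1):
            if k == len(mags) or gaps[k]:
                if k > start:
                    seqs.append(mags[start:k])
                start = k + 1
    return seqs


def segment_states(
    tracks: list[Track],
    n_states: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> StateSegmentation:
    """Fit a 2-state Rayleigh-emission HMM to jump magnitudes and decode links.

    EM (Baum-Welch) runs over all tracks of a movie jointly, sequences
    broken at gap links; decoding is by the most-probable path.  On
    non-convergence the labels fall back to a threshold at the crossing
    point of the two emission densities (flagged via ``converged=False``).
    """
    if n_states != 2:
        raise ValueError("only the 2-state bound/free model is supported")
    seqs = [s for s in _track_sequences(tracks) if len(s) >= 1]
    if not seqs:
        raise ValueError("no tracks with >= 1 link")
    all_mags = np.concatenate(seqs)
    # moment init: split at the median
    med = np.median(all_mags)
    lo = all_mags[all_mags <= med]
    hi = all_mags[all_mags > med]
    sigma = np.array(
        [
            np.sqrt(np.mean(lo**2) / 2) if len(lo) else med / 2,
            np.sqrt(np.mean(hi**2) / 2) if len(hi) else med * 2,
        ]
    )
    sigma = np.maximum(sigma, 1e-6)
    A = np.array([[0.9, 0.1], [0.1, 0.9]])
    pi = np.array([0.5, 0.5])

    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        ll_total = 0.0
        gamma_sum = np.zeros(2)
        gamma_r2 = np.zeros(2)
        xi_sum = np.zeros((2, 2))
        pi_new = np.zeros(2)
        for s in seqs:
            logb = np.column_stack([_rayleigh_logpdf(s, sigma[0]), _rayleigh_logpdf(s, sigma[1])])
            b = np.exp(logb - logb.max(axis=1, keepdims=True))
            T = len(s)
            alpha = np.zeros((T, 2))
            c = np.zeros(T)
            alpha[0] = pi * b[0]
            c[0] = alpha[0].sum()
            alpha[0] /= c[0]
            for t in range(1, T):
                alpha[t] = (alpha[t - 1] @ A) * b[t]
                c[t] = alpha[t].sum()
                alpha[t] /= c[t]
            beta = np.zeros((T, 2))
            beta[-1] = 1.0
            for t in range(T - 2, -1, -1):
                beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            # b was shifted by its per-row max; restore it in the likelihood
            ll_total += float(np.sum(np.log(c))) + float(logb.max(axis=1).sum())
            for t in range(T - 1):
                xi = alpha[t][:, None] * A * (b[t + 1] * beta[t + 1])[None, :] / c[t + 1]
                xi_sum += xi
            pi_new += gamma[0]
            gamma_sum += gamma.sum(axis=0)
            gamma_r2 += (gamma * (s**2)[:, None]).sum(axis=0)
        sigma = np.sqrt(np.maximum(gamma_r2 / np.maximum(gamma_sum, 1e-12) / 2.0, 1e-12))
        rows = xi_sum.sum(axis=1, keepdims=True)
        A = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-12), A)
        A = A / A.sum(axis=1, keepdims=True)
        pi = pi_new / pi_new.sum()
        if abs(ll_total - prev_ll) < tol * max(1.0, abs(prev_ll)):
            converged = True
            prev_ll = ll_total
            break
        prev_ll = ll_total

    # canonical order: bound = smaller scale
    order = np.argsort(sigma)
    sigma = sigma[order]
    A = A[np.ix_(order, order)]
    pi = pi[order]

    if not converged:
        logger.warning("HMM EM did not converge; falling back to threshold classification")

    # degenerate fit: indistinguishable emission scales mean a single
    # effective state, and a single mobility state is 'free' by definition
    if sigma[1] - sigma[0] <= 1e-6 * sigma[1]:
        for tr in tracks:
            n_links = max(len(tr) - 1, 0)
            tr.state_labels = np.array(["free"] * n_links, dtype=object)
        return StateSegmentation(
            tracks=tracks, sigma=sigma, transition=A, initial=pi,
            log_likelihood=prev_ll, converged=converged,
        )

    # decode per track link (Viterbi on each gap-free segment)
    def viterbi(s: np.ndarray) -> np.ndarray:
        logb = np.column_stack([_rayleigh_logpdf(s, sigma[0]), _rayleigh_logpdf(s, sigma[1])])
        logA = np.log(np.maximum(A, 1e-300))
        T = len(s)
        delta = np.zeros((T, 2))
        psi = np.zeros((T, 2), dtype=int)
        delta[0] = np.log(np.maximum(pi, 1e-300)) + logb[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + logA
            psi[t] = cand.argmax(axis=0)
            delta[t] = cand.max(axis=0) + logb[t]
        path = np.zeros(T, dtype=int)
        path[-1] = int(delta[-1].argmax())
        for t in range(T - 2, -1, -1):
            path[t] = psi[t + 1][path[t + 1]]
        return path

    threshold = _rayleigh_crossing(sigma)
    for tr in tracks:
        if len(tr) < 2:
            tr.state_labels = np.empty(0, dtype=object)
            continue
        mags = tr.jumps
        labels = np.empty(len(mags), dtype=object)
        gaps = tr.gap_after
        start = 0
        for k in range(len(mags) + 1):
            if k == len(mags) or gaps[k]:
                if k > start:
                    seg = mags[start:k]
                    if converged:
                        states = viterbi(seg)
                    else:
                        states = (seg > threshold).astype(int)
                    labels[start:k] = np.where(states == 0, "bound", "free")
                if k < len(mags):
                    labels[k] = "free" if mags[k] > threshold else "bound"
                start = k + 1
        tr.state_labels = labels
    return StateSegmentation(
        tracks=tracks, sigma=sigma, transition=A, initial=pi, log_likelihood=prev_ll, converged=converged
    )


def _rayleigh_crossing(sigma: np.ndarray) -> float:
    """Jump magnitude where the two Rayleigh emission densities cross."""
    s0, s1 = float(sigma[0]), float(sigma[1])
    if abs(s0 - s1) < 1e-12:
        return s0
    num = 2 * np.log(s1 / s0)
    den = 1 / s0**2 - 1 / s1**2
    return float(np.sqrt(2 * num / den))


def free_segments(track: Track) -> list[tuple[int, int]]:
    """Maximal runs [start_link, end_link) of free links (gap links break runs)."""
    if track.state_labels is None or len(track) < 2:
        return []
    segs = []
    n = len(track.state_labels)
    start = None
    for k in range(n + 1):
        free = k < n and track.state_labels[k] == "free" and not track.gap_after[k]
        if free and start is None:
            start = k
        elif not free and start is not None:
            segs.append((start, k))
            start = None
    return segs


def turning_angles(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Turning angle in degrees [0, 360) between consecutive displacement vectors."""
    a1 = np.arctan2(v1[:, 1], v1[:, 0])
    a2 = np.arctan2(v2[:, 1], v2[:, 0])
    return np.degrees(a2 - a1) % 360.0


def compute_angles(
    tracks: list[Track],
    min_jump_um: float = 0.13,
    regions: RegionSet | None = None,
    region_of_pair: str = "midpoint",
) -> pd.DataFrame:
    """Turning angles from free segments of state-segmented tracks.

    A pair of consecutive links qualifies when both links are free, both
    jump distances exceed ``min_jump_um``, and neither link spans a gap
    frame.  With ``regions`` given, the angle is labeled by the region of
    the shared (vertex) localization.  Returns a table
    (track_id, region, angle_deg, jump1_um, jump2_um).
    """
    rows = []
    for tr in tracks:
        for s, e in free_segments(tr):
            for k in range(s, e - 1):
                d1 = tr.xy[k + 1] - tr.xy[k]
                d2 = tr.xy[k + 2] - tr.xy[k + 1]
                j1 = float(np.hypot(*d1))
                j2 = float(np.hypot(*d2))
                if j1 <= min_jump_um or j2 <= min_jump_um:
                    continue
                ang = float(turning_angles(d1[None], d2[None])[0])
                if regions is not None:
                    lab = str(
                        regions.label_points(tr.xy[k + 1][None], np.array([tr.frames[k + 1]]))[0]
                    )
                else:
                    lab = ""
                rows.append((tr.track_id, lab, ang, j1, j2))
    df = pd.DataFrame(rows, columns=["track_id", "region", "angle_deg", "jump1_um", "jump2_um"])
    if df.empty:
        warnings.warn("no qualifying angle pairs found", stacklevel=2)
    return df


def fold_anisotropy(
    angles_deg: np.ndarray,
    half_window_deg: float = 30.0,
    n_resamples: int = 50,
    resample_fraction: float = 0.5,
    seed: int = 0,
    histogram_bin_deg: float = 15.0,
    region: str = "",
) -> AnisotropyResult:
    """Fold-anisotropy f_180/0 with half-data resampling error.

    f = N(180° ± w) / N(0° ± w) with closed windows (the forward window
    wraps around 0°).  The resampling statistic draws
    ⌊fraction·n⌋ angles without replacement ``n_resamples`` times
    (fixed seed) and reports the mean and STD of f across draws.  A zero
    denominator yields NaN (reported, never an infinity).
    """
    ang = np.asarray(angles_deg, dtype=float) % 360.0
    w = half_window_deg

    def f_ratio(a: np.ndarray) -> float:
        back = np.sum((a >= 180.0 - w) & (a <= 180.0 + w))
        fwd = np.sum((a >= 360.0 - w) | (a <= w))
        return back / fwd if fwd > 0 else np.nan

    f = f_ratio(ang)
    rng = np.random.default_rng(seed)
    k = int(np.floor(resample_fraction * len(ang)))
    fs = []
    for _ in range(n_resamples):
        idx = rng.choice(len(ang), size=k, replace=False) if k > 0 else np.empty(0, dtype=int)
        fs.append(f_ratio(ang[idx]))
    fs = np.asarray(fs, dtype=float)
    good = np.isfinite(fs)
    edges = np.arange(0.0, 360.0 + histogram_bin_deg, histogram_bin_deg)
    counts, _ = np.histogram(ang, bins=edges)
    return AnisotropyResult(
        f_180_0=float(f) if np.isfinite(f) else np.nan,
        n_angles=len(ang),
        resample_mean=float(fs[good].mean()) if good.any() else np.nan,
        resample_std=float(fs[good].std(ddof=1)) if good.sum() > 1 else np.nan,
        region=region,
        histogram=(edges, counts),
    )


def classify_shuttling(
    segmentation: StateSegmentation | list[Track],
    regions: RegionSet,
    use_free_segments: bool = True,
) -> list[ShuttlingEvent]:
    """Detect granule entry/exit events from free tracks.

    A track (or each of its free segments when ``use_free_segments``)
    produces an event when its first and last localizations lie on
    opposite sides of the granule boundary: outside → inside is 'enter',
    inside → outside is 'leave'.  The granule id is the mask component at
    the inside endpoint (nearest-in-time control frame).
    """
    from scipy import ndimage

    tracks = segmentation.tracks if isinstance(segmentation, StateSegmentation) else segmentation
    events = []
    for tr in tracks:
        if use_free_segments and tr.state_labels is not None:
            # a segment of links [s, e) spans localizations s .. e
            spans = [(s, e) for s, e in free_segments(tr)] or []
        else:
            spans = [(0, len(tr) - 1)] if len(tr) >= 2 else []
        for s, e in spans:
            first_xy, last_xy = tr.xy[s], tr.xy[e]
            first_f, last_f = int(tr.frames[s]), int(tr.frames[e])
            lab0 = str(regions.label_points(first_xy[None], np.array([first_f]))[0])
            lab1 = str(regions.label_points(last_xy[None], np.array([last_f]))[0])
            in0, in1 = lab0 == "granule", lab1 == "granule"
            if in0 == in1:
                continue
            direction = "enter" if in1 else "leave"
            inside_xy, inside_f = (last_xy, last_f) if in1 else (first_xy, first_f)
            ci = int(regions.nearest_control_index(inside_f)[0])
            lab_mask, _ = ndimage.label(regions.granule_masks[ci])
            jj = int(np.floor(inside_xy[0] / regions.pixel_size))
            ii = int(np.floor(inside_xy[1] / regions.pixel_size))
            gid = int(lab_mask[ii, jj]) if 0 <= ii < lab_mask.shape[0] and 0 <= jj < lab_mask.shape[1] else 0
            events.append(
                ShuttlingEvent(
                    track_id=tr.track_id,
                    direction=direction,
                    granule_id=gid,
                    frame_start=first_f,
                    frame_end=last_f,
                )
            )
    return events


def shuttling_stats(events: list[ShuttlingEvent], regions: RegionSet) -> dict:
    """Shuttling counts, events per µm² of granule area and entering fraction."""
    n_enter = sum(1 for e in events if e.direction == "enter")
    n_leave = sum(1 for e in events if e.direction == "leave")
    total = n_enter + n_leave
    mean_granule_area = float(regions.granule_masks.sum(axis=(1, 2)).mean()) * regions.pixel_size**2
    out = {
        "n_enter": n_enter,
        "n_leave": n_leave,
        "n_total": total,
        "mean_granule_area_um2": mean_granule_area,
        "events_per_um2": (total / mean_granule_area) if mean_granule_area > 0 else np.nan,
        "fraction_entering": (n_enter / total) if total > 0 else np.nan,
    }
    if total == 0:
        logger.info("no shuttling events; entering fraction undefined")
    return out
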