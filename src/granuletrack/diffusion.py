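"""Jump-distance-distribution analysis: Brownian mixture fitting and QC.

For molecules diffusing freely in 2-D with coefficient D, the distance r
jumped between consecutive frames (Δt apart) is Rayleigh distributed and
the cumulative distribution of a mixture of m Brownian populations is

    P(r <= R) = 1 - sum_i F_i * exp(-R² / (4 D_i Δt)),   sum_i F_i = 1.

The module collects consecutive-frame jump distances per region (first
five jumps of each track by default, to limit the over-representation of
slow and bound molecules whose tracks last longer), builds the empirical
CDF on a 1-nm grid, fits 1-3 component mixtures by constrained least
squares with multi-start, derives the effective diffusion coefficient
D_eff = sum_i F_i D_i, and applies movie-level quality-control filters
before aggregating movie-wise means and standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from granuletrack.regions import RegionAssignment
from granuletrack.tracking import Track

logger = logging.getLogger(__name__)

__all__ = [
    "JumpSample",
    "DiffusionFit",
    "collect_jumps",
    "empirical_cdf",
    "fit_mixture",
    "effective_diffusion",
    "qc_filter",
    "aggregate",
]


@dataclass
class JumpSample:
    """Consecutive-frame jump distances (µm) for one region of one movie."""

    region: str
    magnitudes: np.ndarray
    movie_id: str = ""

    @property
    def n_jumps(self) -> int:
        return len(self.magnitudes)


@dataclass
class DiffusionFit:
    """Result of an m-exponential Brownian mixture fit to a jump-distance CDF."""

    n_components: int
    D: np.ndarray  # µm²/s ascending
    F: np.ndarray  # fractions, sum 1
    D_eff: float
    sse: float
    adjusted_r2: float
    ci95_halfwidth_D: np.ndarray
    ci95_halfwidth_F: np.ndarray
    n_jumps: int
    frame_cycle: float
    region: str = ""
    movie_id: str = ""
    valid: bool = True

    @property
    def ci_error(self) -> float:
        """Scale-free fit error: sum of relative 95% CI half-widths."""
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_d = np.where(self.D > 0, self.ci95_halfwidth_D / self.D, np.inf)
        rel_f = np.where(self.F > 1e-12, self.ci95_halfwidth_F / self.F, 0.0)
        return float(np.sum(rel_d) + np.sum(rel_f))


def track_jumps(track: Track, first_n: int | None = 5) -> np.ndarray:
    """Consecutive-frame jump distances of one (sub-)track, gap links excluded.

    Jumps are taken in track order, skipping gap links without counting
    them, until ``first_n`` jumps are collected (all jumps when
    ``first_n`` is None).
    """
    if len(track) < 2:
        return np.empty(0)
    mags = track.jumps
    keep = ~track.gap_after
    mags = mags[keep]
    if first_n is not None:
        mags = mags[:first_n]
    return mags


def collect_jumps(
    assignment: RegionAssignment | list[Track],
    first_n: int | None = 5,
    use_all: bool = False,
    movie_id: str = "",
) -> dict[str, JumpSample]:
    """Per-region jump samples from region-split sub-tracks.

    ``use_all`` disables the first-n-jumps rule (mirrors the
    all-jumps comparison).  Sub-tracks labeled 'outside' are ignored.
    """
    subtracks = assignment.subtracks if isinstance(assignment, RegionAssignment) else assignment
    if use_all:
        first_n = None
    pools: dict[str, list[np.ndarray]] = {}
    for sub in subtracks:
        label = sub.region_label or "all"
        if label == "outside":
            continue
        j = track_jumps(sub, first_n)
        if len(j):
            pools.setdefault(label, []).append(j)
    return {
        lab: JumpSample(region=lab, magnitudes=np.concatenate(js), movie_id=movie_id)
        for lab, js in pools.items()
    }


def empirical_cdf(sample: JumpSample | np.ndarray, bin_nm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF of jump distances on a 1-nm grid.

    Returns (grid in µm from 0 to the maximum displacement, cumulative
    fraction); the final value is exactly 1.
    """
    mags = sample.magnitudes if isinstance(sample, JumpSample) else np.asarray(sample, dtype=float)
    if len(mags) == 0:
        raise ValueError("empty jump sample")
    bin_um = bin_nm * 1e-3
    n_bins = int(np.ceil(mags.max() / bin_um)) + 1
    grid = np.arange(n_bins + 1) * bin_um
    counts, _ = np.histogram(mags, bins=np.append(grid, np.inf))
    cdf = np.cumsum(counts) / len(mags)
    return grid, cdf


def _mixture_cdf(r: np.ndarray, D: np.ndarray, F: np.ndarray, dt: float) -> np.ndarray:
    return 1.0 - np.sum(F[:, None] * np.exp(-(r[None, :] ** 2) / (4.0 * D[:, None] * dt)), axis=0)


def _unpack(theta: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """theta = (log D_1..m, stick-breaking logits for fractions)."""
    D = np.exp(theta[:m])
    if m == 1:
        return D, np.ones(1)
    logits = theta[m:]
    F = np.empty(m)
    rest = 1.0
    for i in range(m - 1):
        s = 1.0 / (1.0 + np.exp(-logits[i]))
        F[i] = rest * s
        rest *= 1.0 - s
    F[m - 1] = rest
    return D, F


def fit_mixture(
    cdf: tuple[np.ndarray, np.ndarray],
    n_components: int = 3,
    frame_cycle: float = 0.006742,
    n_jumps: int | None = None,
    n_starts: int = 20,
    seed: int = 12345,
    region: str = "",
    movie_id: str = "",
) -> DiffusionFit:
    """Constrained least-squares fit of an m-exponential Brownian mixture CDF.

    Fractions are kept non-negative and summing to one through a
    stick-breaking parametrization, diffusion coefficients positive
    through log parametrization.  ``n_starts`` starts combine log-spaced
    D values with Dirichlet-drawn fractions (fixed seed); the best SSE
    wins, ties broken by the lower D1.  95% CI half-widths come from the
    Jacobian at the optimum via the delta method.
    """
    r, y = cdf
    m = int(n_components)
    if m not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    if len(r) < m * 2 + 2 or np.ptp(y) == 0:
        raise ValueError("degenerate CDF")
    dt = frame_cycle
    rng = np.random.default_rng(seed)

    # moment-informed scale for starts: mean squared jump ~ 4 D dt
    msd = np.interp(0.5, y, r) ** 2 / (4 * dt * np.log(2)) if y[0] < 0.5 else r[-1] ** 2 / (4 * dt)
    msd = max(msd, 1e-6)

    def residual(theta: np.ndarray) -> np.ndarray:
        D, F = _unpack(theta, m)
        return _mixture_cdf(r, D, F, dt) - y

    best = None
    for k in range(n_starts):
        if m == 1:
            d0 = np.array([msd * 10 ** rng.uniform(-0.5, 0.5)])
        else:
            span = 10 ** rng.uniform(0.5, 1.8)
            center = msd * 10 ** rng.uniform(-0.5, 0.5)
            d0 = np.geomspace(center / span, center * span, m)
        f0 = rng.dirichlet(np.ones(m))
        theta0 = np.concatenate([np.log(d0), _stick_logits(f0)])
        try:
            res = least_squares(residual, theta0, method="lm", max_nfev=400)
        except Exception:  # pragma: no cover - numerical corner cases
            continue
        sse = float(np.sum(res.fun**2))
        d_fit, _ = _unpack(res.x, m)
        key = (sse, float(np.min(d_fit)))
        if best is None or key < (best[0], best[1]):
            best = (sse, float(np.min(d_fit)), res)
    if best is None:
        logger.warning("mixture fit failed to converge for region=%s movie=%s", region, movie_id)
        nanarr = np.full(m, np.nan)
        return DiffusionFit(m, nanarr, nanarr, np.nan, np.inf, -np.inf, nanarr, nanarr,
                            n_jumps or len(r), dt, region, movie_id, valid=False)
    sse, _, res = best
    D, F = _unpack(res.x, m)
    order = np.argsort(D)
    D, F = D[order], F[order]

    n = len(r)
    p = 2 * m - 1
    dof = max(n - p, 1)
    sigma2 = sse / dof
    J = res.jac
    try:
        cov_theta = sigma2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov_theta = np.full((p, p), np.nan)
    # delta method: d(D, F)/d(theta) by finite differences
    G = np.zeros((2 * m, p))
    h = 1e-6
    for j in range(p):
        tp = res.x.copy()
        tp[j] += h
        Dp, Fp = _unpack(tp, m)
        G[:m, j] = (Dp - np.exp(res.x[:m])) / h
        G[m:, j] = (Fp - _unpack(res.x, m)[1]) / h
    cov_nat = G @ cov_theta @ G.T
    se = np.sqrt(np.clip(np.diag(cov_nat), 0, None))
    ci = 1.96 * se
    ci_D, ci_F = ci[:m][order], ci[m:][order]

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    adj_r2 = 1.0 - (sse / dof) / (ss_tot / (n - 1)) if ss_tot > 0 else -np.inf

    fit = DiffusionFit(
        n_components=m,
        D=D,
        F=F,
        D_eff=float(np.dot(D, F)),
        sse=sse,
        adjusted_r2=adj_r2,
        ci95_halfwidth_D=ci_D,
        ci95_halfwidth_F=ci_F,
        n_jumps=n_jumps if n_jumps is not None else n,
        frame_cycle=dt,
        region=region,
        movie_id=movie_id,
    )
    return fit


def _stick_logits(F: np.ndarray) -> np.ndarray:
    """Inverse of the stick-breaking transform used in :func:`fit_mixture`."""
    m = len(F)
    if m == 1:
        return np.empty(0)
    logits = np.empty(m - 1)
    rest = 1.0
    for i in range(m - 1):
        s = np.clip(F[i] / rest if rest > 0 else 0.5, 1e-9, 1 - 1e-9)
        logits[i] = np.log(s / (1 - s))
        rest *= 1.0 - s
    return logits


def effective_diffusion(fit: DiffusionFit) -> float:
    """Fraction-weighted mean of the component coefficients, stored on the fit."""
    d_eff = float(np.dot(fit.D, fit.F))
    fit.D_eff = d_eff
    return d_eff


def qc_filter(
    fits: list[DiffusionFit],
    group_keys: "dict[int, tuple] | None" = None,
    min_jumps: int = 30,
    ci_factor: float = 5.0,
) -> tuple[list[DiffusionFit], pd.DataFrame]:
    """Movie-level quality control.

    Drops fits with fewer than ``min_jumps`` jumps or an invalid fit;
    within each group (by default the fit's region; pass ``group_keys``
    mapping fit index -> hashable key to group by region and condition),
    drops fits whose CI-based error exceeds ``ci_factor`` × the group
    median error.  Returns (retained fits, rejection log).
    """
    log_rows = []
    prelim: list[tuple[int, DiffusionFit]] = []
    for i, f in enumerate(fits):
        if not f.valid:
            log_rows.append((f.movie_id, f.region, "fit_invalid"))
        elif f.n_jumps < min_jumps:
            log_rows.append((f.movie_id, f.region, f"n_jumps<{min_jumps}"))
        else:
            prelim.append((i, f))
    groups: dict = {}
    for i, f in prelim:
        key = group_keys[i] if group_keys else f.region
        groups.setdefault(key, []).append(f)
    kept: list[DiffusionFit] = []
    for key, fs in groups.items():
        errors = np.array([f.ci_error for f in fs])
        med = np.median(errors)
        for f, e in zip(fs, errors):
            if med > 0 and e > ci_factor * med:
                log_rows.append((f.movie_id, f.region, f"ci_error>{ci_factor}x_median"))
            else:
                kept.append(f)
    if not kept:
        logger.warning("qc_filter: no fits retained")
    log = pd.DataFrame(log_rows, columns=["movie_id", "region", "reason"])
    return kept, log


def aggregate(
    fits: list[DiffusionFit],
    group_keys: "dict[int, tuple] | None" = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Movie-wise mean ± STD of D_eff, D_i and F_i per (region, condition) group.

    Standard deviations use the sample convention (n−1) by default and
    are reported as 0 (flagged) for single-movie groups.
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    groups: dict = {}
    for i, f in enumerate(fits):
        key = group_keys[i] if group_keys else f.region
        groups.setdefault(key, []).append(f)
    rows = []
    for key, fs in sorted(groups.items(), key=lambda kv: str(kv[0])):
        m = max(f.n_components for f in fs)
        row: dict = {"group": key, "n_movies": len(fs), "single_movie": len(fs) == 1}
        deff = np.array([f.D_eff for f in fs])
        row["D_eff_mean"] = deff.mean()
        row["D_eff_std"] = deff.std(ddof=ddof) if len(fs) > 1 else 0.0
        for c in range(m):
            dc = np.array([f.D[c] for f in fs if f.n_components > c])
            fc = np.array([f.F[c] for f in fs if f.n_components > c])
            row[f"D{c + 1}_mean"] = dc.mean()
            row[f"D{c + 1}_std"] = dc.std(ddof=ddof) if len(dc) > 1 else 0.0
            row[f"F{c + 1}_mean"] = fc.mean()
            row[f"F{c + 1}_std"] = fc.std(ddof=ddof) if len(fc) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
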