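"""Jump-distance collection, mixture fitting, QC and aggregation tests.

Closed-form oracle: jump distances of 2-D diffusion with coefficient D
are Rayleigh with CDF 1 − exp(−r²/(4DΔt)); mixtures add with their
fractions.  Expected values below are computed from those forms.
"""

import numpy as np
import pytest

from granuletrack import diffusion as df
from granuletrack.diffusion import DiffusionFit, JumpSample
from granuletrack.tracking import Track

DT = 0.006742


def rayleigh_jumps(rng, d, n, dt=DT):
    """Draw n jump distances for diffusion coefficient d (closed-form sampler)."""
    return np.sqrt(4 * d * dt) * np.sqrt(-np.log(rng.uniform(size=n)))


def mixture_jumps(rng, D, F, n, dt=DT):
    comps = rng.choice(len(D), size=n, p=F)
    return np.concatenate([rayleigh_jumps(rng, D[k], (comps == k).sum(), dt) for k in range(len(D))])


class TestCollectJumps:
    def make(self, n, gaps=None, label="cytoplasm"):
        tr = Track(0, np.arange(n), np.cumsum(np.ones((n, 2)) * 0.01, axis=0),
                   gap_after=gaps, region_label=label)
        return tr

    def test_first_five_rule(self):
        sample = df.collect_jumps([self.make(8)])["cytoplasm"]
        assert sample.n_jumps == 5

    def test_short_track(self):
        assert df.collect_jumps([self.make(3)])["cytoplasm"].n_jumps == 2

    def test_gap_link_excluded_but_quota_continues(self):
        # 8 localizations, gap on link index 2: links 0,1 then 3,4,5 fill the quota of 5
        gaps = np.zeros(7, dtype=bool)
        gaps[2] = True
        tr = Track(0, [0, 1, 2, 4, 5, 6, 7, 8], np.cumsum(np.ones((8, 2)) * 0.01, axis=0),
                   gap_after=gaps, region_label="cytoplasm")
        sample = df.collect_jumps([tr])["cytoplasm"]
        assert sample.n_jumps == 5  # 6 non-gap links available, capped at 5

    def test_use_all_never_fewer(self):
        tracks = [self.make(12), self.make(4)]
        first5 = df.collect_jumps(tracks)["cytoplasm"].n_jumps
        all_j = df.collect_jumps(tracks, use_all=True)["cytoplasm"].n_jumps
        assert all_j >= first5


class TestEmpiricalCdf:
    def test_two_point_sample(self):
        grid, cdf = df.empirical_cdf(np.array([0.010, 0.020]))  # 10 and 20 nm
        i10 = np.searchsorted(grid, 0.010)
        i15 = np.searchsorted(grid, 0.015)
        assert cdf[i10] == pytest.approx(0.5)
        assert cdf[i15] == pytest.approx(0.5)
        assert cdf[-1] == pytest.approx(1.0)

    def test_identical_jumps_step(self):
        grid, cdf = df.empirical_cdf(np.full(5, 0.010))
        assert set(np.unique(cdf)) <= {0.0, 1.0}

    def test_rayleigh_ks_bound(self):
        """Empirical CDF of 10⁴ Rayleigh draws is Kolmogorov-close to the analytic CDF."""
        rng = np.random.default_rng(0)
        jumps = rayleigh_jumps(rng, 1.0, 10_000)
        grid, cdf = df.empirical_cdf(jumps)
        analytic = 1 - np.exp(-(grid**2) / (4 * 1.0 * DT))
        sup = np.max(np.abs(cdf - analytic))
        assert sup <= 1.63 / np.sqrt(10_000)  # alpha = 0.01


class TestFitMixture:
    def test_exact_three_component_recovery(self):
        D = np.array([0.05, 0.5, 5.0])
        F = np.array([0.2, 0.3, 0.5])
        r = np.arange(0, 1.2, 0.001)
        y = 1 - np.sum(F[:, None] * np.exp(-(r[None] ** 2) / (4 * D[:, None] * DT)), axis=0)
        fit = df.fit_mixture((r, y), 3, DT)
        np.testing.assert_allclose(fit.D, D, rtol=0.01)
        np.testing.assert_allclose(fit.F, F, atol=0.005)

    def test_exact_rayleigh_single_component(self):
        r = np.arange(0, 1.0, 0.001)
        y = 1 - np.exp(-(r**2) / (4 * 1.0 * DT))
        fit = df.fit_mixture((r, y), 1, DT)
        assert abs(fit.D[0] - 1.0) <= 1e-6

    def test_monte_carlo_single_population(self):
        rng = np.random.default_rng(1)
        jumps = rayleigh_jumps(rng, 1.0, 10_000)
        fit = df.fit_mixture(df.empirical_cdf(jumps), 1, DT, n_jumps=len(jumps))
        assert fit.D[0] == pytest.approx(1.0, rel=0.05)

    def test_model_selection_by_adjusted_r2(self):
        rng = np.random.default_rng(2)
        jumps = mixture_jumps(rng, [0.05, 0.5, 5.0], [0.2, 0.3, 0.5], 20_000)
        cdf = df.empirical_cdf(jumps)
        r2 = [df.fit_mixture(cdf, m, DT).adjusted_r2 for m in (1, 2, 3)]
        assert r2[2] == max(r2)
        assert r2[0] < r2[1] < r2[2]

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        jumps = mixture_jumps(rng, [0.1, 2.0], [0.4, 0.6], 3_000)
        fit = df.fit_mixture(df.empirical_cdf(jumps), 3, DT)
        assert fit.F.sum() == pytest.approx(1.0, abs=1e-6)
        assert (fit.F >= -1e-12).all()

    def test_parameter_recovery_well_separated(self):
        """3-component fit on 10⁴ mixture jumps: D within 15%, F within 0.05."""
        rng = np.random.default_rng(4)
        D, F = np.array([0.05, 0.5, 5.0]), np.array([0.2, 0.3, 0.5])
        jumps = mixture_jumps(rng, D, F, 10_000)
        fit = df.fit_mixture(df.empirical_cdf(jumps), 3, DT, n_jumps=len(jumps))
        np.testing.assert_allclose(fit.D, D, rtol=0.15)
        np.testing.assert_allclose(fit.F, F, atol=0.05)


class TestEffectiveDiffusion:
    def make_fit(self, D, F):
        D, F = np.asarray(D, float), np.asarray(F, float)
        return DiffusionFit(len(D), D, F, float(D @ F), 0.0, 1.0, np.zeros(len(D)),
                            np.zeros(len(D)), 100, DT)

    def test_degenerate_mixture(self):
        assert df.effective_diffusion(self.make_fit([0.5, 1, 2], [1, 0, 0])) == pytest.approx(0.5)

    def test_weighted_mean_arithmetic(self):
        fit = self.make_fit([0.1, 1.0, 5.0], [0.25, 0.35, 0.40])
        assert df.effective_diffusion(fit) == pytest.approx(2.375)

    def test_convexity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            D = np.sort(rng.uniform(0.01, 6, 3))
            F = rng.dirichlet(np.ones(3))
            fit = self.make_fit(D, F)
            assert D[0] <= df.effective_diffusion(fit) <= D[2]


class TestQcAndAggregate:
    def make_fit(self, n_jumps=100, ci=0.1, movie="m", region="cytoplasm", deff=1.0):
        m = 3
        return DiffusionFit(m, np.array([0.1, 1.0, 3.0]), np.array([0.3, 0.3, 0.4]), deff,
                            0.0, 1.0, np.full(m, ci), np.full(m, 0.0), n_jumps, DT,
                            region=region, movie_id=movie)

    def test_too_few_jumps_rejected(self):
        fits = [self.make_fit(n_jumps=29, movie="a"), self.make_fit(n_jumps=30, movie="b")]
        kept, log = df.qc_filter(fits)
        assert [f.movie_id for f in kept] == ["b"]
        assert "n_jumps<30" in log.reason.iloc[0]

    def test_large_ci_error_rejected(self):
        fits = [self.make_fit(ci=0.1, movie=f"m{i}") for i in range(5)]
        fits.append(self.make_fit(ci=10.0, movie="bad"))  # 100x median relative error
        kept, log = df.qc_filter(fits)
        assert "bad" not in [f.movie_id for f in kept]
        assert len(kept) == 5

    def test_identical_errors_none_rejected(self):
        fits = [self.make_fit(ci=0.2, movie=f"m{i}") for i in range(4)]
        kept, log = df.qc_filter(fits)
        assert len(kept) == 4 and len(log) == 0

    def test_aggregate_mean_std(self):
        fits = [self.make_fit(deff=2.0, movie="a"), self.make_fit(deff=4.0, movie="b")]
        out = df.aggregate(fits)
        assert out.D_eff_mean.iloc[0] == pytest.approx(3.0)
        assert out.D_eff_std.iloc[0] == pytest.approx(np.sqrt(2), rel=1e-6)  # sample STD

    def test_single_movie_flagged(self):
        out = df.aggregate([self.make_fit()])
        assert bool(out.single_movie.iloc[0]) is True
        assert out.D_eff_std.iloc[0] == 0.0

    def test_movie_set_recovers_truth(self):
        """Movie-wise mean D_eff from 20 simulated movies brackets F·D within 2 STD."""
        rng = np.random.default_rng(6)
        D, F = np.array([0.05, 0.5, 5.0]), np.array([0.2, 0.3, 0.5])
        truth = float(D @ F)
        fits = []
        for i in range(20):
            jumps = mixture_jumps(rng, D, F, 2_000)
            f = df.fit_mixture(df.empirical_cdf(jumps), 3, DT, n_jumps=len(jumps),
                               movie_id=f"m{i}", n_starts=10)
            df.effective_diffusion(f)
            fits.append(f)
        kept, _ = df.qc_filter(fits)
        out = df.aggregate(kept)
        assert abs(out.D_eff_mean.iloc[0] - truth) <= 2 * out.D_eff_std.iloc[0]


class TestSamplingBias:
    def test_first_five_raises_deff_when_slow_tracks_are_long(self):
        """Long-lived slow molecules dominate the all-jumps pool; first-5 limits that."""
        rng = np.random.default_rng(7)
        tracks = []
        tid = 0
        for _ in range(150):  # slow, long tracks
            n = 30
            steps = rng.normal(0, np.sqrt(2 * 0.05 * DT), (n - 1, 2))
            tracks.append(Track(tid, np.arange(n), np.vstack([[0, 0], np.cumsum(steps, 0)]),
                                region_label="cytoplasm"))
            tid += 1
        for _ in range(150):  # fast, short tracks
            n = 5
            steps = rng.normal(0, np.sqrt(2 * 5.0 * DT), (n - 1, 2))
            tracks.append(Track(tid, np.arange(n), np.vstack([[0, 0], np.cumsum(steps, 0)]),
                                region_label="cytoplasm"))
            tid += 1
        s5 = df.collect_jumps(tracks)["cytoplasm"]
        sall = df.collect_jumps(tracks, use_all=True)["cytoplasm"]
        assert sall.n_jumps > s5.n_jumps
        f5 = df.fit_mixture(df.empirical_cdf(s5), 2, DT, n_starts=10)
        fall = df.fit_mixture(df.empirical_cdf(sall), 2, DT, n_starts=10)
        assert df.effective_diffusion(f5) >= df.effective_diffusion(fall)
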