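"""DEER pipeline: background, form factor, inversion, validation, scaling."""

import numpy as np
import pytest
from scipy.optimize import lsq_linear

import pentaspin as ps
from pentaspin import PipelineError
from pentaspin.deer import _second_difference, default_r_grid
from pentaspin.kernel import build_kernel
from pentaspin.simulate import deer_background

GOLDEN = (1 + np.sqrt(5)) / 2


@pytest.fixture
def small_inversion_problem():
    """30-bin inversion instance with a bimodal truth and mild noise."""
    rng = np.random.default_rng(0)
    t = np.arange(0, 2.0, 0.02)
    r = np.linspace(2.0, 5.0, 30)
    kern = build_kernel(t, r)
    dens = np.exp(-0.5 * ((r - 2.7) / 0.12) ** 2) + np.exp(-0.5 * ((r - 4.3) / 0.15) ** 2)
    dens /= np.trapezoid(dens, r)
    w = np.full(30, kern.dr)
    w[0] = w[-1] = 0.5 * kern.dr
    F = 1 + 0.3 * ((kern.matrix - 1) @ (dens * w)) + rng.normal(0, 0.005, len(t))
    return ps.TimeTrace(axis=t, real=F, meta={}), kern, dens, w


class TestBackground:
    def test_pure_background_recovers_rate(self):
        t = np.arange(0, 3.0, 0.01)
        for fit_start in (0.1, 0.3, 0.6):
            trace = ps.TimeTrace(axis=t, real=deer_background(t, 0.25), meta={})
            bg = ps.fit_background(trace, fit_start=fit_start)
            assert bg.rate == pytest.approx(0.25, rel=0.01)

    def test_modulated_trace_recovers_rate_within_10pct(self):
        r = ps.deer.default_r_grid()
        dens = np.exp(-0.5 * ((r - 3.0) / 0.08) ** 2)
        pr = ps.DistanceDistribution(r, dens / np.trapezoid(dens, r))
        params = ps.DeerParameters(mod_depth=0.3, bg_rate=0.15, noise_sd=0.0,
                                   time_axis=np.arange(0, 3.0, 0.012))
        trace = ps.simulate_deer(pr, params, seed=0)
        bg = ps.fit_background(trace, fit_start=0.5)
        assert bg.rate == pytest.approx(0.15, rel=0.10)

    def test_flat_trace(self):
        t = np.arange(0, 2.0, 0.01)
        trace = ps.TimeTrace(axis=t, real=np.full_like(t, 0.7), meta={})
        bg = ps.fit_background(trace, fit_start=0.2)
        assert bg.rate == pytest.approx(0.0, abs=1e-6)
        assert bg.scale == pytest.approx(0.7, rel=1e-6)

    def test_rising_background_clamped_unless_allowed(self):
        t = np.arange(0, 2.0, 0.01)
        trace = ps.TimeTrace(axis=t, real=np.exp(0.1 * t), meta={})
        bg = ps.fit_background(trace, fit_start=0.2)
        assert bg.rate == 0.0 and not bg.unphysical
        bg2 = ps.fit_background(trace, fit_start=0.2, allow_unphysical=True)
        assert bg2.rate == pytest.approx(-0.1, rel=0.01) and bg2.unphysical

    def test_short_tail_rejected(self):
        t = np.arange(0, 0.1, 0.01)
        trace = ps.TimeTrace(axis=t, real=np.ones_like(t), meta={})
        with pytest.raises(PipelineError, match="tail"):
            ps.fit_background(trace, fit_start=0.9)


class TestFormFactor:
    def test_background_only_gives_unity(self):
        t = np.arange(0, 2.0, 0.01)
        trace = ps.TimeTrace(axis=t, real=deer_background(t, 0.3), meta={})
        bg = ps.fit_background(trace, fit_start=0.3)
        ff = ps.form_factor(trace, bg)
        assert np.allclose(ff.real, 1.0, atol=1e-5)

    def test_long_time_level_is_one_minus_depth(self, noiseless_deer_trace):
        ff = ps.DeerModel(noiseless_deer_trace).fit().form_factor
        tail = ff.real[ff.axis > 0.8 * ff.axis[-1]]
        assert np.mean(tail) == pytest.approx(0.7, rel=0.02)
        assert ff.real[0] == pytest.approx(1.0, abs=0.01)


class TestTikhonovInvert:
    def test_matches_bounded_qp_oracle(self, small_inversion_problem):
        """The stacked NNLS solve must agree with an independent bounded
        least-squares (QP) oracle bin by bin."""
        ff, kern, _, w = small_inversion_problem
        L = _second_difference(30)
        for alpha in (0.01, 0.1, 1.0):
            res = ps.tikhonov_invert(ff, kern, alpha)
            A = (kern.matrix - 1.0) * w[None, :]
            A_st = np.vstack([A, alpha * L])
            b_st = np.concatenate([ff.real - 1, np.zeros(28)])
            oracle = lsq_linear(A_st, b_st, bounds=(0, np.inf), tol=1e-14, max_iter=3000)
            q = res.pr.density * res.mod_depth
            assert np.max(np.abs(q - oracle.x)) < 1e-6

    def test_noiseless_unimodal_recovery(self):
        t = np.arange(0, 2.5, 0.015)
        r = np.linspace(1.5, 6.0, 91)
        kern = build_kernel(t, r)
        dens = np.exp(-0.5 * ((r - 3.2) / 0.1) ** 2)
        dens /= np.trapezoid(dens, r)
        w = np.full(len(r), kern.dr)
        w[0] = w[-1] = 0.5 * kern.dr
        ff = ps.TimeTrace(axis=t, real=1 + 0.3 * ((kern.matrix - 1) @ (dens * w)), meta={})
        res = ps.tikhonov_invert(ff, kern, 1e-3)
        mode = r[np.argmax(res.pr.density)]
        assert abs(mode - 3.2) <= kern.dr + 1e-12

    def test_rmsd_monotone_in_alpha(self, small_inversion_problem):
        ff, kern, _, _ = small_inversion_problem
        rmsds = [ps.tikhonov_invert(ff, kern, a).rmsd for a in np.logspace(-4, 1, 10)]
        assert np.all(np.diff(rmsds) >= -1e-12)

    def test_result_normalized_nonnegative(self, small_inversion_problem):
        ff, kern, _, _ = small_inversion_problem
        res = ps.tikhonov_invert(ff, kern, 0.05)
        assert np.all(res.pr.density >= 0)
        assert res.pr.integral() == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd >= 0

    def test_nonpositive_alpha_rejected(self, small_inversion_problem):
        ff, kern, _, _ = small_inversion_problem
        with pytest.raises(PipelineError, match="alpha"):
            ps.tikhonov_invert(ff, kern, 0.0)


class TestSelectAlpha:
    def test_single_point_grid_returned(self, small_inversion_problem):
        ff, kern, _, _ = small_inversion_problem
        assert ps.select_alpha(ff, kern, np.array([0.3])) == 0.3

    def test_noiseless_selects_at_or_below_median(self):
        t = np.arange(0, 2.0, 0.02)
        r = np.linspace(2.0, 5.0, 30)
        kern = build_kernel(t, r)
        dens = np.exp(-0.5 * ((r - 3.0) / 0.15) ** 2)
        dens /= np.trapezoid(dens, r)
        w = np.full(30, kern.dr)
        w[0] = w[-1] = 0.5 * kern.dr
        ff = ps.TimeTrace(axis=t, real=1 + 0.3 * ((kern.matrix - 1) @ (dens * w)), meta={})
        grid = np.logspace(-4, 1, 16)
        assert ps.select_alpha(ff, kern, grid) <= grid[len(grid) // 2]

    def test_pure_noise_selects_upper_half(self):
        t = np.arange(0, 2.0, 0.02)
        kern = build_kernel(t, np.linspace(2.0, 5.0, 30))
        grid = np.logspace(-4, 1, 16)
        for seed in range(3):
            noise = 1 + np.random.default_rng(seed).normal(0, 0.02, len(t))
            ff = ps.TimeTrace(axis=t, real=noise, meta={})
            with pytest.warns(UserWarning, match="degenerate L-curve"):
                a = ps.select_alpha(ff, kern, grid)
            assert a >= grid[len(grid) // 2]


class TestValidate:
    def test_small_ensemble_counts_and_filter(self, noiseless_deer_trace):
        ens = ps.validate(
            noiseless_deer_trace, n_steps=4, trials_per_step=5, seed=1,
            r_grid=np.linspace(1.8, 5.5, 30),
        )
        assert ens.n_planned == 20
        assert 1 <= ens.n_kept <= 20
        best = min(t.rmsd for t in ens.trials if np.isfinite(t.rmsd))
        assert all(t.rmsd <= ens.rmsd_cut * best for t in ens.trials if t.kept)
        lo, mean, hi = ens.bands()
        assert np.all(lo <= mean + 1e-12) and np.all(mean <= hi + 1e-12)

    def test_degenerate_ensemble_zero_spread(self, noiseless_deer_trace):
        """noise_scale 0 and a single fit start: identical trials, sigma = 0."""
        ens = ps.validate(
            noiseless_deer_trace, n_steps=2, start_lo=0.3, start_hi=0.3 + 1e-9,
            trials_per_step=3, noise_scale=0.0, seed=0,
            r_grid=np.linspace(1.8, 5.5, 30),
        )
        lo, mean, hi = ens.bands()
        assert np.allclose(lo, hi, atol=1e-10)
        assert ens.n_kept == ens.n_planned

    def test_ensemble_mean_consistent_with_single_fit(self, noiseless_deer_trace):
        r_grid = np.linspace(1.8, 5.5, 30)
        res = ps.DeerModel(noiseless_deer_trace, r_grid=r_grid).fit()
        ens = ps.validate(noiseless_deer_trace, n_steps=16, trials_per_step=2,
                          seed=2, r_grid=r_grid, alpha=res.alpha)
        lo, mean, hi = ens.bands()
        sigma = (hi - mean) / 2.0
        assert np.all(np.abs(mean - res.distribution.density) <= 2 * sigma + 1e-2)

    def test_fit_start_third_vs_best_regression(self, noiseless_deer_trace):
        """Fitting the background to the latter two-thirds gives essentially
        the same distribution as the best-RMSD fit start."""
        model = ps.DeerModel(noiseless_deer_trace)
        best = model.fit()
        third = model.fit(fit_start=1.0 / 3.0, alpha=best.alpha)
        overlap = np.trapezoid(
            np.minimum(best.distribution.density, third.distribution.density),
            best.distribution.r,
        )
        assert overlap > 0.8
        assert abs(best.distribution.mean() - third.distribution.mean()) < 0.15


class TestPowerScale:
    def test_identity_for_pairs(self, noiseless_deer_trace):
        ff = ps.TimeTrace(axis=np.arange(0, 1.0, 0.01), real=np.linspace(1, 0.7, 100), meta={})
        out = ps.power_scale(ff, 2)
        assert np.array_equal(out.real, ff.real)

    def test_pentamer_exponent(self):
        ff = ps.TimeTrace(axis=np.arange(0, 1.0, 0.01), real=np.full(100, 0.81), meta={})
        out = ps.power_scale(ff, 5)
        assert np.allclose(out.real, 0.81**0.25)

    def test_nonpositive_clipped_with_warning(self):
        ff = ps.TimeTrace(axis=np.arange(0, 0.3, 0.01),
                          real=np.linspace(1, -0.1, 30), meta={})
        with pytest.warns(UserWarning, match="clipped"):
            out = ps.power_scale(ff, 5)
        assert np.all(out.real > 0)

    def test_reduces_multispin_ghost_mass(self, pentamer_geometry):
        """5-spin product form factor: after power scaling the inverted P(r)
        carries less mass outside the true modes than without."""
        t = np.arange(0, 3.0, 0.012)
        F = np.ones_like(t)
        for d in pentamer_geometry.pairwise_distances():
            pair = build_kernel(t, np.array([d]))
            F *= 0.96 + 0.04 * pair.matrix[:, 0]
        ff = ps.TimeTrace(axis=t, real=F, meta={})
        kern = build_kernel(t, default_r_grid())
        truth = pentamer_geometry.unique_distances(4)

        def ghost_mass(res):
            mask = np.ones_like(res.pr.r, dtype=bool)
            for d in truth:
                mask &= np.abs(res.pr.r - d) > 0.3
            return np.trapezoid(res.pr.density * mask, res.pr.r)

        raw = ps.tikhonov_invert(ff, kern, ps.select_alpha(ff, kern))
        scaled_ff = ps.power_scale(ff, 5)
        scaled = ps.tikhonov_invert(scaled_ff, kern, ps.select_alpha(scaled_ff, kern))
        assert ghost_mass(scaled) < ghost_mass(raw)


class TestReliabilityRanges:
    def test_monotone_in_trace_length(self):
        r1 = ps.reliability_ranges(1.0)
        r2 = ps.reliability_ranges(2.5)
        assert all(r2[k] > r1[k] for k in r1)

    def test_cube_root_scaling(self):
        r1 = ps.reliability_ranges(1.3)
        r2 = ps.reliability_ranges(2.6)
        for k in r1:
            assert r2[k] / r1[k] == pytest.approx(2 ** (1 / 3), rel=1e-9)

    def test_zero_length_rejected(self):
        with pytest.raises(PipelineError):
            ps.reliability_ranges(0.0)


class TestRoundTrip:
    def test_noiseless_pentamer_recovery(self, noiseless_deer_trace, pentamer_geometry):
        """Full chain on a noiseless pentamer: modal distances within one
        grid step of truth, D2/D1 in the pentamer window, depth within 10%."""
        res = ps.DeerModel(noiseless_deer_trace).fit()
        truth = pentamer_geometry.unique_distances(4)
        peaks = res.peak_distances
        assert len(peaks) == 2
        dr = res.distribution.dr
        assert abs(peaks[0] - truth[0]) <= dr + 1e-12
        assert abs(peaks[1] - truth[1]) <= dr + 1e-12
        ratio = peaks[1] / peaks[0]
        assert 1.55 <= ratio <= 1.70
        assert res.mod_depth == pytest.approx(0.3, rel=0.10)

    def test_summary_mentions_key_estimates(self, noiseless_deer_trace):
        res = ps.DeerModel(noiseless_deer_trace).fit()
        text = res.summary()
        assert "modulation depth" in text
        assert "D2/D1" in text
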