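"""Generator-level checks: brightness mixtures, Brownian motion, FRAP
curves, subunit exchange, and the TOCCSL movie's physical invariants."""

import numpy as np
import pytest
from scipy.stats import ks_1samp

from toccsl.mixture import build_components, estimate_monomer_pdf
from toccsl.simulate import (
    apply_subunit_exchange,
    draw_monomer_brightness,
    population_from_truth,
    simulate_brightness_samples,
    simulate_frap_curve,
    simulate_toccsl_movie,
    simulate_trajectories,
    simulate_repeat_toccsl,
)
from toccsl.spots import counts_to_photons, estimate_density
from toccsl.types import (
    CameraModel,
    ComplexPopulation,
    GroundTruth,
    ProtocolTimings,
    ValidationError,
)


class TestBrightnessSamples:
    def test_pure_monomer_mean(self):
        truth = GroundTruth(alpha_true=(1.0,))
        b, labels = simulate_brightness_samples(truth, 10_000, rng=1)
        se = b.std() / np.sqrt(b.size)
        assert abs(b.mean() - 100.0) < 3 * se
        assert set(labels) == {1}

    def test_mixture_mean_matches_closed_form(self):
        truth = GroundTruth(alpha_true=(0.55, 0.35, 0.10))
        b, _ = simulate_brightness_samples(truth, 10_000, rng=2)
        expected = (0.55 * 1 + 0.35 * 2 + 0.10 * 3) * 100.0
        se = b.std() / np.sqrt(b.size)
        assert abs(b.mean() - expected) < 3 * se

    def test_degenerate_noise_gives_integer_multiples(self):
        truth = GroundTruth(alpha_true=(0.6, 0.4), monomer_brightness_cv=0.0)
        b, labels = simulate_brightness_samples(truth, 500, rng=3)
        assert set(np.round(b, 9)) <= {100.0, 200.0}
        np.testing.assert_allclose(b, labels * 100.0)

    def test_non_normalized_alpha_rejected(self):
        with pytest.raises(ValidationError):
            GroundTruth(alpha_true=(0.5, 0.4))

    def test_empirical_pdf_converges_to_analytic_mixture(self):
        """KS distance to the analytic N-fold-convolution mixture shrinks
        with sample size."""
        truth = GroundTruth(alpha_true=(0.55, 0.35, 0.10))
        rho1 = estimate_monomer_pdf(
            draw_monomer_brightness(100, 0.35, 100_000, np.random.default_rng(4)),
            n_max=3)
        comps = build_components(rho1, 3)
        grid = comps[0].grid
        mix = sum(a * c.density for a, c in
                  zip(truth.alpha_true, comps))
        cdf_grid = np.concatenate([[0], np.cumsum(
            (mix[1:] + mix[:-1]) / 2 * np.diff(grid))])
        cdf_grid /= cdf_grid[-1]

        def cdf(x):
            return np.interp(x, grid, cdf_grid)

        stats = {}
        for n in (500, 20_000):
            b, _ = simulate_brightness_samples(truth, n, rng=5)
            stats[n] = ks_1samp(b, cdf).statistic
        assert stats[20_000] < stats[500]
        assert stats[20_000] < 0.02

    def test_seeded_runs_are_bit_reproducible(self):
        truth = GroundTruth()
        b1, s1 = simulate_brightness_samples(truth, 1000, rng=11)
        b2, s2 = simulate_brightness_samples(truth, 1000, rng=11)
        np.testing.assert_array_equal(b1, b2)
        np.testing.assert_array_equal(s1, s2)


class TestTrajectories:
    def test_zero_diffusion_is_static(self):
        pos = simulate_trajectories(0.0, 0.01, 50, 10, rng=0)
        assert np.all(pos == pos[:, :1, :])

    def test_step_variance(self):
        D, dt = 0.118, 0.01
        pos = simulate_trajectories(D, dt, 10_000, 1, rng=1)
        steps = np.diff(pos[0], axis=0)
        var = steps.var(axis=0)
        target = 2 * D * dt
        se = target * np.sqrt(2.0 / steps.shape[0])
        assert np.all(np.abs(var - target) < 3 * se)

    def test_msd_lag2_closed_form(self):
        pos = simulate_trajectories(1.0, 1.0, 4, 10_000, rng=2)
        disp2 = np.sum((pos[:, 2, :] - pos[:, 0, :]) ** 2, axis=1)
        se = disp2.std() / np.sqrt(disp2.size)
        assert abs(disp2.mean() - 8.0) < 3 * se


class TestFrapCurve:
    def test_plateau(self):
        t = np.linspace(0, 1000, 50)
        curve = simulate_frap_curve(0.78, 10.0, t)
        assert abs(curve[-1] - 0.78) < 1e-9

    def test_immobile_limit(self):
        curve = simulate_frap_curve(0.0, 5.0, np.linspace(0, 100, 20))
        assert np.all(curve == 0)

    def test_one_tau_point(self):
        curve = simulate_frap_curve(1.0, 7.0, np.array([7.0]))
        assert curve[0] == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            simulate_frap_curve(0.5, 1.0, [0, 1], noise_sd=-0.1)


class TestSubunitExchange:
    def _dimer_population(self, n_dimers, n_monomers, f, rng):
        sizes = np.concatenate([np.ones(n_monomers, int),
                                np.full(n_dimers, 2, int)])
        active = rng.random(int(sizes.sum())) < f
        return ComplexPopulation(sizes=sizes, active=active)

    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        pop = self._dimer_population(500, 500, 0.5, rng)
        out = apply_subunit_exchange(pop, 0.0, 1e9, rng)
        np.testing.assert_array_equal(out.active, pop.active)

    def test_fast_exchange_matches_binomial_oracle(self):
        """After complete mixing, the visible-spot dimer fraction equals
        d f^2 / (m f + d (2 f (1-f) + f^2))."""
        rng = np.random.default_rng(1)
        d, f = 0.39, 0.5
        n = 200_000
        n_dim = int(d * n)
        pop = self._dimer_population(n_dim, n - n_dim, f, rng)
        f_actual = pop.active_fraction
        out = apply_subunit_exchange(pop, 1e9, 1.0, rng)
        n_act = out.n_active_per_complex
        visible = n_act > 0
        dimer_visible = (n_act == 2)
        observed = dimer_visible.sum() / visible.sum()
        m = 1 - d
        expected = d * f_actual**2 / (
            m * f_actual + d * (2 * f_actual * (1 - f_actual) + f_actual**2))
        assert observed == pytest.approx(expected, abs=0.01)

    def test_nothing_bleached_keeps_composition(self):
        rng = np.random.default_rng(2)
        pop = self._dimer_population(400, 600, 1.0, rng)
        out = apply_subunit_exchange(pop, 5.0, 100.0, rng)
        assert np.all(out.active)
        np.testing.assert_array_equal(out.sizes, pop.sizes)

    def test_fluorophore_count_conserved(self):
        rng = np.random.default_rng(3)
        pop = self._dimer_population(300, 300, 0.4, rng)
        before = pop.active.sum()
        out = apply_subunit_exchange(pop, 0.01, 300.0, rng)
        assert out.active.sum() == before

    def test_negative_rate_rejected(self):
        pop = ComplexPopulation(sizes=[1], active=[True])
        with pytest.raises(ValidationError):
            apply_subunit_exchange(pop, -1.0, 1.0)


class TestToccslMovie:
    def test_pre_bleach_signal_matches_density_times_area(self):
        truth = GroundTruth(surface_density=40.0, alpha_true=(1.0,))
        cam = CameraModel(field_of_view=(128, 128))  # 20.48 um field
        stack = simulate_toccsl_movie(truth, ProtocolTimings(), cam, rng=6)
        photons = counts_to_photons(stack.frames[0], cam, clip=False).photons
        est = estimate_density(photons, cam, 100.0)
        # Poisson fluctuation of the molecule count plus brightness noise
        assert est.density == pytest.approx(40.0, rel=0.08)

    def test_no_bleach_limit_recovers_pre_bleach_statistics(self):
        truth = GroundTruth(surface_density=10.0)
        cam = CameraModel(field_of_view=(64, 64))
        stack = simulate_toccsl_movie(truth, ProtocolTimings(), cam,
                                      bleach_efficiency=0.0, rng=7)
        pre = counts_to_photons(stack.frames[0], cam, clip=False).photons
        rec = counts_to_photons(stack.frames[-1], cam, clip=False).photons
        assert rec.sum() == pytest.approx(pre.sum(), rel=0.05)

    def test_bleach_empties_region_and_only_bleach_reduces_signal(self):
        truth = GroundTruth(surface_density=10.0)
        cam = CameraModel(field_of_view=(64, 64))
        stack = simulate_toccsl_movie(truth, ProtocolTimings(), cam, rng=8)
        r0, c0, r1, c1 = stack.bleach_region
        pre = counts_to_photons(stack.frames[0], cam, clip=False).photons
        post = counts_to_photons(stack.frames[1], cam, clip=False).photons
        # erode by 4 px so PSF tails of unbleached molecules just outside
        # the field stop do not count as residual signal
        region_pre = pre[r0 + 4:r1 - 4, c0 + 4:c1 - 4].sum()
        region_post = post[r0 + 4:r1 - 4, c0 + 4:c1 - 4].sum()
        assert region_post < 0.05 * region_pre
        # outside the region the signal is preserved (diffusion conserves it)
        mask = np.ones_like(pre, dtype=bool)
        mask[r0:r1, c0:c1] = False
        assert post[mask].sum() == pytest.approx(pre[mask].sum(), rel=0.15)

    def test_stable_repeat_preserves_composition(self):
        """With no subunit exchange the visible composition of consecutive
        runs is unchanged even as spots deplete."""
        truth = GroundTruth(alpha_true=(0.55, 0.35, 0.10), exchange_rate=0.0)
        obs = simulate_repeat_toccsl(
            truth, ProtocolTimings(n_runs=2), n_cells=40,
            complexes_per_cell=500, rng=9)
        f1 = np.mean(obs[0].apparent_sizes == 2)
        f2 = np.mean(obs[1].apparent_sizes == 2)
        se = np.sqrt(f1 * (1 - f1) / obs[0].apparent_sizes.size
                     + f2 * (1 - f2) / obs[1].apparent_sizes.size)
        assert abs(f1 - f2) < 3 * se
        assert obs[1].n_visible < obs[0].n_visible

    def test_movie_is_bit_reproducible(self):
        truth = GroundTruth(surface_density=5.0)
        cam = CameraModel(field_of_view=(32, 32))
        s1 = simulate_toccsl_movie(truth, ProtocolTimings(), cam, rng=10)
        s2 = simulate_toccsl_movie(truth, ProtocolTimings(), cam, rng=10)
        np.testing.assert_array_equal(s1.frames, s2.frames)

    def test_population_sampling_follows_alpha(self):
        truth = GroundTruth(alpha_true=(0.7, 0.3))
        pop = population_from_truth(truth, 50_000, rng=11)
        frac_dimer = np.mean(pop.sizes == 2)
        assert frac_dimer == pytest.approx(0.3, abs=0.01)
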