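"""Monomer-PDF estimation, autoconvolution, constrained mixture fitting,
bootstrap errors, and detection sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from toccsl.mixture import (
    _ml_weights,
    autoconvolve,
    bootstrap_alpha,
    build_components,
    detection_sensitivity,
    estimate_monomer_pdf,
    fit_mixture,
    fit_mixture_with_bootstrap,
    sample_from_pdf,
)
from toccsl.simulate import draw_monomer_brightness, simulate_brightness_samples
from toccsl.types import BrightnessPDF, GroundTruth, ValidationError


class TestEstimateMonomerPdf:
    def test_mean_recovered_within_1_percent(self):
        rng = np.random.default_rng(0)
        x = draw_monomer_brightness(100.0, 0.35, 100_000, rng)
        pdf = estimate_monomer_pdf(x)
        assert pdf.mean() == pytest.approx(100.0, rel=0.01)
        assert pdf.integral() == pytest.approx(1.0, abs=1e-6)

    def test_grid_spans_nmax_fold_support(self):
        rng = np.random.default_rng(1)
        x = draw_monomer_brightness(100.0, 0.35, 5000, rng)
        pdf = estimate_monomer_pdf(x, n_max=5)
        assert pdf.grid[-1] >= 5 * np.quantile(x, 0.999)

    def test_degenerate_samples_give_near_delta(self):
        pdf = estimate_monomer_pdf(np.full(250, 80.0), grid_max=500.0)
        assert pdf.integral() == pytest.approx(1.0, abs=1e-6)
        assert pdf.grid[np.argmax(pdf.density)] == pytest.approx(80.0, abs=1.0)
        assert np.sqrt(pdf.var()) < 2.0

    def test_negative_samples_rejected(self):
        with pytest.raises(ValidationError):
            estimate_monomer_pdf(np.array([-1.0] + [50.0] * 99))

    def test_too_few_samples_hard_error(self):
        with pytest.raises(ValidationError):
            estimate_monomer_pdf(np.full(19, 50.0))

    def test_sparse_calibration_warns(self):
        rng = np.random.default_rng(2)
        x = draw_monomer_brightness(100.0, 0.35, 50, rng)
        with pytest.warns(UserWarning, match="calibration"):
            estimate_monomer_pdf(x)


class TestAutoconvolve:
    def test_identity_for_n1(self, rho1):
        out = autoconvolve(rho1, 1)
        np.testing.assert_allclose(out.density, rho1.density)

    def test_gaussian_closed_form(self):
        """The 2-fold autoconvolution of N(mu, s^2) is N(2 mu, 2 s^2)."""
        grid = np.linspace(0.0, 600.0, 2048)
        mu, s = 100.0, 15.0
        g1 = norm.pdf(grid, mu, s)
        g1 /= np.trapezoid(g1, grid)
        rho = BrightnessPDF(grid=grid, density=g1)
        rho2 = autoconvolve(rho, 2)
        expected = norm.pdf(grid, 2 * mu, s * np.sqrt(2))
        np.testing.assert_allclose(rho2.density, expected, atol=1e-4)

    def test_moment_additivity(self, rho1):
        for n in (2, 3, 5):
            rn = autoconvolve(rho1, n)
            assert rn.mean() == pytest.approx(n * rho1.mean(), rel=1e-3)
            assert rn.var() == pytest.approx(n * rho1.var(), rel=5e-3)
            assert rn.integral() == pytest.approx(1.0, abs=1e-6)

    def test_truncation_loss_raises(self):
        grid = np.linspace(0.0, 300.0, 512)
        g = norm.pdf(grid, 200.0, 20.0)
        g /= np.trapezoid(g, grid)
        rho = BrightnessPDF(grid=grid, density=g)
        with pytest.raises(ValidationError, match="grid too short"):
            autoconvolve(rho, 3)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=5, max_size=12))
    def test_moment_additivity_for_arbitrary_densities(self, knots):
        """Mean/variance additivity and normalization hold for any valid
        monomer density, not just the lognormal default."""
        grid = np.linspace(0.0, 400.0, 1024)
        support = np.linspace(5.0, 95.0, len(knots))
        dens = np.interp(grid, support, knots, left=0.0, right=0.0)
        dens /= np.trapezoid(dens, grid)
        rho = BrightnessPDF(grid=grid, density=dens)
        for n in (2, 3):
            rn = autoconvolve(rho, n)
            assert rn.integral() == pytest.approx(1.0, abs=1e-6)
            assert rn.mean() == pytest.approx(n * rho.mean(), rel=2e-3)
            assert rn.var() == pytest.approx(n * rho.var(), rel=1e-2)


class TestFitMixture:
    def test_pure_monomer(self, components):
        truth = GroundTruth(alpha_true=(1.0,))
        b, _ = simulate_brightness_samples(truth, 5000, rng=1)
        res = fit_mixture(b, components)
        assert res.alpha[0] > 0.98
        assert abs(res.alpha.sum() - 1.0) < 1e-8

    def test_mixture_recovery_within_3_points(self, components):
        truth = GroundTruth(alpha_true=(0.55, 0.35, 0.10))
        b, _ = simulate_brightness_samples(truth, 10_000, rng=2)
        res = fit_mixture(b, components)
        assert res.alpha[0] == pytest.approx(0.55, abs=0.03)
        assert res.alpha[1] == pytest.approx(0.35, abs=0.03)
        assert res.alpha[2] == pytest.approx(0.10, abs=0.03)

    def test_solver_matches_exhaustive_ml_on_discrete_alphabet(self):
        """On a 3-atom brightness alphabet the constrained solver must find
        the same weights as an exhaustive grid search of the likelihood."""
        # component pmfs over atoms
        A = np.array([[0.7, 0.2, 0.1],
                      [0.2, 0.5, 0.3],
                      [0.1, 0.2, 0.7]]).T        # rows: atoms, cols: comps
        rng = np.random.default_rng(3)
        true_alpha = np.array([0.5, 0.3, 0.2])
        atom_p = A @ true_alpha
        counts = rng.multinomial(400, atom_p)

        L = np.repeat(A, counts, axis=0)
        alpha_hat = _ml_weights(L)

        def ll(a1, a2):
            a = np.array([a1, a2, 1 - a1 - a2])
            return counts @ np.log(A @ a)

        best, best_ll = None, -np.inf
        step = 2e-3
        for a1 in np.arange(0, 1 + step, step):
            a2 = np.arange(0, 1 - a1 + step / 2, step)
            a = np.column_stack([np.full_like(a2, a1), a2, 1 - a1 - a2])
            a[:, 2] = np.clip(a[:, 2], 0, 1)
            lls = counts @ np.log(np.clip(A @ a.T, 1e-300, None))
            i = np.argmax(lls)
            if lls[i] > best_ll:
                best_ll, best = lls[i], a[i]
        # local refinement around the coarse optimum
        fine = 1e-4
        g1 = np.arange(max(best[0] - step, 0), min(best[0] + step, 1), fine)
        g2 = np.arange(max(best[1] - step, 0), min(best[1] + step, 1), fine)
        G1, G2 = np.meshgrid(g1, g2)
        mask = G1 + G2 <= 1
        cand = np.column_stack([G1[mask], G2[mask], 1 - G1[mask] - G2[mask]])
        lls = counts @ np.log(np.clip(A @ cand.T, 1e-300, None))
        best = cand[np.argmax(lls)]
        np.testing.assert_allclose(alpha_hat, best, atol=1e-3)

    def test_lsq_mode_agrees_with_ml(self, components):
        truth = GroundTruth(alpha_true=(0.55, 0.35, 0.10))
        b, _ = simulate_brightness_samples(truth, 10_000, rng=4)
        ml = fit_mixture(b, components, method="ml")
        lsq = fit_mixture(b, components, method="lsq")
        se, _ = bootstrap_alpha(b, components, n_reps=30, seed=5)
        assert np.all(np.abs(ml.alpha - lsq.alpha) < np.maximum(3 * se, 0.02))

    def test_permutation_invariance(self, components):
        b, _ = simulate_brightness_samples(GroundTruth(), 2000, rng=6)
        res1 = fit_mixture(b, components)
        res2 = fit_mixture(np.random.default_rng(0).permutation(b), components)
        np.testing.assert_allclose(res1.alpha, res2.alpha, atol=1e-12)

    def test_pooling_equals_pooled_fit(self, components):
        """Fitting per simulated cell then pooling the raw samples equals
        fitting the pooled sample directly (the pipeline pools spots)."""
        parts = [simulate_brightness_samples(GroundTruth(), 3000, rng=s)[0]
                 for s in (7, 8, 9)]
        pooled = np.concatenate(parts)
        res = fit_mixture(pooled, components)
        res_again = fit_mixture(np.concatenate(parts[::-1]), components)
        np.testing.assert_allclose(res.alpha, res_again.alpha, atol=1e-12)

    def test_parametric_bootstrap_closure(self, components):
        """Samples drawn from a fitted mixture refit to the same alpha
        within bootstrap error."""
        truth = GroundTruth(alpha_true=(0.55, 0.35, 0.10))
        b, _ = simulate_brightness_samples(truth, 8000, rng=10)
        fit1 = fit_mixture_with_bootstrap(b, components, n_reps=40, seed=11)
        rng = np.random.default_rng(12)
        sizes = rng.choice(np.arange(1, 6), size=8000, p=fit1.alpha)
        resampled = np.concatenate([
            sample_from_pdf(components[s - 1], int((sizes == s).sum()), rng)
            for s in range(1, 6) if np.any(sizes == s)])
        fit2 = fit_mixture(resampled, components)
        tol = np.maximum(3 * fit1.alpha_se, 0.02)
        assert np.all(np.abs(fit2.alpha - fit1.alpha) < tol)

    def test_ill_conditioning_warning_for_narrow_monomer_pdf(self):
        pdf = estimate_monomer_pdf(
            np.random.default_rng(13).normal(100.0, 1.0, 1000),
            grid_max=600.0)
        comps = build_components(pdf, 2)
        b = np.random.default_rng(14).normal(100.0, 1.0, 500)
        res = fit_mixture(np.clip(b, 0, None), comps)
        assert any("ill-conditioned" in w for w in res.warnings)


class TestBootstrap:
    def test_se_shrinks_as_root_n(self, components):
        truth = GroundTruth(alpha_true=(0.55, 0.35, 0.10))
        ses = {}
        for n in (1000, 4000):
            b, _ = simulate_brightness_samples(truth, n, rng=20)
            se, _ = bootstrap_alpha(b, components, n_reps=60, seed=21)
            ses[n] = se[1]
        ratio = ses[1000] / ses[4000]
        assert 1.3 < ratio < 3.1      # ~2 expected for a 4x sample increase

    def test_dimer_se_below_5_points_at_n10000(self, components):
        truth = GroundTruth(alpha_true=(0.55, 0.35, 0.10))
        b, _ = simulate_brightness_samples(truth, 10_000, rng=22)
        se, skipped = bootstrap_alpha(b, components, n_reps=40, seed=23)
        assert skipped == 0
        assert se[1] < 0.05

    def test_reproducible_given_seed(self, components):
        b, _ = simulate_brightness_samples(GroundTruth(), 2000, rng=24)
        se1, _ = bootstrap_alpha(b, components, n_reps=20, seed=25)
        se2, _ = bootstrap_alpha(b, components, n_reps=20, seed=25)
        np.testing.assert_array_equal(se1, se2)

    def test_subsample_too_small_rejected(self, components):
        b, _ = simulate_brightness_samples(GroundTruth(), 30, rng=26)
        with pytest.raises(ValidationError):
            bootstrap_alpha(b, components, n_reps=10,
                            subsample_fraction=0.1, seed=27)


class TestDetectionSensitivity:
    def test_large_dimer_fraction_detected(self, rho1):
        sens = detection_sensitivity(
            rho1, n_max=3, n_spots=2000, alpha_background=(1.0, 0.0, 0.0),
            fractions=(0.05, 0.35), n_seeds=8, n_boot=12, seed=0)
        assert sens[2] <= 0.35

    def test_tiny_pentamer_fraction_not_reliably_detected(self, rho1):
        """0.5% pentamers among 1000 spots fail the 95%-reliability
        detection criterion (a handful of tail events is not enough)."""
        sens = detection_sensitivity(
            rho1, n_max=5, n_spots=1000,
            alpha_background=(1.0, 0.0, 0.0, 0.0, 0.0),
            fractions=(0.005,), n_seeds=8, n_boot=12, seed=1)
        assert np.isnan(sens[5])


def test_decomposition_plot_written(tmp_path, components):
    from toccsl.mixture import plot_decomposition
    b, _ = simulate_brightness_samples(
        GroundTruth(alpha_true=(0.55, 0.35, 0.10)), 2000, rng=30)
    res = fit_mixture(b, components)
    out = tmp_path / "decomposition.png"
    plot_decomposition(b, components, res, path=out)
    assert out.exists() and out.stat().st_size > 0
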