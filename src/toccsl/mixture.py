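"""Oligomer stoichiometry by brightness-PDF autoconvolution and mixture fitting.

The observable is the single-spot brightness B of diffraction-limited
signals.  A spot containing N active fluorophores has brightness
distributed as the N-fold autoconvolution rho_N(B) of the single-fluorophore
density rho_1(B), because the N photon contributions add independently.
The measured brightness density is therefore the finite mixture

    rho(B) = sum_{N=1}^{N_max} alpha_N * rho_N(B),

and the oligomeric-state distribution alpha is obtained by a constrained
fit (alpha_N >= 0, sum alpha_N = 1).  The default criterion is maximum
likelihood of the raw brightness samples; a least-squares fit to the
binned density is provided as a cross-check mode.  Errors on alpha come
from a subsampling bootstrap: the fit is repeated on random halves of the
data and the standard deviation over repetitions is divided by sqrt(2).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize, nnls
from scipy.signal import fftconvolve
from scipy.stats import gaussian_kde

from .types import BrightnessPDF, MixtureResult, ValidationError, as_rng

__all__ = [
    "estimate_monomer_pdf",
    "autoconvolve",
    "build_components",
    "fit_mixture",
    "bootstrap_alpha",
    "fit_mixture_with_bootstrap",
    "sample_from_pdf",
    "detection_sensitivity",
    "plot_decomposition",
]

_DENSITY_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# monomer PDF estimation

def estimate_monomer_pdf(
    samples,
    n_grid: int = 2048,
    n_max: int = 5,
    grid_max: float | None = None,
) -> BrightnessPDF:
    """Estimate the single-fluorophore brightness density rho_1(B).

    A Gaussian kernel density with Silverman bandwidth, evaluated on a
    uniform grid of ``n_grid`` points spanning ``[0, grid_max]``.  The grid
    must be long enough to later hold the ``n_max``-fold autoconvolution,
    so by default ``grid_max`` is set a little above ``n_max`` times the
    99.9th sample percentile.

    Raises a hard error below 20 samples; warns below 200 (brightness
    calibrations that sparse give unstable mixture components).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValidationError("calibration samples must be a 1-D vector")
    if x.size < 20:
        raise ValidationError(
            f"at least 20 calibration samples required (got {x.size})")
    if np.any(x < 0):
        raise ValidationError("brightness samples must be non-negative")
    if x.size < 200:
        warnings.warn(
            f"only {x.size} calibration spots; >= 200 recommended",
            stacklevel=2)
    if grid_max is None:
        grid_max = 1.08 * n_max * float(np.quantile(x, 0.999))
    grid = np.linspace(0.0, float(grid_max), n_grid)
    sd = float(np.std(x))
    if sd < 1e-12 * max(1.0, float(np.mean(x))):
        # degenerate calibration: represent as a narrow Gaussian spike
        dx = grid[1] - grid[0]
        width = 2.0 * dx
        dens = np.exp(-0.5 * ((grid - x.mean()) / width) ** 2)
    else:
        kde = gaussian_kde(x, bw_method="silverman")
        dens = kde(grid)
    dens = np.clip(dens, 0.0, None)
    dens /= np.trapezoid(dens, grid)
    return BrightnessPDF(grid=grid, density=dens,
                         provenance="monomer-empirical")


# ---------------------------------------------------------------------------
# autoconvolution

def autoconvolve(rho1: BrightnessPDF, N: int) -> BrightnessPDF:
    """N-fold autoconvolution of the monomer brightness density.

    Computed by FFT convolution on the common grid; the full linear
    convolution is evaluated (implicit zero padding, no wrap-around) and
    truncated back to the grid.  If more than 1e-4 of probability mass
    would be lost to truncation the grid is too short and an error is
    raised.  Means and variances add: mean(rho_N) = N mean(rho_1),
    var(rho_N) = N var(rho_1).
    """
    if N < 1:
        raise ValidationError("N must be at least 1")
    if N == 1:
        return BrightnessPDF(rho1.grid.copy(), rho1.density.copy(),
                             provenance="autoconvolved-1")
    dx = rho1.dx
    dens = rho1.density
    out = dens
    for _ in range(N - 1):
        out = fftconvolve(out, dens) * dx
    lost = float(np.sum(out[len(rho1.grid):]) * dx)
    if lost > 1e-4:
        raise ValidationError(
            f"grid too short for {N}-fold convolution: {lost:.2e} of mass "
            "beyond grid_max")
    out = np.clip(out[: len(rho1.grid)], 0.0, None)
    out /= np.trapezoid(out, rho1.grid)
    return BrightnessPDF(grid=rho1.grid.copy(), density=out,
                         provenance=f"autoconvolved-{N}")


def build_components(rho1: BrightnessPDF, n_max: int) -> list[BrightnessPDF]:
    """rho_N for N = 1..n_max on the common grid."""
    if n_max < 1:
        raise ValidationError("n_max must be at least 1")
    return [autoconvolve(rho1, n) for n in range(1, n_max + 1)]


# ---------------------------------------------------------------------------
# constrained mixture fit

def _component_matrix(samples: np.ndarray,
                      components: list[BrightnessPDF]) -> np.ndarray:
    """Likelihood matrix L[i, k] = rho_{k+1}(B_i) by linear interpolation."""
    grid = components[0].grid
    return np.column_stack([
        np.interp(samples, grid, c.density, left=0.0, right=0.0)
        for c in components
    ])


def _em_weights(L: np.ndarray, alpha0=None, tol: float = 1e-12,
                max_iter: int = 2000) -> np.ndarray:
    k = L.shape[1]
    alpha = (np.full(k, 1.0 / k) if alpha0 is None
             else np.asarray(alpha0, dtype=float))
    for _ in range(max_iter):
        mix = L @ alpha
        mix = np.clip(mix, _DENSITY_FLOOR, None)
        resp = L * alpha / mix[:, None]
        new = resp.mean(axis=0)
        new /= new.sum()
        if np.max(np.abs(new - alpha)) < tol:
            alpha = new
            break
        alpha = new
    return alpha


def _loglik(alpha: np.ndarray, L: np.ndarray) -> float:
    return float(np.sum(np.log(np.clip(L @ alpha, _DENSITY_FLOOR, None))))


def _ml_weights(L: np.ndarray) -> np.ndarray:
    """Maximum-likelihood weights on the probability simplex.

    EM warm start (monotone, safe) followed by an SLSQP polish on the
    simplex for fast terminal convergence; if the polish fails or degrades
    the likelihood, EM is continued instead.
    """
    alpha = _em_weights(L, max_iter=300, tol=1e-10)

    def neg_ll(a):
        mix = np.clip(L @ a, _DENSITY_FLOOR, None)
        return -np.sum(np.log(mix))

    def grad(a):
        mix = np.clip(L @ a, _DENSITY_FLOOR, None)
        return -(L / mix[:, None]).sum(axis=0)

    k = L.shape[1]
    res = minimize(
        neg_ll, alpha, jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0,
                      "jac": lambda a: np.ones(k)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    if res.success:
        cand = np.clip(res.x, 0.0, None)
        cand /= cand.sum()
        if _loglik(cand, L) >= _loglik(alpha, L) - 1e-9:
            return cand
    return _em_weights(L, alpha0=alpha, max_iter=200000, tol=1e-13)


def fit_mixture(
    samples,
    components: list[BrightnessPDF],
    method: str = "ml",
    n_bins: int = 128,
) -> MixtureResult:
    """Fit the oligomer fractions alpha_N from a brightness sample.

    ``method='ml'``: constrained maximum likelihood of the raw samples
    under the mixture density (the default; deterministic given samples
    and grid).  ``method='lsq'``: non-negative least squares of the binned
    sample density against the component densities, renormalized — a
    cross-check that should agree with ML within bootstrap error.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("samples must be a non-empty 1-D vector")
    if not components:
        raise ValidationError("at least one component density required")
    n_max = len(components)
    warns: list[str] = []
    if components[0].cv() < 0.05:
        warns.append("ill-conditioned: monomer PDF CV < 0.05, "
                     "components are near-collinear")

    L = _component_matrix(x, components)
    supported = L.sum(axis=1) > 0
    n_out = int((~supported).sum())
    if n_out:
        warns.append(f"{n_out} samples outside the component support "
                     "were excluded")
        L = L[supported]
        x_used = x[supported]
    else:
        x_used = x
    if L.shape[0] == 0:
        raise ValidationError("no samples inside the component support")

    if method == "ml":
        alpha = _ml_weights(L)
        ll = _loglik(alpha, L)
    elif method == "lsq":
        grid = components[0].grid
        hist, edges = np.histogram(
            x_used, bins=n_bins, range=(0.0, float(grid[-1])), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        A = np.column_stack([
            np.interp(centers, grid, c.density) for c in components])
        w, _ = nnls(A, hist)
        if w.sum() <= 0:
            raise ValidationError("least-squares fit returned all-zero weights")
        alpha = w / w.sum()
        ll = _loglik(alpha, L)
    else:
        raise ValidationError(f"unknown fit method {method!r}")

    # goodness of fit: L2 distance between binned sample density and model
    grid = components[0].grid
    hist, edges = np.histogram(
        x_used, bins=n_bins, range=(0.0, float(grid[-1])), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    model = sum(a * np.interp(centers, grid, c.density)
                for a, c in zip(alpha, components))
    width = edges[1] - edges[0]
    residual = float(np.sqrt(np.sum((hist - model) ** 2) * width))

    return MixtureResult(alpha=alpha, n_max=n_max, n_spots=int(x.size),
                         residual_norm=residual, log_likelihood=ll,
                         method=method, warnings=warns)


def bootstrap_alpha(
    samples,
    components: list[BrightnessPDF],
    n_reps: int = 100,
    subsample_fraction: float = 0.5,
    seed=None,
    method: str = "ml",
) -> tuple[np.ndarray, int]:
    """Bootstrap standard errors for the fitted fractions.

    Random subsamples containing ``subsample_fraction`` of the data (drawn
    without replacement) are refitted ``n_reps`` times; the standard error
    of each alpha_N is the standard deviation over repetitions divided by
    sqrt(2).  Replicates whose fit fails are skipped and counted; more
    than 10% skips is an error.
    """
    x = np.asarray(samples, dtype=float)
    if not 0.0 < subsample_fraction < 1.0:
        raise ValidationError("subsample_fraction must lie in (0, 1)")
    if n_reps < 2:
        raise ValidationError("n_reps must be at least 2")
    rng = as_rng(seed)
    m = int(np.floor(subsample_fraction * x.size))
    if m < max(len(components) + 1, 10):
        raise ValidationError("subsample too small to fit the mixture")
    reps, skipped = [], 0
    for _ in range(n_reps):
        idx = rng.choice(x.size, size=m, replace=False)
        try:
            reps.append(fit_mixture(x[idx], components, method=method).alpha)
        except ValidationError:
            skipped += 1
    if skipped > 0.1 * n_reps:
        raise ValidationError(
            f"{skipped}/{n_reps} bootstrap replicates failed to fit")
    se = np.std(np.vstack(reps), axis=0, ddof=1) / np.sqrt(2.0)
    return se, skipped


def fit_mixture_with_bootstrap(
    samples,
    components: list[BrightnessPDF],
    n_reps: int = 100,
    subsample_fraction: float = 0.5,
    seed=None,
    method: str = "ml",
) -> MixtureResult:
    """Convenience wrapper: point fit plus bootstrap errors in one result."""
    result = fit_mixture(samples, components, method=method)
    se, skipped = bootstrap_alpha(samples, components, n_reps=n_reps,
                                  subsample_fraction=subsample_fraction,
                                  seed=seed, method=method)
    result.alpha_se = se
    if skipped:
        result.warnings.append(f"{skipped} bootstrap replicates skipped")
    return result


# ---------------------------------------------------------------------------
# sampling and sensitivity

def sample_from_pdf(pdf: BrightnessPDF, n: int, rng=None) -> np.ndarray:
    """Draw samples from a gridded density by inverse-CDF interpolation."""
    rng = as_rng(rng)
    cdf = cumulative_trapezoid(pdf.density, pdf.grid, initial=0.0)
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, pdf.grid)


def detection_sensitivity(
    rho1: BrightnessPDF,
    n_max: int,
    n_spots: int,
    alpha_background,
    fractions=(0.005, 0.01, 0.02, 0.05, 0.1, 0.2),
    n_seeds: int = 20,
    n_boot: int = 25,
    success_level: float = 0.95,
    seed=None,
) -> dict[int, float]:
    """Smallest reliably detectable fraction for each oligomer size.

    For each N >= 2 and each candidate fraction, spots are repeatedly
    simulated from the background mixture with the candidate fraction
    injected at size N; the injection counts as detected when the fitted
    alpha_N exceeds twice its bootstrap error.  The minimal detectable
    fraction is the smallest candidate detected in at least
    ``success_level`` of the simulations (NaN if none qualifies).
    """
    bg = np.asarray(alpha_background, dtype=float)
    if bg.size != n_max or np.any(bg < 0) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValidationError(
            "alpha_background must be a distribution of length n_max")
    rng = as_rng(seed)
    components = build_components(rho1, n_max)
    sizes = np.arange(1, n_max + 1)
    out: dict[int, float] = {}
    for N in range(2, n_max + 1):
        found = np.nan
        for frac in sorted(fractions):
            alpha = bg * (1.0 - frac)
            alpha[N - 1] += frac
            hits = 0
            for _ in range(n_seeds):
                draw_sizes = rng.choice(sizes, size=n_spots, p=alpha)
                b = np.concatenate([
                    sample_from_pdf(components[s - 1], int(np.sum(draw_sizes == s)), rng)
                    for s in sizes if np.any(draw_sizes == s)
                ])
                res = fit_mixture(b, components)
                se, _ = bootstrap_alpha(b, components, n_reps=n_boot,
                                        seed=rng.integers(2**31))
                if se[N - 1] > 0 and res.alpha[N - 1] > 2.0 * se[N - 1]:
                    hits += 1
            if hits >= success_level * n_seeds:
                found = frac
                break
        out[N] = found
    return out


# ---------------------------------------------------------------------------
# plotting

def plot_decomposition(samples, components, result: MixtureResult,
                       path=None, n_bins: int = 80):
    """Plot the sample brightness density, the fitted mixture and the
    weighted n-mer components (the standard decomposition figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(samples, dtype=float)
    grid = components[0].grid
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(x, bins=n_bins, density=True, histtype="step", color="black",
            label=f"data (n={x.size})")
    model = sum(a * c.density for a, c in zip(result.alpha, components))
    ax.plot(grid, model, "r--", label="mixture fit")
    for n, (a, c) in enumerate(zip(result.alpha, components), start=1):
        if a > 1e-3:
            ax.plot(grid, a * c.density, color="C0", alpha=0.7,
                    label=f"{n}-mer ({a:.0%})")
    ax.set_xlabel("single-spot brightness B (photons)")
    ax.set_ylabel("probability density (1/photons)")
    ax.set_xlim(0, np.quantile(x, 0.999) * 1.3)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
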