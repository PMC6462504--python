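"""End-to-end TOCCSL orchestration: frames -> spots -> mixture -> report.

One TOCCSL run is analyzed in three steps that mirror the acquisition
protocol: the pre-bleach frame gives the surface density, the post-bleach
control frame verifies complete bleaching (a run failing this check is
invalid and yields no mixture fit), and the recovery frame provides the
single-spot brightness sample for the oligomer mixture fit.

The repeated protocol (one run every few minutes on the same cell) is
summarized by a stability report: if subunit interactions are stable, the
visible-spot count depletes run over run while the apparent oligomer
distribution stays constant; if subunits exchange between complexes,
bleached and fluorescent subunits mix and the apparent distribution drifts
toward monomers.  The two regimes are discriminated by the trend of the
dimer fraction across runs together with an explicit binomial mixing model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import mixture as mx
from . import spots as sp
from .simulate import RepeatRunObservation
from .types import (
    BrightnessPDF,
    CameraModel,
    DensityEstimate,
    FrameStack,
    MixtureResult,
    ValidationError,
)

__all__ = [
    "ToccslConfig",
    "ToccslRun",
    "StabilityReport",
    "run_toccsl_analysis",
    "pool_brightness",
    "compare_density_groups",
    "analyze_repeat_toccsl",
    "exchange_model_predict",
    "apparent_alpha",
    "complex_alpha",
    "runs_from_repeat_simulation",
]


@dataclass(frozen=True)
class ToccslConfig:
    """Analysis thresholds for one TOCCSL run.

    ``completeness_max_density`` is the residual spot density (per um^2)
    tolerated in the bleached region on the post-bleach control frame;
    anything above marks the run invalid.  ``region_margin_um`` erodes the
    analysis region so that PSF tails of unbleached molecules just outside
    the field stop do not contaminate detection.
    """

    detection_threshold: float = 12.0
    min_separation: float = 5.0
    fit_window: int = 7
    sigma_band: tuple[float, float] = (0.7, 1.5)
    region_margin_um: float = 0.6
    completeness_max_density: float = 0.01
    min_spots_for_fit: int = 30
    n_max: int = 5
    bootstrap_reps: int = 100
    bootstrap_fraction: float = 0.5
    seed: int = 0
    equalize_run_sampling: bool = False


@dataclass
class ToccslRun:
    """Result of one analyzed TOCCSL run."""

    recovery_spots: pd.DataFrame
    density: Optional[DensityEstimate] = None
    post_bleach_residual: int = 0
    mixture: Optional[MixtureResult] = None
    run_index: int = 0
    elapsed: float = 0.0
    condition: str = "untreated"
    cell_id: str = "cell-0"
    n_visible: Optional[int] = None
    valid: bool = True
    diagnostics: list[str] = field(default_factory=list)

    @property
    def brightness(self) -> np.ndarray:
        df = self.recovery_spots
        ok = df[df["status"] == "ok"]
        return ok["B"].to_numpy(dtype=float)


@dataclass
class StabilityReport:
    """Verdict on subunit stability from a repeated TOCCSL series."""

    run_indices: np.ndarray
    alpha_per_run: np.ndarray           # (n_runs, n_max)
    alpha_se_per_run: np.ndarray
    dimer_slope: float
    dimer_slope_se: float
    verdict: str                        # stable | exchanging | inconclusive
    depletion: np.ndarray               # visible spots per run
    model_sse: dict
    excluded_runs: list[int] = field(default_factory=list)


def _eroded_region(stack: FrameStack, camera: CameraModel,
                   margin_um: float) -> tuple[int, int, int, int]:
    r0, c0, r1, c1 = stack.bleach_region
    m = int(round(margin_um / camera.pixel_size))
    rr0, cc0, rr1, cc1 = r0 + m, c0 + m, r1 - m, c1 - m
    if rr1 <= rr0 or cc1 <= cc0:
        raise ValidationError("region margin leaves no analysis area")
    return rr0, cc0, rr1, cc1


def run_toccsl_analysis(
    stack: FrameStack,
    camera: CameraModel,
    rho1: BrightnessPDF,
    config: ToccslConfig = ToccslConfig(),
    components: Optional[list[BrightnessPDF]] = None,
    fit_mixture: bool = True,
    **run_labels,
) -> ToccslRun:
    """Analyze one TOCCSL frame stack end to end.

    Requires pre-bleach, post-bleach and recovery frames.  The surface
    density comes from the integrated pre-bleach intensity; the bleach
    completeness check counts residual spots in the (eroded) bleached
    region of the post-bleach frame; the brightness sample and mixture fit
    come from spots detected in the same region of the recovery frame(s).
    An incomplete bleach invalidates the run: its spot sample would mix
    surviving and recovered complexes with unknown stoichiometry bias.
    """
    for role in ("pre-bleach", "post-bleach", "recovery"):
        if not stack.frames_with_role(role):
            raise ValidationError(f"stack is missing a {role} frame")
    region = _eroded_region(stack, camera, config.region_margin_um)
    r0, c0, r1, c1 = region
    region_area = (r1 - r0) * (c1 - c0) * camera.pixel_size**2

    # surface density from the pre-bleach frame (unclipped photons)
    i_pre = stack.frames_with_role("pre-bleach")[0]
    pre_photons = sp.counts_to_photons(stack.frames[i_pre], camera,
                                       clip=False).photons
    density = sp.estimate_density(pre_photons, camera, rho1.mean())

    diagnostics: list[str] = []

    # bleach completeness from the post-bleach control frame
    i_post = stack.frames_with_role("post-bleach")[0]
    post_photons = sp.counts_to_photons(stack.frames[i_post], camera).photons
    # min_separation 0: the overlap-discard rule would hide exactly the
    # crowded survivors this check exists to catch; candidates must then
    # survive the Gaussian fit so isolated noise maxima do not count
    residual_spots = sp.analyze_frame(
        post_photons, camera, config.detection_threshold,
        min_separation=0, window=config.fit_window,
        sigma_band=config.sigma_band, frame_index=i_post, region_px=region)
    n_residual = sum(s.accepted for s in residual_spots)
    valid = n_residual / region_area <= config.completeness_max_density
    if not valid:
        diagnostics.append(
            f"incomplete bleach: {n_residual} residual spots "
            f"({n_residual / region_area:.3f}/um^2) in the control frame")

    # brightness sample from the recovery frame(s)
    all_spots = []
    if valid:
        for i_rec in stack.frames_with_role("recovery"):
            rec_photons = sp.counts_to_photons(stack.frames[i_rec],
                                               camera).photons
            all_spots.extend(sp.analyze_frame(
                rec_photons, camera, config.detection_threshold,
                config.min_separation, config.fit_window, config.sigma_band,
                frame_index=i_rec, region_px=region))
    table = sp.spots_to_table(all_spots)

    result = None
    if valid and fit_mixture:
        b = table.loc[table["status"] == "ok", "B"].to_numpy(dtype=float)
        if b.size >= config.min_spots_for_fit:
            if components is None:
                components = mx.build_components(rho1, config.n_max)
            result = mx.fit_mixture_with_bootstrap(
                b, components, n_reps=config.bootstrap_reps,
                subsample_fraction=config.bootstrap_fraction,
                seed=config.seed)
        else:
            diagnostics.append(
                f"only {b.size} accepted spots; "
                f"{config.min_spots_for_fit} required for a mixture fit")

    return ToccslRun(recovery_spots=table, density=density,
                     post_bleach_residual=n_residual, mixture=result,
                     valid=valid, diagnostics=diagnostics, **run_labels)


def pool_brightness(runs: Sequence[ToccslRun]) -> np.ndarray:
    """Concatenate accepted spot brightnesses across runs (unweighted
    pooling across cells, the default for per-condition fits)."""
    parts = [r.brightness for r in runs if r.valid]
    return np.concatenate(parts) if parts else np.array([])


def compare_density_groups(
    runs: Sequence[ToccslRun],
    density_cut: float,
    components: list[BrightnessPDF],
    config: ToccslConfig = ToccslConfig(),
) -> dict:
    """Compare oligomer fractions between low- and high-density cells.

    Runs are split by their pre-bleach density estimate at ``density_cut``
    (molecules/um^2); spots are pooled within each group and fitted with
    bootstrap errors.  The headline number is the dimer-fraction difference
    |delta alpha_2| with its combined bootstrap SE: under
    density-independent oligomerization it should stay within ~2 SE.
    """
    low = [r for r in runs if r.valid and r.density is not None
           and r.density.density < density_cut]
    high = [r for r in runs if r.valid and r.density is not None
            and r.density.density >= density_cut]
    if not low or not high:
        raise ValidationError("both density groups must be non-empty")
    out = {}
    for name, group in (("low", low), ("high", high)):
        b = pool_brightness(group)
        res = mx.fit_mixture_with_bootstrap(
            b, components, n_reps=config.bootstrap_reps,
            subsample_fraction=config.bootstrap_fraction, seed=config.seed)
        out[name] = {
            "result": res,
            "n_runs": len(group),
            "mean_density": float(np.mean([r.density.density for r in group])),
        }
    a_lo, a_hi = out["low"]["result"], out["high"]["result"]
    delta = a_hi.alpha[1] - a_lo.alpha[1] if config.n_max >= 2 else 0.0
    comb_se = float(np.sqrt(a_lo.alpha_se[1] ** 2 + a_hi.alpha_se[1] ** 2)) \
        if config.n_max >= 2 else np.nan
    out["delta_alpha2"] = float(delta)
    out["combined_se"] = comb_se
    return out


# ---------------------------------------------------------------------------
# repeated TOCCSL

def exchange_model_predict(
    alpha_true,
    unbleached_fraction_schedule,
    regime: str = "stable",
) -> np.ndarray:
    """Apparent oligomer fractions per run under the two mixing regimes.

    ``unbleached_fraction_schedule`` gives f_k, the fraction of subunits
    still fluorescent when run k is imaged; it must lie in (0, 1] and be
    non-increasing.  Stable complexes are all-or-none bleached, so the
    apparent distribution among visible spots equals ``alpha_true`` for
    every f.  Under fast exchange the fluorescent subunits are binomially
    re-assigned: a true N-mer carries j active fluorophores with
    probability C(N, j) f^j (1-f)^(N-j), and the apparent fraction of
    j-mers among visible spots (j >= 1) follows by normalizing out the
    fully dark complexes.  For a monomer/dimer population this reduces to
    d f^2 / (m f + d (2 f (1-f) + f^2)) for the apparent dimer fraction.
    """
    alpha = np.asarray(alpha_true, dtype=float)
    if np.any(alpha < 0) or abs(alpha.sum() - 1.0) > 1e-9:
        raise ValidationError("alpha_true must be a probability vector")
    f = np.asarray(unbleached_fraction_schedule, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValidationError("unbleached fractions must lie in (0, 1]")
    if np.any(np.diff(f) > 1e-9):
        raise ValidationError("unbleached fractions must be non-increasing")
    n_max = alpha.size
    if regime == "stable":
        return np.tile(alpha, (f.size, 1))
    if regime != "fast":
        raise ValidationError(f"unknown regime {regime!r}")
    out = np.zeros((f.size, n_max))
    for k, fk in enumerate(f):
        vis = np.zeros(n_max)
        for j in range(1, n_max + 1):
            vis[j - 1] = sum(
                alpha[N - 1] * comb(N, j) * fk**j * (1 - fk) ** (N - j)
                for N in range(j, n_max + 1))
        total = vis.sum()   # = 1 - sum alpha_N (1-f)^N
        if total <= 0:
            raise ValidationError("no visible spots at this bleach level")
        out[k] = vis / total
    return out


def apparent_alpha(alpha_complex, active_fraction: float) -> np.ndarray:
    """Spot-level fractions observed when each subunit of an
    ``alpha_complex``-distributed population is fluorescent independently
    with probability ``active_fraction`` (binomial thinning, dark
    complexes excluded).  The fractions the pipeline reports are
    spot-level; this converts explicitly from complex level."""
    return exchange_model_predict(alpha_complex, [active_fraction],
                                  "fast")[0]


def complex_alpha(alpha_apparent, active_fraction: float) -> np.ndarray:
    """Inverse of :func:`apparent_alpha`: the underlying complex-level
    distribution whose thinned image matches the observed spot-level
    fractions (fixed-point inversion of the binomial thinning map)."""
    return _deapparent(np.asarray(alpha_apparent, dtype=float),
                       float(active_fraction))


def runs_from_repeat_simulation(
    observations: Sequence[RepeatRunObservation], **labels
) -> list[ToccslRun]:
    """Wrap population-level repeat-TOCCSL observations as analyzed runs."""
    runs = []
    for obs in observations:
        table = pd.DataFrame({
            "frame": 0, "x": np.nan, "y": np.nan, "sigma": np.nan,
            "B": obs.brightness, "uncertainty": np.nan, "status": "ok",
        })
        runs.append(ToccslRun(recovery_spots=table, run_index=obs.run_index,
                              elapsed=obs.elapsed, n_visible=obs.n_visible,
                              **labels))
    return runs


def _wls_slope(x, y, se):
    """Weighted least-squares slope with an error-scaled uncertainty.

    The per-point bootstrap errors understate between-run dispersion (they
    see only spot-sampling noise, not the finite visible pool or the
    small-sample behaviour of the constrained fit), so the slope SE is
    inflated by sqrt(reduced chi-square) when the fit is overdispersed.
    """
    w = 1.0 / np.clip(np.asarray(se, dtype=float), 1e-6, None) ** 2
    W = w.sum()
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    sxx = np.sum(w * (x - xb) ** 2)
    slope = np.sum(w * (x - xb) * (y - yb)) / sxx
    intercept = yb - slope * xb
    se_slope = np.sqrt(1.0 / sxx)
    dof = len(x) - 2
    if dof > 0:
        chi2red = np.sum(w * (y - intercept - slope * x) ** 2) / dof
        se_slope *= np.sqrt(max(chi2red, 1.0))
    return slope, se_slope


def analyze_repeat_toccsl(
    runs: Sequence[ToccslRun],
    components: list[BrightnessPDF],
    config: ToccslConfig = ToccslConfig(),
) -> StabilityReport:
    """Stability verdict from a repeated TOCCSL series.

    Spots are pooled by run index across cells and each run index fitted
    with bootstrap errors (indices with fewer than
    ``config.min_spots_for_fit`` pooled spots are excluded and listed).
    The dimer fraction alpha_2 is regressed on run index by weighted least
    squares; the per-run series is also compared against the stable and
    fast-exchange predictions of :func:`exchange_model_predict`, with the
    bleach depth per run inferred from the visible-spot depletion trace.
    Verdict: ``exchanging`` when the dimer fraction decreases by more than
    3 SE per the slope test *and* the mixing model out-fits the stable
    model; ``stable`` when the slope is within 3 SE of zero and the stable
    model fits at least as well; otherwise ``inconclusive``.
    """
    by_index: dict[int, list[ToccslRun]] = {}
    for r in runs:
        if r.valid:
            by_index.setdefault(r.run_index, []).append(r)
    indices = sorted(by_index)
    if len(indices) < 2:
        return StabilityReport(
            run_indices=np.asarray(indices), alpha_per_run=np.zeros((0, 0)),
            alpha_se_per_run=np.zeros((0, 0)), dimer_slope=np.nan,
            dimer_slope_se=np.nan, verdict="inconclusive",
            depletion=np.asarray([sum(x.n_visible or 0 for x in by_index[i])
                                  for i in indices]),
            model_sse={}, excluded_runs=[])

    kept, excluded, pooled, depletion = [], [], [], []
    for i in indices:
        b = pool_brightness(by_index[i])
        depletion.append(sum(x.n_visible or len(x.brightness)
                             for x in by_index[i]))
        if b.size < config.min_spots_for_fit:
            excluded.append(i)
            continue
        kept.append(i)
        pooled.append(b)
    depletion = np.asarray(depletion)

    if config.equalize_run_sampling and len(pooled) > 1:
        # the constrained fit's small-sample behaviour depends on n, so a
        # 10x depletion across runs would masquerade as a trend; fitting
        # every run on the same number of spots removes that gradient
        m = min(b.size for b in pooled)
        rng = np.random.default_rng(config.seed)
        pooled = [b if b.size == m else rng.choice(b, size=m, replace=False)
                  for b in pooled]

    alphas, ses = [], []
    for i, b in zip(kept, pooled):
        res = mx.fit_mixture_with_bootstrap(
            b, components, n_reps=config.bootstrap_reps,
            subsample_fraction=config.bootstrap_fraction,
            seed=config.seed + i)
        alphas.append(res.alpha)
        ses.append(res.alpha_se)
    if len(kept) < 2:
        return StabilityReport(
            run_indices=np.asarray(kept),
            alpha_per_run=np.asarray(alphas).reshape(len(kept), -1),
            alpha_se_per_run=np.asarray(ses).reshape(len(kept), -1),
            dimer_slope=np.nan, dimer_slope_se=np.nan,
            verdict="inconclusive", depletion=depletion,
            model_sse={}, excluded_runs=excluded)

    alphas = np.vstack(alphas)
    ses = np.vstack(ses)
    x = np.asarray(kept, dtype=float)
    slope, slope_se = _wls_slope(x, alphas[:, 1], ses[:, 1])

    # infer the per-run bleach survival from the depletion trace (stable
    # approximation: visible count proportional to unbleached fraction)
    dep = np.asarray([depletion[indices.index(i)] for i in kept], dtype=float)
    with np.errstate(divide="ignore"):
        ratios = dep / dep[0]
    pos = ratios > 0
    if pos.sum() >= 2:
        decay = np.polyfit(x[pos], np.log(ratios[pos]), 1)[0]
        survival = float(np.exp(decay))
    else:
        survival = 1.0
    survival = min(max(survival, 1e-3), 1.0)
    # run k is imaged after k mixing intervals; the bleach pulse of run k
    # removes whole complexes and leaves the visible composition untouched
    f_schedule = survival ** (x - x[0])

    sse = {}
    for regime in ("stable", "fast"):
        pred = exchange_model_predict(alphas[0] if regime == "stable"
                                      else _deapparent(alphas[0], f_schedule[0]),
                                      f_schedule, regime)
        resid = (alphas[:, 1] - pred[:, 1]) / np.clip(ses[:, 1], 1e-6, None)
        sse[regime] = float(np.sum(resid**2))

    # subunit exchange can only shift the apparent distribution toward
    # monomers, so only a *decreasing* dimer trend argues for exchange;
    # the slope test and the explicit model comparison must agree.  The
    # 3-SE window absorbs the residual dispersion the bootstrap errors do
    # not see (finite visible pool, n-dependence of the constrained fit).
    if slope < -3.0 * slope_se and sse["fast"] < sse["stable"]:
        verdict = "exchanging"
    elif abs(slope) < 3.0 * slope_se and sse["stable"] <= sse["fast"]:
        verdict = "stable"
    else:
        verdict = "inconclusive"
    return StabilityReport(
        run_indices=np.asarray(kept), alpha_per_run=alphas,
        alpha_se_per_run=ses, dimer_slope=float(slope),
        dimer_slope_se=float(slope_se), verdict=verdict,
        depletion=depletion, model_sse=sse, excluded_runs=excluded)


def _deapparent(apparent_alpha: np.ndarray, f: float) -> np.ndarray:
    """Invert the binomial thinning of the first observed run to recover an
    underlying size distribution for the fast-exchange prediction.

    For the shallow first-run bleach depths used here the apparent and
    underlying distributions are close; a short fixed-point iteration on
    the thinning map suffices and keeps the prediction self-consistent.
    """
    alpha = np.clip(np.asarray(apparent_alpha, dtype=float), 0, None)
    alpha /= alpha.sum()
    target = alpha.copy()
    for _ in range(200):
        pred = exchange_model_predict(alpha, [f], "fast")[0]
        err = target - pred
        if np.max(np.abs(err)) < 1e-10:
            break
        alpha = np.clip(alpha + err, 1e-12, None)
        alpha /= alpha.sum()
    return alpha
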