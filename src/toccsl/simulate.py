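"""Synthetic single-molecule data with known ground truth.

This module emulates the experimental regime the analysis pipeline is built
for: fluorescently labelled membrane-protein complexes (n-mers) diffusing in
a supported plasma membrane at 5-40 molecules/um^2, imaged by TIRF through a
CCD camera, photobleached through a rectangular field stop (TOCCSL), and
probed by FRAP and single-molecule tracking.  Every generator takes explicit
ground truth and a seedable random generator so that each downstream
estimator can be verified by parameter recovery.

Physical model
--------------
* Complexes are point emitters; the N subunits of a complex are co-located
  and each carries one fluorophore (configurable labelling fraction).
* Single-fluorophore brightness per exposure is lognormal with configurable
  mean and coefficient of variation (CV = 0 degenerates to a constant);
  the brightness of an n-mer is the sum of its active subunits' draws.
* Motion is 2-D Brownian with per-axis step variance 2 D dt; an immobile
  subpopulation (1 - mobile_fraction) has D = 0.
* Bleaching is binary per fluorophore: anything inside the field-stop
  region during the bleach pulse is switched off (subject to a configurable
  efficiency); edge effects arise from diffusion across the region boundary
  during the 800 ms pulse, sampled at sub-steps.
* Camera: Poisson shot noise on the photon field, then
  counts = offset + photons / inverse_gain + Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .types import (
    CameraModel,
    ComplexPopulation,
    FrameStack,
    GroundTruth,
    ProtocolTimings,
    ValidationError,
    as_rng,
)

__all__ = [
    "draw_monomer_brightness",
    "simulate_brightness_samples",
    "simulate_frap_curve",
    "simulate_trajectories",
    "population_from_truth",
    "apply_subunit_exchange",
    "render_photons",
    "photons_to_counts",
    "simulate_toccsl_movie",
    "simulate_repeat_toccsl",
    "RepeatRunObservation",
]


# ---------------------------------------------------------------------------
# brightness draws

def draw_monomer_brightness(mean: float, cv: float, size, rng) -> np.ndarray:
    """Draw single-fluorophore brightness values (photons per exposure).

    Lognormal with the requested arithmetic mean and coefficient of
    variation; ``cv = 0`` returns the constant ``mean``.
    """
    if mean <= 0:
        raise ValidationError("monomer brightness mean must be positive")
    if cv < 0:
        raise ValidationError("monomer brightness CV must be non-negative")
    rng = as_rng(rng)
    if cv == 0:
        return np.full(size, float(mean))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def simulate_brightness_samples(
    truth: GroundTruth, n_spots: int, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw single-spot brightness values from the true oligomer mixture.

    Each spot's oligomer size N is drawn from ``truth.alpha_true``; its
    brightness is the sum of N independent single-fluorophore draws.

    Returns
    -------
    brightness : ndarray, shape (n_spots,)
        Spot brightness in photons.
    labels : ndarray of int, shape (n_spots,)
        The ground-truth oligomer size of each spot, for recovery tests.
    """
    if n_spots < 1:
        raise ValidationError("n_spots must be at least 1")
    rng = as_rng(rng)
    alpha = np.asarray(truth.alpha_true, dtype=float)
    sizes = rng.choice(np.arange(1, alpha.size + 1), size=n_spots, p=alpha)
    brightness = np.zeros(n_spots)
    for n in range(1, alpha.size + 1):
        mask = sizes == n
        k = int(mask.sum())
        if k == 0:
            continue
        draws = draw_monomer_brightness(
            truth.monomer_brightness_mean, truth.monomer_brightness_cv,
            (k, n), rng)
        brightness[mask] = draws.sum(axis=1)
    return brightness, sizes


# ---------------------------------------------------------------------------
# FRAP and trajectories

def simulate_frap_curve(
    mobile_fraction: float, tau: float, timestamps, noise_sd: float = 0.0,
    rng=None,
) -> np.ndarray:
    """Normalized FRAP recovery curve m * (1 - exp(-t / tau)) + noise."""
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValidationError("mobile_fraction must lie in [0, 1]")
    if tau <= 0:
        raise ValidationError("tau must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    t = np.asarray(timestamps, dtype=float)
    curve = mobile_fraction * -np.expm1(-t / tau)
    if noise_sd > 0:
        curve = curve + as_rng(rng).normal(0.0, noise_sd, size=t.shape)
    return curve


def simulate_trajectories(
    D: float, dt: float, n_steps: int, n_tracks: int, rng=None
) -> np.ndarray:
    """Brownian 2-D trajectories starting at the origin.

    Per-step displacements are independent Gaussian with variance
    ``2 D dt`` per axis.

    Returns an array of shape ``(n_tracks, n_steps + 1, 2)`` in um.
    """
    if D < 0:
        raise ValidationError("D must be non-negative")
    if dt <= 0:
        raise ValidationError("dt must be positive")
    rng = as_rng(rng)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt),
                       size=(n_tracks, n_steps, 2))
    pos = np.zeros((n_tracks, n_steps + 1, 2))
    np.cumsum(steps, axis=1, out=pos[:, 1:, :])
    return pos


# ---------------------------------------------------------------------------
# populations and subunit exchange

def population_from_truth(
    truth: GroundTruth, n_complexes: int, rng=None
) -> ComplexPopulation:
    """Sample a complex population with sizes drawn from ``alpha_true``.

    Subunits are labelled fluorescent independently with probability
    ``truth.labeling_fraction`` (default 1: every subunit active).
    """
    rng = as_rng(rng)
    alpha = np.asarray(truth.alpha_true, dtype=float)
    sizes = rng.choice(np.arange(1, alpha.size + 1), size=n_complexes, p=alpha)
    n_sub = int(sizes.sum())
    if truth.labeling_fraction >= 1.0:
        active = np.ones(n_sub, dtype=bool)
    else:
        active = rng.random(n_sub) < truth.labeling_fraction
    return ComplexPopulation(sizes=sizes, active=active)


def apply_subunit_exchange(
    population: ComplexPopulation, exchange_rate: float, elapsed: float,
    rng=None,
) -> ComplexPopulation:
    """Randomly re-pair subunits between complexes.

    Each complex independently undergoes complete subunit randomization with
    probability ``1 - exp(-exchange_rate * elapsed)``; the subunit labels of
    all randomizing complexes are pooled, permuted, and dealt back into the
    same size structure.  A rate of zero returns an identical copy; in the
    fast-exchange limit every fluorescent label is assigned binomially at
    the global unbleached fraction.  The total number of fluorescent
    subunits is conserved exactly.
    """
    if exchange_rate < 0:
        raise ValidationError("exchange_rate must be non-negative")
    if elapsed < 0:
        raise ValidationError("elapsed must be non-negative")
    out = population.copy()
    p_mix = float(-np.expm1(-exchange_rate * elapsed))
    if p_mix == 0.0:
        return out
    rng = as_rng(rng)
    mixing = rng.random(out.sizes.size) < p_mix
    if not np.any(mixing):
        return out
    subunit_in_mix = np.repeat(mixing, out.sizes)
    labels = out.active[subunit_in_mix]
    out.active[subunit_in_mix] = rng.permutation(labels)
    return out


# ---------------------------------------------------------------------------
# camera rendering

def render_photons(
    positions_um: np.ndarray, brightness: np.ndarray, camera: CameraModel,
    background_photons: float = 0.0,
) -> np.ndarray:
    """Render point emitters into an expected-photon image.

    Each emitter deposits ``brightness[i]`` photons spread as a 2-D Gaussian
    of width ``camera.psf_sigma`` integrated exactly over pixel areas
    (half-open pixel intervals, pixel (0, 0) at the top-left).  Emitters
    outside the field of view contribute whatever PSF tail falls inside.
    """
    h, w = camera.field_of_view
    img = np.full((h, w), float(background_photons))
    if len(positions_um) == 0:
        return img
    pos = np.asarray(positions_um, dtype=float)
    bright = np.asarray(brightness, dtype=float)
    sig = camera.psf_sigma_px
    col = pos[:, 0] / camera.pixel_size       # x -> column
    row = pos[:, 1] / camera.pixel_size       # y -> row
    r = int(np.ceil(4.0 * sig)) + 1
    # keep only emitters whose stamp can intersect the frame
    keep = (row > -r) & (row < h + r) & (col > -r) & (col < w + r)
    if not np.any(keep):
        return img
    row, col, bright = row[keep], col[keep], bright[keep]
    m = row.size
    c0 = np.floor(col).astype(int)
    r0 = np.floor(row).astype(int)
    span = np.arange(-r, r + 1)
    # PSF mass per pixel: difference of Gaussian CDFs at the pixel edges
    def edge_weights(center, base):
        edges = base[:, None] + np.concatenate([span, [span[-1] + 1]])[None, :]
        z = (edges - center[:, None]) / sig
        return np.diff(ndtr(z), axis=1)           # (m, 2r+1)

    wr = edge_weights(row, r0.astype(float))
    wc = edge_weights(col, c0.astype(float))
    stamp = bright[:, None, None] * wr[:, :, None] * wc[:, None, :]
    rows = (r0[:, None] + span[None, :])[:, :, None] + np.zeros(
        (1, 1, span.size), dtype=int)
    cols = (c0[:, None] + span[None, :])[:, None, :] + np.zeros(
        (1, span.size, 1), dtype=int)
    rows = np.broadcast_to(rows, stamp.shape).ravel()
    cols = np.broadcast_to(cols, stamp.shape).ravel()
    vals = stamp.ravel()
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    np.add.at(img, (rows[inside], cols[inside]), vals[inside])
    return img


def photons_to_counts(
    photons: np.ndarray, camera: CameraModel, rng=None, shot_noise: bool = True
) -> np.ndarray:
    """Convert an expected-photon image to noisy camera counts."""
    rng = as_rng(rng)
    field = rng.poisson(np.clip(photons, 0, None)).astype(float) \
        if shot_noise else np.asarray(photons, dtype=float)
    counts = camera.offset + field / camera.inverse_gain
    if camera.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, camera.read_noise_sd,
                                     size=counts.shape)
    return counts


# ---------------------------------------------------------------------------
# full TOCCSL / FRAP movie

def _default_bleach_region_um(camera: CameraModel) -> tuple[float, float, float, float]:
    h, w = camera.field_of_view
    wx = w * camera.pixel_size
    wy = h * camera.pixel_size
    # central square covering ~55% of the linear field
    fx, fy = 0.55 * wx, 0.55 * wy
    return ((wx - fx) / 2, (wy - fy) / 2, (wx + fx) / 2, (wy + fy) / 2)


def simulate_toccsl_movie(
    truth: GroundTruth,
    timings: ProtocolTimings | None = None,
    camera: CameraModel | None = None,
    *,
    bleach_region_um: tuple[float, float, float, float] | None = None,
    domain_margin_um: float = 3.0,
    recovery_times_ms=None,
    bleach_efficiency: float = 1.0,
    background_photons: float = 0.0,
    n_bleach_substeps: int = 8,
    spot_separation_limit_um: float | None = None,
    rng=None,
) -> FrameStack:
    """Simulate one TOCCSL run as a camera-count frame stack.

    The protocol: a pre-bleach frame at t = 0, a high-power pulse of
    duration ``t_bleach`` confined to the field-stop rectangle, a
    post-bleach control frame ``t_post`` after the pulse, and one recovery
    (TOCCSL) frame after ``t_recovery`` — or several, at
    ``recovery_times_ms`` after the pulse, which turns the run into a FRAP
    series.  Molecules live in a domain extending ``domain_margin_um``
    beyond the field of view so that recovery is fed by a realistic
    reservoir.  Fluorophores found inside the bleach region at any of
    ``n_bleach_substeps`` instants during the pulse are switched off with
    probability ``bleach_efficiency`` (1 = ideal binary bleaching; 0
    disables the pulse entirely).

    An immobile subpopulation ``1 - truth.mobile_fraction`` does not
    diffuse; complexes bleached inside the region therefore never recover,
    so the recovery image reports the mobile pool only.

    If the visible spots in the recovery analysis region are denser than a
    separation limit (default ``4 * psf_sigma``) allows, a crowding warning
    is recorded in ``stack.metadata`` rather than raised.
    """
    timings = timings or ProtocolTimings()
    camera = camera or CameraModel()
    rng = as_rng(rng)
    if bleach_region_um is None:
        bleach_region_um = _default_bleach_region_um(camera)
    if not 0.0 <= bleach_efficiency <= 1.0:
        raise ValidationError("bleach_efficiency must lie in [0, 1]")
    bx0, by0, bx1, by1 = bleach_region_um
    h, w = camera.field_of_view
    fov_x = w * camera.pixel_size
    fov_y = h * camera.pixel_size
    if not (0 <= bx0 < bx1 <= fov_x and 0 <= by0 < by1 <= fov_y):
        raise ValidationError("bleach region must lie inside the field of view")
    if (bx1 - bx0) * (by1 - by0) >= fov_x * fov_y:
        raise ValidationError("bleach region must be smaller than the field of view")

    # --- populate the domain -------------------------------------------
    lo_x, hi_x = -domain_margin_um, fov_x + domain_margin_um
    lo_y, hi_y = -domain_margin_um, fov_y + domain_margin_um
    area = (hi_x - lo_x) * (hi_y - lo_y)
    n_complexes = int(round(truth.surface_density * area / truth.mean_complex_size))
    pop = population_from_truth(truth, n_complexes, rng)
    pos = np.column_stack([
        rng.uniform(lo_x, hi_x, n_complexes),
        rng.uniform(lo_y, hi_y, n_complexes),
    ])
    mobile = rng.random(n_complexes) < truth.mobile_fraction
    offsets = pop.offsets

    def diffuse(pos, dt_s):
        if dt_s <= 0:
            return pos
        step = rng.normal(0.0, np.sqrt(2.0 * truth.diffusion_coeff * dt_s),
                          size=pos.shape)
        step[~mobile] = 0.0
        new = pos + step
        # reflecting domain walls keep the reservoir density stationary
        new[:, 0] = lo_x + np.abs(new[:, 0] - lo_x)
        new[:, 0] = hi_x - np.abs(hi_x - new[:, 0])
        new[:, 1] = lo_y + np.abs(new[:, 1] - lo_y)
        new[:, 1] = hi_y - np.abs(hi_y - new[:, 1])
        return new

    def in_region(pos):
        return ((pos[:, 0] >= bx0) & (pos[:, 0] < bx1)
                & (pos[:, 1] >= by0) & (pos[:, 1] < by1))

    def render(pos):
        n_act = pop.n_active_per_complex
        vis = n_act > 0
        draws = np.zeros(n_act.size)
        if np.any(vis):
            # per-frame fresh brightness draw for every active fluorophore
            per_sub = draw_monomer_brightness(
                truth.monomer_brightness_mean, truth.monomer_brightness_cv,
                pop.active.size, rng)
            per_sub[~pop.active] = 0.0
            draws = np.add.reduceat(per_sub, offsets[:-1])
        photons = render_photons(pos[vis], draws[vis], camera,
                                 background_photons)
        return photons_to_counts(photons, camera, rng)

    frames, timestamps, roles = [], [], []
    t = 0.0

    # pre-bleach frame
    frames.append(render(pos))
    timestamps.append(t)
    roles.append("pre-bleach")

    # pause before the pulse, then the pulse itself at sub-steps
    pos = diffuse(pos, timings.t_pre / 1000.0)
    t += timings.t_pre / 1000.0
    sub_dt = timings.t_bleach / 1000.0 / n_bleach_substeps
    # bleach_efficiency is the whole-pulse bleach probability for a
    # fluorophore that stays inside the region; convert to per-substep
    p_sub = (1.0 if bleach_efficiency >= 1.0
             else 1.0 - (1.0 - bleach_efficiency) ** (1.0 / n_bleach_substeps))
    for _ in range(n_bleach_substeps):
        inside = in_region(pos)
        if bleach_efficiency > 0 and np.any(inside):
            sub_mask = np.repeat(inside, pop.sizes)
            if p_sub >= 1.0:
                pop.active[sub_mask] = False
            else:
                zap = rng.random(int(sub_mask.sum())) < p_sub
                idx = np.flatnonzero(sub_mask)
                pop.active[idx[zap]] = False
        pos = diffuse(pos, sub_dt)
        t += sub_dt

    # post-bleach control frame
    pos = diffuse(pos, timings.t_post / 1000.0)
    t += timings.t_post / 1000.0
    frames.append(render(pos))
    timestamps.append(t)
    roles.append("post-bleach")

    # recovery frame(s)
    t_pulse_end = t - timings.t_post / 1000.0
    if recovery_times_ms is None:
        recovery_times_ms = [timings.t_recovery]
    rec_times = np.sort(np.asarray(recovery_times_ms, dtype=float))
    for t_rec in rec_times:
        target = t_pulse_end + t_rec / 1000.0
        if target <= t:
            raise ValidationError("recovery times must follow the post-bleach frame")
        pos = diffuse(pos, target - t)
        t = target
        frames.append(render(pos))
        timestamps.append(t)
        roles.append("recovery")

    # crowding diagnostic in the final recovery frame
    vis = (pop.n_active_per_complex > 0) & in_region(pos)
    sep_limit = spot_separation_limit_um or 4.0 * camera.psf_sigma
    crowded = 0
    pts = pos[vis]
    if len(pts) > 1:
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        crowded = int(np.sum(d2.min(axis=1) < sep_limit**2))

    region_px = (
        int(np.floor(by0 / camera.pixel_size)),
        int(np.floor(bx0 / camera.pixel_size)),
        int(np.ceil(by1 / camera.pixel_size)),
        int(np.ceil(bx1 / camera.pixel_size)),
    )
    meta = {
        "truth": {
            "surface_density": truth.surface_density,
            "alpha_true": list(truth.alpha_true),
            "diffusion_coeff": truth.diffusion_coeff,
            "mobile_fraction": truth.mobile_fraction,
            "monomer_brightness_mean": truth.monomer_brightness_mean,
            "monomer_brightness_cv": truth.monomer_brightness_cv,
            "seed": truth.seed,
        },
        "n_complexes": n_complexes,
        "bleach_region_um": list(bleach_region_um),
        "n_visible_in_region_at_recovery": int(vis.sum()),
        "n_crowded_spots": crowded,
        "crowding_warning": bool(len(pts) > 0 and crowded > 0.05 * len(pts)),
    }
    return FrameStack(
        frames=np.stack(frames),
        timestamps=np.asarray(timestamps),
        roles=roles,
        bleach_region=region_px,
        camera=camera,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# repeated TOCCSL at the population level

@dataclass
class RepeatRunObservation:
    """Pooled observation of one run index in a repeated TOCCSL protocol."""

    run_index: int
    elapsed: float                    # s since the first bleach pulse
    brightness: np.ndarray            # photons, pooled over cells
    apparent_sizes: np.ndarray        # active fluorophores per observed spot
    n_visible: int                    # visible complexes summed over cells
    active_fraction: float            # global fluorescent subunit fraction


def simulate_repeat_toccsl(
    truth: GroundTruth,
    timings: ProtocolTimings | None = None,
    *,
    n_cells: int = 20,
    complexes_per_cell: int = 400,
    bleach_fraction: float = 0.25,
    observe_fraction: float = 0.2,
    rng=None,
) -> list[RepeatRunObservation]:
    """Simulate the repeated TOCCSL protocol at the complex-population level.

    Each of ``timings.n_runs`` runs bleaches a random fraction
    ``bleach_fraction`` of every cell's complexes (bleaching acts on whole
    complexes because subunits are co-located during the pulse) and then
    observes a random subset ``observe_fraction`` of the remaining visible
    complexes in the recovery image; between runs the population mixes for
    ``timings.run_interval`` seconds under ``truth.exchange_rate``.

    Stable complexes (rate 0) keep their all-or-none labelling, so the
    observed composition stays at ``alpha_true`` while the visible-spot
    count depletes run over run.  With fast exchange, bleached and
    fluorescent subunits re-pair and the apparent distribution shifts
    toward monomers — the discriminating signature the repeated protocol
    exists to detect.
    """
    timings = timings or ProtocolTimings()
    if not 0.0 < bleach_fraction < 1.0:
        raise ValidationError("bleach_fraction must lie in (0, 1)")
    if not 0.0 < observe_fraction <= 1.0:
        raise ValidationError("observe_fraction must lie in (0, 1]")
    rng = as_rng(rng)

    cells = [population_from_truth(truth, complexes_per_cell, rng)
             for _ in range(n_cells)]
    runs: list[RepeatRunObservation] = []
    for k in range(timings.n_runs):
        all_b, all_sizes, n_vis, act = [], [], 0, []
        for pop in cells:
            # bleach pulse: whole complexes, positional
            zap = rng.random(pop.sizes.size) < bleach_fraction
            pop.active[np.repeat(zap, pop.sizes)] = False
            n_active = pop.n_active_per_complex
            visible = np.flatnonzero(n_active > 0)
            n_vis += visible.size
            act.append(pop.active_fraction)
            if visible.size:
                chosen = visible[rng.random(visible.size) < observe_fraction]
                for idx in chosen:
                    k_act = int(n_active[idx])
                    b = draw_monomer_brightness(
                        truth.monomer_brightness_mean,
                        truth.monomer_brightness_cv, k_act, rng).sum()
                    all_b.append(b)
                    all_sizes.append(k_act)
        runs.append(RepeatRunObservation(
            run_index=k,
            elapsed=k * timings.run_interval,
            brightness=np.asarray(all_b, dtype=float),
            apparent_sizes=np.asarray(all_sizes, dtype=int),
            n_visible=n_vis,
            active_fraction=float(np.mean(act)),
        ))
        # mixing between runs
        for i, pop in enumerate(cells):
            cells[i] = apply_subunit_exchange(
                pop, truth.exchange_rate, timings.run_interval, rng)
    return runs
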