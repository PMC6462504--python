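"""Mobile-fraction (FRAP) and diffusion-coefficient (MSD) estimation.

FRAP: the integrated intensity of the central part of the bleached region,
normalized to the pre-bleach image, is fitted with the bounded recovery
model ``I/I0 = m * (1 - exp(-t / tau))`` where ``m`` in [0, 1] is the
mobile fraction and ``tau`` the recovery time constant.

MSD: time-ensemble averaged mean square displacements of 2-D trajectories;
for Brownian motion ``MSD = 4 D t_lag + offset``, the offset reflecting
static localization error.  ``D`` is determined from the first two MSD
points by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lmfit import Model

from .types import (
    DiffusionFit,
    FrameStack,
    FrapFit,
    ValidationError,
)

__all__ = ["normalize_frap", "fit_frap", "compute_msd", "fit_diffusion"]


def normalize_frap(
    stack: FrameStack, roi_margin: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized recovery curve I/I0 from a FRAP frame stack.

    The analysis ROI is the bleach rectangle eroded by ``roi_margin`` of
    its width on each side (default 25%, i.e. the central part).  Counts
    are integrated over the ROI, dark level removed (camera offset if a
    camera is attached to the stack), and normalized to the mean
    pre-bleach value.  Time zero is the first post-bleach timestamp.

    Returns ``(t, curve)`` with t in seconds from the end of the pulse.
    """
    if not 0.0 <= roi_margin < 0.5:
        raise ValidationError("roi_margin must lie in [0, 0.5)")
    pre = stack.frames_with_role("pre-bleach")
    rec = stack.frames_with_role("recovery")
    if not pre:
        raise ValidationError("at least one pre-bleach frame required")
    if not rec:
        raise ValidationError("at least one recovery frame required")
    r0, c0, r1, c1 = stack.bleach_region
    dr = int(round((r1 - r0) * roi_margin))
    dc = int(round((c1 - c0) * roi_margin))
    rr0, rr1 = r0 + dr, r1 - dr
    cc0, cc1 = c0 + dc, c1 - dc
    if rr1 <= rr0 or cc1 <= cc0:
        raise ValidationError("ROI margin leaves an empty analysis region")
    dark = stack.camera.offset if stack.camera is not None else 0.0
    n_px = (rr1 - rr0) * (cc1 - cc0)

    def roi_sum(i):
        return float(stack.frames[i, rr0:rr1, cc0:cc1].sum()) - dark * n_px

    i0 = float(np.mean([roi_sum(i) for i in pre]))
    if i0 <= 0:
        raise ValidationError("pre-bleach ROI intensity must be positive")
    post = stack.frames_with_role("post-bleach")
    t0 = stack.timestamps[post[0]] if post else stack.timestamps[rec[0]]
    t = np.array([stack.timestamps[i] - t0 for i in rec])
    curve = np.array([roi_sum(i) / i0 for i in rec])
    return t, curve


def fit_frap(t, curve, weights=None) -> FrapFit:
    """Fit m * (1 - exp(-t / tau)) to a normalized recovery curve.

    Weighted least squares with the mobile fraction bounded to [0, 1].
    Degenerate data are flagged rather than hidden: a vanishing mobile
    fraction leaves tau unidentifiable (``tau-unidentifiable``), and a
    series shorter than twice the fitted tau has no reliable plateau
    (``plateau-not-reached``).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(curve, dtype=float)
    if t.size != y.size or t.size < 5:
        raise ValidationError("at least 5 matching timepoints required")

    def recovery(t, m, tau):
        return m * -np.expm1(-t / tau)

    model = Model(recovery)
    params = model.make_params(
        m=dict(value=min(max(float(y[-1]), 0.05), 1.0), min=0.0, max=1.0),
        tau=dict(value=max(float(t[-1]) / 4.0, 1e-3), min=1e-6),
    )
    flags: list[str] = []
    try:
        out = model.fit(y, params, t=t, weights=weights)
    except Exception:
        raise ValidationError("FRAP fit failed to converge") from None
    m = float(out.params["m"].value)
    tau = float(out.params["tau"].value)
    m_se = float(out.params["m"].stderr or np.nan)
    tau_se = float(out.params["tau"].stderr or np.nan)
    if m < 1e-3:
        flags.append("tau-unidentifiable")
    if t[-1] < 2.0 * tau:
        flags.append("plateau-not-reached")
        if np.isnan(tau_se):
            tau_se = np.inf
    return FrapFit(mobile_fraction=min(max(m, 0.0), 1.0), tau=tau,
                   mobile_fraction_se=m_se, tau_se=tau_se,
                   n_timepoints=int(t.size), flags=flags)


def compute_msd(
    trajectories: np.ndarray, dt: float, max_lag: int | None = None
) -> pd.DataFrame:
    """Time-ensemble averaged MSD per lag, with standard errors.

    ``trajectories`` has shape ``(n_tracks, n_points, 2)`` in um with a
    uniform time base ``dt`` (seconds).  Within each track all overlapping
    displacement pairs contribute (time averaging); tracks are then pooled
    weighted by their number of contributing pairs.  The quoted standard
    error treats pairs as independent and therefore understates the true
    uncertainty at long lags where pairs overlap heavily.
    """
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 3 or traj.shape[1] < 2 or traj.shape[2] != 2:
        raise ValidationError(
            "trajectories must be (n_tracks, n_points>=2, 2)")
    if dt <= 0:
        raise ValidationError("dt must be positive")
    n_points = traj.shape[1]
    if max_lag is None:
        max_lag = n_points - 1
    if max_lag >= n_points:
        import warnings
        warnings.warn(
            f"max_lag {max_lag} >= trajectory length; truncating",
            stacklevel=2)
        max_lag = n_points - 1
    rows = []
    for lag in range(1, max_lag + 1):
        disp = traj[:, lag:, :] - traj[:, :-lag, :]
        sq = np.sum(disp**2, axis=-1).ravel()
        rows.append({
            "lag": lag,
            "t_lag": lag * dt,
            "msd": float(sq.mean()),
            "se": float(sq.std(ddof=1) / np.sqrt(sq.size)) if sq.size > 1 else np.nan,
            "n_pairs": int(sq.size),
        })
    return pd.DataFrame(rows)


def fit_diffusion(msd: pd.DataFrame, lags_used: int = 2,
                  mode: str = "two-point") -> DiffusionFit:
    """Diffusion coefficient from MSD = 4 D t_lag + offset.

    The default draws the exact line through the first two MSD points
    (slope / 4 = D, intercept = offset), the conventional short-lag
    estimator that avoids the downward-biased long lags.  ``mode='wls'``
    fits a weighted line through the first ``lags_used`` points instead.
    A negative slope clips D at zero with a flag; the offset is reported,
    never subtracted.
    """
    if len(msd) < 2:
        raise ValidationError("at least 2 MSD lags required")
    t = msd["t_lag"].to_numpy(dtype=float)
    y = msd["msd"].to_numpy(dtype=float)
    se = msd["se"].to_numpy(dtype=float)
    flags: list[str] = []
    if mode == "two-point":
        slope = (y[1] - y[0]) / (t[1] - t[0])
        offset = y[0] - slope * t[0]
        se_slope = (np.sqrt(se[0] ** 2 + se[1] ** 2) / (t[1] - t[0])
                    if np.all(np.isfinite(se[:2])) else np.nan)
        lags = 2
    elif mode == "wls":
        if lags_used < 2 or lags_used > len(msd):
            raise ValidationError("lags_used out of range")
        tt, yy, ss = t[:lags_used], y[:lags_used], se[:lags_used]
        w = 1.0 / np.where(np.isfinite(ss) & (ss > 0), ss, np.nanmean(ss)) ** 2
        W = np.sum(w)
        tbar = np.sum(w * tt) / W
        ybar = np.sum(w * yy) / W
        sxx = np.sum(w * (tt - tbar) ** 2)
        slope = np.sum(w * (tt - tbar) * (yy - ybar)) / sxx
        offset = ybar - slope * tbar
        se_slope = np.sqrt(1.0 / sxx)
        lags = lags_used
    else:
        raise ValidationError(f"unknown fit mode {mode!r}")
    D = slope / 4.0
    if D < 0:
        flags.append("negative-slope-clipped")
        D = 0.0
    return DiffusionFit(D=float(D), offset=float(offset),
                        se_D=float(se_slope / 4.0), lags_used=lags,
                        flags=flags)
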