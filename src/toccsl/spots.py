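"""Spot detection, Gaussian fitting and surface-density estimation.

Camera counts are first converted to photons using the calibrated offset
and inverse gain.  Diffraction-limited signals are then detected as local
maxima and fitted with a pixel-integrated 2-D Gaussian; the integrated,
background-corrected photon count of each accepted fit is the single-spot
brightness B that feeds the oligomer mixture analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.special import ndtr
from skimage.feature import peak_local_max

from .types import CameraModel, DensityEstimate, Spot, ValidationError

__all__ = [
    "PhotonImage",
    "counts_to_photons",
    "detect_spots",
    "fit_gaussian_spot",
    "analyze_frame",
    "spots_to_table",
    "estimate_density",
]

SPOT_TABLE_COLUMNS = ["frame", "x", "y", "sigma", "B", "uncertainty", "status"]


@dataclass
class PhotonImage:
    """Photon-converted image plus conversion diagnostics."""

    photons: np.ndarray
    clipped_fraction: float
    n_saturated: int


def counts_to_photons(
    image: np.ndarray, camera: CameraModel, clip: bool = True
) -> PhotonImage:
    """Convert camera counts to photons: (counts - offset) * inverse_gain.

    Negative results (read noise below the offset) are clipped at zero by
    default and the clipped fraction reported; pass ``clip=False`` for
    zero-mean noise, which is what integrated-intensity estimators want.
    Saturated pixels are counted, never silently used.
    """
    image = np.asarray(image, dtype=float)
    h, w = camera.field_of_view
    if image.shape != (h, w):
        raise ValidationError(
            f"image shape {image.shape} does not match camera field {(h, w)}")
    n_sat = int(np.sum(image >= camera.saturation_level))
    photons = (image - camera.offset) * camera.inverse_gain
    clipped = float(np.mean(photons < 0)) if clip else 0.0
    if clip:
        photons = np.clip(photons, 0.0, None)
    return PhotonImage(photons=photons, clipped_fraction=clipped,
                       n_saturated=n_sat)


def detect_spots(
    photons: np.ndarray,
    detection_threshold: float,
    min_separation: float = 5.0,
    merge_radius: int = 2,
    subtract_background: bool = True,
) -> np.ndarray:
    """Find candidate spot positions as isolated local maxima.

    The image median is subtracted as a global background estimate (valid
    for the sparse recovery frames this is designed for).  Candidates are
    local maxima exceeding ``detection_threshold`` photons above
    background; maxima within ``merge_radius`` pixels (shot-noise ripples
    on a single PSF) collapse to the brightest.  Any two surviving
    candidates closer than ``min_separation`` pixels are then *both*
    discarded: an overlapping pair would bias the brightness statistics
    more than the lost events cost.

    Returns an ``(n, 2)`` integer array of (row, col) candidates; empty is
    a legitimate result (e.g. a post-bleach control frame).
    """
    img = np.asarray(photons, dtype=float)
    if subtract_background:
        img = img - np.median(img)
    peaks = peak_local_max(img, min_distance=max(int(merge_radius), 1),
                           threshold_abs=detection_threshold,
                           exclude_border=False)
    if len(peaks) > 1 and min_separation > 0:
        tree = cKDTree(peaks.astype(float))
        pairs = tree.query_pairs(r=min_separation)
        drop = set()
        for i, j in pairs:
            drop.add(i)
            drop.add(j)
        if drop:
            keep = np.setdiff1d(np.arange(len(peaks)), list(drop))
            peaks = peaks[keep]
    return peaks


def _integrated_gaussian_model(params, rows, cols):
    # params: (B, row0, col0, sigma, background)
    B, r0, c0, sig, bg = params
    zr = np.diff(ndtr((np.stack([rows, rows + 1]) - r0) / sig), axis=0)[0]
    zc = np.diff(ndtr((np.stack([cols, cols + 1]) - c0) / sig), axis=0)[0]
    return bg + B * zr * zc


def fit_gaussian_spot(
    photons: np.ndarray,
    candidate,
    camera: CameraModel,
    window: int = 7,
    sigma_band: tuple[float, float] = (0.7, 1.5),
    frame_index: int = 0,
) -> Spot:
    """Fit one candidate with a pixel-integrated 2-D Gaussian.

    The model is ``background + B * G(row, col; sigma)`` where G integrates
    to one over the plane, so the fitted ``B`` is directly the integrated
    spot brightness in photons.  Fits are rejected (with a reason code in
    ``Spot.status``) when the optimizer fails, the amplitude is not
    positive, the fitted width leaves ``sigma_band`` times the nominal PSF
    width, or the fitted centre escapes the window.
    """
    img = np.asarray(photons, dtype=float)
    r_peak, c_peak = int(candidate[0]), int(candidate[1])
    half = window // 2
    r0, r1 = r_peak - half, r_peak + half + 1
    c0, c1 = c_peak - half, c_peak + half + 1
    h, w = img.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        return Spot(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                    frame_index, status="window-out-of-bounds")
    win = img[r0:r1, c0:c1]
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                             indexing="ij")
    rows = rows.ravel().astype(float)
    cols = cols.ravel().astype(float)
    data = win.ravel()

    border = np.concatenate([win[0, :], win[-1, :], win[1:-1, 0], win[1:-1, -1]])
    bg0 = float(np.median(border))
    sig0 = camera.psf_sigma_px
    B0 = max(float(data.sum() - bg0 * data.size), 1e-3)
    x0 = np.array([B0, r_peak + 0.5, c_peak + 0.5, sig0, bg0])

    def residuals(p):
        return _integrated_gaussian_model(p, rows, cols) - data

    try:
        res = least_squares(residuals, x0, method="lm", max_nfev=400)
    except Exception:
        return Spot(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                    frame_index, status="non-convergence")
    B, rc, cc, sig, bg = res.x
    sig = abs(sig)
    if not res.success:
        status = "non-convergence"
    elif B <= 0:
        status = "non-positive-amplitude"
    elif not sigma_band[0] * camera.psf_sigma_px <= sig <= sigma_band[1] * camera.psf_sigma_px:
        status = "sigma-out-of-band"
    elif not (r0 <= rc <= r1 and c0 <= cc <= c1):
        status = "centre-out-of-window"
    else:
        status = "ok"

    # parameter uncertainty from the local linearization
    se_B = np.nan
    dof = data.size - res.x.size
    if dof > 0:
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.inv(jtj) * (2 * res.cost / dof)
            se_B = float(np.sqrt(max(cov[0, 0], 0.0)))
        except np.linalg.LinAlgError:
            status = status if status != "ok" else "singular-fit"

    px = camera.pixel_size
    return Spot(x=float(cc * px), y=float(rc * px), sigma=float(sig * px),
                brightness_B=float(B), background=float(bg),
                fit_uncertainty=se_B, frame_index=frame_index, status=status)


def analyze_frame(
    photons: np.ndarray,
    camera: CameraModel,
    detection_threshold: float,
    min_separation: float = 5.0,
    window: int = 7,
    sigma_band: tuple[float, float] = (0.7, 1.5),
    frame_index: int = 0,
    region_px: tuple[int, int, int, int] | None = None,
) -> list[Spot]:
    """Detect and fit all spots in a frame, optionally restricted to a region.

    ``region_px`` is a half-open (row0, col0, row1, col1) rectangle;
    candidates outside it are dropped before fitting.
    """
    cands = detect_spots(photons, detection_threshold, min_separation)
    if region_px is not None and len(cands):
        r0, c0, r1, c1 = region_px
        inside = ((cands[:, 0] >= r0) & (cands[:, 0] < r1)
                  & (cands[:, 1] >= c0) & (cands[:, 1] < c1))
        cands = cands[inside]
    return [fit_gaussian_spot(photons, c, camera, window, sigma_band,
                              frame_index) for c in cands]


def spots_to_table(spots: list[Spot]) -> pd.DataFrame:
    """Collect fitted spots into the standard per-spot table."""
    return pd.DataFrame(
        [(s.frame_index, s.x, s.y, s.sigma, s.brightness_B,
          s.fit_uncertainty, s.status) for s in spots],
        columns=SPOT_TABLE_COLUMNS,
    )


def estimate_density(
    photons: np.ndarray,
    camera: CameraModel,
    monomer_mean_brightness: float,
    background_per_pixel: float = 0.0,
    method: str = "intensity",
    detection_threshold: float | None = None,
) -> DensityEstimate:
    """Estimate the fluorophore surface density of a (pre-bleach) frame.

    The default estimator divides the total background-corrected photon
    count by the mean single-fluorophore brightness and the imaged area —
    it therefore works at densities far beyond single-molecule
    resolvability, which is exactly the pre-bleach situation.  For sparse
    frames ``method='count'`` cross-checks by counting detected spots.

    The input should be an *unclipped* photon image (``clip=False`` in
    :func:`counts_to_photons`) so that read noise averages to zero.
    """
    img = np.asarray(photons, dtype=float)
    area = img.size * camera.pixel_size**2
    if area <= 0:
        raise ValidationError("analyzed area must be positive")
    if monomer_mean_brightness <= 0:
        raise ValidationError("monomer mean brightness must be positive")
    if method == "intensity":
        total = float(img.sum() - background_per_pixel * img.size)
        density = total / (monomer_mean_brightness * area)
        if density < -0.2:
            raise ValidationError(
                "corrected intensity is strongly negative; check offset "
                "and background calibration")
        density = max(density, 0.0)
        basis = "integrated-intensity"
    elif method == "count":
        thr = (detection_threshold if detection_threshold is not None
               else 0.3 * monomer_mean_brightness)
        n = len(detect_spots(img, thr))
        density = n / area
        basis = f"spot-count (threshold {thr:g} photons)"
    else:
        raise ValidationError(f"unknown density method {method!r}")
    return DensityEstimate(density=density, analyzed_area=area, basis=basis)
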