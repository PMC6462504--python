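"""Domain types shared across the TOCCSL analysis pipeline.

The containers here are deliberately thin: validated dataclasses holding
physical quantities in fixed units (micrometres, seconds, photons, camera
counts).  All heavy computation lives in the functional modules
(:mod:`toccsl.simulate`, :mod:`toccsl.spots`, :mod:`toccsl.mixture`,
:mod:`toccsl.mobility`, :mod:`toccsl.pipeline`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CameraModel",
    "ProtocolTimings",
    "GroundTruth",
    "FrameStack",
    "ComplexPopulation",
    "Spot",
    "DensityEstimate",
    "BrightnessPDF",
    "MixtureResult",
    "FrapFit",
    "DiffusionFit",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented physical invariant."""


@dataclass(frozen=True)
class CameraModel:
    """EMCCD/CCD camera and optics calibration.

    Counts and photons are related by ``photons = (counts - offset) * inverse_gain``;
    ``inverse_gain`` therefore carries units of photons per count.

    Parameters
    ----------
    offset : float
        Dark level of the analogue-digital converter, in counts.
    inverse_gain : float
        Photons per count.
    read_noise_sd : float
        Gaussian readout noise, in counts.
    pixel_size : float
        Back-projected pixel edge in the sample plane, micrometres.
    psf_sigma : float
        Standard deviation of the Gaussian approximation to the point
        spread function, micrometres.
    field_of_view : (int, int)
        Image shape (rows, columns) in pixels.
    saturation_level : float, optional
        Counts at which the ADC saturates; pixels at or above are flagged.
    """

    offset: float = 100.0
    inverse_gain: float = 2.0
    read_noise_sd: float = 1.5
    pixel_size: float = 0.16
    psf_sigma: float = 0.13
    field_of_view: tuple[int, int] = (64, 64)
    saturation_level: float = 65535.0

    def __post_init__(self) -> None:
        if self.inverse_gain <= 0:
            raise ValidationError("inverse_gain must be positive")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if self.psf_sigma <= 0:
            raise ValidationError("psf_sigma must be positive")
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be non-negative")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size

    @property
    def fov_area_um2(self) -> float:
        h, w = self.field_of_view
        return h * w * self.pixel_size**2


@dataclass(frozen=True)
class ProtocolTimings:
    """Timing of one TOCCSL run and of the repeated protocol.

    Defaults follow the standard protocol: a 50 ms pre-bleach image, an
    800 ms high-power bleach pulse confined by the field stop, a post-bleach
    control image 40 ms later, and the recovery (TOCCSL) image after
    15-20 s.  The repeated protocol runs once every 5 minutes, ten times.
    All per-frame durations are milliseconds; run_interval is seconds.
    """

    t_pre: float = 50.0
    t_bleach: float = 800.0
    t_post: float = 40.0
    t_recovery: float = 15000.0
    run_interval: float = 300.0
    n_runs: int = 10
    excitation_time: float = 10.0

    def __post_init__(self) -> None:
        for name in ("t_pre", "t_bleach", "t_post", "t_recovery",
                     "run_interval", "excitation_time"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_runs < 1:
            raise ValidationError("n_runs must be at least 1")


@dataclass(frozen=True)
class GroundTruth:
    """Simulator ground truth for parameter-recovery experiments.

    ``alpha_true[N-1]`` is the fraction of complexes that are N-mers; the
    vector must be a probability distribution.  ``surface_density`` counts
    individual protein molecules (subunits), not complexes, per square
    micrometre.  Single-fluorophore brightness is lognormal with the given
    mean (photons) and coefficient of variation; ``cv = 0`` degenerates to
    a fixed brightness.
    """

    surface_density: float = 20.0
    alpha_true: tuple[float, ...] = (0.55, 0.35, 0.10)
    diffusion_coeff: float = 0.118
    mobile_fraction: float = 0.78
    exchange_rate: float = 0.0
    monomer_brightness_mean: float = 100.0
    monomer_brightness_cv: float = 0.35
    labeling_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_true, dtype=float)
        if a.ndim != 1 or a.size == 0:
            raise ValidationError("alpha_true must be a non-empty 1-D vector")
        if np.any(a < 0):
            raise ValidationError("alpha_true entries must be non-negative")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"alpha_true must sum to 1 (got {a.sum()!r})")
        if self.surface_density <= 0:
            raise ValidationError("surface_density must be positive")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValidationError("mobile_fraction must lie in [0, 1]")
        if self.exchange_rate < 0:
            raise ValidationError("exchange_rate must be non-negative")
        if self.monomer_brightness_mean <= 0:
            raise ValidationError("monomer_brightness_mean must be positive")
        if self.monomer_brightness_cv < 0:
            raise ValidationError("monomer_brightness_cv must be non-negative")
        if not 0.0 < self.labeling_fraction <= 1.0:
            raise ValidationError("labeling_fraction must lie in (0, 1]")

    @property
    def mean_complex_size(self) -> float:
        a = np.asarray(self.alpha_true)
        return float(np.sum(a * np.arange(1, a.size + 1)))


@dataclass
class FrameStack:
    """A sequence of camera frames with per-frame roles and timestamps.

    ``bleach_region`` is given in pixel coordinates as half-open bounds
    ``(row0, col0, row1, col1)`` with pixel (0, 0) at the image top-left.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    roles: list[str]
    bleach_region: tuple[int, int, int, int]
    camera: Optional[CameraModel] = None
    metadata: dict = field(default_factory=dict)

    VALID_ROLES = ("pre-bleach", "bleach", "post-bleach", "recovery")

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a 3-D (n, H, W) array")
        n = self.frames.shape[0]
        if self.timestamps.shape != (n,) or len(self.roles) != n:
            raise ValidationError("one timestamp and one role per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        for r in self.roles:
            if r not in self.VALID_ROLES:
                raise ValidationError(f"unknown frame role {r!r}")
        r0, c0, r1, c1 = self.bleach_region
        h, w = self.frames.shape[1:]
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValidationError("bleach_region must lie inside the field of view")

    def frames_with_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]


@dataclass
class ComplexPopulation:
    """A set of protein complexes with per-subunit fluorophore labels.

    ``sizes[i]`` is the subunit count of complex ``i``; ``active`` is the
    flat concatenation of per-subunit booleans (True = fluorescent), so the
    labels of complex ``i`` occupy ``active[offsets[i]:offsets[i+1]]``.
    """

    sizes: np.ndarray
    active: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.active = np.asarray(self.active, dtype=bool)
        if np.any(self.sizes < 1):
            raise ValidationError("complex sizes must be at least 1")
        if self.active.size != int(self.sizes.sum()):
            raise ValidationError("one label per subunit required")

    @property
    def offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.sizes)])

    @property
    def n_active_per_complex(self) -> np.ndarray:
        """Number of fluorescent subunits in each complex."""
        return np.add.reduceat(self.active.astype(int), self.offsets[:-1])

    @property
    def active_fraction(self) -> float:
        return float(self.active.mean()) if self.active.size else 0.0

    def copy(self) -> "ComplexPopulation":
        return ComplexPopulation(self.sizes.copy(), self.active.copy())


@dataclass
class Spot:
    """One diffraction-limited detection after Gaussian fitting.

    Positions and widths are in micrometres; ``brightness_B`` is the
    background-corrected integrated photon count of the spot.  ``status``
    is ``"ok"`` for accepted fits, otherwise a rejection reason code.
    """

    x: float
    y: float
    sigma: float
    brightness_B: float
    background: float
    fit_uncertainty: float
    frame_index: int = 0
    status: str = "ok"

    @property
    def accepted(self) -> bool:
        return self.status == "ok"


@dataclass
class DensityEstimate:
    density: float                      # molecules / um^2
    analyzed_area: float                # um^2
    basis: str = "integrated-intensity"

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValidationError("density must be non-negative")


@dataclass
class BrightnessPDF:
    """A brightness probability density on a uniform photon grid."""

    grid: np.ndarray
    density: np.ndarray
    provenance: str = "monomer-empirical"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape or self.grid.ndim != 1:
            raise ValidationError("grid and density must be matching 1-D arrays")
        dx = np.diff(self.grid)
        if dx.size and not np.allclose(dx, dx[0], rtol=1e-9, atol=1e-12):
            raise ValidationError("grid spacing must be uniform")
        if np.any(self.density < -1e-12):
            raise ValidationError("density must be non-negative")
        self.density = np.clip(self.density, 0.0, None)
        total = self.integral()
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"density must integrate to 1 (got {total:.8f})")

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def var(self) -> float:
        m = self.mean()
        return float(np.trapezoid((self.grid - m) ** 2 * self.density, self.grid))

    def cv(self) -> float:
        m = self.mean()
        return float(np.sqrt(self.var()) / m) if m > 0 else np.inf


@dataclass
class MixtureResult:
    """Oligomer fractions fitted from a brightness sample.

    ``alpha[N-1]`` is the fraction of visible complexes with N co-diffusing
    active fluorophores; ``alpha_se`` the bootstrap standard errors (may be
    None before bootstrapping).
    """

    alpha: np.ndarray
    n_max: int
    n_spots: int
    residual_norm: float
    alpha_se: Optional[np.ndarray] = None
    log_likelihood: float = np.nan
    method: str = "ml"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (self.n_max,):
            raise ValidationError("alpha must have length n_max")
        if np.any(self.alpha < -1e-8):
            raise ValidationError("alpha entries must be non-negative")
        if abs(self.alpha.sum() - 1.0) > 1e-8:
            raise ValidationError("alpha must sum to 1")
        if self.alpha_se is not None:
            self.alpha_se = np.asarray(self.alpha_se, dtype=float)


@dataclass
class FrapFit:
    """Bounded fit of the recovery model I/I0 = m * (1 - exp(-t / tau))."""

    mobile_fraction: float
    tau: float
    mobile_fraction_se: float
    tau_se: float
    n_timepoints: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -1e-9 <= self.mobile_fraction <= 1 + 1e-9:
            raise ValidationError("mobile_fraction must lie in [0, 1]")


@dataclass
class DiffusionFit:
    """Diffusion coefficient from MSD = 4 D t_lag + offset."""

    D: float
    offset: float
    se_D: float
    lags_used: int = 2
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValidationError("D must be non-negative")


def as_rng(rng: "np.random.Generator | int | None") -> np.random.Generator:
    """Coerce a seed, Generator or None into a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
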