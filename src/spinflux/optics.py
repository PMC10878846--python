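"""Illumination patterns and photon-budget normalization.

Spinning-disk modulation-enhanced localization illuminates the sample with a
sequence of focused patterns, one per pinhole exposure.  Each pattern is a
peak-normalized intensity profile :math:`P(\\Delta x, \\Delta y) \\in [0, 1]`
centered on its pinhole, so that the emitter brightness parameter
``theta_I`` is the expected signal photon count under maximum illumination.

Two physical patterns are modeled:

* ``gaussian`` — a diffraction-limited Gaussian focus,
  :math:`P = \\exp(-r^2 / 2\\sigma_\\mathrm{illum}^2)`.
* ``donut`` — a first-order vortex (MINFLUX-style) beam with a zero-intensity
  minimum at the pinhole center,
  :math:`P = (r^2 / 2\\sigma^2)\\,\\exp(1 - r^2 / 2\\sigma^2)`,
  which peaks at 1 on the ring :math:`r = \\sigma\\sqrt{2}`.

A third ``uniform`` kind (:math:`P \\equiv 1`) expresses the widefield
reference through the same code path.

The normalization constant ``A`` encodes how the fixed signal photon budget
is shared across the pattern sequence: in the ``exhaust_budget`` scenario the
whole budget is spent regardless of how brightly the emitter is illuminated
(``A = 1 / sum_k P_k``); in the ``fixed_power`` scenario each pattern gets the
same dose as a single widefield exposure would (``A = 1 / K``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "OpticalConfig",
    "Exposure",
    "IlluminationSequence",
    "pattern_intensity",
    "pattern_gradient",
    "normalization_A",
    "normalization_A_gradient",
    "SUM_INTENSITY_FLOOR",
]

#: Lower floor on the summed pattern intensity at the emitter in the
#: exhaust-budget scenario.  Below this the emitter is effectively
#: unilluminated and the configuration is rejected rather than producing an
#: arbitrarily large budget amplification.
SUM_INTENSITY_FLOOR = 1e-12

#: Diffraction-limited Gaussian PSF width prefactor: sigma = 0.21 * lambda / NA.
PSF_WIDTH_FACTOR = 0.21

_PATTERN_KINDS = ("gaussian", "donut", "uniform")
_BUDGET_SCENARIOS = ("exhaust_budget", "fixed_power")
_BACKGROUND_MODELS = ("pattern_dependent", "overlap_area")


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the microscope, all lengths in sample-plane nm.

    Parameters
    ----------
    sigma_psf : float
        Standard deviation of the Gaussian emission PSF (nm).
    sigma_illum : float
        Standard deviation of the Gaussian/donut illumination profile (nm).
    pixel_size : float
        Back-projected camera pixel size (nm); magnification is folded in.
    roi_nx, roi_ny : int
        Region-of-interest size in pixels; the ROI is centered on the origin.
    lambda_ex, lambda_em, numerical_aperture : float, optional
        If given, the diffraction-limited relations
        ``sigma_illum = 0.21 lambda_ex / NA`` and
        ``sigma_psf = 0.21 lambda_em / NA`` must hold to 1e-9 relative.
    """

    sigma_psf: float
    sigma_illum: float
    pixel_size: float
    roi_nx: int = 10
    roi_ny: int = 10
    lambda_ex: Optional[float] = None
    lambda_em: Optional[float] = None
    numerical_aperture: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("sigma_psf", "sigma_illum", "pixel_size"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        if self.roi_nx < 1 or self.roi_ny < 1:
            raise ValueError("ROI must contain at least one pixel per axis")
        na = self.numerical_aperture
        if na is not None:
            for lam, sig, label in (
                (self.lambda_ex, self.sigma_illum, "sigma_illum"),
                (self.lambda_em, self.sigma_psf, "sigma_psf"),
            ):
                if lam is None:
                    continue
                expected = PSF_WIDTH_FACTOR * lam / na
                if abs(expected - sig) > 1e-9 * expected:
                    raise ValueError(
                        f"{label}={sig} inconsistent with 0.21*lambda/NA={expected}"
                    )

    @classmethod
    def from_wavelengths(
        cls,
        lambda_ex: float,
        lambda_em: float,
        numerical_aperture: float,
        pixel_size: float,
        roi_nx: int = 10,
        roi_ny: int = 10,
    ) -> "OpticalConfig":
        """Build a config with diffraction-limited PSF widths 0.21*lambda/NA."""
        return cls(
            sigma_psf=PSF_WIDTH_FACTOR * lambda_em / numerical_aperture,
            sigma_illum=PSF_WIDTH_FACTOR * lambda_ex / numerical_aperture,
            pixel_size=pixel_size,
            roi_nx=roi_nx,
            roi_ny=roi_ny,
            lambda_ex=lambda_ex,
            lambda_em=lambda_em,
            numerical_aperture=numerical_aperture,
        )


@dataclass(frozen=True)
class Exposure:
    """One illumination pattern co-centered with one emission pinhole.

    ``pinhole_radius`` may be ``math.inf`` (no pinhole) or 0 (fully closed,
    useful only as a degenerate limit in analyses).
    """

    kind: str
    xp: float
    yp: float
    pinhole_radius: float = math.inf

    def __post_init__(self) -> None:
        if self.kind not in _PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}; expected one of {_PATTERN_KINDS}")
        if not (np.isfinite(self.xp) and np.isfinite(self.yp)):
            raise ValueError("pattern/pinhole center must be finite")
        if math.isnan(self.pinhole_radius) or self.pinhole_radius < 0:
            raise ValueError("pinhole_radius must be >= 0 or infinite")

    @property
    def has_pinhole(self) -> bool:
        return math.isfinite(self.pinhole_radius)


@dataclass(frozen=True)
class IlluminationSequence:
    """Ordered pattern/pinhole exposures plus the photon-budget scenario."""

    exposures: Tuple[Exposure, ...]
    budget_scenario: str = "exhaust_budget"
    background_model: str = "pattern_dependent"

    def __post_init__(self) -> None:
        object.__setattr__(self, "exposures", tuple(self.exposures))
        if len(self.exposures) < 1:
            raise ValueError("sequence needs at least one exposure")
        if self.budget_scenario not in _BUDGET_SCENARIOS:
            raise ValueError(f"unknown budget scenario {self.budget_scenario!r}")
        if self.background_model not in _BACKGROUND_MODELS:
            raise ValueError(f"unknown background model {self.background_model!r}")

    def __len__(self) -> int:
        return len(self.exposures)


def _check_offsets(dx, dy):
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if not (np.all(np.isfinite(dx)) and np.all(np.isfinite(dy))):
        raise ValueError("pattern offsets must be finite")
    return dx, dy


def pattern_intensity(kind: str, dx, dy, sigma_illum: float):
    """Peak-normalized illumination intensity at offset (dx, dy) from center.

    Returns a value (or array) in [0, 1].  ``dx``/``dy`` broadcast.
    """
    if sigma_illum <= 0:
        raise ValueError("sigma_illum must be positive")
    dx, dy = _check_offsets(dx, dy)
    u = (dx * dx + dy * dy) / (2.0 * sigma_illum * sigma_illum)
    if kind == "gaussian":
        return np.exp(-u)
    if kind == "donut":
        return u * np.exp(1.0 - u)
    if kind == "uniform":
        return np.ones_like(u)
    raise ValueError(f"unknown pattern kind {kind!r}")


def pattern_gradient(kind: str, dx, dy, sigma_illum: float):
    """Analytic gradient of :func:`pattern_intensity` w.r.t. (dx, dy)."""
    if sigma_illum <= 0:
        raise ValueError("sigma_illum must be positive")
    dx, dy = _check_offsets(dx, dy)
    s2 = sigma_illum * sigma_illum
    u = (dx * dx + dy * dy) / (2.0 * s2)
    if kind == "gaussian":
        common = -np.exp(-u) / s2
    elif kind == "donut":
        # d/du [u e^{1-u}] = (1-u) e^{1-u};  du/d(dx) = dx / s2
        common = (1.0 - u) * np.exp(1.0 - u) / s2
    elif kind == "uniform":
        common = np.zeros_like(u)
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return common * dx, common * dy


def normalization_A(
    theta_x: float,
    theta_y: float,
    seq: IlluminationSequence,
    sigma_illum: float,
    floor: float = SUM_INTENSITY_FLOOR,
) -> float:
    """Photon-budget normalization constant A for an emitter at (theta_x, theta_y).

    ``exhaust_budget``: A = 1 / sum_k P_k(theta - p_k) — the full budget is
    spent however weakly the emitter is illuminated.  ``fixed_power``:
    A = 1 / K, independent of the emitter position.
    """
    if seq.budget_scenario == "fixed_power":
        return 1.0 / len(seq)
    total = 0.0
    for exp_ in seq.exposures:
        total += float(
            pattern_intensity(exp_.kind, theta_x - exp_.xp, theta_y - exp_.yp, sigma_illum)
        )
    if total < floor:
        raise ValueError(
            "emitter is effectively unilluminated: summed pattern intensity "
            f"{total:.3e} below floor {floor:.0e}"
        )
    return 1.0 / total


def normalization_A_gradient(
    theta_x: float,
    theta_y: float,
    seq: IlluminationSequence,
    sigma_illum: float,
    floor: float = SUM_INTENSITY_FLOOR,
) -> Tuple[float, float]:
    """Gradient (dA/dtheta_x, dA/dtheta_y) of :func:`normalization_A`."""
    if seq.budget_scenario == "fixed_power":
        return (0.0, 0.0)
    a = normalization_A(theta_x, theta_y, seq, sigma_illum, floor=floor)
    gx = 0.0
    gy = 0.0
    for exp_ in seq.exposures:
        px, py = pattern_gradient(
            exp_.kind, theta_x - exp_.xp, theta_y - exp_.yp, sigma_illum
        )
        gx += float(px)
        gy += float(py)
    return (-a * a * gx, -a * a * gy)
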