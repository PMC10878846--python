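"""Forward image-formation model for pattern-modulated, pinhole-windowed SMLM.

The expected photon count in pixel i during exposure k is

    mu_{i,k} = A theta_I P_k(theta - p_k) H(theta_x, theta_y, x_i, y_i)
             + A theta_b B_{i,k}

with emitter parameters theta = (theta_x, theta_y, theta_I, theta_b):
position (nm), expected signal photons under maximum illumination, and
expected background photons per pixel.  Camera counts are independent Poisson
draws around mu.  Analytic Jacobians chain through A(theta), P(theta) and
H(theta); they are the ingredients of the Fisher information.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Tuple

import numpy as np

from .background import background_stack
from .optics import (
    Exposure,
    IlluminationSequence,
    OpticalConfig,
    normalization_A,
    normalization_A_gradient,
    pattern_gradient,
    pattern_intensity,
)
from .pinhole import PixelGrid, windowed_psf_H_all, windowed_psf_H_gradient_all

__all__ = [
    "EmitterParams",
    "ExpectedImageStack",
    "JacobianStack",
    "PhotonBookkeeping",
    "pixel_grid_for",
    "expected_counts",
    "jacobian",
    "sample_counts",
    "photon_bookkeeping",
]


@dataclass(frozen=True)
class EmitterParams:
    """theta = (theta_x, theta_y, theta_I, theta_b)."""

    theta_x: float
    theta_y: float
    theta_I: float
    theta_b: float

    def __post_init__(self) -> None:
        if self.theta_I < 0:
            raise ValueError("theta_I must be nonnegative")
        if self.theta_b < 0:
            raise ValueError("theta_b must be nonnegative")
        if not (np.isfinite(self.theta_x) and np.isfinite(self.theta_y)):
            raise ValueError("emitter position must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_x, self.theta_y, self.theta_I, self.theta_b])


@dataclass(frozen=True)
class ExpectedImageStack:
    """Expected counts mu (K, ny, nx) plus the signal/background split."""

    mu: np.ndarray
    signal: np.ndarray
    background: np.ndarray
    emitter: EmitterParams
    sequence: IlluminationSequence
    config: OpticalConfig


@dataclass(frozen=True)
class JacobianStack:
    """dmu/dtheta, one (K, ny, nx) array per parameter (x, y, I, b order)."""

    d_theta_x: np.ndarray
    d_theta_y: np.ndarray
    d_theta_I: np.ndarray
    d_theta_b: np.ndarray

    def as_array(self) -> np.ndarray:
        """Stacked (4, K, ny, nx) array in canonical parameter order."""
        return np.stack(
            [self.d_theta_x, self.d_theta_y, self.d_theta_I, self.d_theta_b]
        )


@dataclass(frozen=True)
class PhotonBookkeeping:
    """Where the signal photon budget went, in expected counts.

    ``collected_signal`` sums the signal component of mu over pixels and
    exposures; ``blocked_signal`` is the emitted budget minus that (pinhole
    blocking plus ROI truncation, not distinguished).
    ``mean_background_per_pixel`` is the expected background per camera pixel
    accumulated over the whole exposure sequence — directly comparable to the
    widefield reference where a single frame carries theta_b per pixel.
    """

    collected_signal: float
    blocked_signal: float
    emitted_signal: float
    mean_background_per_pixel: float


def pixel_grid_for(config: OpticalConfig) -> PixelGrid:
    return PixelGrid(config.pixel_size, config.roi_nx, config.roi_ny)


@lru_cache(maxsize=128)
def _cached_background(
    exposures: Tuple[Exposure, ...],
    model: str,
    config: OpticalConfig,
    grid: PixelGrid,
    mesh_n: int,
) -> np.ndarray:
    b = background_stack(exposures, model, config, grid, mesh_n)
    b.setflags(write=False)
    return b


def _signal_terms(emitter, seq, config, grid, mesh_n):
    """Per-exposure P_k and H_k arrays plus the budget constant A."""
    a_norm = normalization_A(emitter.theta_x, emitter.theta_y, seq, config.sigma_illum)
    p_vals = []
    h_maps = []
    for exp_ in seq.exposures:
        p_vals.append(
            float(
                pattern_intensity(
                    exp_.kind,
                    emitter.theta_x - exp_.xp,
                    emitter.theta_y - exp_.yp,
                    config.sigma_illum,
                )
            )
        )
        h_maps.append(
            windowed_psf_H_all(
                emitter.theta_x, emitter.theta_y, exp_, grid, config.sigma_psf, mesh_n
            )
        )
    return a_norm, np.array(p_vals), np.stack(h_maps)


def expected_counts(
    emitter: EmitterParams,
    seq: IlluminationSequence,
    config: OpticalConfig,
    mesh_n: int = 100,
) -> ExpectedImageStack:
    """Expected camera counts mu_{i,k} for all pixels and exposures."""
    grid = pixel_grid_for(config)
    a_norm, p_vals, h_maps = _signal_terms(emitter, seq, config, grid, mesh_n)
    b_stack = _cached_background(seq.exposures, seq.background_model, config, grid, mesh_n)
    signal = a_norm * emitter.theta_I * p_vals[:, None, None] * h_maps
    backgr = a_norm * emitter.theta_b * b_stack
    mu = signal + backgr
    return ExpectedImageStack(mu, signal, backgr, emitter, seq, config)


def jacobian(
    emitter: EmitterParams,
    seq: IlluminationSequence,
    config: OpticalConfig,
    mesh_n: int = 100,
) -> JacobianStack:
    """Analytic dmu/dtheta for the four emitter parameters."""
    grid = pixel_grid_for(config)
    a_norm, p_vals, h_maps = _signal_terms(emitter, seq, config, grid, mesh_n)
    da_x, da_y = normalization_A_gradient(
        emitter.theta_x, emitter.theta_y, seq, config.sigma_illum
    )
    b_stack = _cached_background(seq.exposures, seq.background_model, config, grid, mesh_n)

    dp_x = np.empty(len(seq))
    dp_y = np.empty(len(seq))
    dh_x = []
    dh_y = []
    for k, exp_ in enumerate(seq.exposures):
        gx, gy = pattern_gradient(
            exp_.kind,
            emitter.theta_x - exp_.xp,
            emitter.theta_y - exp_.yp,
            config.sigma_illum,
        )
        dp_x[k], dp_y[k] = float(gx), float(gy)
        hx, hy = windowed_psf_H_gradient_all(
            emitter.theta_x, emitter.theta_y, exp_, grid, config.sigma_psf, mesh_n
        )
        dh_x.append(hx)
        dh_y.append(hy)
    dh_x = np.stack(dh_x)
    dh_y = np.stack(dh_y)

    ti, tb = emitter.theta_I, emitter.theta_b
    ph = p_vals[:, None, None] * h_maps
    core = ti * ph + tb * b_stack  # mu / A
    d_x = da_x * core + a_norm * ti * (dp_x[:, None, None] * h_maps + p_vals[:, None, None] * dh_x)
    d_y = da_y * core + a_norm * ti * (dp_y[:, None, None] * h_maps + p_vals[:, None, None] * dh_y)
    d_i = a_norm * ph
    d_b = a_norm * np.broadcast_to(b_stack, ph.shape).copy()
    return JacobianStack(d_x, d_y, d_i, d_b)


def sample_counts(mu: ExpectedImageStack | np.ndarray, seed: int) -> np.ndarray:
    """Independent Poisson draws per pixel per exposure; reproducible by seed."""
    arr = mu.mu if isinstance(mu, ExpectedImageStack) else np.asarray(mu, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("expected counts must be finite")
    if np.any(arr < 0):
        raise ValueError("expected counts must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(arr)


def photon_bookkeeping(
    emitter: EmitterParams,
    seq: IlluminationSequence,
    config: OpticalConfig,
    mesh_n: int = 100,
) -> PhotonBookkeeping:
    """Expected signal collected/blocked and mean background per pixel."""
    stack = expected_counts(emitter, seq, config, mesh_n)
    a_norm = normalization_A(emitter.theta_x, emitter.theta_y, seq, config.sigma_illum)
    emitted = 0.0
    for exp_ in seq.exposures:
        emitted += a_norm * emitter.theta_I * float(
            pattern_intensity(
                exp_.kind,
                emitter.theta_x - exp_.xp,
                emitter.theta_y - exp_.yp,
                config.sigma_illum,
            )
        )
    collected = float(stack.signal.sum())
    npix = config.roi_nx * config.roi_ny
    return PhotonBookkeeping(
        collected_signal=collected,
        blocked_signal=emitted - collected,
        emitted_signal=emitted,
        mean_background_per_pixel=float(stack.background.sum()) / npix,
    )
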