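"""Effective background coefficients B_{i,k} under patterned illumination.

A spatially uniform density of background fluorophores is excited by the
illumination pattern and imaged through the pinhole, so the expected
background in camera pixel i during exposure k is ``A * theta_b * B_{i,k}``
with

    B_{i,k} = (1 / a^2) * \\iint_sample P_k(u - x_p, v - y_p) H(u, v, x_i, y_i) du dv .

B depends on the pixel, the pinhole and the pattern — but not on the emitter.
The coefficients are anchored so that the widefield reference (uniform
illumination, no pinhole) has B_i = 1 for every pixel: ``theta_b`` is then
"expected background photons per pixel" on the same scale for every method.

Because H is itself an integral of the emission-PSF density over
(pixel ∩ pinhole), the order of integration can be swapped exactly:

    B_{i,k} = (1 / a^2) * \\int_{pixel_i ∩ pinhole} (P_k ⊛ g_psf)(s) ds ,

where ``P ⊛ g_psf`` is the convolution of the illumination pattern with the
normalized emission PSF.  That convolution is closed-form for the uniform,
Gaussian and donut patterns, so B reduces to the same pinhole-mesh quadrature
used for H — with no sample-plane truncation error.  A literal sample-plane
double integral is kept in the test suite as an independent oracle.

The pattern-independent variant approximates B_{i,k} by the geometrical
pixel–pinhole overlap area divided by the pixel area.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np
from scipy.special import ndtr

from .optics import Exposure, OpticalConfig
from .pinhole import PixelGrid, _boundary_quadrature, _pixel_disk_classification

__all__ = [
    "illumination_psf_convolution",
    "background_pattern_dependent",
    "background_pattern_dependent_all",
    "background_overlap_area",
    "background_overlap_area_all",
    "background_stack",
]


def illumination_psf_convolution(
    kind: str, dx, dy, sigma_illum: float, sigma_psf: float
):
    """(P ⊛ g_psf)(dx, dy): pattern blurred by the normalized emission PSF.

    Closed forms (s^2 = sigma_illum^2 + sigma_psf^2, d^2 = dx^2 + dy^2):

    * uniform:  1
    * gaussian: (sigma_illum^2 / s^2) exp(-d^2 / 2 s^2)
    * donut:    e sigma_illum^2 / (2 s^4) exp(-d^2 / 2 s^2)
                * (sigma_illum^2 d^2 / s^2 + 2 sigma_psf^2)
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    d2 = dx * dx + dy * dy
    si2 = sigma_illum * sigma_illum
    sp2 = sigma_psf * sigma_psf
    s2 = si2 + sp2
    if kind == "uniform":
        return np.ones_like(d2)
    if kind == "gaussian":
        return (si2 / s2) * np.exp(-d2 / (2.0 * s2))
    if kind == "donut":
        amp = math.e * si2 / (2.0 * s2 * s2)
        return amp * np.exp(-d2 / (2.0 * s2)) * (si2 * d2 / s2 + 2.0 * sp2)
    raise ValueError(f"unknown pattern kind {kind!r}")


def _gauss_legendre_pixel(blur, cx: float, cy: float, a: float, order: int = 24):
    """Integral of ``blur(x, y)`` over one a-by-a pixel, Gauss-Legendre."""
    nodes, weights = np.polynomial.legendre.leggauss(order)
    x = cx + 0.5 * a * nodes
    y = cy + 0.5 * a * nodes
    gx, gy = np.meshgrid(x, y, indexing="ij")
    w2 = np.outer(weights, weights) * (0.5 * a) ** 2
    return float(np.sum(blur(gx, gy) * w2))


def background_pattern_dependent_all(
    exposure: Exposure,
    config: OpticalConfig,
    grid: PixelGrid,
    mesh_n: int = 100,
) -> np.ndarray:
    """Pattern-dependent B_i for every ROI pixel; (ny, nx) array, >= 0."""
    a = grid.pixel_size
    open_b = _open_pixel_background(exposure, config, grid)
    if not exposure.has_pinhole:
        return open_b
    xp, yp, radius = exposure.xp, exposure.yp, exposure.pinhole_radius
    fully_inside, _ = _pixel_disk_classification(xp, yp, radius, grid)
    out = np.where(fully_inside, open_b, 0.0).reshape(-1)
    pts, idx, cell_area = _boundary_quadrature(xp, yp, radius, mesh_n, grid)
    if len(pts):
        vals = illumination_psf_convolution(
            exposure.kind, pts[:, 0] - xp, pts[:, 1] - yp,
            config.sigma_illum, config.sigma_psf,
        )
        out += np.bincount(idx, weights=vals * cell_area, minlength=out.size) / (a * a)
    return out.reshape(grid.ny, grid.nx)


def _open_pixel_background(
    exposure: Exposure, config: OpticalConfig, grid: PixelGrid
) -> np.ndarray:
    """B_i without any aperture: pixel integral of P ⊛ g_psf over pixel area."""
    a = grid.pixel_size
    if exposure.kind == "uniform":
        return np.ones((grid.ny, grid.nx))
    if exposure.kind == "gaussian":
        # pixel integral of the blurred Gaussian is an erf product
        si2 = config.sigma_illum**2
        s = math.sqrt(si2 + config.sigma_psf**2)
        fx = ndtr((grid.x_edges - exposure.xp) / s)
        fy = ndtr((grid.y_edges - exposure.yp) / s)
        amp = 2.0 * math.pi * si2 / (a * a)
        return amp * np.outer(np.diff(fy), np.diff(fx))

    # donut: closed-form convolution, numeric pixel quadrature
    def blur(x, y):
        return illumination_psf_convolution(
            exposure.kind, x - exposure.xp, y - exposure.yp,
            config.sigma_illum, config.sigma_psf,
        )

    out = np.empty((grid.ny, grid.nx))
    for iy, cy in enumerate(grid.y_centers):
        for ix, cx in enumerate(grid.x_centers):
            out[iy, ix] = _gauss_legendre_pixel(blur, cx, cy, a) / (a * a)
    return out


def background_pattern_dependent(
    pixel: Tuple[int, int],
    exposure: Exposure,
    config: OpticalConfig,
    grid: PixelGrid,
    mesh_n: int = 100,
) -> float:
    ix, iy = pixel
    grid.pixel_center(ix, iy)
    return float(background_pattern_dependent_all(exposure, config, grid, mesh_n)[iy, ix])


def background_overlap_area_all(
    exposure: Exposure, grid: PixelGrid, mesh_n: int = 100
) -> np.ndarray:
    """Pixel–pinhole overlap area / pixel area, for every ROI pixel."""
    if not exposure.has_pinhole:
        return np.ones((grid.ny, grid.nx))
    xp, yp, radius = exposure.xp, exposure.yp, exposure.pinhole_radius
    fully_inside, _ = _pixel_disk_classification(xp, yp, radius, grid)
    out = fully_inside.astype(float).reshape(-1)
    pts, idx, cell_area = _boundary_quadrature(xp, yp, radius, mesh_n, grid)
    if len(idx):
        a = grid.pixel_size
        counts = np.bincount(idx, minlength=out.size).astype(float)
        out += counts * cell_area / (a * a)
    return out.reshape(grid.ny, grid.nx)


def background_overlap_area(
    pixel: Tuple[int, int], exposure: Exposure, grid: PixelGrid, mesh_n: int = 100
) -> float:
    ix, iy = pixel
    grid.pixel_center(ix, iy)
    return float(background_overlap_area_all(exposure, grid, mesh_n)[iy, ix])


def background_stack(
    seq_exposures: Tuple[Exposure, ...],
    model: str,
    config: OpticalConfig,
    grid: PixelGrid,
    mesh_n: int = 100,
) -> np.ndarray:
    """B_{i,k} for a whole exposure sequence; (K, ny, nx) array."""
    if model == "pattern_dependent":
        return np.stack(
            [background_pattern_dependent_all(e, config, grid, mesh_n) for e in seq_exposures]
        )
    if model == "overlap_area":
        return np.stack(
            [background_overlap_area_all(e, grid, mesh_n) for e in seq_exposures]
        )
    raise ValueError(f"unknown background model {model!r}")
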