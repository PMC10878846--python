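"""Pinhole-windowed, pixel-integrated emission PSF.

The emission PSF is an isotropic 2D Gaussian of width ``sigma_psf`` centered
on the emitter.  Before reaching the camera it is windowed by the circular
pinhole of the active exposure (a sharp mask: the camera plane is treated as
conjugate to the pinhole plane with no additional relay blur).  The quantity

    H(theta_x, theta_y, x_i, y_i)

is the expected fraction of emitted photons that pass the pinhole AND land in
camera pixel i.  Pixels fully inside the aperture are integrated in closed
form (product of error-function differences); pixels cut by the aperture edge
are evaluated by midpoint quadrature on an ``mesh_n x mesh_n`` mesh over the
pinhole's bounding square, keeping cells whose centers fall inside the
aperture and assigning each cell to the pixel containing its center.  Without
a pinhole the closed form applies everywhere.

Gradients with respect to the emitter position are computed analytically
inside the same quadrature (finite differences serve only as a test oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Tuple

import numpy as np
from scipy.special import ndtr  # standard normal CDF, vectorized

from .optics import Exposure

__all__ = [
    "PixelGrid",
    "PinholeMesh",
    "pinhole_mesh",
    "windowed_psf_H",
    "windowed_psf_H_all",
    "windowed_psf_H_gradient",
    "windowed_psf_H_gradient_all",
    "total_transmission",
]


@dataclass(frozen=True)
class PixelGrid:
    """Camera pixel grid; the ROI of ``nx`` x ``ny`` pixels is centered on (0, 0).

    Pixel (ix, iy) has center ((ix + 0.5) a - nx a / 2, (iy + 0.5) a - ny a / 2)
    with a = ``pixel_size`` in nm.
    """

    pixel_size: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or not np.isfinite(self.pixel_size):
            raise ValueError("pixel_size must be finite and positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid needs at least one pixel per axis")

    @property
    def x_centers(self) -> np.ndarray:
        a = self.pixel_size
        return (np.arange(self.nx) + 0.5) * a - self.nx * a / 2.0

    @property
    def y_centers(self) -> np.ndarray:
        a = self.pixel_size
        return (np.arange(self.ny) + 0.5) * a - self.ny * a / 2.0

    @property
    def x_edges(self) -> np.ndarray:
        a = self.pixel_size
        return np.arange(self.nx + 1) * a - self.nx * a / 2.0

    @property
    def y_edges(self) -> np.ndarray:
        a = self.pixel_size
        return np.arange(self.ny + 1) * a - self.ny * a / 2.0

    def pixel_center(self, ix: int, iy: int) -> Tuple[float, float]:
        if not (0 <= ix < self.nx and 0 <= iy < self.ny):
            raise IndexError(f"pixel ({ix}, {iy}) outside {self.nx}x{self.ny} grid")
        return float(self.x_centers[ix]), float(self.y_centers[iy])


@dataclass(frozen=True)
class PinholeMesh:
    """Midpoint mesh over a circular pinhole aperture.

    ``points`` are the centers of mesh cells lying inside the disk (shape
    (M, 2), nm); every included cell carries the same ``cell_area``.
    ``pixel_index`` maps each cell to a flattened ROI pixel
    (iy * nx + ix), or -1 when the cell center falls outside the ROI.
    """

    points: np.ndarray
    cell_area: float
    pixel_index: np.ndarray
    mesh_n: int
    center: Tuple[float, float]
    radius: float

    @property
    def covered_area(self) -> float:
        return self.cell_area * len(self.points)


@lru_cache(maxsize=256)
def _build_mesh(
    xp: float, yp: float, radius: float, mesh_n: int, grid: PixelGrid
) -> PinholeMesh:
    if mesh_n < 2:
        raise ValueError("mesh_n must be at least 2")
    if not math.isfinite(radius):
        raise ValueError("mesh is only defined for a finite pinhole radius")
    if radius == 0.0:
        pts = np.empty((0, 2))
        return PinholeMesh(pts, 0.0, np.empty(0, dtype=np.intp), mesh_n, (xp, yp), radius)
    step = 2.0 * radius / mesh_n
    coords = xp - radius + (np.arange(mesh_n) + 0.5) * step
    coords_y = yp - radius + (np.arange(mesh_n) + 0.5) * step
    gx, gy = np.meshgrid(coords, coords_y, indexing="ij")
    inside = (gx - xp) ** 2 + (gy - yp) ** 2 <= radius * radius
    pts = np.column_stack([gx[inside], gy[inside]])
    a = grid.pixel_size
    ix = np.floor(pts[:, 0] / a + grid.nx / 2.0).astype(np.intp)
    iy = np.floor(pts[:, 1] / a + grid.ny / 2.0).astype(np.intp)
    ok = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
    flat = np.where(ok, iy * grid.nx + ix, -1)
    pts.setflags(write=False)
    flat.setflags(write=False)
    return PinholeMesh(pts, step * step, flat, mesh_n, (xp, yp), radius)


def pinhole_mesh(exposure: Exposure, grid: PixelGrid, mesh_n: int) -> PinholeMesh:
    """Cached midpoint mesh for one exposure's pinhole over the given grid."""
    return _build_mesh(exposure.xp, exposure.yp, exposure.pinhole_radius, mesh_n, grid)


@lru_cache(maxsize=256)
def _pixel_disk_classification(
    xp: float, yp: float, radius: float, grid: PixelGrid
) -> Tuple[np.ndarray, np.ndarray]:
    """Classify every ROI pixel against the aperture disk.

    Returns boolean (ny, nx) masks ``(fully_inside, boundary)``.  A pixel is
    fully inside when all four corners are within the radius (the disk is
    convex); fully outside when the nearest point of the pixel rectangle is
    beyond the radius; boundary otherwise.
    """
    xe, ye = grid.x_edges, grid.y_edges
    cx = np.meshgrid(xe, ye, indexing="xy")
    corner_r2 = (cx[0] - xp) ** 2 + (cx[1] - yp) ** 2
    corners_in = corner_r2 <= radius * radius
    fully_inside = (
        corners_in[:-1, :-1] & corners_in[:-1, 1:] & corners_in[1:, :-1] & corners_in[1:, 1:]
    )
    # nearest point of each pixel rectangle to the disk center
    nx_ = np.clip(xp, xe[:-1], xe[1:])
    ny_ = np.clip(yp, ye[:-1], ye[1:])
    near_r2 = (nx_[None, :] - xp) ** 2 + (ny_[:, None] - yp) ** 2
    touched = near_r2 <= radius * radius
    boundary = touched & ~fully_inside
    fully_inside.setflags(write=False)
    boundary.setflags(write=False)
    return fully_inside, boundary


@lru_cache(maxsize=256)
def _boundary_quadrature(
    xp: float, yp: float, radius: float, mesh_n: int, grid: PixelGrid
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Midpoint quadrature points for pixels cut by the aperture edge.

    Fully-inside pixels are integrated in closed form elsewhere; each boundary
    pixel gets its own pixel-aligned midpoint sub-grid whose cell size matches
    the pinhole mesh prescription (2 radius / mesh_n per axis), keeping points
    inside the aperture.  Returns (points, flat pixel index, cell area).
    """
    if mesh_n < 2:
        raise ValueError("mesh_n must be at least 2")
    empty = (np.empty((0, 2)), np.empty(0, dtype=np.intp), 0.0)
    if radius == 0.0:
        return empty
    _, boundary = _pixel_disk_classification(xp, yp, radius, grid)
    if not boundary.any():
        return empty
    a = grid.pixel_size
    target = 2.0 * radius / mesh_n
    n_sub = max(2, int(math.ceil(a / target)))
    step = a / n_sub
    offsets = (np.arange(n_sub) + 0.5) * step
    iy_list, ix_list = np.nonzero(boundary)
    x0 = grid.x_edges[ix_list]
    y0 = grid.y_edges[iy_list]
    px = (x0[:, None] + offsets[None, :])[:, :, None] + np.zeros((1, 1, n_sub))
    py = (y0[:, None] + offsets[None, :])[:, None, :] + np.zeros((1, n_sub, 1))
    flat_idx = np.repeat(iy_list * grid.nx + ix_list, n_sub * n_sub)
    pts = np.column_stack([px.reshape(-1), py.reshape(-1)])
    keep = (pts[:, 0] - xp) ** 2 + (pts[:, 1] - yp) ** 2 <= radius * radius
    pts = pts[keep]
    idx = flat_idx[keep]
    pts.setflags(write=False)
    idx.setflags(write=False)
    return pts, idx, step * step


def _open_pixel_integrals(theta: float, edges: np.ndarray, sigma: float) -> np.ndarray:
    """1D pixel integrals of the unit Gaussian centered at theta (no pinhole)."""
    z = (edges - theta) / sigma
    cdf = ndtr(z)
    return cdf[1:] - cdf[:-1]


def _open_pixel_integrals_grad(theta: float, edges: np.ndarray, sigma: float) -> np.ndarray:
    """d/dtheta of :func:`_open_pixel_integrals`."""
    z = (edges - theta) / sigma
    pdf = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    return -(pdf[1:] - pdf[:-1]) / sigma


def windowed_psf_H_all(
    theta_x: float,
    theta_y: float,
    exposure: Exposure,
    grid: PixelGrid,
    sigma_psf: float,
    mesh_n: int = 100,
) -> np.ndarray:
    """H for every ROI pixel at once; returns an (ny, nx) array in [0, 1]."""
    if not (np.isfinite(theta_x) and np.isfinite(theta_y)):
        raise ValueError("emitter coordinates must be finite")
    hx = _open_pixel_integrals(theta_x, grid.x_edges, sigma_psf)
    hy = _open_pixel_integrals(theta_y, grid.y_edges, sigma_psf)
    open_h = np.outer(hy, hx)
    if not exposure.has_pinhole:
        return open_h
    if mesh_n < 2:
        raise ValueError("mesh_n must be at least 2")
    xp, yp, radius = exposure.xp, exposure.yp, exposure.pinhole_radius
    fully_inside, _ = _pixel_disk_classification(xp, yp, radius, grid)
    out = np.where(fully_inside, open_h, 0.0).reshape(-1)
    pts, idx, cell_area = _boundary_quadrature(xp, yp, radius, mesh_n, grid)
    if len(pts):
        dx = pts[:, 0] - theta_x
        dy = pts[:, 1] - theta_y
        dens = np.exp(-(dx * dx + dy * dy) / (2.0 * sigma_psf**2))
        dens *= cell_area / (2.0 * math.pi * sigma_psf**2)
        out += np.bincount(idx, weights=dens, minlength=out.size)
    return out.reshape(grid.ny, grid.nx)


def windowed_psf_H(
    theta_x: float,
    theta_y: float,
    pixel: Tuple[int, int],
    exposure: Exposure,
    grid: PixelGrid,
    sigma_psf: float,
    mesh_n: int = 100,
) -> float:
    """Pinhole-windowed emission-PSF mass in one pixel ``(ix, iy)``."""
    ix, iy = pixel
    grid.pixel_center(ix, iy)  # bounds check
    return float(
        windowed_psf_H_all(theta_x, theta_y, exposure, grid, sigma_psf, mesh_n)[iy, ix]
    )


def windowed_psf_H_gradient_all(
    theta_x: float,
    theta_y: float,
    exposure: Exposure,
    grid: PixelGrid,
    sigma_psf: float,
    mesh_n: int = 100,
) -> Tuple[np.ndarray, np.ndarray]:
    """(dH/dtheta_x, dH/dtheta_y) for every ROI pixel; two (ny, nx) arrays."""
    if not (np.isfinite(theta_x) and np.isfinite(theta_y)):
        raise ValueError("emitter coordinates must be finite")
    hx = _open_pixel_integrals(theta_x, grid.x_edges, sigma_psf)
    hy = _open_pixel_integrals(theta_y, grid.y_edges, sigma_psf)
    ghx = _open_pixel_integrals_grad(theta_x, grid.x_edges, sigma_psf)
    ghy = _open_pixel_integrals_grad(theta_y, grid.y_edges, sigma_psf)
    open_gx, open_gy = np.outer(hy, ghx), np.outer(ghy, hx)
    if not exposure.has_pinhole:
        return open_gx, open_gy
    if mesh_n < 2:
        raise ValueError("mesh_n must be at least 2")
    xp, yp, radius = exposure.xp, exposure.yp, exposure.pinhole_radius
    fully_inside, _ = _pixel_disk_classification(xp, yp, radius, grid)
    out_x = np.where(fully_inside, open_gx, 0.0).reshape(-1)
    out_y = np.where(fully_inside, open_gy, 0.0).reshape(-1)
    pts, idx, cell_area = _boundary_quadrature(xp, yp, radius, mesh_n, grid)
    if len(pts):
        s2 = sigma_psf * sigma_psf
        dx = pts[:, 0] - theta_x
        dy = pts[:, 1] - theta_y
        dens = np.exp(-(dx * dx + dy * dy) / (2.0 * s2))
        dens *= cell_area / (2.0 * math.pi * s2)
        out_x += np.bincount(idx, weights=dens * dx / s2, minlength=out_x.size)
        out_y += np.bincount(idx, weights=dens * dy / s2, minlength=out_y.size)
    shape = (grid.ny, grid.nx)
    return out_x.reshape(shape), out_y.reshape(shape)


def windowed_psf_H_gradient(
    theta_x: float,
    theta_y: float,
    pixel: Tuple[int, int],
    exposure: Exposure,
    grid: PixelGrid,
    sigma_psf: float,
    mesh_n: int = 100,
) -> Tuple[float, float]:
    ix, iy = pixel
    grid.pixel_center(ix, iy)
    gx, gy = windowed_psf_H_gradient_all(theta_x, theta_y, exposure, grid, sigma_psf, mesh_n)
    return float(gx[iy, ix]), float(gy[iy, ix])


def total_transmission(
    theta_x: float,
    theta_y: float,
    exposure: Exposure,
    grid: PixelGrid,
    sigma_psf: float,
    mesh_n: int = 100,
) -> float:
    """Fraction of emitted photons passing the pinhole and landing in the ROI."""
    return float(
        windowed_psf_H_all(theta_x, theta_y, exposure, grid, sigma_psf, mesh_n).sum()
    )
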