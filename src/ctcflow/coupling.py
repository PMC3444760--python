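"""Eulerian–Lagrangian exchange via a regularized Dirac delta.

Boundary forces are spread from the Lagrangian points onto the fluid grid,

    f(x) = sum_l F(l) * delta_h(x - X(l)) * ds(l),

and fluid velocity is interpolated back to the points,

    U(l) = sum_x u(x) * delta_h(x - X(l)) * h^2,

with the same kernel in both directions, which makes the two operators
exact adjoints (the discrete power identity sum_x u . f h^2 =
sum_l U . F ds holds to round-off).  The default kernel is Peskin's
4-point function

    phi(r) = (3 - 2|r| + sqrt(1 + 4|r| - 4 r^2)) / 8        for |r| <= 1,
             (5 - 2|r| - sqrt(-7 + 12|r| - 4 r^2)) / 8      for 1 <= |r| <= 2,

whose translates form a partition of unity and reproduce linear fields
exactly.  The domain is periodic in both directions; point coordinates are
wrapped into the box only inside these operators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DeltaKernel", "PESKIN4", "delta_weight", "spread", "interpolate"]


def _phi4(r: np.ndarray) -> np.ndarray:
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    m1 = r <= 1.0
    m2 = (r > 1.0) & (r < 2.0)
    out[m1] = (3.0 - 2.0 * r[m1] + np.sqrt(1.0 + 4.0 * r[m1] - 4.0 * r[m1] ** 2)) / 8.0
    out[m2] = (5.0 - 2.0 * r[m2] - np.sqrt(-7.0 + 12.0 * r[m2] - 4.0 * r[m2] ** 2)) / 8.0
    return out


@dataclass(frozen=True)
class DeltaKernel:
    """Regularized 1D delta weight function with compact support."""

    support: int  # half-width in grid cells
    name: str = "peskin4"

    def __call__(self, r):
        scalar = np.isscalar(r)
        w = _phi4(r)
        return float(w) if scalar else w

    def offsets(self) -> np.ndarray:
        """Stencil offsets relative to floor(x/h)."""
        return np.arange(1 - self.support, self.support + 1)


PESKIN4 = DeltaKernel(support=2)


def delta_weight(r, kernel: DeltaKernel = PESKIN4):
    """1D kernel weight phi(r) at dimensionless grid offset r."""
    return kernel(r)


def _stencil(x, h, n, kernel):
    """Stencil indices (wrapped) and weights along one axis."""
    s = np.asarray(x, dtype=float) / h
    base = np.floor(s).astype(np.intp)
    offs = kernel.offsets()  # e.g. [-1, 0, 1, 2]
    idx = (base[:, None] + offs[None, :]) % n
    w = kernel(s[:, None] - (base[:, None] + offs[None, :]))
    return idx, w


def spread(xy: np.ndarray, forces: np.ndarray, ds: np.ndarray, grid,
           kernel: DeltaKernel = PESKIN4) -> np.ndarray:
    """Spread per-point forces onto the grid as a body-force field.

    Parameters
    ----------
    xy : (N, 2) point positions, cm
    forces : (N, 2) point forces, dyn
    ds : (N,) boundary quadrature weights, cm
    grid : object with nx, ny, hx, hy, Lx, Ly attributes

    Returns
    -------
    (2, ny, nx) body-force field: forces[l] * phi * phi * ds[l] / (hx*hy)
    accumulated over the tensor-product stencil of each point.
    """
    xy = np.asarray(xy, dtype=float)
    forces = np.asarray(forces, dtype=float)
    ix, wx = _stencil(xy[:, 0], grid.hx, grid.nx, kernel)
    iy, wy = _stencil(xy[:, 1], grid.hy, grid.ny, kernel)
    f = np.zeros((2, grid.ny, grid.nx))
    scale = np.asarray(ds, dtype=float) / (grid.hx * grid.hy)
    fw = forces * scale[:, None]  # (N, 2)
    ns = wx.shape[1]
    for a in range(ns):
        wya = wy[:, a]
        iya = iy[:, a]
        for b in range(ns):
            w = wya * wx[:, b]
            flat = iya * grid.nx + ix[:, b]
            np.add.at(f[0].ravel(), flat, fw[:, 0] * w)
            np.add.at(f[1].ravel(), flat, fw[:, 1] * w)
    return f


def interpolate(u: np.ndarray, xy: np.ndarray, grid,
                kernel: DeltaKernel = PESKIN4) -> np.ndarray:
    """Interpolate a grid velocity field to the points.

    ``u`` is (2, ny, nx) in cm/s; returns (N, 2) point velocities.  For any
    field that is constant or linear in x and y the interpolated values are
    exact (moment conditions of the 4-point kernel).
    """
    xy = np.asarray(xy, dtype=float)
    ix, wx = _stencil(xy[:, 0], grid.hx, grid.nx, kernel)
    iy, wy = _stencil(xy[:, 1], grid.hy, grid.ny, kernel)
    out = np.zeros((len(xy), 2))
    u0 = u[0].ravel()
    u1 = u[1].ravel()
    ns = wx.shape[1]
    for a in range(ns):
        wya = wy[:, a]
        iya = iy[:, a]
        for b in range(ns):
            w = wya * wx[:, b]
            flat = iya * grid.nx + ix[:, b]
            out[:, 0] += u0[flat] * w
            out[:, 1] += u1[flat] * w
    return out
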