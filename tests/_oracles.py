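"""Independent reference computations used by the test suite.

These deliberately avoid the package's time-stepping code paths: the
homogeneous-medium oracle evaluates the closed-form free-space solution
``p(t) = IFFT[cos(c k t) FFT(p0)]`` of the lossless wave equation on an
enlarged periodic grid (large enough that wrap-around cannot reach the
sensors within the horizon), and the interpolation oracle is a separable
two-pass 1D linear interpolation.
"""

from __future__ import annotations

import numpy as np

from patjrec.grid import Grid, SensorArray


def analytic_homogeneous_field(
    grid: Grid, c: float, p0_interior: np.ndarray, step: int, factor: int = 4
) -> np.ndarray:
    """Free-space pressure at time step ``step`` on the full grid."""
    nbig = grid.n_total * factor
    off = (nbig - grid.n_total) // 2
    big = np.zeros((nbig, nbig))
    big[off : off + grid.n_total, off : off + grid.n_total] = grid.embed(p0_interior)
    k1 = 2.0 * np.pi * np.fft.fftfreq(nbig, d=grid.dx)
    kk = np.hypot(k1[:, None], k1[None, :])
    p = np.fft.ifft2(np.cos(c * kk * step * grid.dt) * np.fft.fft2(big)).real
    return p[off : off + grid.n_total, off : off + grid.n_total]


def analytic_homogeneous_traces(
    grid: Grid, c: float, p0_interior: np.ndarray, sensors: SensorArray, factor: int = 4
) -> np.ndarray:
    """Free-space sensor traces, shape (count, nt)."""
    nbig = grid.n_total * factor
    off = (nbig - grid.n_total) // 2
    big = np.zeros((nbig, nbig))
    big[off : off + grid.n_total, off : off + grid.n_total] = grid.embed(p0_interior)
    k1 = 2.0 * np.pi * np.fft.fftfreq(nbig, d=grid.dx)
    kk = np.hypot(k1[:, None], k1[None, :])
    P0 = np.fft.fft2(big)
    si = sensors.indices[:, 0] + off
    sj = sensors.indices[:, 1] + off
    y = np.empty((sensors.count, grid.nt))
    for n in range(grid.nt):
        p = np.fft.ifft2(np.cos(c * kk * n * grid.dt) * P0).real
        y[:, n] = p[si, sj]
    return y


def separable_linear_interp(field: np.ndarray, x_from: np.ndarray, x_to: np.ndarray) -> np.ndarray:
    """Two-pass 1D linear interpolation of a square field (rows then cols)."""
    x_to = np.clip(x_to, x_from[0], x_from[-1])
    tmp = np.empty((field.shape[0], x_to.size))
    for i in range(field.shape[0]):
        tmp[i] = np.interp(x_to, x_from, field[i])
    out = np.empty((x_to.size, x_to.size))
    for j in range(x_to.size):
        out[:, j] = np.interp(x_to, x_from, tmp[:, j])
    return out


def gaussian_blob(grid: Grid, centre_frac=(0.5, 0.5), width_m: float = 3e-4, amp: float = 10.0) -> np.ndarray:
    """Band-limited initial pressure on the target domain."""
    xi = grid.interior_coords()
    xx, yy = np.meshgrid(xi, xi, indexing="ij")
    cx, cy = centre_frac[0] * grid.extent, centre_frac[1] * grid.extent
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * width_m**2))
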