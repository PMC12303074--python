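"""k-space pseudo-spectral solution of the photoacoustic initial value problem.

The acoustic model is the lossless second-order wave equation

    (1/c(r)^2) d2p/dt2 - laplacian(p) = 0,   p(.,0) = p0,  dp/dt(.,0) = 0,

solved as the equivalent first-order system in particle velocity ``u`` and
split acoustic density ``(rho_x, rho_y)`` (unit ambient density) with
spectral spatial derivatives on staggered grids, a k-space correction factor
``sinc(c_ref k dt / 2)`` that makes the scheme exact for homogeneous media
at any stable time step, a leapfrog time stagger (velocities live at half
steps), and a split-field PML.  The initial condition ``dp/dt(.,0) = 0`` is
realised by a symmetric half-length first velocity update.

Pressure is recorded at sensor nodes every time step; the full
spatio-temporal field can be kept for adjoint-state gradient computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.fft as _fft

from .grid import Grid, PMLProfile, SensorArray, make_pml

__all__ = [
    "Medium",
    "PressureField",
    "SensorData",
    "StabilityError",
    "KSpaceSolver",
    "simulate_forward",
    "second_time_derivative",
    "sample_sensors",
    "save_sensor_datasets",
    "load_sensor_datasets",
    "export_sensor_data_csv",
]

#: leapfrog stability bound on c_max * dt / dx for the uncorrected scheme;
#: kept as a hard limit even though the k-space correction with
#: c_ref >= max(c) relaxes it, because accuracy degrades well before blow-up.
CFL_LIMIT = 2.0 / np.pi


class StabilityError(RuntimeError):
    pass


@dataclass
class Medium:
    """Heterogeneous speed of sound on the full grid.

    ``c_ref`` is the scalar reference speed of the k-space correction;
    stability of the corrected scheme requires ``c_ref >= max(c)``, which is
    the default.  A fixed ``c_ref`` independent of ``c`` should be used when
    ``c`` is an optimisation variable so the propagator's spectral filter
    does not change between gradient evaluations.
    """

    c: np.ndarray
    c_ref: Optional[float] = None

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if np.any(self.c <= 0):
            raise ValueError("speed of sound must be positive everywhere")
        if self.c_ref is None:
            self.c_ref = float(self.c.max())


@dataclass
class PressureField:
    """Full spatio-temporal pressure, shape ``(nt, n_total, n_total)``."""

    p: np.ndarray
    dt: float

    @property
    def nt(self) -> int:
        return self.p.shape[0]


@dataclass
class SensorData:
    """Sensor traces ``y`` with shape ``(n_sensors, nt)`` plus provenance."""

    y: np.ndarray
    dt: float
    dx: float
    sensor_positions: np.ndarray
    dataset_index: int = 0

    @property
    def nt(self) -> int:
        return self.y.shape[1]

    @property
    def n_sensors(self) -> int:
        return self.y.shape[0]


class KSpaceSolver:
    """Precomputed spectral operators and PML factors for one grid/medium.

    The instance is reused across forward and adjoint runs; the adjoint in
    :mod:`patjrec.adjoint` is the exact algebraic transpose of
    :meth:`run_forward`.
    """

    def __init__(self, grid: Grid, medium: Medium, pml: Optional[PMLProfile] = None):
        if medium.c.shape != (grid.n_total, grid.n_total):
            raise ValueError("medium must be defined on the full grid")
        cfl = float(medium.c.max()) * grid.dt / grid.dx
        if cfl > CFL_LIMIT:
            raise StabilityError(
                f"c_max*dt/dx = {cfl:.3f} exceeds the stability bound "
                f"{CFL_LIMIT:.3f}; reduce dt or refine the medium"
            )
        self.grid = grid
        self.medium = medium
        self.c2 = medium.c ** 2
        if pml is None:
            pml = make_pml(grid)
        self.pml = pml

        n = grid.n_total
        k1 = 2.0 * np.pi * np.fft.fftfreq(n, d=grid.dx)
        kx = k1[:, None]  # full length along axis 0
        ky = np.abs(k1[: n // 2 + 1])[None, :]  # rfft half axis 1
        k = np.hypot(kx, ky)
        kappa = np.sinc(medium.c_ref * k * grid.dt / (2.0 * np.pi))
        sx = np.exp(1j * kx * grid.dx / 2.0)
        sy = np.exp(1j * ky * grid.dx / 2.0)
        self._dxf = 1j * kx * kappa * sx
        self._dxb = 1j * kx * kappa / sx
        self._dyf = 1j * ky * kappa * sy
        self._dyb = 1j * ky * kappa / sy

        # split-field damping factors, exp(-sigma/2) applied twice per update
        self.au_x = np.exp(-pml.sigma_x_stag / 2.0)[:, None]
        self.au_y = np.exp(-pml.sigma_y_stag / 2.0)[None, :]
        self.ar_x = np.exp(-pml.sigma_x / 2.0)[:, None]
        self.ar_y = np.exp(-pml.sigma_y / 2.0)[None, :]
        self.au_x2 = self.au_x**2
        self.au_y2 = self.au_y**2
        self.ar_x2 = self.ar_x**2
        self.ar_y2 = self.ar_y**2
        self._shape = (n, n)

    # -- spectral derivatives ------------------------------------------------
    def _apply(self, spectrum: np.ndarray, tf: np.ndarray) -> np.ndarray:
        return _fft.irfft2(tf * spectrum, s=self._shape, overwrite_x=True)

    def grad_p(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Staggered-forward spectral gradient of a pressure field."""
        spec = _fft.rfft2(p)
        return self._apply(spec, self._dxf), self._apply(spec, self._dyf)

    def div_u(self, ux: np.ndarray, uy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Staggered-backward spectral x- and y-derivatives of velocities."""
        return (
            self._apply(_fft.rfft2(ux), self._dxb),
            self._apply(_fft.rfft2(uy), self._dyb),
        )

    # transposed operators: adjoint of d_forward is -d_backward and v.v.
    def grad_p_T(self, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
        return -(
            self._apply(_fft.rfft2(fx), self._dxb)
            + self._apply(_fft.rfft2(fy), self._dyb)
        )

    def div_u_T(self, gx: np.ndarray, gy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (
            -self._apply(_fft.rfft2(gx), self._dxf),
            -self._apply(_fft.rfft2(gy), self._dyf),
        )

    # -- forward run ---------------------------------------------------------
    def run_forward(
        self,
        p0_full: np.ndarray,
        sensors: Optional[SensorArray] = None,
        record_full: bool = False,
    ) -> tuple[Optional[np.ndarray], Optional[np.ndarray]]:
        """March the scheme from an initial pressure on the full grid.

        Returns ``(y, p_all)``: sensor traces ``(count, nt)`` if ``sensors``
        given, and the pressure movie ``(nt, n, n)`` if ``record_full``.
        """
        grid, dt = self.grid, self.grid.dt
        c2 = self.c2
        rhox = p0_full / (2.0 * c2)
        rhoy = rhox.copy()
        ux = np.zeros(self._shape)
        uy = np.zeros(self._shape)
        p = p0_full.astype(float, copy=True)

        y = None
        if sensors is not None:
            y = np.empty((sensors.count, grid.nt))
            si, sj = sensors.indices[:, 0], sensors.indices[:, 1]
            y[:, 0] = p[si, sj]
        p_all = None
        if record_full:
            p_all = np.empty((grid.nt, *self._shape))
            p_all[0] = p

        for n in range(grid.nt - 1):
            dtn = dt / 2.0 if n == 0 else dt
            gx, gy = self.grad_p(p)
            ux = self.au_x2 * ux - (dtn * self.au_x) * gx
            uy = self.au_y2 * uy - (dtn * self.au_y) * gy
            hx, hy = self.div_u(ux, uy)
            rhox = self.ar_x2 * rhox - (dt * self.ar_x) * hx
            rhoy = self.ar_y2 * rhoy - (dt * self.ar_y) * hy
            p = c2 * (rhox + rhoy)
            if sensors is not None:
                y[:, n + 1] = p[si, sj]
            if record_full:
                p_all[n + 1] = p
            if (n + 1) % 128 == 0 and not np.isfinite(p[0, 0]):
                raise StabilityError(f"numerical blow-up at step {n + 1}")
        if not np.all(np.isfinite(p)):
            raise StabilityError("numerical blow-up: non-finite pressure at final step")
        return y, p_all


def simulate_forward(
    medium: Medium,
    p0: np.ndarray,
    grid: Grid,
    sensors: SensorArray,
    record_full: bool = False,
    pml: Optional[PMLProfile] = None,
    dataset_index: int = 0,
) -> tuple[SensorData, Optional[PressureField]]:
    """Propagate an initial pressure and record it at the sensors.

    ``p0`` may be given on the target domain (zero-padded into the margins)
    or on the full grid.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape == (grid.n_interior, grid.n_interior):
        p0_full = grid.embed(p0)
    elif p0.shape == (grid.n_total, grid.n_total):
        p0_full = p0
    else:
        raise ValueError(f"p0 shape {p0.shape} matches neither target nor full grid")
    solver = KSpaceSolver(grid, medium, pml)
    y, p_all = solver.run_forward(p0_full, sensors, record_full)
    data = SensorData(
        y=y,
        dt=grid.dt,
        dx=grid.dx,
        sensor_positions=sensors.positions.copy(),
        dataset_index=dataset_index,
    )
    full = PressureField(p=p_all, dt=grid.dt) if record_full else None
    return data, full


def second_time_derivative(field: PressureField) -> PressureField:
    """d2p/dt2 by centred differences; second-order one-sided at the ends."""
    p, dt = field.p, field.dt
    if field.nt < 3:
        raise ValueError("need at least 3 time samples")
    out = np.empty_like(p)
    out[1:-1] = (p[2:] - 2.0 * p[1:-1] + p[:-2]) / dt**2
    if field.nt >= 4:
        out[0] = (2.0 * p[0] - 5.0 * p[1] + 4.0 * p[2] - p[3]) / dt**2
        out[-1] = (2.0 * p[-1] - 5.0 * p[-2] + 4.0 * p[-3] - p[-4]) / dt**2
    else:
        out[0] = out[1]
        out[-1] = out[1]
    return PressureField(p=out, dt=dt)


def sample_sensors(field: PressureField, sensors: SensorArray) -> SensorData:
    """Extract sensor-node traces from a recorded pressure movie."""
    n = field.p.shape[1]
    si, sj = sensors.indices[:, 0], sensors.indices[:, 1]
    if si.max() >= n or sj.max() >= n or si.min() < 0 or sj.min() < 0:
        raise ValueError("sensor index outside the recorded field")
    return SensorData(
        y=field.p[:, si, sj].T.copy(),
        dt=field.dt,
        dx=np.nan,
        sensor_positions=sensors.positions.copy(),
    )


# -- persistence -------------------------------------------------------------

def save_sensor_datasets(path, datasets: list[SensorData]) -> None:
    """Write datasets to an HDF5 container, one group per dataset."""
    import h5py

    with h5py.File(path, "w") as f:
        for d in datasets:
            g = f.create_group(f"dataset_{d.dataset_index}")
            g.create_dataset("y", data=d.y)
            g.attrs["dt"] = d.dt
            g.attrs["dx"] = d.dx
            g.create_dataset("sensor_positions", data=d.sensor_positions)


def load_sensor_datasets(path) -> list[SensorData]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f, key=lambda s: int(s.split("_")[1])):
            g = f[name]
            out.append(
                SensorData(
                    y=g["y"][()],
                    dt=float(g.attrs["dt"]),
                    dx=float(g.attrs["dx"]),
                    sensor_positions=g["sensor_positions"][()],
                    dataset_index=int(name.split("_")[1]),
                )
            )
    return out


def export_sensor_data_csv(path, data: SensorData) -> None:
    """Plain-text export: one row per time sample, one column per sensor."""
    import pandas as pd

    t = np.arange(data.nt) * data.dt
    df = pd.DataFrame(
        data.y.T, columns=[f"sensor_{i}" for i in range(data.n_sensors)]
    )
    df.insert(0, "time_s", t)
    df.to_csv(path, index=False)
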