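"""Computational grids, spectral operators, sensor layout and PML profiles.

The computational domain is a square: an ``n_interior`` x ``n_interior``
target region (the imaged object), surrounded on each side by a band of
``n_sensor_margin`` pixels in which point-like ultrasound sensors live, and
an outermost perfectly-matched-layer (PML) band of ``n_pml`` pixels that
absorbs outgoing waves.  All lengths are SI metres, times are seconds.

Coordinate convention: 0-based pixel indices over the *full* grid; physical
coordinates are pixel centres with the origin at the corner of the target
domain, so target pixel ``(0, 0)`` sits at ``(dx/2, dx/2)`` and the sensor
and PML bands have negative / beyond-extent coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Grid",
    "Wavenumbers",
    "SensorArray",
    "PMLProfile",
    "make_grid",
    "max_supported_frequency",
    "make_wavenumbers",
    "place_sensors",
    "make_pml",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent grid / sensor / PML configuration."""


@dataclass(frozen=True)
class Grid:
    """Spatial and temporal discretisation of the computational domain.

    Parameters
    ----------
    n_interior : int
        Pixels per side of the target domain.
    dx : float
        Pixel size in metres (the grid is isotropic).
    n_sensor_margin : int
        Pixels added outside the target on each side to hold sensors.
    n_pml : int
        PML pixels added outside the target + sensor region on each side.
    dt : float
        Time step in seconds.
    nt : int
        Number of recorded time samples; the horizon is ``T = (nt - 1) dt``.
    """

    n_interior: int
    dx: float
    n_sensor_margin: int
    n_pml: int
    dt: float
    nt: int

    def __post_init__(self) -> None:
        if self.n_interior < 1 or self.nt < 2:
            raise ConfigurationError("n_interior >= 1 and nt >= 2 required")
        if self.n_sensor_margin < 0 or self.n_pml < 0:
            raise ConfigurationError("margins must be non-negative")
        if not (self.dx > 0 and self.dt > 0):
            raise ConfigurationError("dx and dt must be positive")

    @property
    def n_total(self) -> int:
        """Pixels per side of the full grid (target + margins + PML)."""
        return self.n_interior + 2 * (self.n_sensor_margin + self.n_pml)

    @property
    def i0(self) -> int:
        """Index of the first target-domain pixel along either axis."""
        return self.n_pml + self.n_sensor_margin

    @property
    def interior_slice(self) -> slice:
        return slice(self.i0, self.i0 + self.n_interior)

    @property
    def extent(self) -> float:
        """Physical side length of the target domain, metres."""
        return self.n_interior * self.dx

    @property
    def T(self) -> float:
        """Final simulated time, seconds."""
        return (self.nt - 1) * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.nt) * self.dt

    def axis_coords(self) -> np.ndarray:
        """Pixel-centre coordinates of the full grid along one axis."""
        return (np.arange(self.n_total) - self.i0 + 0.5) * self.dx

    def interior_coords(self) -> np.ndarray:
        """Pixel-centre coordinates of the target domain along one axis."""
        return (np.arange(self.n_interior) + 0.5) * self.dx

    def embed(self, interior_field: np.ndarray) -> np.ndarray:
        """Zero-pad a target-domain field onto the full grid."""
        interior_field = np.asarray(interior_field, dtype=float)
        if interior_field.shape != (self.n_interior, self.n_interior):
            raise ValueError(
                f"expected {(self.n_interior,) * 2}, got {interior_field.shape}"
            )
        full = np.zeros((self.n_total, self.n_total))
        full[self.interior_slice, self.interior_slice] = interior_field
        return full

    def restrict(self, full_field: np.ndarray) -> np.ndarray:
        """Extract the target-domain part of a full-grid field."""
        return np.asarray(full_field)[self.interior_slice, self.interior_slice]


@dataclass(frozen=True)
class Wavenumbers:
    """FFT-ordered angular spatial frequencies of the full grid, rad/m."""

    kx: np.ndarray
    ky: np.ndarray
    k: np.ndarray


@dataclass(frozen=True)
class SensorArray:
    """Point sensors snapped to full-grid nodes.

    ``indices`` are (row, col) full-grid pixel indices, ``positions`` the
    corresponding physical pixel-centre coordinates in metres.
    """

    indices: np.ndarray  # (count, 2) int
    positions: np.ndarray  # (count, 2) float

    @property
    def count(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class PMLProfile:
    """Per-axis polynomial absorption ramps (1/s), zero off the PML bands."""

    sigma_x: np.ndarray  # varies along axis 0, shape (n_total,)
    sigma_y: np.ndarray  # varies along axis 1, shape (n_total,)
    sigma_x_stag: np.ndarray  # evaluated at half-pixel staggered points
    sigma_y_stag: np.ndarray
    order: int
    peak: float


def make_grid(
    n_interior: int,
    dx: float,
    n_sensor_margin: int,
    n_pml: int,
    dt: float,
    nt: int,
) -> Grid:
    """Build a :class:`Grid`; raises ``ConfigurationError`` on bad input."""
    return Grid(n_interior, dx, n_sensor_margin, n_pml, dt, nt)


def max_supported_frequency(grid: Grid, c_min: float) -> float:
    """Highest acoustic frequency the grid can represent, ``c_min / (2 dx)``.

    Two points per wavelength at the slowest propagation speed; the
    reference speed is explicit because heterogeneous media have no single
    canonical choice.
    """
    if c_min <= 0:
        raise ConfigurationError("c_min must be positive")
    return c_min / (2.0 * grid.dx)


def make_wavenumbers(grid: Grid) -> Wavenumbers:
    """Angular wavenumber fields of the full grid in FFT ordering."""
    n = grid.n_total
    k1 = 2.0 * np.pi * np.fft.fftfreq(n, d=grid.dx)
    kx = np.broadcast_to(k1[:, None], (n, n)).copy()
    ky = np.broadcast_to(k1[None, :], (n, n)).copy()
    return Wavenumbers(kx=kx, ky=ky, k=np.hypot(kx, ky))


def place_sensors(grid: Grid, count: int, inset: float) -> SensorArray:
    """Distribute ``count`` point sensors on a square contour around the target.

    The contour sits at a distance ``inset`` outside the target boundary,
    inside the sensor margin band.  Sensors are spread as evenly as possible
    over the four sides (``count // 4`` per side plus remainders, corners not
    duplicated) and snapped to the nearest grid node.
    """
    if count < 4:
        raise ConfigurationError("need at least 4 sensors (one per side)")
    band = grid.n_sensor_margin * grid.dx
    if not (0.0 <= inset < band):
        raise ConfigurationError(
            f"sensor inset {inset} outside the sensor margin band [0, {band})"
        )
    lo, hi = -inset, grid.extent + inset
    per_side = [count // 4] * 4
    for s in range(count % 4):
        per_side[s] += 1

    pts = []
    for side, m in enumerate(per_side):
        # place m points evenly on the open side segment (corners excluded
        # by a half-step offset so adjacent sides never collide)
        t = (np.arange(m) + 0.5) / m * (hi - lo) + lo
        if side == 0:  # top edge  (row = lo)
            pts.extend((lo, ti) for ti in t)
        elif side == 1:  # right edge (col = hi)
            pts.extend((ti, hi) for ti in t)
        elif side == 2:  # bottom edge
            pts.extend((hi, ti) for ti in t)
        else:  # left edge
            pts.extend((ti, lo) for ti in t)

    coords = grid.axis_coords()
    idx = np.empty((count, 2), dtype=int)
    for s, (r, c) in enumerate(pts):
        idx[s] = (np.argmin(np.abs(coords - r)), np.argmin(np.abs(coords - c)))
    # snapping may merge neighbours on very coarse grids; keep order, dedupe
    seen: dict[tuple[int, int], None] = {}
    for i, j in idx:
        seen.setdefault((int(i), int(j)), None)
    uniq = np.array(list(seen.keys()), dtype=int)
    positions = np.stack([coords[uniq[:, 0]], coords[uniq[:, 1]]], axis=1)
    return SensorArray(indices=uniq, positions=positions)


def make_pml(grid: Grid, order: int = 4, peak: float = 2.0) -> PMLProfile:
    """Polynomial PML absorption ramps.

    The stored profile is the dimensionless absorption accumulated per time
    step: ``peak * (depth / n_pml) ** order``, zero inside the target and
    sensor bands.  The wave solver damps split fields by
    ``exp(-profile / 2)`` before and after each update, so at full depth a
    field loses a factor ``exp(-peak)`` per step.  Staggered samples are
    provided for the velocity components.
    """
    if order < 1 or peak < 0:
        raise ConfigurationError("order >= 1 and peak >= 0 required")
    n, npml = grid.n_total, grid.n_pml

    def ramp(x: np.ndarray) -> np.ndarray:
        sigma = np.zeros_like(x)
        if npml > 0:
            left = x < npml
            sigma[left] = ((npml - x[left]) / npml) ** order
            right = x > n - 1 - npml
            sigma[right] = ((x[right] - (n - 1 - npml)) / npml) ** order
        return peak * sigma

    xi = np.arange(n, dtype=float)
    return PMLProfile(
        sigma_x=ramp(xi),
        sigma_y=ramp(xi),
        sigma_x_stag=ramp(xi + 0.5),
        sigma_y_stag=ramp(xi + 0.5),
        order=order,
        peak=peak,
    )
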