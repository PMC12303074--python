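"""Synthetic phantoms, light transport, and measurement-noise generation.

Two phantom families are provided:

* simple circular-inclusion phantoms -- piecewise-constant speed of sound
  (circular inclusions, optional water-bath layer, optional high-contrast
  rectangular bone-like inclusion) with initial-pressure disk sets defined
  directly, dataset by dataset;
* a procedural 2D breast-like tissue phantom -- chromophore volume-fraction
  maps (oxy-/deoxyhaemoglobin as whole-blood fractions, water, fat) with
  vessel-like curvilinear absorbers, a reference reduced-scattering map,
  and a smoothly heterogeneous speed of sound, from which initial pressures
  are produced by a continuous-wave diffusion-approximation light model
  under planar multi-directional illumination, multiple wavelengths, or
  exogenous boundary absorbers.

The bundled chromophore table (``data/chromophore_spectra_representative.csv``)
holds representative literature-scale absorption values per unit volume
fraction; it is a synthetic stand-in, not a measured reference spectrum,
and can be replaced by the user.

Optical quantities use millimetres (the field's convention); acoustic
quantities stay in SI metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .forward import Medium, SensorData
from .grid import Grid

__all__ = [
    "Disk",
    "PhantomSpec",
    "OpticalMaps",
    "IlluminationSpec",
    "build_simple_phantom",
    "simple_phantom_spec",
    "scaled_twin_spec",
    "diffusion_fluence",
    "p0_from_fluence",
    "load_chromophore_table",
    "spectral_mu_a",
    "add_exogenous_absorbers",
    "add_noise",
    "tissue_phantom",
]

SIDES = ("top", "left", "bottom", "right")


@dataclass(frozen=True)
class Disk:
    """Circular region: centre (metres, target-domain coords), radius, value."""

    cx: float
    cy: float
    r: float
    value: float


@dataclass
class PhantomSpec:
    """Piecewise-constant acoustic phantom with per-dataset pressure disks."""

    background_c: float
    c_inclusions: list[Disk]
    p0_disks: list[list[Disk]]  # one disk list per dataset
    water_bath: Optional[tuple[float, float, float]] = None  # (y0, y1, c) band
    bone: Optional[tuple[float, float, float, float, float]] = None  # (x0,x1,y0,y1,c)

    @property
    def n_datasets(self) -> int:
        return len(self.p0_disks)


@dataclass
class OpticalMaps:
    """Either direct optical coefficients or chromophore volume fractions.

    ``mu_a`` and ``mu_s_prime`` are in 1/mm.  Fraction maps are
    dimensionless in [0, 1]; ``mu_s_ref`` (1/mm) is the reduced scattering
    at ``lambda_ref`` (nm), scaled to other wavelengths by a power law with
    exponent ``scatter_power``.
    """

    mu_a: Optional[np.ndarray] = None
    mu_s_prime: Optional[np.ndarray] = None
    v_hbo2: Optional[np.ndarray] = None
    v_hhb: Optional[np.ndarray] = None
    v_water: Optional[np.ndarray] = None
    v_fat: Optional[np.ndarray] = None
    mu_s_ref: Optional[np.ndarray] = None
    lambda_ref: float = 800.0
    scatter_power: float = 1.2
    mu_a_baseline: float = 1e-3  # residual background absorption, 1/mm

    def mu_s_at(self, wavelength_nm: float) -> np.ndarray:
        if self.mu_s_prime is not None:
            return self.mu_s_prime
        if self.mu_s_ref is None:
            raise ValueError("no scattering information available")
        return self.mu_s_ref * (wavelength_nm / self.lambda_ref) ** (-self.scatter_power)


@dataclass
class IlluminationSpec:
    """Planar illumination sides, wavelengths, and exogenous absorbers."""

    sides: tuple[str, ...] = ("top",)
    wavelengths_nm: tuple[float, ...] = ()
    absorbers: list[Disk] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sides:
            raise ValueError("at least one illuminated side required")
        bad = set(self.sides) - set(SIDES)
        if bad:
            raise ValueError(f"unknown sides {bad}; use {SIDES}")


# -- rasterisation -----------------------------------------------------------

def _pixel_centres(grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    xi = grid.interior_coords()
    return np.meshgrid(xi, xi, indexing="ij")


def _disk_mask(grid: Grid, d: Disk) -> np.ndarray:
    xx, yy = _pixel_centres(grid)
    return (xx - d.cx) ** 2 + (yy - d.cy) ** 2 <= d.r**2


def _check_inside(grid: Grid, d: Disk, what: str) -> None:
    ext = grid.extent
    if not (0 <= d.cx - d.r and d.cx + d.r <= ext and 0 <= d.cy - d.r and d.cy + d.r <= ext):
        raise ValueError(f"{what} disk at ({d.cx:.4g},{d.cy:.4g}) r={d.r:.4g} "
                         f"extends outside the {ext:.4g} m target domain")


def build_simple_phantom(spec: PhantomSpec, grid: Grid) -> tuple[Medium, list[np.ndarray]]:
    """Rasterise a :class:`PhantomSpec` onto a grid.

    Pixel membership is a centre-inside-region test.  Returns a full-grid
    :class:`Medium` (margins at the background speed) and one target-domain
    initial pressure map per dataset.
    """
    n = grid.n_interior
    c = np.full((n, n), spec.background_c)
    xx, yy = _pixel_centres(grid)
    if spec.water_bath is not None:
        y0, y1, cw = spec.water_bath
        c[(xx >= y0) & (xx < y1)] = cw  # band across the top rows
    if spec.bone is not None:
        x0, x1, y0, y1, cb = spec.bone
        c[(xx >= x0) & (xx < x1) & (yy >= y0) & (yy < y1)] = cb
    for d in spec.c_inclusions:
        _check_inside(grid, d, "speed-of-sound")
        c[_disk_mask(grid, d)] = d.value
    p0_list = []
    for disks in spec.p0_disks:
        p0 = np.zeros((n, n))
        for d in disks:
            _check_inside(grid, d, "initial-pressure")
            p0[_disk_mask(grid, d)] = d.value
        p0_list.append(p0)
    c_full = np.full((grid.n_total, grid.n_total), spec.background_c)
    c_full[grid.interior_slice, grid.interior_slice] = c
    return Medium(c=c_full), p0_list


def simple_phantom_spec(variant: str = "low_contrast") -> PhantomSpec:
    """Default circular-inclusion phantom on a 20 mm domain.

    Nine 1580 m/s inclusions in a 1430 m/s background on a loose 3x3
    arrangement; four initial-pressure datasets of 10 Pa disks in distinct
    arrangements.  ``water_bath`` adds a 1482 m/s layer; ``high_contrast``
    adds a 2500 m/s bone-like rectangle.  The inclusion geometry is a
    parameterised default, not a measured layout.
    """
    mm = 1e-3
    centres = [
        (4.0, 4.2), (10.0, 3.4), (16.0, 4.6),
        (3.6, 10.0), (10.2, 10.2), (16.4, 9.4),
        (4.0, 16.0), (9.6, 16.6), (16.0, 15.4),
    ]
    c_inc = [Disk(x * mm, y * mm, 1.5 * mm, 1580.0) for x, y in centres]
    p0_sets_mm = [
        [(4.5, 4.5), (10, 8), (15.5, 12), (7, 15)],
        [(15.5, 4.5), (10, 12), (4.5, 15.5), (13, 8)],
        [(10, 4), (4.5, 10), (10, 16), (15.5, 10)],
        [(6.5, 6.5), (13.5, 6.5), (13.5, 13.5), (6.5, 13.5)],
    ]
    p0_disks = [
        [Disk(x * mm, y * mm, 1.1 * mm, 10.0) for x, y in disks]
        for disks in p0_sets_mm
    ]
    spec = PhantomSpec(background_c=1430.0, c_inclusions=c_inc, p0_disks=p0_disks)
    if variant == "low_contrast":
        return spec
    if variant == "water_bath":
        spec.water_bath = (0.0, 2.5 * mm, 1482.0)
        return spec
    if variant == "high_contrast":
        spec.bone = (12.0 * mm, 17.0 * mm, 12.0 * mm, 17.0 * mm, 2500.0)
        return spec
    raise ValueError(f"unknown variant {variant!r}")


def scaled_twin_spec() -> PhantomSpec:
    """Desk-scale twin phantom on a 12.8 mm domain: three speed inclusions,
    four initial-pressure datasets whose disks cover different regions."""
    mm = 1e-3
    c_inc = [
        Disk(3.6 * mm, 4.4 * mm, 1.7 * mm, 1580.0),
        Disk(9.0 * mm, 3.4 * mm, 1.5 * mm, 1580.0),
        Disk(6.4 * mm, 9.4 * mm, 1.8 * mm, 1580.0),
    ]
    p0_sets_mm = [
        [(3.2, 3.2), (9.6, 6.4), (6.4, 10.6)],
        [(9.6, 3.2), (3.2, 9.6), (8.0, 9.8)],
        [(6.4, 3.0), (3.0, 6.4), (9.8, 9.6)],
        [(4.8, 8.0), (8.0, 4.8), (9.8, 3.0)],
    ]
    p0_disks = [
        [Disk(x * mm, y * mm, 0.9 * mm, 10.0) for x, y in disks]
        for disks in p0_sets_mm
    ]
    return PhantomSpec(background_c=1430.0, c_inclusions=c_inc, p0_disks=p0_disks)


# -- light transport ---------------------------------------------------------

def diffusion_fluence(
    mu_a: np.ndarray,
    mu_s_prime: np.ndarray,
    grid: Grid,
    sides: Sequence[str] = ("top",),
    source: float = 1.0,
) -> np.ndarray:
    """Continuous-wave diffusion-approximation fluence on the target domain.

    Solves ``-div(kappa grad(phi)) + mu_a phi = 0`` with
    ``kappa = 1/(2 (mu_a + mu_s'))`` (2D convention) and Robin boundary
    conditions ``kappa dphi/dn + phi/2 = I_s`` with inward flux ``I_s``
    equal to ``source`` on illuminated sides and zero elsewhere, via a
    finite-volume five-point scheme with harmonic-mean face diffusivities.

    ``mu_a``/``mu_s_prime`` are 1/mm on the ``n_interior`` grid.
    """
    n = grid.n_interior
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if mu_a.shape != (n, n) or mu_s_prime.shape != (n, n):
        raise ValueError("optical maps must live on the target-domain grid")
    if np.any(mu_a <= 0) or np.any(mu_s_prime <= 0):
        raise ValueError("mu_a and mu_s' must be positive")
    bad = set(sides) - set(SIDES)
    if bad:
        raise ValueError(f"unknown sides {bad}")
    dx = grid.dx * 1e3  # mm
    kappa = 1.0 / (2.0 * (mu_a + mu_s_prime))

    idx = np.arange(n * n).reshape(n, n)
    rows, cols, vals = [], [], []
    diag = mu_a.ravel().copy()

    def face(i_a, j_a, i_b, j_b):
        ka, kb = kappa[i_a, j_a], kappa[i_b, j_b]
        kf = 2.0 * ka * kb / (ka + kb)
        w = kf / dx**2
        a, b = idx[i_a, j_a], idx[i_b, j_b]
        rows.extend([a, a, b, b])
        cols.extend([a, b, b, a])
        vals.extend([w, -w, w, -w])

    for i in range(n):
        for j in range(n - 1):
            face(i, j, i, j + 1)
    for i in range(n - 1):
        for j in range(n):
            face(i, j, i + 1, j)

    rhs = np.zeros(n * n)
    # Robin faces: outward flux (phi/2 - I_s) per unit boundary length
    boundary = {
        "top": (idx[0, :],),
        "bottom": (idx[-1, :],),
        "left": (idx[:, 0],),
        "right": (idx[:, -1],),
    }
    for side, (cells,) in boundary.items():
        w = 0.5 / dx
        for a in cells:
            rows.append(a)
            cols.append(a)
            vals.append(w)
        if side in sides:
            rhs[cells] += source / dx

    A = sp.coo_matrix(
        (np.concatenate([vals, diag]),
         (np.concatenate([rows, np.arange(n * n)]),
          np.concatenate([cols, np.arange(n * n)]))),
        shape=(n * n, n * n),
    ).tocsc()
    phi = spla.spsolve(A, rhs)
    if not np.all(np.isfinite(phi)):
        raise RuntimeError(
            f"diffusion solve failed; residual {np.linalg.norm(A @ phi - rhs):.3e}"
        )
    return phi.reshape(n, n)


def p0_from_fluence(
    mu_a: np.ndarray, fluence: np.ndarray, gruneisen_scale: float = 1.0
) -> np.ndarray:
    """Photoacoustic efficiency: ``p0 = Gamma * mu_a * phi``."""
    mu_a = np.asarray(mu_a, dtype=float)
    fluence = np.asarray(fluence, dtype=float)
    if mu_a.shape != fluence.shape:
        raise ValueError("mu_a and fluence shapes differ")
    return gruneisen_scale * mu_a * fluence


_TABLE_CACHE: Optional[pd.DataFrame] = None


def load_chromophore_table() -> pd.DataFrame:
    """Bundled representative chromophore absorption table (1/mm per unit
    volume fraction; haemoglobin columns refer to whole blood)."""
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        with resources.files("patjrec.data").joinpath(
            "chromophore_spectra_representative.csv"
        ).open() as f:
            _TABLE_CACHE = pd.read_csv(f, comment="#")
    return _TABLE_CACHE


def spectral_mu_a(
    optics: OpticalMaps,
    wavelength_nm: float,
    spectra_table: Optional[pd.DataFrame] = None,
) -> np.ndarray:
    """Absorption map at a wavelength from chromophore volume fractions."""
    table = spectra_table if spectra_table is not None else load_chromophore_table()
    lam = table["wavelength_nm"].to_numpy()
    if not (lam.min() <= wavelength_nm <= lam.max()):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside table range "
            f"[{lam.min()}, {lam.max()}]"
        )
    parts = {
        "hbo2": optics.v_hbo2,
        "hhb": optics.v_hhb,
        "water": optics.v_water,
        "fat": optics.v_fat,
    }
    mu = None
    for col, frac in parts.items():
        if frac is None:
            continue
        val = np.interp(wavelength_nm, lam, table[col].to_numpy())
        term = np.asarray(frac, dtype=float) * val
        mu = term if mu is None else mu + term
    if mu is None:
        raise ValueError("optical maps carry no volume fractions")
    return mu + optics.mu_a_baseline


def add_exogenous_absorbers(
    mu_a: np.ndarray, absorbers: Sequence[Disk], grid: Grid
) -> np.ndarray:
    """Overwrite the absorption map inside absorber disks (override wins)."""
    out = np.asarray(mu_a, dtype=float).copy()
    for d in absorbers:
        _check_inside(grid, d, "exogenous absorber")
        out[_disk_mask(grid, d)] = d.value
    return out


def add_noise(data: SensorData, level: float, seed: int) -> SensorData:
    """Additive zero-mean Gaussian noise, std = level x peak-to-peak of the
    clean dataset; deterministic under a fixed seed."""
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if level == 0:
        y = data.y.copy()
    else:
        std = level * float(data.y.max() - data.y.min())
        rng = np.random.default_rng(seed)
        y = data.y + std * rng.standard_normal(data.y.shape)
    return SensorData(
        y=y, dt=data.dt, dx=data.dx,
        sensor_positions=data.sensor_positions, dataset_index=data.dataset_index,
    )


# -- procedural tissue-mimicking phantom -------------------------------------

def _smooth_bump(xx, yy, cx, cy, s):
    return np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * s**2))


def tissue_phantom(
    grid: Grid, seed: int = 0, n_vessels: int = 6
) -> tuple[OpticalMaps, np.ndarray]:
    """Procedural 2D breast-like phantom: fraction maps + speed of sound.

    Background tissue with smoothly varying water/fat content, vessel-like
    curvilinear blood structures, a reference scattering map, and a speed
    of sound with two soft heterogeneity lobes (1430-1580 m/s range).
    Returns ``(OpticalMaps, c_interior)``.
    """
    rng = np.random.default_rng(seed)
    n = grid.n_interior
    ext = grid.extent
    xx, yy = _pixel_centres(grid)

    blood = np.full((n, n), 0.01)
    so2 = np.full((n, n), 0.75)
    for _ in range(n_vessels):
        # smooth random curve across the domain
        t = np.linspace(0.0, 1.0, 200)
        x0, x1 = rng.uniform(0.1, 0.9, 2) * ext
        y0, y1 = rng.uniform(0.1, 0.9, 2) * ext
        amp = rng.uniform(0.05, 0.18) * ext
        ph = rng.uniform(0, 2 * np.pi)
        cx = x0 + (x1 - x0) * t + amp * np.sin(2 * np.pi * t + ph)
        cy = y0 + (y1 - y0) * t + amp * np.cos(3 * np.pi * t + ph)
        keep = (cx > 0.03 * ext) & (cx < 0.97 * ext) & (cy > 0.03 * ext) & (cy < 0.97 * ext)
        cx, cy = cx[keep], cy[keep]
        if cx.size == 0:
            continue
        radius = rng.uniform(0.25e-3, 0.5e-3) * (ext / 20e-3 + 0.5)
        d2 = np.min(
            (xx[..., None] - cx[None, None, :]) ** 2
            + (yy[..., None] - cy[None, None, :]) ** 2,
            axis=-1,
        )
        mask = d2 <= radius**2
        blood[mask] = rng.uniform(0.6, 1.0)
        so2[mask] = rng.uniform(0.5, 0.95)

    water = 0.50 + 0.20 * _smooth_bump(xx, yy, 0.35 * ext, 0.6 * ext, 0.22 * ext)
    fat = np.clip(0.35 - 0.5 * blood - 0.25 * _smooth_bump(xx, yy, 0.6 * ext, 0.3 * ext, 0.25 * ext), 0.02, 1.0)
    mu_s_ref = 1.0 + 0.4 * _smooth_bump(xx, yy, 0.5 * ext, 0.5 * ext, 0.3 * ext)

    c = (
        1480.0
        + 80.0 * _smooth_bump(xx, yy, 0.32 * ext, 0.38 * ext, 0.16 * ext)
        + 50.0 * _smooth_bump(xx, yy, 0.68 * ext, 0.66 * ext, 0.20 * ext)
        - 30.0 * _smooth_bump(xx, yy, 0.75 * ext, 0.25 * ext, 0.18 * ext)
    )
    c = np.clip(c + 20.0 * (blood > 0.5), 1430.0, 1580.0)

    optics = OpticalMaps(
        v_hbo2=blood * so2,
        v_hhb=blood * (1.0 - so2),
        v_water=water * (blood < 0.5),  # vessels dominated by blood
        v_fat=fat,
        mu_s_ref=mu_s_ref,
    )
    return optics, c
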