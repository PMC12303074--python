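"""Coarse-to-fine multigrid continuation for the joint reconstruction.

Optimising the non-convex joint objective directly on a fine grid risks
cycle skipping: simulated waveforms lock onto the wrong oscillation cycle
of the data.  The continuation starts on a coarse grid, which supports only
low frequencies and smooths the objective, runs the bound-constrained
L-BFGS until its stopping rule fires, then linearly interpolates the
estimates to the next finer grid as its initial guess.  Measured data are
resampled onto each level's time axis (with an optional anti-aliasing
low-pass at the level's supported band), and the priors are rebuilt from
each level's pixel coordinates with the same physical hyperparameters.

Data simulation and reconstruction must use different spatial steps (the
"inverse crime" guard); the driver refuses schedules that reuse the data
grid's ``dx`` unless explicitly overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .forward import SensorData
from .grid import Grid, place_sensors
from .objective import JointProblem, UnknownVector
from .optimizer import Bounds, OptimizeTrace, StoppingRule, minimize, project_bounds
from .priors import NoiseModel, OUPrior, build_ou_prior

__all__ = [
    "LevelSchedule",
    "PriorSettings",
    "MultigridConfig",
    "LevelResult",
    "ReconstructionResult",
    "prolong_field",
    "resample_data_time",
    "initial_guess",
    "run_multigrid",
]


@dataclass
class LevelSchedule:
    """Ordered coarse-to-fine grids with per-level stopping rules."""

    grids: list[Grid]
    stops: list[StoppingRule]

    def __post_init__(self) -> None:
        if len(self.grids) != len(self.stops):
            raise ValueError("one stopping rule per level required")
        dxs = [g.dx for g in self.grids]
        if any(b >= a for a, b in zip(dxs, dxs[1:])):
            raise ValueError("level dx must be strictly decreasing (coarse to fine)")
        # printed pixel sizes rarely tile the nominal domain exactly, so a
        # modest relative mismatch between level extents is tolerated and
        # absorbed by physical-coordinate interpolation with edge clamping
        e0 = self.grids[0].extent
        for g in self.grids[1:]:
            if abs(g.extent - e0) > EXTENT_RTOL * e0:
                raise ValueError(
                    f"levels disagree on physical extent beyond {EXTENT_RTOL:.0%}: "
                    f"{[round(gg.extent, 6) for gg in self.grids]}"
                )


@dataclass
class PriorSettings:
    """Physical-units hyperparameters shared by all levels."""

    p0_mean: float
    p0_sigma: float
    c_mean: float
    c_sigma: float
    tau: float  # correlation length, metres


@dataclass
class MultigridConfig:
    """Everything the driver needs besides the schedule and the data."""

    priors: PriorSettings
    sensor_count: int
    sensor_inset: float
    noise_sigmas: list[float]
    c_bounds: tuple[float, float] = (1300.0, 1800.0)
    p0_lower: float = 0.0
    c_background: Optional[float] = None  # defaults to the c prior mean
    memory: int = 20
    lowpass: bool = True
    allow_inverse_crime: bool = False
    #: physical extent of the data-simulation target; when level extents
    #: differ slightly from it (printed pixel sizes rarely tile the nominal
    #: domain exactly) the per-level sensor inset is adjusted so the sensor
    #: ring stays on the same physical contour as during data simulation
    data_extent: Optional[float] = None


@dataclass
class LevelResult:
    grid: Grid
    x: UnknownVector
    trace: OptimizeTrace


@dataclass
class ReconstructionResult:
    """Finest-level estimates plus per-level snapshots and traces."""

    p0: list[np.ndarray]
    c: np.ndarray
    levels: list[LevelResult]
    status: str = "ok"

    @property
    def grid(self) -> Grid:
        return self.levels[-1].grid


EXTENT_RTOL = 0.08


def prolong_field(field_coarse: np.ndarray, grid_from: Grid, grid_to: Grid) -> np.ndarray:
    """Bilinear interpolation of a target-domain field onto a finer grid.

    Interpolation runs on physical pixel-centre coordinates; query points
    are clamped to the coarse hull so the result is a convex combination of
    coarse values (bounds are preserved, small extent mismatches tolerated).
    """
    if abs(grid_from.extent - grid_to.extent) > EXTENT_RTOL * grid_from.extent:
        raise ValueError("grids cover different physical extents")
    field_coarse = np.asarray(field_coarse, dtype=float)
    xc = grid_from.interior_coords()
    interp = RegularGridInterpolator((xc, xc), field_coarse, method="linear")
    xf = np.clip(grid_to.interior_coords(), xc[0], xc[-1])
    xx, yy = np.meshgrid(xf, xf, indexing="ij")
    return interp(np.stack([xx.ravel(), yy.ravel()], axis=1)).reshape(
        grid_to.n_interior, grid_to.n_interior
    )


def resample_data_time(
    data: SensorData,
    dt_new: float,
    nt_new: int,
    lowpass_cutoff: Optional[float] = None,
) -> SensorData:
    """Linear per-sensor interpolation of traces onto a new time axis.

    ``lowpass_cutoff`` (Hz) applies a zero-phase Butterworth filter before
    interpolation to suppress content above the target grid's band.
    Identical axes return the data unchanged (bit for bit).
    """
    t_old = np.arange(data.nt) * data.dt
    t_new = np.arange(nt_new) * dt_new
    if t_new[-1] > t_old[-1] * (1.0 + 1e-12):
        raise ValueError(
            f"new horizon {t_new[-1]:.3e}s exceeds the recorded horizon {t_old[-1]:.3e}s"
        )
    y = data.y
    nyquist = 0.5 / data.dt
    if lowpass_cutoff is not None and lowpass_cutoff < nyquist:
        from scipy.signal import butter, sosfiltfilt

        sos = butter(6, lowpass_cutoff / nyquist, output="sos")
        y = sosfiltfilt(sos, y, axis=1)
    if nt_new == data.nt and abs(dt_new - data.dt) <= 1e-15 * data.dt:
        y_new = y.copy()
    else:
        y_new = np.empty((y.shape[0], nt_new))
        for s in range(y.shape[0]):
            y_new[s] = np.interp(t_new, t_old, y[s])
    return SensorData(
        y=y_new,
        dt=dt_new,
        dx=data.dx,
        sensor_positions=data.sensor_positions,
        dataset_index=data.dataset_index,
    )


def initial_guess(p0_priors, c_prior: OUPrior, n_datasets: int, n_side: int) -> UnknownVector:
    """Zero initial pressures; speed of sound at its prior mean."""
    zeros = [np.zeros((n_side, n_side)) for _ in range(n_datasets)]
    c0 = c_prior.mean.reshape(n_side, n_side).copy()
    return UnknownVector.pack(zeros, c0)


def _build_priors(grid: Grid, ps: PriorSettings) -> tuple[OUPrior, OUPrior]:
    xi = grid.interior_coords()
    xx, yy = np.meshgrid(xi, xi, indexing="ij")
    coords = np.stack([xx.ravel(), yy.ravel()], axis=1)
    p0_prior = build_ou_prior(coords, ps.p0_sigma, ps.tau, ps.p0_mean)
    c_prior = build_ou_prior(coords, ps.c_sigma, ps.tau, ps.c_mean)
    return p0_prior, c_prior


def run_multigrid(
    schedule: LevelSchedule,
    datasets: Sequence[SensorData],
    config: MultigridConfig,
    x_init: Optional[UnknownVector] = None,
    callback: Optional[Callable[[int, int, float], None]] = None,
) -> ReconstructionResult:
    """Run the full coarse-to-fine reconstruction.

    ``datasets`` are the (noisy) measurements on the data-simulation grid's
    time axis; each level resamples them and rebuilds priors, sensors and
    bounds on its own pixel set.
    """
    I = len(datasets)
    if I == 0:
        raise ValueError("need at least one dataset")
    if len(config.noise_sigmas) != I:
        raise ValueError("need one noise sigma per dataset")
    data_dx = datasets[0].dx
    if not config.allow_inverse_crime:
        for g in schedule.grids:
            if abs(g.dx - data_dx) <= 1e-12 * data_dx:
                raise ValueError(
                    "reconstruction level reuses the data-simulation dx "
                    f"({data_dx:.3e} m): inverse crime; set allow_inverse_crime "
                    "to override"
                )
    c_background = (
        config.c_background if config.c_background is not None else config.priors.c_mean
    )
    c_ref = config.c_bounds[1]

    x = x_init
    prev_grid: Optional[Grid] = None
    levels: list[LevelResult] = []
    status = "ok"
    for li, (grid, stop) in enumerate(zip(schedule.grids, schedule.stops)):
        p0_prior, c_prior = _build_priors(grid, config.priors)
        inset = config.sensor_inset
        if config.data_extent is not None:
            inset += (config.data_extent - grid.extent) / 2.0
        sensors = place_sensors(grid, config.sensor_count, inset)
        cutoff = (
            min(config.c_bounds[0], c_background) / (2.0 * grid.dx)
            if config.lowpass
            else None
        )
        level_data = [
            resample_data_time(d, grid.dt, grid.nt, lowpass_cutoff=cutoff)
            for d in datasets
        ]
        noise = [NoiseModel(s) for s in config.noise_sigmas]
        problem = JointProblem(
            grid, sensors, level_data, p0_prior, c_prior, noise,
            c_background=c_background, c_ref=c_ref,
        )
        bounds = Bounds.for_joint(
            I, grid.n_interior**2,
            p0_lower=config.p0_lower, c_bounds=config.c_bounds,
        )
        if x is None:
            x = initial_guess(p0_prior, c_prior, I, grid.n_interior)
        elif prev_grid is not None:
            p0s, c = x.unpack()
            x = UnknownVector.pack(
                [prolong_field(p, prev_grid, grid) for p in p0s],
                prolong_field(c, prev_grid, grid),
            )
        x_vec = project_bounds(x.vector, bounds)
        cb = (lambda k, xv, f: callback(li, k, f)) if callback is not None else None
        x_vec, trace = minimize(
            problem.objective_and_gradient,
            x_vec,
            bounds=bounds,
            memory=config.memory,
            stop=stop,
            value=problem.objective,
            callback=cb,
        )
        if trace.status == "line_search_failure":
            status = f"warning: line-search failure at level {li}"
        x = UnknownVector(x_vec, I, grid.n_interior)
        levels.append(LevelResult(grid=grid, x=x.copy(), trace=trace))
        prev_grid = grid

    p0s, c = x.unpack()
    return ReconstructionResult(p0=p0s, c=c, levels=levels, status=status)
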