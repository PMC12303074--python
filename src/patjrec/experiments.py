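"""Twin experiments: data simulation, reconstruction, and error metrics.

An experiment simulates photoacoustic data from a known phantom on a fine
data grid, adds measurement noise, reconstructs on a separate multigrid
schedule (avoiding the inverse crime), and scores the estimates against the
truth with relative errors

    E_z = 100% * ||z_true - z_rec|| / ||z_true||

computed on the finest reconstruction grid (truth bilinearly resampled).
``mode="proposed"`` uses all I datasets jointly; ``mode="reference"`` is
the conventional single-dataset reconstruction (dataset 1 only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .forward import Medium, SensorData, simulate_forward
from .grid import Grid, make_grid, place_sensors
from .multigrid import (
    LevelSchedule,
    MultigridConfig,
    PriorSettings,
    ReconstructionResult,
    prolong_field,
    run_multigrid,
)
from .optimizer import StoppingRule
from .phantoms import (
    OpticalMaps,
    PhantomSpec,
    add_exogenous_absorbers,
    add_noise,
    build_simple_phantom,
    diffusion_fluence,
    p0_from_fluence,
    scaled_twin_spec,
    simple_phantom_spec,
    spectral_mu_a,
)

__all__ = [
    "ExperimentConfig",
    "ErrorReport",
    "relative_error",
    "truth_on_grid",
    "simulate_datasets",
    "run_experiment",
    "scaled_twin_config",
    "paper_data_grid",
    "paper_table1_schedule",
    "paper_scale_config",
    "tissue_p0_datasets",
]


def relative_error(true_field: np.ndarray, rec_field: np.ndarray) -> float:
    """Euclidean relative error in percent."""
    t = np.asarray(true_field, dtype=float).ravel()
    r = np.asarray(rec_field, dtype=float).ravel()
    if t.shape != r.shape:
        raise ValueError("field shapes differ")
    nt = np.linalg.norm(t)
    if nt == 0.0:
        raise ValueError("true field has zero norm")
    return 100.0 * float(np.linalg.norm(t - r)) / float(nt)


def truth_on_grid(true_field: np.ndarray, grid_from: Grid, grid_to: Grid) -> np.ndarray:
    """Bilinear resampling of a truth map onto another grid's pixel set."""
    return prolong_field(true_field, grid_from, grid_to)


@dataclass
class ErrorReport:
    """Per-dataset initial-pressure errors and the speed-of-sound error, %."""

    e_p0: list[float]
    e_c: float
    mode: str = "proposed"


@dataclass
class ExperimentConfig:
    """Complete twin-experiment definition."""

    name: str
    phantom: PhantomSpec
    data_grid: Grid
    schedule: LevelSchedule
    sensor_count: int
    sensor_inset: float
    noise_level: float
    prior: PriorSettings
    c_bounds: tuple[float, float] = (1300.0, 1800.0)
    c_background: float = 1430.0
    memory: int = 20


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulate_datasets(
    config: ExperimentConfig, seed: int, n_datasets: Optional[int] = None
) -> tuple[list[SensorData], list[float], Medium, list[np.ndarray]]:
    """Forward-simulate noisy sensor data on the data grid.

    Returns the noisy datasets, the per-dataset noise standard deviations
    estimated from the noisy signals, the true medium, and the true initial
    pressure maps.
    """
    medium, p0_true = build_simple_phantom(config.phantom, config.data_grid)
    if n_datasets is not None:
        p0_true = p0_true[:n_datasets]
    sensors = place_sensors(config.data_grid, config.sensor_count, config.sensor_inset)
    seeds = _child_seeds(seed, len(p0_true))
    datasets, sigmas = [], []
    for i, p0 in enumerate(p0_true):
        clean, _ = simulate_forward(
            medium, p0, config.data_grid, sensors, dataset_index=i
        )
        noisy = add_noise(clean, config.noise_level, seeds[i])
        datasets.append(noisy)
        # weighting uses the std estimated from the noisy signal itself;
        # noiseless runs keep a nominal 1% weighting scale (the residual
        # weighting is arbitrary without noise but must stay finite)
        level = config.noise_level if config.noise_level > 0 else 0.01
        sigmas.append(level * float(noisy.y.max() - noisy.y.min()))
    return datasets, sigmas, medium, p0_true


def run_experiment(
    config: ExperimentConfig, mode: str = "proposed", seed: int = 0
) -> tuple[ReconstructionResult, ErrorReport]:
    """Simulate, reconstruct and score one twin experiment."""
    if mode not in ("proposed", "reference"):
        raise ValueError("mode must be 'proposed' or 'reference'")
    n_use = None if mode == "proposed" else 1
    datasets, sigmas, medium_true, p0_true = simulate_datasets(config, seed, n_datasets=n_use)
    mg = MultigridConfig(
        priors=config.prior,
        sensor_count=config.sensor_count,
        sensor_inset=config.sensor_inset,
        noise_sigmas=sigmas,
        c_bounds=config.c_bounds,
        c_background=config.c_background,
        memory=config.memory,
        data_extent=config.data_grid.extent,
    )
    result = run_multigrid(config.schedule, datasets, mg)
    fine = result.grid
    c_true = config.data_grid.restrict(medium_true.c)
    e_p0 = [
        relative_error(
            truth_on_grid(p0_true[i], config.data_grid, fine), result.p0[i]
        )
        for i in range(len(result.p0))
    ]
    e_c = relative_error(truth_on_grid(c_true, config.data_grid, fine), result.c)
    return result, ErrorReport(e_p0=e_p0, e_c=e_c, mode=mode)


# -- canonical configurations ------------------------------------------------

def scaled_twin_config(
    max_iter: tuple[int, int] = (50, 110),
    noise_level: float = 0.01,
) -> ExperimentConfig:
    """Desk-scale twin experiment on a 12.8 mm domain.

    Data grid: 64^2 interior pixels at 0.2 mm (full grid 96^2 with sensor
    and PML bands), 320 samples at 40 ns.  Reconstruction: two levels,
    28^2 at 0.457 mm and 40^2 at 0.32 mm, each with its own time axis;
    all spatial steps differ from the data grid.  Priors follow the
    quarter-range rule on the true parameter ranges (p0 in [0, 10] Pa,
    c in [1430, 1580] m/s), correlation length 1.5 mm.  The fine-level
    iteration cap is generous on purpose: runs end through the
    relative-decrease stopping rule (typically near 90 iterations for the
    joint mode, which fits four datasets, and earlier for the reference
    mode), keeping a proposed-plus-reference pair around two minutes on
    one CPU.
    """
    phantom = scaled_twin_spec()
    data_grid = make_grid(64, 0.2e-3, 4, 12, 4.0e-8, 320)
    levels = [
        make_grid(28, 12.8e-3 / 28, 2, 6, 9.1e-8, 141),
        make_grid(40, 0.32e-3, 3, 7, 6.4e-8, 200),
    ]
    stops = [
        StoppingRule(tol=1e-4, patience=5, max_iter=max_iter[0]),
        StoppingRule(tol=1e-4, patience=5, max_iter=max_iter[1]),
    ]
    prior = PriorSettings(
        p0_mean=5.0, p0_sigma=2.5, c_mean=1505.0, c_sigma=37.5, tau=1.5e-3
    )
    return ExperimentConfig(
        name="scaled_twin",
        phantom=phantom,
        data_grid=data_grid,
        schedule=LevelSchedule(levels, stops),
        sensor_count=64,
        sensor_inset=0.4e-3,
        noise_level=noise_level,
        prior=prior,
        c_bounds=(1300.0, 1800.0),
        c_background=1430.0,
    )


#: printed discretisation table of the reference study:
#: (dx_um, n_interior, n_sensor_margin, n_pml, dt_ns, nt)
TABLE1 = {
    "data": (63.7, 335, 10, 20, 12.1, 1747),
    1: (526.3, 39, 2, 19, 99.9, 212),
    2: (370.4, 55, 4, 31, 70.4, 301),
    3: (227.3, 89, 4, 14, 43.2, 490),
    4: (156.3, 129, 6, 17, 29.7, 712),
    5: (101.0, 199, 8, 14, 19.2, 1101),
}


def _grid_from_row(row) -> Grid:
    dx_um, n, ns, npml, dt_ns, nt = row
    return make_grid(n, dx_um * 1e-6, ns, npml, dt_ns * 1e-9, nt)


def paper_data_grid() -> Grid:
    """Full-scale data-simulation grid (20 mm domain, 63.7 um pixels)."""
    return _grid_from_row(TABLE1["data"])


def paper_table1_schedule(
    rows: Sequence[int] = (1, 2, 3, 4),
    max_iter: int = 200,
) -> LevelSchedule:
    """Multigrid schedule from the published discretisation table."""
    grids = [_grid_from_row(TABLE1[r]) for r in rows]
    stops = [StoppingRule(tol=1e-4, patience=5, max_iter=max_iter) for _ in rows]
    return LevelSchedule(grids, stops)


def paper_scale_config(variant: str = "low_contrast") -> ExperimentConfig:
    """Full-scale simple-phantom experiment (multi-hour on one CPU).

    Uses the published data grid, schedule rows 1-4, 236 sensors 0.2 mm
    outside the target boundary, 1% peak-to-peak noise, quarter-range
    priors with a 1.5 mm correlation length, and the published speed
    bounds (upper bound 3000 m/s for the high-contrast variant).
    """
    phantom = simple_phantom_spec(variant)
    c_hi = 3000.0 if variant == "high_contrast" else 1800.0
    prior = PriorSettings(
        p0_mean=5.0, p0_sigma=2.5,
        c_mean=1482.0 if variant == "high_contrast" else 1505.0,
        c_sigma=37.5, tau=1.5e-3,
    )
    return ExperimentConfig(
        name=f"paper_{variant}",
        phantom=phantom,
        data_grid=paper_data_grid(),
        schedule=paper_table1_schedule(),
        sensor_count=236,
        sensor_inset=0.2e-3,
        noise_level=0.01,
        prior=prior,
        c_bounds=(1300.0, c_hi),
        c_background=1430.0,
    )


# -- tissue-mimicking initial pressure generation ----------------------------

def tissue_p0_datasets(
    optics: OpticalMaps,
    grid: Grid,
    mode: str = "illumination",
    wavelengths: Sequence[float] = (650.0, 750.0, 850.0, 950.0),
    absorber_sets: Optional[Sequence[Sequence]] = None,
    gruneisen_scale: float = 1.0,
) -> list[np.ndarray]:
    """Generate multiple initial pressures from one optical phantom.

    ``mode="illumination"``: one wavelength (800 nm), planar illumination
    from each of the four sides in turn.  ``mode="wavelength"``: fixed
    top+left illumination, one dataset per wavelength.
    ``mode="absorbers"``: fixed top+left illumination at 800 nm; dataset 1
    without exogenous absorbers, subsequent datasets with the given
    absorber disk sets stamped into the absorption map.
    """
    p0_list = []
    if mode == "illumination":
        mu_a = spectral_mu_a(optics, 800.0)
        mu_s = optics.mu_s_at(800.0)
        for side in ("top", "left", "bottom", "right"):
            phi = diffusion_fluence(mu_a, mu_s, grid, sides=(side,))
            p0_list.append(p0_from_fluence(mu_a, phi, gruneisen_scale))
    elif mode == "wavelength":
        for lam in wavelengths:
            mu_a = spectral_mu_a(optics, lam)
            mu_s = optics.mu_s_at(lam)
            phi = diffusion_fluence(mu_a, mu_s, grid, sides=("top", "left"))
            p0_list.append(p0_from_fluence(mu_a, phi, gruneisen_scale))
    elif mode == "absorbers":
        if absorber_sets is None:
            raise ValueError("absorber_sets required for mode='absorbers'")
        mu_a0 = spectral_mu_a(optics, 800.0)
        mu_s = optics.mu_s_at(800.0)
        phi = diffusion_fluence(mu_a0, mu_s, grid, sides=("top", "left"))
        p0_list.append(p0_from_fluence(mu_a0, phi, gruneisen_scale))
        for disks in absorber_sets:
            mu_a = add_exogenous_absorbers(mu_a0, disks, grid)
            phi = diffusion_fluence(mu_a, mu_s, grid, sides=("top", "left"))
            p0_list.append(p0_from_fluence(mu_a, phi, gruneisen_scale))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return p0_list
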