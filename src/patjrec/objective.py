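"""Multi-dataset objective and adjoint-state gradients.

The unknown vector stacks ``I`` initial pressure fields and one shared
speed-of-sound field, all on the target-domain pixels:

    x = (p0^1, ..., p0^I, c),   length (I + 1) N.

The objective is the regularised least-squares functional

    eps(x) = sum_i 0.5 ||L_e^i (y^i - f_i(x_i))||^2
           + sum_i 0.5 ||L_p0 (p0^i - eta_p0)||^2
           + 0.5 ||L_c (c - eta_c)||^2,

with ``f_i`` the forward wave solve of dataset ``i`` sharing the single
``c``.  Gradients follow the adjoint-state method: one adjoint sweep per
dataset, driven by the weighted residual ``f_i - y^i`` (this residual sign
makes the assembled gradient descent-consistent).  The initial-pressure
gradient is the adjoint terminal snapshot plus the prior term; the
speed-of-sound gradient is accumulated from the exact forward/adjoint
pressure pairing ``(2/c) sum_n p^n q^n`` (minus its initial-condition
correction), which is the algebraically exact derivative of the discrete
objective, and sums over datasets.

Speeds outside the target domain are held at a fixed background value and
initial pressures at zero; gradients exist only on the target pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .adjoint import AdjointField, assemble_adjoint_source, simulate_adjoint
from .forward import KSpaceSolver, Medium, PressureField, SensorData
from .grid import Grid, PMLProfile, SensorArray
from .priors import NoiseModel, OUPrior, prior_energy, prior_gradient

__all__ = [
    "UnknownVector",
    "ObjectiveReport",
    "JointProblem",
    "evaluate_objective",
    "gradient_p0",
    "gradient_c",
    "stack_gradient",
]


class UnknownVector:
    """Packed unknowns ``(p0^1, ..., p0^I, c)`` over ``n x n`` target pixels."""

    def __init__(self, vector: np.ndarray, n_datasets: int, n_side: int):
        vector = np.asarray(vector, dtype=float).ravel()
        expected = (n_datasets + 1) * n_side * n_side
        if vector.size != expected:
            raise ValueError(f"vector length {vector.size}, expected {expected}")
        self.vector = vector
        self.I = n_datasets
        self.n = n_side
        self.N = n_side * n_side

    @classmethod
    def pack(cls, p0_fields: Sequence[np.ndarray], c_field: np.ndarray) -> "UnknownVector":
        p0_fields = [np.asarray(p, dtype=float) for p in p0_fields]
        c_field = np.asarray(c_field, dtype=float)
        n = c_field.shape[0]
        blocks = [p.reshape(-1) for p in p0_fields] + [c_field.reshape(-1)]
        return cls(np.concatenate(blocks), len(p0_fields), n)

    def p0(self, i: int) -> np.ndarray:
        if not 0 <= i < self.I:
            raise IndexError(i)
        return self.vector[i * self.N : (i + 1) * self.N].reshape(self.n, self.n)

    @property
    def c(self) -> np.ndarray:
        return self.vector[self.I * self.N :].reshape(self.n, self.n)

    def unpack(self) -> tuple[list[np.ndarray], np.ndarray]:
        return [self.p0(i) for i in range(self.I)], self.c

    def copy(self) -> "UnknownVector":
        return UnknownVector(self.vector.copy(), self.I, self.n)


def stack_gradient(
    grad_p0_blocks: Sequence[np.ndarray], grad_c: np.ndarray
) -> UnknownVector:
    """Pack per-block gradients in the unknown-vector ordering."""
    return UnknownVector.pack(list(grad_p0_blocks), grad_c)


@dataclass
class ObjectiveReport:
    """Objective value split into its data-misfit and prior parts."""

    data_terms: list[float]
    prior_p0_terms: list[float]
    prior_c_term: float

    @property
    def total(self) -> float:
        return sum(self.data_terms) + sum(self.prior_p0_terms) + self.prior_c_term


def gradient_p0(adjoint_terminal: np.ndarray, p0: np.ndarray, prior: OUPrior) -> np.ndarray:
    """Initial-pressure gradient: adjoint terminal snapshot + prior term."""
    adjoint_terminal = np.asarray(adjoint_terminal, dtype=float)
    if adjoint_terminal.shape != np.asarray(p0).shape:
        raise ValueError("terminal snapshot and p0 shapes differ")
    return adjoint_terminal + prior_gradient(p0, prior)


def gradient_c(
    adjoint_fields: Sequence[AdjointField],
    c: np.ndarray,
    prior: OUPrior,
    grid: Grid,
    forward_fields: Optional[Sequence[PressureField]] = None,
) -> np.ndarray:
    """Speed-of-sound gradient summed over datasets, plus the prior term.

    Uses the pairing sums accumulated during the adjoint sweeps; if an
    adjoint field carries the full movie instead, the pairing is formed here
    from the matching ``forward_fields`` entry.
    """
    c = np.asarray(c, dtype=float)
    c_full_shape = (grid.n_total, grid.n_total)
    data = np.zeros(c_full_shape)
    for i, adj in enumerate(adjoint_fields):
        if adj.pair_sum is not None:
            pair, pair_init = adj.pair_sum, adj.pair_init
        elif adj.q is not None and forward_fields is not None:
            p = forward_fields[i].p
            pair = np.einsum("tij,tij->ij", p, adj.q)
            pair_init = p[0] * adj.terminal
        else:
            raise ValueError(
                "adjoint field carries neither pairing sums nor a full movie; "
                "rerun simulate_adjoint with forward_pressure or record_full"
            )
        data += pair - pair_init
    data_int = (2.0 / c) * grid.restrict(data)
    return data_int + prior_gradient(c, prior)


class JointProblem:
    """Objective/gradient oracle binding grids, data, priors and noise.

    Parameters
    ----------
    grid : Grid
        Reconstruction grid; datasets must already be resampled to its
        time axis.
    sensors : SensorArray
        Sensors on the reconstruction grid.
    datasets : list of SensorData
        One measured dataset per initial pressure.
    p0_priors : OUPrior or list of OUPrior
        Prior(s) for the initial pressure blocks (shared if a single one).
    c_prior : OUPrior
        Prior for the speed of sound.
    noise : list of NoiseModel
        Per-dataset white-noise models.
    c_background : float
        Speed of sound held fixed in the sensor margin and PML bands.
    c_ref : float
        Fixed reference speed of the k-space correction; must bound the
        admissible ``c`` from above (use the upper optimisation bound).
    """

    def __init__(
        self,
        grid: Grid,
        sensors: SensorArray,
        datasets: Sequence[SensorData],
        p0_priors,
        c_prior: OUPrior,
        noise: Sequence[NoiseModel],
        c_background: float,
        c_ref: float,
        pml: Optional[PMLProfile] = None,
    ) -> None:
        self.grid = grid
        self.sensors = sensors
        self.datasets = list(datasets)
        self.I = len(self.datasets)
        if isinstance(p0_priors, OUPrior):
            p0_priors = [p0_priors] * self.I
        if len(p0_priors) != self.I:
            raise ValueError("need one p0 prior per dataset (or a shared one)")
        self.p0_priors = list(p0_priors)
        self.c_prior = c_prior
        if len(noise) != self.I:
            raise ValueError("need one noise model per dataset")
        self.noise = list(noise)
        self.c_background = float(c_background)
        self.c_ref = float(c_ref)
        self.pml = pml
        for d in self.datasets:
            if d.y.shape != (sensors.count, grid.nt):
                raise ValueError(
                    f"dataset {d.dataset_index} shape {d.y.shape} does not match "
                    f"(sensors, nt) = {(sensors.count, grid.nt)}"
                )

    # -- helpers -------------------------------------------------------------
    def medium(self, c_interior: np.ndarray) -> Medium:
        c_full = np.full((self.grid.n_total,) * 2, self.c_background)
        c_full[self.grid.interior_slice, self.grid.interior_slice] = c_interior
        return Medium(c=c_full, c_ref=self.c_ref)

    def _solver(self, x: UnknownVector) -> KSpaceSolver:
        return KSpaceSolver(self.grid, self.medium(x.c), self.pml)

    def _prior_report(self, x: UnknownVector) -> tuple[list[float], float]:
        p0s, c = x.unpack()
        return (
            [prior_energy(p0s[i], self.p0_priors[i]) for i in range(self.I)],
            prior_energy(c, self.c_prior),
        )

    # -- objective and gradient ----------------------------------------------
    def objective_report(self, x: UnknownVector, _cache: bool = True) -> ObjectiveReport:
        solver = self._solver(x)
        data_terms = []
        y_sims, movies = [], []
        for i in range(self.I):
            y_sim, p_all = solver.run_forward(
                self.grid.embed(x.p0(i)), self.sensors, record_full=_cache
            )
            r = y_sim - self.datasets[i].y
            data_terms.append(0.5 * float(np.sum(r * r)) / self.noise[i].sigma ** 2)
            y_sims.append(y_sim)
            movies.append(p_all)
        if _cache:
            # a following gradient call at the same x reuses these solves
            self._cache = (x.vector.copy(), solver, y_sims, movies)
        p0_terms, c_term = self._prior_report(x)
        return ObjectiveReport(data_terms, p0_terms, c_term)

    def objective(self, x_vec: np.ndarray) -> float:
        return self.objective_report(self._as_unknown(x_vec)).total

    _cache: Optional[tuple] = None

    def _forward_all(self, x: UnknownVector) -> tuple[KSpaceSolver, list, list]:
        if self._cache is not None and np.array_equal(self._cache[0], x.vector):
            return self._cache[1], self._cache[2], self._cache[3]
        solver = self._solver(x)
        y_sims, movies = [], []
        for i in range(self.I):
            y_sim, p_all = solver.run_forward(
                self.grid.embed(x.p0(i)), self.sensors, record_full=True
            )
            y_sims.append(y_sim)
            movies.append(p_all)
        return solver, y_sims, movies

    def objective_and_gradient(self, x_vec: np.ndarray) -> tuple[float, np.ndarray]:
        x = self._as_unknown(x_vec)
        solver, y_sims, movies = self._forward_all(x)
        data_terms = []
        grad_p0_blocks = []
        adjoints = []
        for i in range(self.I):
            y_sim, p_all = y_sims[i], movies[i]
            r = y_sim - self.datasets[i].y
            data_terms.append(0.5 * float(np.sum(r * r)) / self.noise[i].sigma ** 2)
            residual = SensorData(
                y=r, dt=self.grid.dt, dx=self.grid.dx,
                sensor_positions=self.sensors.positions, dataset_index=i,
            )
            src = assemble_adjoint_source(
                residual, self.noise[i].sigma, self.sensors, self.grid
            )
            adj = simulate_adjoint(
                Medium(solver.medium.c, self.c_ref), src, self.grid,
                forward_pressure=PressureField(p=p_all, dt=self.grid.dt),
                solver=solver,
            )
            adjoints.append(adj)
            grad_p0_blocks.append(
                gradient_p0(self.grid.restrict(adj.terminal), x.p0(i), self.p0_priors[i])
            )
        grad_c = gradient_c(adjoints, x.c, self.c_prior, self.grid)
        p0_terms, c_term = self._prior_report(x)
        report = ObjectiveReport(data_terms, p0_terms, c_term)
        grad = stack_gradient(grad_p0_blocks, grad_c)
        return report.total, grad.vector

    def _as_unknown(self, x_vec) -> UnknownVector:
        if isinstance(x_vec, UnknownVector):
            return x_vec
        return UnknownVector(x_vec, self.I, self.grid.n_interior)


def evaluate_objective(
    x: UnknownVector,
    data: Sequence[SensorData],
    p0_priors,
    c_prior: OUPrior,
    noise: Sequence[NoiseModel],
    grid: Grid,
    sensors: SensorArray,
    c_background: float,
    c_ref: Optional[float] = None,
) -> ObjectiveReport:
    """Evaluate the multi-dataset objective at ``x`` (forward solves only)."""
    problem = JointProblem(
        grid, sensors, data, p0_priors, c_prior, noise,
        c_background=c_background,
        c_ref=c_ref if c_ref is not None else max(float(np.max(x.c)), c_background),
    )
    return problem.objective_report(x)
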