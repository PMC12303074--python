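"""Adjoint wave problem: weighted-residual source and transpose propagation.

The adjoint solver is the exact algebraic transpose of the forward k-space
time stepper (same spectral operators, same PML, reverse order), driven by
the noise-weighted data residual injected at the sensor nodes.  Its terminal
snapshot is therefore exactly ``F^T S`` where ``F`` is the discrete linear
map from initial pressure to sensor traces — the quantity appearing in the
adjoint-state gradient with respect to the initial pressure — and the
pairing of adjoint and forward pressures accumulated along the sweep yields
the exact gradient with respect to the squared slowness-free speed field
(see :mod:`patjrec.objective`).

Time bookkeeping: the adjoint sweep runs backwards over the forward step
index ``n``; the stored adjoint pressure ``q[n]`` is indexed in *forward*
time, so the continuous-time pairing ``p(., t) q(., T - t)`` corresponds to
the aligned products ``p[n] * q[n]`` here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .forward import KSpaceSolver, Medium, PressureField, SensorData
from .grid import Grid, PMLProfile, SensorArray

__all__ = [
    "AdjointSource",
    "AdjointField",
    "assemble_adjoint_source",
    "simulate_adjoint",
]


@dataclass
class AdjointSource:
    """Sensor-supported adjoint drive: weighted residual per sensor and step."""

    values: np.ndarray  # (n_sensors, nt)
    sensors: SensorArray

    @property
    def nt(self) -> int:
        return self.values.shape[1]


@dataclass
class AdjointField:
    """Result of an adjoint sweep.

    ``terminal`` is the adjoint pressure at adjoint time ``T`` (full grid):
    the initial-pressure sensitivity of the weighted misfit.  ``q`` is the
    adjoint pressure movie indexed in forward time (kept only on request).
    ``pair_sum`` is ``sum_n p[n] * q[n]`` accumulated inline against a
    supplied forward movie, and ``pair_init`` the initial-condition
    correction ``p[0] * terminal``; together they give the exact data-term
    speed gradient ``(2/c) (pair_sum - pair_init)``.
    """

    terminal: np.ndarray
    q: Optional[np.ndarray] = None
    pair_sum: Optional[np.ndarray] = None
    pair_init: Optional[np.ndarray] = None


def assemble_adjoint_source(
    residual: SensorData,
    noise_sigma: float,
    sensors: SensorArray,
    grid: Grid,
) -> AdjointSource:
    """Weight a sensor residual by the inverse noise covariance.

    With white noise of standard deviation ``sigma_e`` the weighting is
    ``L_e^T L_e = I / sigma_e^2`` applied to the residual traces.
    """
    if residual.y.shape != (sensors.count, grid.nt):
        raise ValueError(
            f"residual shape {residual.y.shape} does not match "
            f"(sensors, nt) = {(sensors.count, grid.nt)}"
        )
    return AdjointSource(values=residual.y / noise_sigma**2, sensors=sensors)


def simulate_adjoint(
    medium: Medium,
    source: AdjointSource,
    grid: Grid,
    record_full: bool = False,
    pml: Optional[PMLProfile] = None,
    forward_pressure: Optional[PressureField] = None,
    solver: Optional[KSpaceSolver] = None,
) -> AdjointField:
    """Run the exact transpose of the forward scheme driven by ``source``.

    If ``forward_pressure`` is supplied, the forward/adjoint pressure
    pairing needed by the speed-of-sound gradient is accumulated inline so
    the adjoint movie need not be stored.
    """
    if solver is None:
        solver = KSpaceSolver(grid, medium, pml)
    nt = grid.nt
    if source.nt != nt:
        raise ValueError("source length does not match grid.nt")
    n = grid.n_total
    si, sj = source.sensors.indices[:, 0], source.sensors.indices[:, 1]
    c2 = solver.c2
    au_x, au_y, ar_x, ar_y = solver.au_x, solver.au_y, solver.ar_x, solver.ar_y
    dt = grid.dt

    p_fwd = None
    if forward_pressure is not None:
        if forward_pressure.p.shape != (nt, n, n):
            raise ValueError("forward_pressure must be a full-grid movie")
        p_fwd = forward_pressure.p

    def scatter(step: int) -> np.ndarray:
        out = np.zeros((n, n))
        np.add.at(out, (si, sj), source.values[:, step])
        return out

    bux = np.zeros((n, n))
    buy = np.zeros((n, n))
    brx = np.zeros((n, n))
    bry = np.zeros((n, n))
    q_all = np.empty((nt, n, n)) if record_full else None
    pair = np.zeros((n, n)) if p_fwd is not None else None

    pbar = scatter(nt - 1)
    if record_full:
        q_all[nt - 1] = pbar
    if pair is not None:
        pair += p_fwd[nt - 1] * pbar
    brx += c2 * pbar
    bry += c2 * pbar

    for m in range(nt - 2, -1, -1):
        dtn = dt / 2.0 if m == 0 else dt
        # transpose of the density updates (consume adjoint of rho^{m+1})
        bhx = -dt * ar_x * brx
        bhy = -dt * ar_y * bry
        brx = solver.ar_x2 * brx
        bry = solver.ar_y2 * bry
        dux, duy = solver.div_u_T(bhx, bhy)
        bux += dux
        buy += duy
        # transpose of the velocity updates
        bgx = -dtn * au_x * bux
        bgy = -dtn * au_y * buy
        bux = solver.au_x2 * bux
        buy = solver.au_y2 * buy
        # transpose of the pressure gradient and of p^m = c2 (rhox + rhoy)
        pbar = scatter(m) + solver.grad_p_T(bgx, bgy)
        if record_full:
            q_all[m] = pbar
        if pair is not None:
            pair += p_fwd[m] * pbar
        brx += c2 * pbar
        bry += c2 * pbar

    terminal = (brx + bry) / (2.0 * c2)
    pair_init = p_fwd[0] * terminal if pair is not None else None
    return AdjointField(terminal=terminal, q=q_all, pair_sum=pair, pair_init=pair_init)
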