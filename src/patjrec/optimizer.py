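"""Bound-constrained limited-memory BFGS with projected backtracking search.

The iteration is

    x_{k+1} = P( x_k - alpha_k H_k grad_k ),

where ``H_k`` is the L-BFGS inverse-Hessian approximation applied through
the two-loop recursion seeded with ``H_k^0 = (kappa^T phi)/(phi^T phi) I``,
``P`` clamps to the elementwise bounds, and ``alpha_k`` comes from an
Armijo backtracking search evaluated at the projected trial points.
Curvature pairs with non-positive ``phi^T kappa`` are rejected so ``H_k``
stays positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "LBFGSHistory",
    "Bounds",
    "StoppingRule",
    "OptimizeTrace",
    "two_loop_direction",
    "project_bounds",
    "backtracking_search",
    "minimize",
]

CURVATURE_TOL = 1e-10


@dataclass
class Bounds:
    """Elementwise box constraints; infinities mark unbounded entries."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        both = np.isfinite(self.lower) & np.isfinite(self.upper)
        if np.any(self.lower[both] > self.upper[both]):
            raise ValueError("lower bound exceeds upper bound")

    @classmethod
    def unbounded(cls, n: int) -> "Bounds":
        return cls(np.full(n, -np.inf), np.full(n, np.inf))

    @classmethod
    def for_joint(
        cls,
        n_datasets: int,
        n_pixels: int,
        p0_lower: float = 0.0,
        p0_upper: float = np.inf,
        c_bounds: tuple[float, float] = (1300.0, 1800.0),
    ) -> "Bounds":
        """Bounds for the stacked PAT unknowns: non-negative pressures,
        boxed speed of sound."""
        lo = np.concatenate(
            [np.full(n_datasets * n_pixels, p0_lower), np.full(n_pixels, c_bounds[0])]
        )
        hi = np.concatenate(
            [np.full(n_datasets * n_pixels, p0_upper), np.full(n_pixels, c_bounds[1])]
        )
        return cls(lo, hi)


class LBFGSHistory:
    """Rolling store of curvature pairs ``(kappa_k, phi_k)`` and ``rho_k``."""

    def __init__(self, memory: int = 20):
        if memory < 1:
            raise ValueError("memory must be >= 1")
        self.memory = memory
        self.kappas: list[np.ndarray] = []
        self.phis: list[np.ndarray] = []
        self.rhos: list[float] = []

    def __len__(self) -> int:
        return len(self.kappas)

    def push(self, kappa: np.ndarray, phi: np.ndarray) -> bool:
        """Append a pair; returns False (pair skipped) if curvature fails."""
        dot = float(phi @ kappa)
        if dot <= CURVATURE_TOL * np.linalg.norm(phi) * np.linalg.norm(kappa):
            return False
        self.kappas.append(kappa)
        self.phis.append(phi)
        self.rhos.append(1.0 / dot)
        if len(self.kappas) > self.memory:
            self.kappas.pop(0)
            self.phis.pop(0)
            self.rhos.pop(0)
        return True

    def clear(self) -> None:
        self.kappas.clear()
        self.phis.clear()
        self.rhos.clear()


def two_loop_direction(grad: np.ndarray, history: LBFGSHistory) -> np.ndarray:
    """Search direction ``-H_k grad`` via the two-loop recursion."""
    grad = np.asarray(grad, dtype=float)
    if grad.size == 0:
        raise ValueError("empty gradient")
    q = grad.copy()
    m = len(history)
    if m == 0:
        return -q
    alphas = np.empty(m)
    for j in range(m - 1, -1, -1):
        alphas[j] = history.rhos[j] * (history.kappas[j] @ q)
        q -= alphas[j] * history.phis[j]
    kappa, phi = history.kappas[-1], history.phis[-1]
    q *= (kappa @ phi) / (phi @ phi)
    for j in range(m):
        beta = history.rhos[j] * (history.phis[j] @ q)
        q += (alphas[j] - beta) * history.kappas[j]
    return -q


def project_bounds(z: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Elementwise clamp of ``z`` into ``[lower, upper]``."""
    return np.clip(z, bounds.lower, bounds.upper)


def backtracking_search(
    x: np.ndarray,
    direction: np.ndarray,
    objective: Callable[[np.ndarray], float],
    grad: np.ndarray,
    bounds: Bounds,
    f0: float,
    alpha0: float = 1.0,
    c1: float = 1e-4,
    beta: float = 0.5,
    max_halvings: int = 30,
) -> Optional[tuple[float, np.ndarray, float]]:
    """Armijo backtracking on projected trial points.

    Accepts the largest ``alpha0 * beta^m`` with
    ``f(P(x + alpha d)) <= f0 + c1 * grad^T (P(x + alpha d) - x)``.
    Returns ``(alpha, x_new, f_new)`` or ``None`` if no step is acceptable.
    """
    alpha = alpha0
    for _ in range(max_halvings + 1):
        x_new = project_bounds(x + alpha * direction, bounds)
        step = x_new - x
        if np.any(step != 0.0):
            f_new = objective(x_new)
            if f_new <= f0 + c1 * float(grad @ step):
                return alpha, x_new, f_new
        alpha *= beta
    return None


@dataclass
class StoppingRule:
    """Stop after ``patience`` consecutive relative decreases below ``tol``,
    or at ``max_iter`` iterations."""

    tol: float = 1e-4
    patience: int = 5
    max_iter: int = 200
    grad_tol: float = 0.0


@dataclass
class OptimizeTrace:
    objective: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    alpha: list[float] = field(default_factory=list)
    n_active_lower: list[int] = field(default_factory=list)
    n_active_upper: list[int] = field(default_factory=list)
    status: str = "running"


def minimize(
    value_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    bounds: Optional[Bounds] = None,
    memory: int = 20,
    stop: Optional[StoppingRule] = None,
    value: Optional[Callable[[np.ndarray], float]] = None,
    callback: Optional[Callable[[int, np.ndarray, float], None]] = None,
) -> tuple[np.ndarray, OptimizeTrace]:
    """Projected L-BFGS loop; returns the final iterate and its trace.

    ``value`` may supply a cheaper objective-only oracle for the line
    search (e.g. forward solves without adjoints); it defaults to calling
    ``value_and_grad``.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    if bounds is None:
        bounds = Bounds.unbounded(x0.size)
    if stop is None:
        stop = StoppingRule()
    if value is None:
        value = lambda z: value_and_grad(z)[0]  # noqa: E731

    x = project_bounds(x0, bounds)
    f, g = value_and_grad(x)
    history = LBFGSHistory(memory)
    trace = OptimizeTrace()
    trace.objective.append(f)
    trace.grad_norm.append(float(np.linalg.norm(g)))
    slow_count = 0

    for k in range(stop.max_iter):
        gnorm_inf = float(np.max(np.abs(g)))
        if gnorm_inf == 0.0 or gnorm_inf <= stop.grad_tol:
            trace.status = "converged_gradient"
            break
        d = two_loop_direction(g, history)
        if float(g @ d) >= 0.0:  # not a descent direction: restart
            history.clear()
            d = -g
        alpha0 = 1.0 / gnorm_inf if k == 0 and len(history) == 0 else 1.0
        result = backtracking_search(x, d, value, g, bounds, f, alpha0=alpha0)
        if result is None and len(history) > 0:
            history.clear()
            result = backtracking_search(x, -g, value, g, bounds, f, alpha0=1.0 / gnorm_inf)
        if result is None:
            trace.status = "line_search_failure"
            break
        alpha, x_new, _ = result
        f_new, g_new = value_and_grad(x_new)
        history.push(x_new - x, g_new - g)
        rel_dec = (f - f_new) / max(abs(f), np.finfo(float).tiny)
        slow_count = slow_count + 1 if rel_dec < stop.tol else 0
        x, f, g = x_new, f_new, g_new
        trace.objective.append(f)
        trace.grad_norm.append(float(np.linalg.norm(g)))
        trace.alpha.append(alpha)
        trace.n_active_lower.append(int(np.sum(x <= bounds.lower)))
        trace.n_active_upper.append(int(np.sum(x >= bounds.upper)))
        if callback is not None:
            callback(k, x, f)
        if slow_count >= stop.patience:
            trace.status = "converged_objective"
            break
    else:
        trace.status = "max_iterations"
    return x, trace
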