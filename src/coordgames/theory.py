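"""Mean-field and replicator-equation theory of the general coordination game.

For the normalised game (1, S; T, 0) on a network of degree k, assuming
well-mixed strategies, a node with coordination rate alpha around it sees
alpha*k neighbours playing A, so the expected payoffs are

    Pi_A = k (alpha - alpha*S + S),      Pi_B = alpha * k * T.

A best-responding node picks A when Pi_A > Pi_B, i.e. when
alpha + S/(1 - S - T) > 0 (for S < 0, T < 1). The mean-field rate
equation for the coordination rate is

    d(alpha)/dt = (k/N) [ theta(alpha + S/(1-S-T)) - alpha ],

with theta the Heaviside step (theta(0) = 0 here, mirroring the strict
inequality). The replicator equation for the same game reduces to the
cubic

    d(alpha)/dt = (S+T-1) alpha^3 + (1-2S-T) alpha^2 + S alpha,

with stationary points {0, S/(S+T-1), 1}; the interior one is linearly
unstable in the coordination region (S+T-1 < 0), so the population
converges to full coordination. Starting from alpha = 1/2 both theories
select A exactly when T < S + 1 — the risk-dominance condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

__all__ = [
    "FixedPoint",
    "FixedPointSet",
    "expected_payoffs",
    "br_selects_A",
    "br_selection",
    "mean_field_br_rhs",
    "replicator_rhs",
    "replicator_fixed_points",
    "predicted_equilibrium",
    "integrate_ode",
    "selection_grid",
]


def _check_cg(S: float, T: float) -> None:
    if not (S < 0 and T < 1):
        raise ValueError(f"coordination game requires S<0 and T<1, got S={S}, T={T}")


def expected_payoffs(alpha: float, k: float, S: float, T: float) -> tuple[float, float]:
    """Mean-field expected payoffs (Pi_A, Pi_B) at coordination rate alpha."""
    if not (0 <= alpha <= 1):
        raise ValueError(f"alpha must be in [0,1], got {alpha}")
    if k < 0:
        raise ValueError("degree k must be >= 0")
    pi_a = k * (alpha - alpha * S + S)
    pi_b = alpha * k * T
    return pi_a, pi_b


def br_selection(alpha: float, S: float, T: float) -> Literal["A", "B", "tie"]:
    """Which strategy mean-field best response picks at coordination rate alpha."""
    _check_cg(S, T)
    x = alpha + S / (1.0 - S - T)
    if x > 0:
        return "A"
    if x < 0:
        return "B"
    return "tie"


def br_selects_A(alpha: float, S: float, T: float) -> bool:
    """Strict version of :func:`br_selection` (the tie counts as not-A)."""
    return br_selection(alpha, S, T) == "A"


def mean_field_br_rhs(alpha: float, S: float, T: float, k: float, N: float) -> float:
    """d(alpha)/dt of the mean-field best-response dynamics; theta(0)=0."""
    _check_cg(S, T)
    theta = 1.0 if alpha + S / (1.0 - S - T) > 0 else 0.0
    return (k / N) * (theta - alpha)


def replicator_rhs(alpha: float, S: float, T: float) -> float:
    """The replicator cubic (S+T-1) a^3 + (1-2S-T) a^2 + S a."""
    return (S + T - 1.0) * alpha**3 + (1.0 - 2.0 * S - T) * alpha**2 + S * alpha


def _replicator_dps(alpha: float, S: float, T: float) -> float:
    """Derivative of the replicator cubic in alpha."""
    return 3.0 * (S + T - 1.0) * alpha**2 + 2.0 * (1.0 - 2.0 * S - T) * alpha + S


@dataclass(frozen=True)
class FixedPoint:
    alpha: float
    stability: Literal["stable", "unstable"]


@dataclass(frozen=True)
class FixedPointSet:
    points: tuple[FixedPoint, ...]

    @property
    def interior(self) -> FixedPoint:
        (p,) = [p for p in self.points if 0 < p.alpha < 1]
        return p

    def __iter__(self):
        return iter(self.points)


def replicator_fixed_points(S: float, T: float) -> FixedPointSet:
    """Stationary points {0, S/(S+T-1), 1} with analytic stability.

    In the coordination region the boundary points are stable sinks and
    the interior point is the unstable separatrix between the two basins.
    """
    _check_cg(S, T)
    interior = S / (S + T - 1.0)
    pts = []
    for a in (0.0, interior, 1.0):
        d = _replicator_dps(a, S, T)
        if d == 0:  # numerical fallback: probe the flow on both sides
            eps = 1e-8
            left = replicator_rhs(max(a - eps, 0.0), S, T)
            right = replicator_rhs(min(a + eps, 1.0), S, T)
            stable = left >= 0 and right <= 0
        else:
            stable = d < 0
        pts.append(FixedPoint(alpha=a, stability="stable" if stable else "unstable"))
    return FixedPointSet(points=tuple(pts))


def predicted_equilibrium(
    S: float, T: float, alpha0: float = 0.5
) -> Literal["A", "B", "boundary"]:
    """Which coordinated state the replicator flow reaches from alpha0.

    A iff alpha0 lies above the interior fixed point S/(S+T-1); at
    alpha0 = 1/2 this reduces to the risk-dominance condition T < S + 1.
    """
    _check_cg(S, T)
    interior = S / (S + T - 1.0)
    if alpha0 > interior:
        return "A"
    if alpha0 < interior:
        return "B"
    return "boundary"


def integrate_ode(
    rhs: Callable[[float], float], alpha0: float, t_max: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 integration of d(alpha)/dt = rhs(alpha), clipped to [0,1]."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = int(round(t_max / dt))
    t = np.linspace(0.0, n * dt, n + 1)
    a = np.empty(n + 1)
    a[0] = alpha0
    x = alpha0
    for i in range(n):
        k1 = rhs(x)
        k2 = rhs(min(max(x + 0.5 * dt * k1, 0.0), 1.0))
        k3 = rhs(min(max(x + 0.5 * dt * k2, 0.0), 1.0))
        k4 = rhs(min(max(x + dt * k3, 0.0), 1.0))
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        x = min(max(x, 0.0), 1.0)
        a[i + 1] = x
    return t, a


def selection_grid(S_grid, T_grid, alpha0: float = 0.5) -> np.ndarray:
    """Predicted equilibrium over an (S, T) grid, encoded 1=A, 0=B, 0.5=boundary.

    Shape (len(S_grid), len(T_grid)); exportable as CSV for overlay against
    simulated phase diagrams.
    """
    out = np.empty((len(S_grid), len(T_grid)))
    code = {"A": 1.0, "B": 0.0, "boundary": 0.5}
    for i, S in enumerate(S_grid):
        for j, T in enumerate(T_grid):
            out[i, j] = code[predicted_equilibrium(S, T, alpha0)]
    return out
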