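"""Two-player 2x2 coordination games.

A symmetric two-player game is given by the payoff matrix

        A    B
    A ( R    S )
    B ( T    P )

read from the row player's perspective. Coordination games satisfy
``R > T`` and ``P > S``, so that both players choosing the same strategy
is a pure Nash equilibrium. Any coordination game with ``R > P`` can be
normalised, without changing best responses, to the general coordination
game (GCG) form ``(1, S; T, 0)`` with ``S < 0`` and ``T < 1``. The pure
coordination game (PCG) ``(1, 0; 0, 1)`` has ``R = P`` and is kept in raw
matrix form.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Union

__all__ = [
    "Strategy",
    "PayoffMatrix",
    "GCGParams",
    "GameClassification",
    "pcg_matrix",
    "normalize_to_gcg",
    "from_b_parametrization",
    "classify_game",
    "as_matrix",
    "resolve_game",
]


class Strategy(enum.IntEnum):
    """The two pure strategies. Integer values index payoff-matrix rows."""

    A = 0
    B = 1

    def other(self) -> "Strategy":
        return Strategy.B if self is Strategy.A else Strategy.A


@dataclass(frozen=True)
class PayoffMatrix:
    """Raw 2x2 payoff matrix (R, S, T, P) of the row player."""

    R: float
    S: float
    T: float
    P: float

    def __post_init__(self) -> None:
        for name in ("R", "S", "T", "P"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"payoff {name}={v!r} must be finite")

    def payoff(self, own: Strategy, opponent: Strategy) -> float:
        """Row player's payoff when playing `own` against `opponent`."""
        table = ((self.R, self.S), (self.T, self.P))
        return table[Strategy(own)][Strategy(opponent)]

    def as_array(self):
        import numpy as np

        return np.array([[self.R, self.S], [self.T, self.P]], dtype=np.float64)

    def relabel(self) -> "PayoffMatrix":
        """Swap the strategy labels A and B (an involution)."""
        return PayoffMatrix(R=self.P, S=self.T, T=self.S, P=self.R)

    @property
    def span(self) -> float:
        """Largest minus smallest matrix entry."""
        entries = (self.R, self.S, self.T, self.P)
        return max(entries) - min(entries)


@dataclass(frozen=True)
class GCGParams:
    """General coordination game in normalised form (1, S; T, 0)."""

    S: float
    T: float

    def is_coordination_game(self) -> bool:
        return self.S < 0 and self.T < 1

    def to_matrix(self) -> PayoffMatrix:
        return PayoffMatrix(R=1.0, S=self.S, T=self.T, P=0.0)

    @property
    def b(self) -> float:
        """The b of the (1, 0; -b, 2) parametrisation; meaningful at T=-1."""
        return -self.S - 1.0


@dataclass(frozen=True)
class GameClassification:
    is_coordination: bool
    is_stag_hunt: bool
    payoff_dominant: str  # always "A" in normalised form (1 > 0)
    risk_dominant: str  # "A", "B" or "boundary"


def pcg_matrix() -> PayoffMatrix:
    """The pure coordination game (1, 0; 0, 1): two equivalent equilibria."""
    return PayoffMatrix(R=1.0, S=0.0, T=0.0, P=1.0)


def normalize_to_gcg(m: PayoffMatrix) -> GCGParams:
    """Normalise a raw matrix with R > P to the (1, S'; T', 0) form.

    The transform S' = (S-P)/(R-P), T' = (T-P)/(R-P) preserves best
    responses, hence the game is strategically equivalent. Requires
    ``R > P`` (strategies already labelled so the Pareto-optimal diagonal
    entry is R); for ``R == P`` (e.g. the PCG) the transform is a division
    by zero and the game has no GCG form.
    """
    if m.R <= m.P:
        raise ValueError(
            f"normalisation requires R > P, got R={m.R}, P={m.P}; "
            "relabel strategies first (or, for R == P, the transform is undefined)"
        )
    d = m.R - m.P
    return GCGParams(S=(m.S - m.P) / d, T=(m.T - m.P) / d)


def from_b_parametrization(b: float) -> GCGParams:
    """GCG equivalent of the (1, 0; -b, 2) stag-hunt-like matrix.

    Relabeling strategies and subtracting 1 from every entry maps that
    game to the GCG with T = -1 and S = -b - 1. It is a coordination game
    only for b > -1.
    """
    if b <= -1:
        raise ValueError(f"b={b} gives S>=0: not a coordination game (need b > -1)")
    return GCGParams(S=-b - 1.0, T=-1.0)


def classify_game(g: GCGParams) -> GameClassification:
    """Coordination / stag-hunt flags and risk dominance of a GCG.

    In normalised form A is always payoff dominant (coordinating on A pays
    1 versus 0 for B). A is risk dominant when its expected payoff against
    a uniformly random opponent exceeds B's: (S+1)/2 > T/2, i.e. T < S+1.
    The line T = S+1 is reported explicitly as "boundary".
    """
    is_coord = g.is_coordination_game()
    is_stag = 0 < g.T < 1 and -1 < g.S < 0
    gap = (g.S + 1.0) - g.T
    if gap > 0:
        risk = "A"
    elif gap < 0:
        risk = "B"
    else:
        risk = "boundary"
    return GameClassification(
        is_coordination=is_coord,
        is_stag_hunt=is_stag,
        payoff_dominant="A",
        risk_dominant=risk,
    )


GameLike = Union[PayoffMatrix, GCGParams]


def as_matrix(game: GameLike) -> PayoffMatrix:
    """Coerce a PayoffMatrix or GCGParams to a raw PayoffMatrix."""
    if isinstance(game, PayoffMatrix):
        return game
    if isinstance(game, GCGParams):
        return game.to_matrix()
    raise TypeError(f"not a game: {game!r}")


def resolve_game(spec: dict) -> PayoffMatrix:
    """Resolve a config-style game spec to a PayoffMatrix.

    Accepted forms: ``{"R":..,"S":..,"T":..,"P":..}``, ``{"S":..,"T":..}``
    (normalised GCG) or ``{"b":..}`` (T=-1 parametrisation).
    """
    keys = set(spec)
    if keys == {"R", "S", "T", "P"}:
        return PayoffMatrix(**{k: float(v) for k, v in spec.items()})
    if keys == {"S", "T"}:
        return GCGParams(S=float(spec["S"]), T=float(spec["T"])).to_matrix()
    if keys == {"b"}:
        return from_b_parametrization(float(spec["b"])).to_matrix()
    raise ValueError(
        f"game spec must have keys {{R,S,T,P}}, {{S,T}} or {{b}}, got {sorted(keys)}"
    )
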