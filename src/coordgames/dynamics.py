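"""Asynchronous Monte-Carlo dynamics of coordination games on networks.

A population of agents sits on a fixed network; each agent holds a pure
strategy (A or B) and a stored "last payoff". At every elementary step one
node is activated uniformly at random and revises its strategy according
to the chosen update rule:

* **RD** (replicator dynamics / proportional imitation): compare with one
  random neighbour and copy its strategy with probability proportional to
  the payoff difference, if the neighbour is better off.
* **BR** (myopic best response): adopt the strategy that would maximise
  the payoff against the neighbours' current strategies (exact ties are
  broken uniformly at random).
* **UI** (unconditional imitation): copy the strategy of the best-paid
  neighbour if its stored payoff beats the agent's own refreshed payoff.

Time is measured in Monte-Carlo (MC) steps: 1 MC step = N elementary
activations. Observables are the coordination rate alpha (fraction of
A-players) and the interface density rho (fraction of edges joining
different strategies). A run stops at the first frozen configuration —
a state from which no activation can ever change a strategy — or at the
configured cap.

Stored payoffs are stale by design: only the activated node refreshes its
own payoff (BR writes its realised best-response payoff); neighbours keep
whatever they last computed. Initialisation plays a full round so stored
payoffs start consistent. The untested alternative in which the focal
node's games also refresh the neighbours' payoffs is available via
``SimulationConfig.refresh_neighbor_payoffs``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import _kernels as K
from .games import GameLike, PayoffMatrix, Strategy, as_matrix
from .networks import Network

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "TrajectoryRecord",
    "initialize_state",
    "accumulate_payoff",
    "rd_phi",
    "rd_update",
    "br_update",
    "ui_update",
    "elementary_step",
    "is_frozen",
    "run_simulation",
    "coordination_rate",
    "interface_density",
    "DegenerateGameError",
]

RULES = ("RD", "BR", "UI")


class DegenerateGameError(ValueError):
    """RD is undefined for a constant payoff matrix (phi would be 0)."""


@dataclass
class SimulationConfig:
    rule: str
    seed: int = 0
    max_mc_steps: int = 100_000
    record_every: int = 0  # 0: record only initial and final observables
    initial_strategies: Optional[Sequence[int]] = None  # testing hook
    refresh_neighbor_payoffs: bool = False

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if self.max_mc_steps < 1:
            raise ValueError("max_mc_steps must be >= 1")


@dataclass
class SimulationState:
    """Mutable per-node state: strategies (0=A, 1=B) and stored payoffs."""

    strategies: np.ndarray  # int8, shape (N,)
    payoffs: np.ndarray  # float64, shape (N,)
    t_elem: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng, repr=False)

    @property
    def N(self) -> int:
        return len(self.strategies)

    def strategy(self, i: int) -> Strategy:
        return Strategy(int(self.strategies[i]))

    def stored_payoff(self, i: int) -> float:
        return float(self.payoffs[i])

    def copy(self) -> "SimulationState":
        return SimulationState(
            strategies=self.strategies.copy(),
            payoffs=self.payoffs.copy(),
            t_elem=self.t_elem,
            rng=self.rng,
        )


@dataclass
class TrajectoryRecord:
    """Sampled (mc_step, alpha, rho) series plus the run outcome."""

    times: np.ndarray
    alpha_series: np.ndarray
    rho_series: np.ndarray
    tau: int
    frozen: bool
    final_state: SimulationState
    meta: dict = field(default_factory=dict)

    @property
    def final_alpha(self) -> float:
        return coordination_rate(self.final_state)

    def final_rho(self, net: Network) -> float:
        return interface_density(self.final_state, net)

    def save(self, basepath: str | Path) -> None:
        """Write <base>.csv (mc_step, alpha, rho) and a <base>.json sidecar."""
        base = Path(basepath)
        with open(base.with_suffix(".csv"), "w") as fh:
            fh.write("mc_step,alpha,rho\n")
            for t, a, r in zip(self.times, self.alpha_series, self.rho_series):
                fh.write(f"{int(t)},{a},{r}\n")
        sidecar = {"tau": int(self.tau), "frozen": bool(self.frozen)}
        sidecar.update(self.meta)
        with open(base.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)


def _matrix_array(game: GameLike) -> np.ndarray:
    return as_matrix(game).as_array()


def initialize_state(
    net: Network,
    game: GameLike,
    config: SimulationConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> SimulationState:
    """Random initial strategies (A/B each with probability 1/2, unless the
    config supplies them) and stored payoffs from a full round of play."""
    if rng is None:
        seed = config.seed if config is not None else 0
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    init = config.initial_strategies if config is not None else None
    if init is not None:
        strat = np.asarray([int(Strategy(s)) for s in init], dtype=np.int8)
        if len(strat) != net.N:
            raise ValueError(
                f"initial_strategies has length {len(strat)}, network has N={net.N}"
            )
    else:
        strat = rng.integers(0, 2, size=net.N).astype(np.int8)
    pay = np.empty(net.N, dtype=np.float64)
    K.init_payoffs(_matrix_array(game), strat, net.indptr, net.indices, pay)
    return SimulationState(strategies=strat, payoffs=pay, t_elem=0, rng=rng)


def accumulate_payoff(state: SimulationState, net: Network, game: GameLike, i: int) -> float:
    """Payoff node i would collect playing its current strategy against all
    neighbours now; does not modify the state."""
    return float(
        K.accumulate_payoff(_matrix_array(game), state.strategies, net.indptr, net.indices, i)
    )


def rd_phi(game: GameLike, net: Network) -> float:
    """RD normalisation: largest possible payoff difference on this network,
    phi = k_max * (max matrix entry - min matrix entry)."""
    if net.N == 0:
        raise ValueError("empty network")
    span = as_matrix(game).span
    if span == 0:
        raise DegenerateGameError(
            "constant payoff matrix: RD imitation probability undefined (phi=0)"
        )
    return net.max_degree * span


def _phi_for(rule: str, game: GameLike, net: Network) -> float:
    return rd_phi(game, net) if rule == "RD" else 1.0


def rd_update(state: SimulationState, net: Network, game: GameLike, i: int) -> bool:
    phi = rd_phi(game, net)
    K.seed_rng(int(state.rng.integers(2**31)))
    flags = K.rd_update(
        _matrix_array(game), state.strategies, state.payoffs, net.indptr, net.indices, i, phi
    )
    return bool(flags & K._CH_STRAT)


def br_update(state: SimulationState, net: Network, game: GameLike, i: int) -> bool:
    K.seed_rng(int(state.rng.integers(2**31)))
    flags = K.br_update(
        _matrix_array(game), state.strategies, state.payoffs, net.indptr, net.indices, i
    )
    return bool(flags & K._CH_STRAT)


def ui_update(state: SimulationState, net: Network, game: GameLike, i: int) -> bool:
    K.seed_rng(int(state.rng.integers(2**31)))
    flags = K.ui_update(
        _matrix_array(game), state.strategies, state.payoffs, net.indptr, net.indices, i
    )
    return bool(flags & K._CH_STRAT)


def elementary_step(
    state: SimulationState, net: Network, game: GameLike, rule: str
) -> bool:
    """Activate one uniformly random node (drawn from the state's RNG) and
    apply the rule's update; increments the elementary-step clock."""
    i = int(state.rng.integers(net.N))
    K.seed_rng(int(state.rng.integers(2**31)))
    flags = K.apply_update(
        _matrix_array(game),
        state.strategies,
        state.payoffs,
        net.indptr,
        net.indices,
        i,
        K.RULE_CODES[rule],
        _phi_for(rule, game, net),
        False,
    )
    state.t_elem += 1
    return bool(flags & K._CH_STRAT)


def is_frozen(state: SimulationState, net: Network, game: GameLike, rule: str) -> bool:
    """True iff no activation of any node could change any strategy with
    positive probability, now or after any sequence of activations."""
    return bool(
        K.is_frozen(
            _matrix_array(game),
            state.strategies,
            state.payoffs,
            net.indptr,
            net.indices,
            K.RULE_CODES[rule],
        )
    )


def coordination_rate(state: SimulationState) -> float:
    """Fraction of agents playing strategy A."""
    return float(np.mean(state.strategies == int(Strategy.A)))


def interface_density(state: SimulationState, net: Network) -> float:
    """Fraction of edges whose endpoints play different strategies."""
    if net.n_edges == 0:
        raise ValueError("interface density undefined on a graph with no edges")
    active = K.count_active_edges(state.strategies, net.indptr, net.indices)
    return active / net.n_edges


def run_simulation(net: Network, game: GameLike, config: SimulationConfig) -> TrajectoryRecord:
    """Run the asynchronous dynamics until frozen or max_mc_steps.

    Fully reproducible from ``config.seed``: a SeedSequence spawns one
    stream for the initial strategies and one 31-bit seed for the
    compiled loop's RNG.
    """
    ss = np.random.SeedSequence(config.seed)
    s_init, s_loop = ss.spawn(2)
    state = initialize_state(net, game, config, rng=np.random.default_rng(s_init))

    rule = K.RULE_CODES[config.rule]
    phi = _phi_for(config.rule, game, net)
    M = _matrix_array(game)

    if config.record_every > 0:
        n_slots = config.max_mc_steps // config.record_every + 1
    else:
        n_slots = 0
    rec_t = np.zeros(n_slots, dtype=np.int64)
    rec_alpha = np.zeros(n_slots, dtype=np.float64)
    rec_rho = np.zeros(n_slots, dtype=np.float64)

    K.seed_rng(int(s_loop.generate_state(1)[0] % 2**31))
    tau, frozen, n_rec = K.run(
        M,
        state.strategies,
        state.payoffs,
        net.indptr,
        net.indices,
        rule,
        phi,
        config.max_mc_steps,
        config.record_every,
        config.refresh_neighbor_payoffs,
        rec_t,
        rec_alpha,
        rec_rho,
    )
    state.t_elem = int(tau) * net.N

    final_alpha = coordination_rate(state)
    final_rho = interface_density(state, net) if net.n_edges > 0 else np.nan
    stop_t = int(tau) if frozen else config.max_mc_steps
    times = np.append(rec_t[:n_rec], stop_t)
    alphas = np.append(rec_alpha[:n_rec], final_alpha)
    rhos = np.append(rec_rho[:n_rec], final_rho)

    m = as_matrix(game)
    meta = {
        "seed": config.seed,
        "rule": config.rule,
        "game": {"R": m.R, "S": m.S, "T": m.T, "P": m.P},
        "network": {k: v for k, v in net.meta.items()},
        "max_mc_steps": config.max_mc_steps,
    }
    return TrajectoryRecord(
        times=times,
        alpha_series=alphas,
        rho_series=rhos,
        tau=int(tau),
        frozen=bool(frozen),
        final_state=state,
        meta=meta,
    )
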