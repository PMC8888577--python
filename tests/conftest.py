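"""Shared fixtures and the independent brute-force activation oracle."""

from __future__ import annotations

import numpy as np
import pytest

from coordgames.dynamics import SimulationState
from coordgames.games import PayoffMatrix, Strategy
from coordgames.networks import Network


@pytest.fixture
def pair_net() -> Network:
    """Two nodes joined by one edge."""
    return Network.from_edges(2, [(0, 1)])


@pytest.fixture
def path3_net() -> Network:
    return Network.from_edges(3, [(0, 1), (1, 2)])


def make_state(net: Network, game, strategies, rng_seed: int = 0) -> SimulationState:
    """State with explicit strategies and stored payoffs from a full round."""
    from coordgames import _kernels as K
    from coordgames.games import as_matrix

    strat = np.asarray([int(Strategy[s]) if isinstance(s, str) else int(s) for s in strategies],
                       dtype=np.int8)
    pay = np.empty(net.N, dtype=np.float64)
    K.init_payoffs(as_matrix(game).as_array(), strat, net.indptr, net.indices, pay)
    return SimulationState(strategies=strat, payoffs=pay, rng=np.random.default_rng(rng_seed))


def brute_force_can_change(state: SimulationState, net: Network, m: PayoffMatrix, rule: str) -> bool:
    """Pure-Python enumeration: can any single activation change any
    strategy with positive probability? Independent of the compiled
    kernels; valid for states whose stored payoffs are consistent."""
    for i in range(net.N):
        nbrs = list(net.neighbors(i))
        if not nbrs:
            continue
        s = Strategy(int(state.strategies[i]))
        fresh = sum(
            m.payoff(s, Strategy(int(state.strategies[j]))) for j in nbrs
        )
        if rule == "BR":
            pi = {
                t: sum(m.payoff(t, Strategy(int(state.strategies[j]))) for j in nbrs)
                for t in (Strategy.A, Strategy.B)
            }
            if pi[Strategy.A] > pi[Strategy.B]:
                best = {Strategy.A}
            elif pi[Strategy.B] > pi[Strategy.A]:
                best = {Strategy.B}
            else:
                best = {Strategy.A, Strategy.B}  # random tie-break: both reachable
            if best != {s}:
                return True
        elif rule == "RD":
            for j in nbrs:
                if state.strategies[j] != state.strategies[i] and state.payoffs[j] > fresh:
                    return True
        else:  # UI
            pmax = max(state.payoffs[j] for j in nbrs)
            if pmax > fresh and any(
                state.payoffs[j] == pmax and state.strategies[j] != state.strategies[i]
                for j in nbrs
            ):
                return True
    return False
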