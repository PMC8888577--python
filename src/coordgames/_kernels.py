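"""Numba-compiled inner loops of the asynchronous Monte-Carlo dynamics.

State arrays: ``strat`` (int8, 0=A, 1=B), ``pay`` (float64 stored "last
payoff" per node), CSR adjacency (``indptr``, ``indices``), and the 2x2
payoff matrix ``M`` with ``M[own, opponent]``.

Randomness uses numba's internal RNG: seed it via :func:`seed_rng` before a
run. Per activation the draw order is fixed: focal node, then (RD) the
neighbour draw and the imitation coin, or (UI) the tie-break draw.

Rule codes: 0 = RD (replicator / proportional imitation), 1 = BR (myopic
best response), 2 = UI (unconditional imitation).
"""

import numpy as np
from numba import njit

RULE_RD = 0
RULE_BR = 1
RULE_UI = 2

RULE_CODES = {"RD": RULE_RD, "BR": RULE_BR, "UI": RULE_UI}

# change flags returned by the update kernels
_CH_STRAT = 1
_CH_PAY = 2


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def accumulate_payoff(M, strat, indptr, indices, i):
    """Total payoff of node i playing its current strategy against all
    neighbours' current strategies."""
    s = strat[i]
    total = 0.0
    for idx in range(indptr[i], indptr[i + 1]):
        total += M[s, strat[indices[idx]]]
    return total


@njit(cache=True)
def init_payoffs(M, strat, indptr, indices, pay):
    for i in range(len(strat)):
        pay[i] = accumulate_payoff(M, strat, indptr, indices, i)


@njit(cache=True)
def rd_update(M, strat, pay, indptr, indices, i, phi):
    """Proportional imitation: refresh own payoff, compare with one random
    neighbour's stored payoff, copy its strategy with probability
    (difference)/phi if the neighbour is better off."""
    lo, hi = indptr[i], indptr[i + 1]
    if hi == lo:
        return 0
    flags = 0
    fresh = accumulate_payoff(M, strat, indptr, indices, i)
    if pay[i] != fresh:
        flags |= _CH_PAY
    pay[i] = fresh
    j = indices[lo + np.random.randint(hi - lo)]
    if pay[j] > fresh:
        p = (pay[j] - fresh) / phi
        if np.random.random() < p:
            if strat[i] != strat[j]:
                strat[i] = strat[j]
                flags |= _CH_STRAT
    return flags


@njit(cache=True)
def br_update(M, strat, pay, indptr, indices, i):
    """Myopic best response: adopt the strategy maximising the hypothetical
    payoff against current neighbour strategies; an exact payoff tie is
    broken uniformly at random (the tie noise is what lets even-degree
    populations escape marginal frozen patterns). Stored payoff becomes
    the chosen hypothetical payoff."""
    lo, hi = indptr[i], indptr[i + 1]
    if hi == lo:
        return 0
    pi_a = 0.0
    pi_b = 0.0
    for idx in range(lo, hi):
        sj = strat[indices[idx]]
        pi_a += M[0, sj]
        pi_b += M[1, sj]
    if pi_a > pi_b:
        new = 0
    elif pi_b > pi_a:
        new = 1
    else:
        new = np.random.randint(2)
    chosen = pi_a if new == 0 else pi_b
    flags = 0
    if pay[i] != chosen:
        flags |= _CH_PAY
    pay[i] = chosen
    if new != strat[i]:
        strat[i] = new
        flags |= _CH_STRAT
    return flags


@njit(cache=True)
def ui_update(M, strat, pay, indptr, indices, i):
    """Unconditional imitation: refresh own payoff; if the best stored
    neighbour payoff beats it, copy a uniformly chosen neighbour among
    those attaining the maximum."""
    lo, hi = indptr[i], indptr[i + 1]
    if hi == lo:
        return 0
    flags = 0
    fresh = accumulate_payoff(M, strat, indptr, indices, i)
    if pay[i] != fresh:
        flags |= _CH_PAY
    pay[i] = fresh
    pmax = -np.inf
    count = 0
    for idx in range(lo, hi):
        pj = pay[indices[idx]]
        if pj > pmax:
            pmax = pj
            count = 1
        elif pj == pmax:
            count += 1
    if pmax > fresh:
        r = np.random.randint(count)
        for idx in range(lo, hi):
            j = indices[idx]
            if pay[j] == pmax:
                if r == 0:
                    if strat[i] != strat[j]:
                        strat[i] = strat[j]
                        flags |= _CH_STRAT
                    break
                r -= 1
    return flags


@njit(cache=True)
def refresh_neighbor_payoffs(M, strat, pay, indptr, indices, i):
    """Optional variant: the focal node's games also refresh every
    neighbour's stored payoff (full recomputation)."""
    flags = 0
    for idx in range(indptr[i], indptr[i + 1]):
        j = indices[idx]
        fresh = accumulate_payoff(M, strat, indptr, indices, j)
        if pay[j] != fresh:
            flags |= _CH_PAY
        pay[j] = fresh
    return flags


@njit(cache=True)
def apply_update(M, strat, pay, indptr, indices, i, rule, phi, refresh_nb):
    if refresh_nb:
        flags = refresh_neighbor_payoffs(M, strat, pay, indptr, indices, i)
    else:
        flags = 0
    if rule == RULE_RD:
        flags |= rd_update(M, strat, pay, indptr, indices, i, phi)
    elif rule == RULE_BR:
        flags |= br_update(M, strat, pay, indptr, indices, i)
    else:
        flags |= ui_update(M, strat, pay, indptr, indices, i)
    return flags


@njit(cache=True)
def is_frozen(M, strat, pay, indptr, indices, rule):
    """True iff no single activation could change any strategy with
    positive probability, now or ever.

    BR: every node's current strategy is a strict best response — a payoff
    tie is not frozen because the random tie-break can flip the strategy
    (BR ignores stored payoffs). RD/UI: every stored payoff equals the
    recomputed payoff (so refreshes change nothing), and no activation can
    imitate across a strategy difference: for RD no differently-playing
    neighbour is strictly better off; for UI no differently-playing
    neighbour attains the strict neighbourhood payoff maximum.
    """
    n = len(strat)
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        if hi == lo:
            continue
        s = strat[i]
        if rule == RULE_BR:
            pi_a = 0.0
            pi_b = 0.0
            for idx in range(lo, hi):
                sj = strat[indices[idx]]
                pi_a += M[0, sj]
                pi_b += M[1, sj]
            if s == 0:
                if not (pi_a > pi_b):
                    return False
            else:
                if not (pi_b > pi_a):
                    return False
        else:
            fresh = accumulate_payoff(M, strat, indptr, indices, i)
            if pay[i] != fresh:
                return False
            if rule == RULE_RD:
                for idx in range(lo, hi):
                    j = indices[idx]
                    if strat[j] != s and pay[j] > fresh:
                        return False
            else:  # UI
                pmax = -np.inf
                for idx in range(lo, hi):
                    pj = pay[indices[idx]]
                    if pj > pmax:
                        pmax = pj
                if pmax > fresh:
                    for idx in range(lo, hi):
                        j = indices[idx]
                        if pay[j] == pmax and strat[j] != s:
                            return False
    return True


@njit(cache=True)
def count_active_edges(strat, indptr, indices):
    """Number of undirected edges whose endpoints play different strategies."""
    active2 = 0
    for i in range(len(strat)):
        s = strat[i]
        for idx in range(indptr[i], indptr[i + 1]):
            if strat[indices[idx]] != s:
                active2 += 1
    return active2 // 2


@njit(cache=True)
def run(M, strat, pay, indptr, indices, rule, phi, max_mc, record_every,
        refresh_nb, rec_t, rec_alpha, rec_rho):
    """Main asynchronous loop. One MC step = N single-node activations.

    Stops at the first MC-step boundary where the state is frozen; tau is
    backdated to the boundary following the last observed state change
    (strategy flip or stored-payoff value change), which is exact because
    the frozen condition is absorbing and depends only on the state.

    Records (mc_step, alpha, rho) every ``record_every`` MC steps into the
    rec_* arrays (record_every == 0 disables periodic recording). Returns
    (tau, frozen, n_recorded).
    """
    n = len(strat)
    n_edges = len(indices) // 2
    n_a = 0
    for i in range(n):
        if strat[i] == 0:
            n_a += 1
    active = count_active_edges(strat, indptr, indices)

    n_rec = 0
    if record_every > 0 and len(rec_t) > 0:
        rec_t[0] = 0
        rec_alpha[0] = n_a / n
        rec_rho[0] = active / n_edges if n_edges > 0 else np.nan
        n_rec = 1

    last_change = 0
    tau = max_mc
    frozen = False
    for t in range(1, max_mc + 1):
        step_changed = False
        for _ in range(n):
            i = np.random.randint(n)
            s_old = strat[i]
            flags = apply_update(M, strat, pay, indptr, indices, i, rule, phi, refresh_nb)
            if flags != 0:
                step_changed = True
            if strat[i] != s_old:
                if strat[i] == 0:
                    n_a += 1
                else:
                    n_a -= 1
                # flipping i toggles the activity of every incident edge
                for idx in range(indptr[i], indptr[i + 1]):
                    if strat[indices[idx]] != strat[i]:
                        active += 1
                    else:
                        active -= 1
        if step_changed:
            last_change = t
        else:
            if is_frozen(M, strat, pay, indptr, indices, rule):
                tau = last_change
                frozen = True
                break
        if record_every > 0 and t % record_every == 0 and n_rec < len(rec_t):
            rec_t[n_rec] = t
            rec_alpha[n_rec] = n_a / n
            rec_rho[n_rec] = active / n_edges if n_edges > 0 else np.nan
            n_rec += 1
    return tau, frozen, n_rec
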