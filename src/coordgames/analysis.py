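"""Ensemble experiments and their statistics.

Runs many independent realisations (fresh network + fresh dynamics seed
per realisation), summarises final coordination rate alpha, interface
density rho and convergence time tau, classifies the modality of alpha
distributions, locates transition points (k_c from the maximum of the
mean convergence time, S_c from the alpha = 1/2 crossing) and fits the
power-law / logarithmic scaling relations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import SimulationConfig, run_simulation
from .games import GameLike, as_matrix
from .networks import make_network

__all__ = [
    "EnsembleResult",
    "TransitionEstimate",
    "FitResult",
    "run_ensemble",
    "conditional_means",
    "classify_modality",
    "estimate_kc_from_tau",
    "estimate_Sc",
    "phase_diagram",
    "fit_power_law",
    "fit_logarithmic",
    "degree_scan",
    "alpha_vs_S_scan",
    "Sc_vs_k",
    "kc_vs_N",
]


@dataclass
class EnsembleResult:
    """Per-realisation final observables over an ensemble of runs."""

    alpha: np.ndarray
    rho: np.ndarray
    tau: np.ndarray
    frozen: np.ndarray
    seeds: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_real(self) -> int:
        return len(self.alpha)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seed": self.seeds,
                "alpha": self.alpha,
                "rho": self.rho,
                "tau": self.tau,
                "frozen": self.frozen,
            }
        )

    def summary(self) -> dict:
        hi, lo = conditional_means(self.alpha)
        return {
            "mean_alpha": float(np.mean(self.alpha)),
            "mean_alpha_hi": hi,
            "mean_alpha_lo": lo,
            "mean_rho": float(np.nanmean(self.rho)),
            "mean_tau": float(np.mean(self.tau)),
            "frac_frozen": float(np.mean(self.frozen)),
            "frac_coordinated": float(np.mean((self.alpha == 0) | (self.alpha == 1))),
            "n_real": self.n_real,
        }


def _dynamics_seed(base_seed: int, r: int) -> int:
    # independent 31-bit stream per realisation, decoupled from the
    # base_seed+r used for network generation
    return int(np.random.SeedSequence((base_seed, r)).generate_state(1)[0] % 2**31)


def run_ensemble(
    game: GameLike,
    rule: str,
    *,
    net_family: str = "random_regular",
    N: int,
    k: float | None = None,
    n_real: int,
    base_seed: int,
    max_mc_steps: int = 100_000,
    regenerate_network: bool = True,
) -> EnsembleResult:
    """n_real independent realisations of the dynamics.

    Realisation r uses network seed ``base_seed + r`` (a fresh graph each
    time unless ``regenerate_network=False``) and an independent dynamics
    seed derived from (base_seed, r); results are order-stable.
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    alphas = np.empty(n_real)
    rhos = np.empty(n_real)
    taus = np.empty(n_real, dtype=np.int64)
    frozen = np.empty(n_real, dtype=bool)
    seeds = np.empty(n_real, dtype=np.int64)
    net = None
    for r in range(n_real):
        if net is None or regenerate_network:
            net = make_network(net_family, N=N, k=k, seed=base_seed + (r if regenerate_network else 0))
        dseed = _dynamics_seed(base_seed, r)
        rec = run_simulation(
            net, game, SimulationConfig(rule=rule, seed=dseed, max_mc_steps=max_mc_steps)
        )
        alphas[r] = rec.final_alpha
        rhos[r] = rec.rho_series[-1]
        taus[r] = rec.tau
        frozen[r] = rec.frozen
        seeds[r] = dseed
    m = as_matrix(game)
    return EnsembleResult(
        alpha=alphas,
        rho=rhos,
        tau=taus,
        frozen=frozen,
        seeds=seeds,
        meta={
            "rule": rule,
            "game": {"R": m.R, "S": m.S, "T": m.T, "P": m.P},
            "net_family": net_family,
            "N": N,
            "k": k,
            "base_seed": base_seed,
            "max_mc_steps": max_mc_steps,
        },
    )


def conditional_means(alphas: Sequence[float]) -> tuple[float, float]:
    """Mean alpha over realisations with alpha > 1/2 and with alpha <= 1/2.

    The two coordinated branches would average to a meaningless 1/2 if
    pooled; an empty branch is reported as nan.
    """
    a = np.asarray(alphas, dtype=float)
    if a.size == 0:
        raise ValueError("empty input")
    hi = a[a > 0.5]
    lo = a[a <= 0.5]
    return (
        float(np.mean(hi)) if hi.size else float("nan"),
        float(np.mean(lo)) if lo.size else float("nan"),
    )


def classify_modality(
    alphas: Sequence[float], n_bins: int = 21, min_peak_mass: float = 0.05
) -> Literal["unimodal", "bimodal", "trimodal", "other"]:
    """Classify the shape of a final-alpha distribution.

    Histogram on [0, 1] with equal bins; a peak is a (plateau-merged)
    local maximum holding at least ``min_peak_mass`` of the sample.
    Peaks with centres below 0.2 / above 0.8 count as boundary peaks
    (coordinated or nearly coordinated outcomes), the rest as interior
    (disorder). Interior peak(s) only -> unimodal; boundary peaks on both
    sides plus interior -> trimodal; boundary peaks only -> bimodal;
    anything else -> other.
    """
    a = np.asarray(alphas, dtype=float)
    if a.size < 50:
        raise ValueError(f"need >= 50 samples to classify modality, got {a.size}")
    counts, edges = np.histogram(a, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])

    # merge runs of equal counts, then mark runs that beat both neighbours
    runs = []  # (count, first_bin, last_bin)
    i = 0
    while i < n_bins:
        j = i
        while j + 1 < n_bins and counts[j + 1] == counts[i]:
            j += 1
        runs.append((counts[i], i, j))
        i = j + 1
    peaks = []
    for r, (c, lo_b, hi_b) in enumerate(runs):
        left = runs[r - 1][0] if r > 0 else -1
        right = runs[r + 1][0] if r + 1 < len(runs) else -1
        if c > left and c > right and c >= min_peak_mass * a.size:
            peaks.append(0.5 * (centers[lo_b] + centers[hi_b]))

    low = any(p < 0.2 for p in peaks)
    high = any(p > 0.8 for p in peaks)
    interior = any(0.2 <= p <= 0.8 for p in peaks)
    if interior and not low and not high:
        return "unimodal"
    if low and high and interior:
        return "trimodal"
    if low and high and not interior:
        return "bimodal"
    return "other"


@dataclass(frozen=True)
class TransitionEstimate:
    location: float
    method: Literal["max_tau", "alpha_crossing", "modality_change"]
    grid: tuple
    aux: dict = field(default_factory=dict)


def estimate_kc_from_tau(
    ks: Sequence[int], mean_taus: Sequence[float], exclude_k_le: int = 2
) -> TransitionEstimate:
    """Transition degree k_c = argmax over k of the mean convergence time.

    Degrees k <= exclude_k_le are ignored (chains and matchings have
    trivially slow dynamics unrelated to the transition); ties resolve to
    the smallest qualifying k.
    """
    ks = np.asarray(ks)
    taus = np.asarray(mean_taus, dtype=float)
    if len(ks) != len(taus):
        raise ValueError("ks and mean_taus must have equal length")
    if np.any(np.diff(ks) <= 0):
        raise ValueError("ks must be strictly increasing")
    mask = ks > exclude_k_le
    if not mask.any():
        raise ValueError(f"no degrees above exclude_k_le={exclude_k_le}")
    sel_ks = ks[mask]
    sel_taus = taus[mask]
    kc = int(sel_ks[int(np.argmax(sel_taus))])  # argmax takes first of ties
    return TransitionEstimate(
        location=float(kc),
        method="max_tau",
        grid=tuple(int(x) for x in ks),
        aux={"mean_taus": tuple(float(x) for x in taus), "exclude_k_le": exclude_k_le},
    )


def estimate_Sc(S_grid: Sequence[float], mean_alphas: Sequence[float]) -> TransitionEstimate:
    """Equilibrium-selection threshold S_c: linear interpolation of the
    alpha = 1/2 crossing of mean final alpha over an increasing S grid."""
    S = np.asarray(S_grid, dtype=float)
    a = np.asarray(mean_alphas, dtype=float)
    if len(S) != len(a):
        raise ValueError("S_grid and mean_alphas must have equal length")
    if np.any(np.diff(S) <= 0):
        raise ValueError("S_grid must be strictly increasing")
    for i in range(len(S) - 1):
        if a[i] <= 0.5 < a[i + 1] or a[i] < 0.5 <= a[i + 1]:
            sc = S[i] + (0.5 - a[i]) * (S[i + 1] - S[i]) / (a[i + 1] - a[i])
            return TransitionEstimate(
                location=float(sc),
                method="alpha_crossing",
                grid=tuple(float(x) for x in S),
                aux={"mean_alphas": tuple(float(x) for x in a)},
            )
    raise ValueError("mean alpha never crosses 1/2 on this grid")


def phase_diagram(
    S_grid: Sequence[float],
    T_grid: Sequence[float],
    rule: str,
    net_params: dict,
    n_real: int,
    base_seed: int = 0,
    max_mc_steps: int = 100_000,
) -> np.ndarray:
    """Mean final alpha on an (S, T) grid; shape (len(S_grid), len(T_grid)).

    ``net_params`` holds the make_network arguments (family, N, k).
    """
    from .games import GCGParams

    out = np.empty((len(S_grid), len(T_grid)))
    for i, S in enumerate(S_grid):
        for j, T in enumerate(T_grid):
            if not (S < 0 and T < 1):
                raise ValueError(f"(S={S}, T={T}) outside the coordination region")
            res = run_ensemble(
                GCGParams(S=S, T=T),
                rule,
                net_family=net_params.get("family", "random_regular"),
                N=net_params["N"],
                k=net_params.get("k"),
                n_real=n_real,
                base_seed=base_seed + 1000 * (i * len(T_grid) + j),
                max_mc_steps=max_mc_steps,
            )
            out[i, j] = float(np.mean(res.alpha))
    return out


@dataclass(frozen=True)
class FitResult:
    exponent: float  # power-law exponent, or slope of the log term
    prefactor: float  # multiplicative prefactor (power law) or intercept
    r_squared: float
    used_abs: bool = False  # |y| was fitted because y had negative values


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS fit of y = C * x^gamma on log-log coordinates.

    Negative y values are fitted in magnitude (|y|) and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0):
        raise ValueError("x must be positive for a power-law fit")
    used_abs = bool(np.any(y < 0))
    yy = np.abs(y)
    if np.any(yy == 0):
        raise ValueError("y must be nonzero for a power-law fit")
    fit = stats.linregress(np.log(x), np.log(yy))
    return FitResult(
        exponent=float(fit.slope),
        prefactor=float(np.exp(fit.intercept)),
        r_squared=float(fit.rvalue**2),
        used_abs=used_abs,
    )


def fit_logarithmic(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS fit of y = a * ln(x) + b on lin-log coordinates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0):
        raise ValueError("x must be positive for a logarithmic fit")
    fit = stats.linregress(np.log(x), y)
    return FitResult(
        exponent=float(fit.slope),
        prefactor=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


# ---------------------------------------------------------------------------
# scan drivers used by the experiments layer and the acceptance checks


def degree_scan(
    game: GameLike,
    rule: str,
    ks: Sequence[int],
    *,
    N: int,
    n_real: int,
    base_seed: int,
    net_family: str = "random_regular",
    max_mc_steps: int = 100_000,
    keep_raw: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Ensemble per degree; one summary row per k."""
    rows = []
    raw: dict[int, EnsembleResult] = {}
    for idx, k in enumerate(ks):
        res = run_ensemble(
            game,
            rule,
            net_family=net_family,
            N=N,
            k=k,
            n_real=n_real,
            base_seed=base_seed + 10_000 * idx,
            max_mc_steps=max_mc_steps,
        )
        row = {"k": k, **res.summary()}
        rows.append(row)
        if keep_raw:
            raw[k] = res
    df = pd.DataFrame(rows)
    return (df, raw) if keep_raw else df


def alpha_vs_S_scan(
    S_grid: Sequence[float],
    rule: str,
    *,
    T: float,
    N: int,
    k: int,
    n_real: int,
    base_seed: int,
    net_family: str = "random_regular",
    max_mc_steps: int = 100_000,
) -> pd.DataFrame:
    """Mean final alpha versus S at fixed T and degree."""
    from .games import GCGParams

    rows = []
    for idx, S in enumerate(S_grid):
        res = run_ensemble(
            GCGParams(S=float(S), T=T),
            rule,
            net_family=net_family,
            N=N,
            k=k,
            n_real=n_real,
            base_seed=base_seed + 10_000 * idx,
            max_mc_steps=max_mc_steps,
        )
        rows.append({"S": float(S), **res.summary()})
    return pd.DataFrame(rows)


def Sc_vs_k(
    ks: Sequence[int],
    *,
    T: float = -1.0,
    S_grid: Sequence[float] | None = None,
    N: int,
    n_real: int,
    base_seed: int,
    rule: str = "UI",
    max_mc_steps: int = 100_000,
) -> tuple[pd.DataFrame, FitResult]:
    """S_c(k) from the alpha crossing per degree, plus the |S_c| power law."""
    if S_grid is None:
        S_grid = np.round(np.arange(-4.0, -1.99, 0.2), 10)
    scs = []
    for idx, k in enumerate(ks):
        df = alpha_vs_S_scan(
            S_grid,
            rule,
            T=T,
            N=N,
            k=k,
            n_real=n_real,
            base_seed=base_seed + 1_000_000 * idx,
            max_mc_steps=max_mc_steps,
        )
        est = estimate_Sc(df["S"].to_numpy(), df["mean_alpha"].to_numpy())
        scs.append({"k": k, "S_c": est.location})
    table = pd.DataFrame(scs)
    fit = fit_power_law(table["k"], table["S_c"])
    return table, fit


def kc_vs_N(
    Ns: Sequence[int],
    ks: Sequence[int],
    *,
    rule: str = "UI",
    game: GameLike | None = None,
    n_real: int,
    base_seed: int,
    max_mc_steps: int = 100_000,
    exclude_k_le: int = 2,
) -> tuple[pd.DataFrame, FitResult]:
    """k_c(N) via the max-tau estimator per system size, plus its power law."""
    from .games import pcg_matrix

    if game is None:
        game = pcg_matrix()
    rows = []
    for idx, N in enumerate(Ns):
        df = degree_scan(
            game,
            rule,
            ks,
            N=N,
            n_real=n_real,
            base_seed=base_seed + 1_000_000 * idx,
            max_mc_steps=max_mc_steps,
        )
        est = estimate_kc_from_tau(df["k"].to_numpy(), df["mean_tau"].to_numpy(), exclude_k_le)
        rows.append({"N": N, "k_c": est.location})
    table = pd.DataFrame(rows)
    fit = fit_power_law(table["N"], table["k_c"])
    return table, fit
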