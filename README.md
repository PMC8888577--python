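# coordgames

Asynchronous evolutionary dynamics of two-player coordination games on
random networks: when does a population of locally interacting agents
reach full coordination, and which equilibrium does it select?

Agents sit on a fixed graph (random regular, Erdős–Rényi, or complete)
and repeatedly play a 2×2 game with their neighbours,

```
        A    B
  A  (  R    S )          normalised coordination game:  ( 1  S )
  B  (  T    P )                                          ( T  0 ),  S < 0, T < 1
```

revising strategies one randomly chosen agent at a time under one of
three update rules:

* **RD** — replicator dynamics / proportional imitation: copy a random
  neighbour with probability proportional to the payoff difference;
* **BR** — myopic best response: pick the strategy maximising the payoff
  against the neighbours' current strategies (ties broken at random);
* **UI** — unconditional imitation: copy the most successful neighbour
  if it is better off.

Observables are the coordination rate α (fraction of A-players), the
interface density ρ (fraction of edges joining unlike strategies) and the
convergence time τ in Monte-Carlo steps (1 MC step = N single-agent
updates), measured until a *frozen configuration* — a state no activation
can ever change. The package provides the game algebra (normalisation to
the (1, S; T, 0) form, the b-parametrisation with T = −1, S = −b−1,
risk/payoff-dominance classification), the graph ensembles, a fast
numba-compiled Monte-Carlo engine with exact frozen-state detection,
ensemble analysis (transition degrees from the maximum of τ, selection
thresholds S_c from the α = ½ crossing, distribution-modality
classification, power-law and logarithmic fits), and the matching
closed-form theory: mean-field best response
∂α/∂t = (k/N)[θ(α + S/(1−S−T)) − α] and the replicator cubic
∂α/∂t = (S+T−1)α³ + (1−2S−T)α² + Sα with fixed points
{0, S/(S+T−1), 1}. Both theories select the risk-dominant strategy
(A iff T < S+1) from α₀ = ½; the interest is in where simulations on
sparse graphs deviate.

Audience: researchers in evolutionary game theory, social dynamics and
statistical physics of networks who need reproducible agent-based
baselines and the accompanying mean-field predictions.

## Worked example

```python
from coordgames import pcg_matrix, GCGParams, random_regular_graph, \
    SimulationConfig, run_simulation, theory
from coordgames.analysis import degree_scan, estimate_kc_from_tau, run_ensemble

# one run of the pure coordination game (two equivalent equilibria)
net = random_regular_graph(1000, 8, seed=0)
rec = run_simulation(net, pcg_matrix(), SimulationConfig(rule="RD", seed=42))
print(f"final alpha = {rec.final_alpha}, tau = {rec.tau} MC steps, frozen = {rec.frozen}")
```

```
final alpha = 0.0, tau = 57 MC steps, frozen = True
```

The population coordinated fully on strategy B after 57 MC steps. A
degree scan locates the coordination transition — the degree where the
mean convergence time peaks:

```python
df = degree_scan(pcg_matrix(), "RD", [3, 4, 5, 6, 8], N=1000, n_real=50, base_seed=7)
print(df[["k", "mean_tau", "mean_alpha_hi", "mean_alpha_lo", "mean_rho"]].round(3))
print("k_c =", estimate_kc_from_tau(df["k"], df["mean_tau"]).location)
```

```
 k  mean_tau  mean_alpha_hi  mean_alpha_lo  mean_rho
 3     52.74          0.573          0.447     0.138
 4    147.68          1.000          0.000     0.000
 5     64.08          1.000          0.000     0.000
 6     45.24          1.000          0.000     0.000
 8     33.90          1.000          0.000     0.000
k_c = 4.0
```

At k = 3 the dynamics freezes in disorder (conditional mean α near ½,
ρ ≈ 0.14); from k = 4 on every realisation coordinates (α ∈ {0, 1},
ρ = 0) and τ is maximal at the transition degree k_c = 4. For the
general coordination game the replicator theory predicts the
risk-dominant equilibrium, but unconditional imitation on a sparse graph
picks the payoff-dominant one:

```python
g = GCGParams(S=-3.0, T=-1.0)           # A payoff-dominant, B risk-dominant
print(theory.predicted_equilibrium(-3.0, -1.0))            # -> 'B'
res = run_ensemble(g, "UI", N=1000, k=8, n_real=20, base_seed=3)
print("UI mean final alpha:", res.alpha.mean())            # -> 1.0
```

Experiment templates (degree scans, phase diagrams, scaling fits) are
also runnable from the shell:

```bash
coordgames list
coordgames run --config my_scan.yml --outdir results --seed 1 --scale 0.2
```

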