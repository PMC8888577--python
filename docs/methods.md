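# Model and methods

## Games

A two-player game is the matrix (R, S; T, P) read from the row player's
perspective; coordination games satisfy R > T, P > S. Two canonical
forms are used throughout:

* the **pure coordination game** (PCG), (1, 0; 0, 1) — two equivalent
  equilibria, kept as a raw matrix (its normalisation would divide by
  R − P = 0);
* the **general coordination game** (GCG), (1, S; T, 0) with S < 0,
  T < 1, obtained from any matrix with R > P by
  S' = (S−P)/(R−P), T' = (T−P)/(R−P). This affine map preserves best
  responses, hence the dynamics. The often-studied matrix (1, 0; −b, 2)
  maps to T = −1, S = −b−1.

Strategy A is payoff dominant in normalised form (coordinating on A pays
1 > 0). A is risk dominant iff its expected payoff against a uniformly
random opponent is larger: (S+1)/2 > T/2, i.e. T < S+1; the line
T = S+1 is reported as an explicit "boundary" label, never silently
resolved, because it is the transition locus of equilibrium selection.
On the T = −1 line the boundary sits at S = −2 (b = 1).

## Networks

Random regular graphs (every degree exactly k, pairing construction with
rejection), Erdős–Rényi G(N, p) with p = k_avg/(N−1) (Bernoulli dialect,
chosen so "same average degree" comparisons are exact in expectation;
isolated nodes are kept — disconnected sparse realisations are part of
the ensemble, not discarded), and complete graphs. Node ids are 0-based
everywhere, including the plain-text edge-list format (`u v` per line,
validated against self-loops and duplicates). Generation is delegated to
networkx and is bit-reproducible per seed.

## Dynamics

State per agent: a pure strategy and a stored **last payoff**. At
initialisation strategies are i.i.d. A/B with probability ½ and every
agent plays one full round, so stored payoffs start consistent (a fixed
artificial initial payoff would change the results; only the full-round
initialisation is implemented).

Time advances by single-agent activations, uniformly at random with
replacement; 1 MC step = N activations, and τ is reported in MC steps.
On activation the focal agent replays its neighbourhood (refreshing its
own stored payoff) and applies the rule:

* **RD**: draw one neighbour uniformly; if the neighbour's stored payoff
  exceeds the focal's refreshed payoff, copy its strategy with
  probability (difference)/φ, where φ = k_max·(max entry − min entry)
  bounds every attainable payoff difference, so the probability is
  always in [0, 1]. A constant matrix (φ = 0) is rejected as degenerate.
* **BR**: compute the two hypothetical payoffs against the current
  neighbour strategies and adopt the better; an exact tie is broken
  uniformly at random. The stored payoff becomes the chosen hypothetical
  payoff. Random tie-breaking is a deliberate design choice: with
  tie-keeping, even-degree populations lock into marginal frozen
  patterns and the even/odd-degree asymmetry of regular graphs
  disappears; the tie noise is what distinguishes even from odd degrees
  (odd degrees admit no ties in the PCG).
* **UI**: if the maximal stored payoff among neighbours strictly exceeds
  the focal's refreshed payoff, copy a uniformly chosen neighbour among
  those attaining the maximum.

**Stale-payoff contract.** Only the focal agent's stored payoff is
refreshed at its activation; neighbours keep whatever they last
computed. UI and RD outcomes depend on this choice, so it is the
documented default; the alternative in which the focal agent's round
also refreshes all neighbour payoffs is available as
`SimulationConfig.refresh_neighbor_payoffs` (it leaves the qualitative
picture unchanged in our scans, but is untested beyond that).

**Frozen configurations.** A state is frozen when no activation can ever
change a strategy: for BR, every agent strictly best-responds (a tie is
not frozen — the random tie-break can flip it); for RD, no
differently-playing neighbour is strictly better off than any agent's
recomputed payoff; for UI, no differently-playing neighbour attains the
strict neighbourhood payoff maximum; for RD and UI additionally every
stored payoff equals its recomputed value, which makes the condition
absorbing (payoff refreshes then change nothing). The engine evaluates
the full check only at MC-step boundaries following a changeless step,
and backdates τ to the boundary after the last observed state change;
because the frozen condition is absorbing and state-only, this yields
the exact first frozen boundary. Runs that reach the configurable cap
(default 10⁵ MC steps) are flagged not-frozen with τ equal to the cap.

**Randomness.** Each realisation derives from one integer seed: a
SeedSequence spawns the initial-strategy stream and a 31-bit seed for
the compiled loop's generator, which draws, in fixed order per
activation, the focal node and then any rule-specific draws (RD
neighbour and coin, BR tie coin, UI tie-break). Runs are bit-reproducible.

## Ensembles and estimators

Ensembles regenerate the graph each realisation (network seed
base_seed + r, independent dynamics seed), so averages include both
graph and dynamics randomness; a switch allows reusing one graph.
Summaries report the mean of α conditioned on α > ½ and α ≤ ½
separately (pooling the two coordinated branches would average to a
meaningless ½), the mean ρ and τ, and the frozen fraction.

* **Transition degree k_c**: argmax over k of the mean τ, excluding
  k ≤ 2 (matchings and chains are trivially slow for topological, not
  collective, reasons); ties resolve to the smaller degree.
* **Selection threshold S_c**: linear interpolation of the α = ½
  crossing of mean final α over an increasing S grid.
* **Modality** of final-α distributions: 21-bin histogram on [0, 1];
  plateau-merged local maxima holding ≥ 5 % of the sample are peaks;
  peaks with centres below 0.2 / above 0.8 are boundary peaks, the rest
  interior. Interior only → unimodal; both boundaries plus interior →
  trimodal; boundaries only → bimodal; anything else → other. The bin
  count, mass threshold and 0.2/0.8 boundaries are this module's
  constructions (distribution shape is otherwise an eyeball judgement).
* **Fits**: ordinary least squares on log–log (power law) or lin–log
  (logarithmic) coordinates; negative quantities (S_c < 0) are fitted in
  magnitude and flagged. |S_c| versus k is the fitted pair for the
  selection-threshold scaling; k_c versus N for the size scaling.

## Theory

Mean-field best response: with well-mixed strategies an agent of degree
k sees αk A-neighbours, so Π_A = k(α − αS + S), Π_B = αkT, A is chosen
when α + S/(1−S−T) > 0, and ∂α/∂t = (k/N)[θ(·) − α] with θ(0) = 0
mirroring the strict inequality (the boundary case is reported
explicitly as a tie). The replicator equation reduces to the cubic
(S+T−1)α³ + (1−2S−T)α² + Sα with stationary points {0, S/(S+T−1), 1};
stability comes from the analytic derivative of the cubic (numerical
flow probing as fallback at a vanishing derivative): boundaries stable,
interior unstable throughout the coordination region. Both theories
therefore select A from α₀ = ½ exactly when T < S+1. A fixed-step RK4
integrator (clipped to [0, 1]) is provided for trajectories.

## Problem sizes

Simulation scales follow the study conditions: N = 1000 agents for the
main scans (500 realisations for PCG degree scans, 100 for GCG scans),
N ∈ {250, 500, 1000, 2000} for size scaling. The shipped analysis
scripts and tests run reduced ensembles (25–500 realisations depending
on the estimator's variance, stated per call) — large enough for the
reported transition degrees and exponents to be stable under reseeding
except where noted below.

## Known limitations

* The UI coordination transition of the PCG lands 2–3 degrees below the
  commonly cited values for this model class (τ-argmax near k ≈ 5–6
  rather than 9 at N = 1000, interface-density maximum near k ≈ 5, side
  peaks of the final-α distribution appearing from k ≈ 7): with the
  exact frozen-state detector, coarsening realisations run until truly
  stuck, which tends to carry them close to (or into) full coordination;
  detectors that stop at long quiescence instead truncate them earlier,
  at more disordered α. The GCG results under UI (selection thresholds,
  their k-scaling, the payoff-dominance window) do not show such an
  offset. Relatedly, rare realisations (~2–3 %) nucleate payoff-dominant
  coordination from an initial high-payoff cluster even on dense graphs
  (k ≈ 100), so "every realisation risk-dominant" plateaus are only
  approached asymptotically.
* Best-response dynamics on random regular graphs keeps frozen
  disordered states at odd degrees with small probability beyond k = 11
  (~0.5 % of realisations at k = 13–15); such states require every agent
  to strictly best-respond inside a balanced bipartition and are
  genuine, just rare.
* The k_c(N) size-scaling exponent for UI is estimated from four
  integer-valued argmax locations and is noisy (0.08–0.20 across seeds
  at 100 realisations per point); the |S_c|(k) exponent is by contrast
  stable (≈ −0.17, R² > 0.97).
* Synchronous update, the Fermi rule, mutation noise, mixed strategies,
  temporal/coevolving networks and asymmetric games are out of scope;
  the ER generator keeps disconnected realisations by design.
* Erdős–Rényi "degree" parameters are ensemble averages; per-graph mean
  degrees fluctuate, which smooths every transition relative to regular
  graphs.
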