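# Methods

## Game and utilities

The iterated ultimatum game runs for `T = 12` trials (configurable). Offers
live on an evenly spaced grid with step 0.1, containing 0.0 and 1.0; the
endowment is fixed at 1. Utilities are threshold-linear,
`u_S = (1 − a_S − η_S)·a_R` and `u_R = (a_S − η_R)·a_R`, and agents maximise
the discounted return `Σ_t u_t γ^(t−1)` with `γ = 0.99`. The study grid uses
sender thresholds η_S ∈ {0.1, 0.5} and receiver thresholds
η_R ∈ {0.0, 0.35}; any dyad with η_S + η_R < 1 is viable. Every agent's
action policy is softmax with a shared, commonly known temperature,
`𝒯 = 0.01` in the low-noise condition and `𝒯 = 1.0` in the high-noise
condition. Trials are 1-indexed in all outputs.

## Reactive (sub-intentional) senders

The random sender draws offers uniformly from the grid and ignores history.
The reactive threshold sender keeps bounds `L, U` (initially 0, 1), updated
mechanically: a rejected offer becomes the new lower bound, an accepted offer
the new upper bound. Its Q-value for a feasible offer is the utility it
would collect if accepted, `1 − a − η_S`, so at low temperature it offers the
smallest feasible amount. Two boundary rules matter and are our choices:

- offers are capped at `1 − η_S` (offers above it have negative utility);
- once any rejection has happened the interval is half-open, `(L, U]` — the
  lower bound is itself a rejected offer and is not repeated. Before the
  first rejection the interval is closed.

Together they produce the characteristic ladder — one grid step up per
rejection, plateau at `1 − η_S` — and a stable plateau under the receiver's
accept-at-the-cap equilibrium. Excluding only the most recently rejected
offer instead would make the steady state oscillate between the cap and the
previously rejected offer, which contradicts the plateau this model family
is meant to produce.

When the empty-set fallback triggers (bounds can cross when a type is
simulated on a counterfactual history), the sender offers the nearest
feasible grid point, keeping every type simulable on every history.

## Belief machinery

Every mentalizing agent maintains a probability vector over a small opponent
type space and updates it by inverting the typed policy: posterior ∝
likelihood × prior, where the likelihood of an action is the probability the
simulated type's softmax policy assigns to it on the realised history.
Likelihoods are floored at ε = 1e−6 per action before the update: at
𝒯 = 0.01 off-policy actions have softmax probabilities far below double
underflow, and the floor turns "impossible" into "highly unlikely", keeping
posteriors proper. Because priors are flat and common knowledge and actions
are fully observed, every belief in the hierarchy is a deterministic
function of the public history — which is what lets higher-DoM agents carry
exact replicas of their partner's beliefs.

Belief convergence onto a type is operationalised as the first trial from
which the posterior mass on that type stays at or above 0.95 through the end
of the run. The threshold is declared in `GameConfig.convergence_threshold`
and reported with all results; runs that never converge are excluded from
mean convergence trials and counted separately.

## Planners

**DoM(0)** plans by exact finite-horizon ExpectiMax over the belief-weighted
reactive-sender dynamics: the value of a response is its immediate utility
plus the discounted expectation, over each believed type's next-offer
distribution, of the best next response, with the belief itself updated
inside the tree. Planner state is immutable and memoised.

**DoM(1)** evaluates each candidate offer by simulating the DoM(0)'s belief
update, its induced response policy (which requires solving the nested
DoM(0) planning problem — memoised and shared), the information the response
carries about the receiver's threshold, and the game that follows. The exact
backend expands this belief tree to the full remaining horizon.

**DoM(2)** inverts the DoM(1) offer policy (alongside the uniform Random
policy) for inference, and plans its responses through the nested DoM(1)
belief dynamics: rejecting an offer shifts the simulated DoM(1)'s belief
toward the high-threshold receiver and raises its future offers.

### Planning noise

Exact Q-values at 𝒯 = 0.01 make intentional-agent policies essentially
deterministic. The Monte-Carlo planning tradition these agents belong to
(POMCP and its interactive extension) instead yields noisy value estimates,
and that imprecision is behaviourally meaningful: it is what makes the
DoM(1)'s random mimicry genuinely dispersed rather than a single fixed
opener. We model it explicitly as a random-utility policy: the agent
softmax-samples from `Q + ε`, `ε ~ N(0, σ_t²)` i.i.d. per action, with

    σ_t = plan_noise · Σ_{k=1}^{T−t} γ^k · (1 − η)

— the noise scales with the discounted length of the lookahead being
estimated (late-game decisions are nearly exact, so the final-trial
exploitation is sharp) and with the agent's own reward scale `1 − η` (return
noise tracks return magnitude). Observers invert the *marginal* policy
`E_ε[softmax((Q + ε)/𝒯)]`, averaged over a fixed set of 256 normal draws so
that beliefs remain deterministic functions of history. `plan_noise = 0.02`
was calibrated once, against the qualitative opening-offer dispersion of the
DoM(1) (mass confined to 0.1–0.4, none on the self-revealing 0.0), before
any downstream quantity was measured; `plan_noise = 0` recovers exact
softmax planning and is what the oracle-equivalence tests exercise. DoM(0)
uses exact ExpectiMax throughout, mirroring the asymmetry between the exact
and Monte-Carlo planner tiers.

### Depth and tractability

Memoisation keys quantise beliefs to `belief_key_decimals` (default 4)
decimals and replace the nested state of any type whose posterior is below
`state_abstraction_tol = 1e−4` by a placeholder; at 𝒯 = 0.01 the belief tree
then collapses after a few trials and exact full-horizon planning is
feasible for DoM(0) and DoM(1). Tests that assert 1e−9 planner-oracle
equivalence use 12-decimal keys and no pruning. Remaining knobs (defaults
chosen as the package's numerical configuration and reported here):

- `branch_tol = 1e−4`: opponent-action branches below this probability are
  pruned and the rest renormalised.
- DoM(2) `plan_depth = 3`: own-response planning uses a receding 3-trial
  horizon — responses are binary and the manipulation payoffs (masquerade →
  higher offers) realise within a few trials, while planning through
  full-horizon nested DoM(1) solves at every tree node is combinatorially
  infeasible.
- DoM(2) `dom1_sim_depth = 2`: lookahead of the DoM(1) models simulated
  *inside* the response-planning tree.
- DoM(2) `dom1_like_depth = 6`: lookahead of the DoM(1) likelihood model
  used for the *actual* belief update against realised offers.
- At 𝒯 ≥ 0.5 softmax branching no longer collapses (every branch survives
  `branch_tol`), so the agent factory switches every planner to a short
  receding horizon (depth 2): under that much decision noise, deep lookahead
  differences are noise-dominated.

## Experiments and reproducibility

`run_game` seeds one RNG stream per agent from `(run seed, role)`, so a
(dyad, seed) pair reproduces the identical game regardless of the partner's
internals. `run_experiment` tabulates per-run summaries (cumulative and
discounted rewards, receiver/sender reward ratio on undiscounted totals, the
scale cumulative-reward comparisons use — undefined and reported as missing when the sender
earned nothing — convergence trials, final beliefs);
`summarize_experiment` averages per dyad, averaging convergence only over
converged runs and reporting the non-converged count. The acceptance script
derives its 20 game seeds from a single base seed.

## What the simulations do and do not show

All data are generated by the simulator itself; there is no empirical input.
The reproduced phenomena — the DoM(0)'s manipulation of reactive senders,
the DoM(1)'s mimic-then-defect deception, the DoM(2)'s counter-deception and
its reward dominance ordering, the over-mentalizing trap against DoM(−1)
senders with its self-confirming beliefs, and the temperature-dependent
attribution contrast (only the DoM(2) reads low-noise randomness as
intention; both receivers explain high-noise behaviour differently, the
DoM(0) keeping the Random label and the DoM(2) preferring a noisy
intentional sender) — are properties of this model family, not of human
data. Quantitatively, one number deviates from the reference behaviour this
family is known for: with a coherent Bayesian inverter whose DoM(1) model
matches the DoM(1)'s actual dispersed policy, the DoM(2) identifies the true
random sender in ~2–3 trials on average rather than ~5; offers outside the
mimicry band are decisive evidence, and only a near-uniform (i.e.
mis-specified) nested DoM(1) model would slow identification further. The
delayed-identification *ordering* (DoM(2) strictly slower than DoM(0)) is
robust across seeds.

Other known limitations: the strict k-level hierarchy is fixed (no mixture
over depths, no adaptive depth); utilities are threshold-linear (no
inequity aversion); the offer grid is discrete with step 0.1; the DoM(2)'s
receding planning horizon can in principle miss manipulations whose payoff
lies more than three trials out.
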