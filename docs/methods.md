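# Methods

## Model

All machinery operates on finite, time-homogeneous Markov chains with a
declared absorbing set. A chain is either

- **discrete-time**: a row-stochastic matrix `q_ij`; absorbing rows are
  identity rows; or
- **continuous-time**: nonnegative off-diagonal rates `ω_ij` (events per
  unit time) with zero diagonal; the generator diagonal is always derived
  as the negative exit rate `a_i = Σ_j ω_ij` and never stored or accepted
  from input — the redundancy invites inconsistency and nothing downstream
  needs it.

Assumptions: time homogeneity, finite state space, and — for every
conditioning workflow — certain absorption from every transient state.
Chains without absorbing states (e.g. the reversible A⇌T⇌B chain) are
valid objects; they become conditionable only through the first-passage
construction below. Reachability of the absorbing set is checked by BFS on
the reversed transition graph and is a validation error once an absorbing
set is declared, because the transform divides by absorption probabilities.

## Absorption probabilities (the h function)

For target set `K` inside the absorbing set, `π_i = P(absorb in K | X₀=i)`
solves the harmonic system

    (I − Q_TT) π_T = Q_TK 1        (discrete)
    (diag(a) − W_TT) π_T = W_TK 1  (continuous)

with boundary values 1 on `K` and 0 on the other absorbing states, solved
densely (LAPACK via `numpy.linalg.solve`). The dense solver is limited to
2,000 states and fails loudly above that; this package targets desk-scale
mechanistic models, not large reaction networks. Target sets are solved in
one system with boundary 1 on the whole set; the test suite independently
checks that this equals the sum of the per-state profiles (a free
partition-of-unity invariant). Solutions within 1e-12 of [0,1] are clipped
to the bounds (float dust); larger excursions raise, since they indicate a
defective system rather than roundoff.

## The conditioned chain

Conditioning on the outcome `K` multiplies each transition by `π_j/π_i`.
The implementation restricts the conditioned chain to the **support**
(states with π > 0): other absorbing states and unreachable-from-the-
outcome transients are dropped, with a log line, rather than kept as
all-zero rows — the transform is undefined there and no selected
trajectory visits them.

Two identities hold by algebra and are *checked, never enforced*
(tolerance 1e-9; violation raises, because it can only come from a
defective π):

- discrete rows over the support sum to 1 (harmonicity of π);
- continuous exit rates are conserved state by state, so the exponential
  sojourn law is invariant under conditioning — the selection bias is
  invisible in dwell-time statistics.

Conditioning on the *entire* absorbing set gives π ≡ 1 and the identity
transform, which the tests use as a degenerate-case anchor.

**De-biasing** is the exact entrywise inverse (`q_ij = q̂_ij·π_i/π_j`) on
the support. The recovered kernel cannot restore mass that flowed to
states outside the support, so its transient rows may undersum; the
round-trip contract is entrywise equality on the support (1e-9), and the
result is deliberately not re-validated as a standalone chain.
Fingerprints (content hashes of the chain) tie profiles to the chains they
were computed from; mismatches raise rather than silently mixing objects.

## First-passage conditioning

"Reach B before returning to A" is reduced to plain outcome conditioning
on an auxiliary chain: A keeps its outgoing rates (it must be left once),
every transition into A is redirected to an absorbing return sink, and B
is made absorbing. Conditioning the auxiliary chain on B is then exact.
The construction is validated against rejection-sampling simulation (keep
only auxiliary trajectories absorbed at B) rather than trusted on its own.
For A⇌T⇌B this yields the closed form ω̂_TB = ω_TA + ω_TB — the apparent
rate always exceeds the true one, by exactly the rate of the discarded
escape channel — with the unbiased limit ω̂_TB → ω_TB as ω_TA → 0.

## Simulation and selection

Discrete trajectories iterate categorical draws (row-cumulative inverse
transform); continuous trajectories draw an exponential sojourn with the
state's exit rate and jump proportionally to the outgoing rates. Cumulative
rows are rescaled so the final entry is exactly 1, making an out-of-range
draw impossible regardless of 1e-9-level row-sum slack.

- **Start rule.** Ensembles for the walk demos start uniformly over the
  transient states. The estimators are Markov and therefore
  start-rule-agnostic; the choice affects only the variance profile across
  positions.
- **Censoring.** The default step cap is 50·n², the diffusive absorption
  scale, under which the fair walk censors ≪ 1% of trajectories. Censored
  trajectories are kept in the ensemble and marked; `select_by_outcome`
  drops them with a warning, because silently truncating them would itself
  be an outcome selection — the exact fallacy the package is about.
- **Seeding.** One `SeedSequence` per ensemble, spawned into per-trajectory
  child streams, so ensembles are bit-reproducible and independent of
  simulation order.

## Estimators

Discrete: `q̂_ij = N_{i→j}/N_i` with binomial SE; continuous:
`ω̂_ij = N_{i→j}/T_i` (occupation-time MLE) with Poisson SE `√N/T`. `N_i`
counts visits with an *observed successor*: the final visit of a trajectory
contributes neither a transition nor (in continuous time) occupation time,
so rates always pair completed sojourns with observed exits. Unvisited
states are reported as missing, never zero — zero would fabricate
certainty. Bias reports attach z-scores `(estimate − prediction)/SE`; with
a degenerate SE of 0 the z is 0 on exact agreement and infinite otherwise
(e.g. scoring an estimate that is exactly 1 against a prediction of 0.5).
No continuity corrections are applied; at the 10⁴–10⁵ trajectory scale of
the demos they are negligible against the 3–4 SE decision bands.

## Synthetic world and what green tests establish

There are no external datasets; everything is generated. The walk demo
defaults (15 intermediate positions, p = 0.5, 10⁵ trajectories) and the
A⇌T⇌B demo (10⁴ trajectories) are sized so that 3-SE bands separate the
biased and unbiased hypotheses decisively. The random-chain generators in
`condchain.testing` produce generic dense-ish chains with guaranteed
absorption reachability; they exercise the algebraic identities (row
normalization, exit-rate conservation, mixture recomposition) far from the
hand-built examples. They do not emulate features of real trajectory data
— aggregated or hidden states, measurement noise, time discretization of
continuous records, non-Markov memory — so a green suite establishes the
conditioning algebra and the estimator contracts, not robustness to those
effects.

## Numerical choices

- Row-stochasticity tolerance 1e-9; rows within it are renormalized
  exactly on file load (logged). Identity checks on conditioned chains use
  the same 1e-9.
- Dense solves only; no sparse/iterative path.
- Stochastic tests pin seeds (chosen once, not tuned) and use 3-SE bands
  per comparison, 4-SE for max-over-many-pairs statistics.
- Tie-breaks: states with π exactly 0 are dropped from the support; the
  comparison layer skips estimate pairs outside the predicted support with
  a logged count.

## Known limitations

- Time-inhomogeneous chains, countable state spaces and semi-Markov
  processes are out of scope, as are expected absorption times and
  quasi-stationary laws.
- Steady-state conditioning (outcome states revisitable before stopping)
  is not implemented; only absorbing-outcome selection is.
- The CLI `select`/`estimate` commands need the chain spec alongside the
  trajectory TSV, since the TSV alone cannot distinguish absorbed from
  censored endings.
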