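# Methods

## Model formalism

A model consists of named populations with non-negative integer counts,
plus reactions.  A reaction `c₁A₁ + … -> d₁B₁ + …` fires at propensity
`rate(t) · Π_i N_i(N_i−1)…(N_i−c_i+1)` — the rate is **per ordered
reactant configuration** (falling factorial), so `2A -> A` with rate λ
fires at total rate λN(N−1), not λN(N−1)/2.  This convention matters for
multi-copy reactants and is the one used throughout, including in the
density-dependent death reaction of the logistic fixture.

Rates are piecewise constant: a vector `values` with `changeTimes`
(`len(values) − 1` of them, strictly increasing).  The function is
right-continuous — at a change time the *new* value already applies, so
`rate="0 1" changeTimes="5"` is zero strictly before t = 5 and one from
t = 5 on.

Punctual reactions have exactly one reactant individual and fire at listed
times, either applying the rule independently with probability p to every
individual present (multiplicity ~ Binomial(N, p)) or to exactly n
individuals drawn without replacement (a hard error if n > N).
Multi-individual reactant configurations for punctual reactions are
rejected at validation: their semantics (what "probability p per
reactant" would mean for pairs) are not well defined.

**Parentage.**  Each product instance records which reactant instance it
descends from; a product matching a reactant's population is the same
individual continuing.  The default rule matches products to same-population
reactants in declaration order and assigns every remaining product —
including samples — to the *first* reactant.  For transmission written as
`I + S -> I + E` this makes the infector I the parent of the new E, the
transmission-tree convention.  The rule is a deliberate design choice (no
single convention is universal) and can be overridden per reaction with an
explicit `parentage` list in the configuration; products of spontaneous
sources (`0 -> A`) are parentless and start new root lineages.

Sample populations are inert: they never appear as reactants, start at
count zero, and every individual placed there becomes one leaf, labelled
`<population>_<ordinal>` in forward order of creation.

## Forward simulation

Gillespie's direct method with scheduled boundaries: waiting times are
drawn from the total propensity; a draw crossing the next boundary (rate
change or punctual time) is discarded and redrawn from the boundary, which
is exact because rates are constant within intervals.  At a boundary the
new rate applies first, then punctual reactions fire in declaration order
— a fixed, documented ordering for coincident events.  Simulation stops at
`t_end`, or earlier when total propensity is zero and no punctual times
remain.  Every firing is logged (punctual firings as one event with a
multiplicity), which makes the trajectory exactly replayable in either
direction.  A trajectory-acceptance condition (default: at least one
sample, at most 10,000 retries, both configurable) makes downstream tree
reconstruction well defined.

## Backward tree reconstruction

The reconstructed tree is drawn conditional on the trajectory by one
reverse sweep over the event log, maintaining per population the set of
sample-ancestral lineages (k) and the population size (N, replayed by
reversing event deltas).  Within a population, individuals are
exchangeable, so the k ancestral lineages are a uniform random subset of
the N individuals.  For each event (punctual multiplicities are processed
one individual at a time, with N and k updated between individuals):

1. Each *product* individual in population j is ancestral with probability
   k_j/N_j, drawn sequentially without replacement within the event
   (second product: (k_j−1)/(N_j−1) or k_j/(N_j−1), and so on); an
   ancestral product claims a uniformly chosen lineage.  Sample products
   always create a leaf.
2. All claimed lineages and new leaves that share a parent reactant merge
   at the event time into a single lineage of the parent's population:
   two or more items form a coalescence node; a leaf plus a claimed
   lineage forms a sampled-ancestor attachment; a lone leaf from a
   removing sample re-enters the source population as a new lineage; a
   lone claimed lineage of a different population records a type change
   (degree-one node); a lone continuation just persists.

These per-case probabilities reduce to k(k−1)/(N(N−1)) for a
within-population birth being a coalescence, and k/N for transmission
seeding and sampled-ancestor attachment — forced by exchangeability.
k ≤ N is asserted at every step of the sweep (a violation would be an
internal bookkeeping bug).  Lineages remaining at the initial time are
returned as a forest; no artificial root edge is added.  Degree-one
type-change nodes are kept internally and suppressed (branch lengths
merged) on output unless typed output is requested, since most downstream
tools reject unary nodes.

The approach is validated distributionally: an independent oracle
(`reactree.oracles`) simulates the *full* genealogy of every individual —
with its own event dispatch and uniform reactant choice — prunes it to the
sample-ancestral tree, and two-sample KS tests compare tree height, total
branch length, leaf count, and sampled-ancestor count on three model
families (Yule with punctual complete sampling; linear birth–death with
serial non-removing sampling; a two-type migration model).

## Coalescent engine

Lineage types with pair-merging reactions `2L -> L` and backward-time
migrations `La -> Lb`.  Per-pair rates come from a population function:

- constant Ne; exponential `N(t) = N₀ e^{r(t − t_ref)}`; piecewise
  constant (same right-continuous convention as rate vectors);
- mean-field trajectory of a reaction model: the rate equations use
  mass-action kinetics (`rate · Π N^c`; for the logistic fixture this
  puts the fixed point exactly at K), solved with an adaptive explicit
  Runge–Kutta method (rtol = atol = 1e−9) and sampled on a dense grid
  (default 1001 points) for linear interpolation.  With `bd_approx` the
  per-pair rate is `2 b(t)/N(t)²`, b(t) the mean-field flux of birth
  reactions creating net new individuals of the focal population; without
  it, N(t) acts directly as an effective size.  Below the trajectory's
  start both functions extend flat, so deep lineages keep coalescing at
  the initial rate rather than erroring out.

Event times are drawn by time rescaling: an Exp(1) deviate is inverted
through the cumulative intensity Λ, scanned segment by segment between
rate breakpoints.  Segments where the total intensity is constant invert
analytically; others use bracketed Brent root-finding (relative tolerance
1e−10) on the analytic or Gauss–Legendre-integrated Λ.  Scheduled leaf
times cap every draw; exhausting Λ with more than one lineage and no
leaves remaining raises a non-coalescence error.  All node times are
forward times anchored by the model-specified leaf times.

## Synthetic study conditions

No external data exist for this package: every validation input is
generated by the package itself under fixed, documented conditions.

- SEIR fixture: S₀ = 99, I₀ = 1, transmission 0.1, progression 1.0,
  removal 0.5, serial sampling rate 0→1 switching at t = 5, punctual
  p = 0.1 at t = 5 and 10, horizon 10.  The compartment sizes are chosen
  so a typical outbreak infects most of the population within the horizon
  and yields tens of samples.
- Validation models: immigration–death ν = μ = 1 (master-equation
  comparison at t = 2); linear birth–death λ = 2, μ = 1 (ensemble mean
  vs N₀e^{(λ−μ)t}); Yule λ = 1 with complete punctual sampling at t = 2;
  birth–death λ = 2, μ = 1, serial non-removing sampling ψ = 0.5 to
  t = 2; a symmetric two-type model (birth 1.5, migration 0.5, death 0.5,
  removal-sampling 0.4 per type, t = 2.5).
- Logistic fixture: birth `X -> 2X` at λ, crowding death `2X -> X` at
  λ/K per ordered pair; the stochastic stationary mean equals K to
  numerical precision (checked against the master equation) and the
  mass-action mean-field fixed point is exactly K.

The birth–death coalescent-approximation consistency check runs the
logistic model at carrying capacity (K = 50, λ = 1, 8 leaves sampled at
t = 120) and compares mean pairwise coalescence times between exact
reconstructed trees and the approximation.  Pairs are compared
conditionally on coalescing within the simulated window on *both* routes
(exact trees cannot coalesce past the trajectory start; the approximation
is truncated identically), keeping the two estimators exchangeable.
Replicate counts (1,500 exact trajectories, 6,000 coalescent trees) were
sized so the Monte Carlo standard error of the ratio (~1.4%) is well
inside the 5% agreement band.  A residual ~2% discrepancy is expected
from demographic stochasticity: the exact pair rate averages
2λ·E[1/N] ≈ (2λ/K)(1 + 1/K), while the mean-field approximation uses
2λ/K.

These synthetic conditions exercise small populations and short horizons;
they do not probe very large state spaces, strongly multimodal outbreak
sizes, or extreme rate ratios, so passing tests demonstrate correctness of
the algorithms rather than performance or robustness at scale.

## Numerical and design choices

- RNG: one numpy PCG64 generator threaded through a replicate (trajectory
  then tree); replicate r of a job uses `SeedSequence((seed, r))`, so a
  job seed fixes every output byte.
- Ties: punctual reactions sharing a time fire in declaration order after
  any coincident rate change takes effect.
- Zero-multiplicity punctual firings are logged (multiplicity 0) and are
  no-ops in replay and reconstruction.
- Branch lengths are differences of stored node times; a computed
  negative length beyond 1e−12 is an error, and exact-zero branches are
  the sampled-ancestor convention.
- Master-equation oracle: dense generator matrix on states 0..cap,
  `expm`; truncation mass loss above 1e−6 is an error.
- The full-tree oracle guards at 10⁵ events; it is a validation device
  for small models, not a simulation route.

## Known limitations

- Tau-leaping or other approximate SSA variants are not provided; very
  large populations cost proportionally many events (use the coalescent
  approximation there).
- Expression-valued rates are out of scope: rates are piecewise-constant
  numeric vectors.
- Coalescent simulations condition on the mean-field trajectory, not on
  individual stochastic realisations; the O(1/K) discrepancy above is
  inherent to that choice.
- Punctual reactions are restricted to single-individual reactant sides.
- The config dialect is deliberately small (YAML with verbatim `rate`,
  `changeTimes`, `p`, `times` fields); no external XML dialects are read
  or written.
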