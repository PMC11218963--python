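# Model and methods

This note documents the model assumptions, the algorithms and their
numerical choices, what the synthetic experiments do and do not emulate,
and the design decisions taken where the design was genuinely open.

## The decision model

Agents face a two-state POMDP: hands are *clean* or *dirty* (hidden), and
at every trial the agent cooks, washes, or checks. Nine parameters define
a scenario:

| parameter | support | meaning |
|---|---|---|
| `p_soiling` | [0, 1] | probability that cooking soils clean hands |
| `p_success` | [0, 1] | probability that washing cleans dirty hands |
| `p_detect_dirty` | [0.5, 1] | P(observe "dirty" when checking dirty hands) |
| `p_detect_clean` | [0.5, 1] | P(observe "clean" when checking clean hands) |
| `reward_dinner` | fixed 0 | utility of cooking with clean hands |
| `cost_sickness` | (−1, 0] | utility of cooking with dirty hands |
| `cost_wash` | (−1, 0] | utility of washing (state-independent) |
| `cost_check` | (−1, 0] | utility of checking (state-independent) |
| `gamma` | [0, 1) | temporal discount (planning horizon) |

Observation reliabilities live on [0.5, 1] because state inference is
symmetric around chance. Since an optimal policy is invariant under
positive affine transformations of the reward function, the four outcome
parameters are overcomplete; we fix the single positive outcome to 0 and
normalize the three costs to sum to −1, so the absolute costs form a point
on the unit 2-simplex and every affine-inequivalent reward function
corresponds to exactly one such point. The normalizing map divides each
reward-relative cost by the summed reward-relative costs; with a zero
baseline this reduces to dividing by the plain cost sum.

Every parameter exists in two copies: **world parameters** generate the
actual states, observations and rewards, while **agent parameters**
(subjective point beliefs, static over an agent's lifetime — there is no
within-lifetime learning) determine the agent's policy and its Bayesian
belief update. The belief is the scalar b = P(dirty). After action a and
observation o, the posterior is the transition-propagated prior reweighted
by the subjective observation likelihood; for cook and wash the observation
is uninformative (0.5/0.5) so the update is pure prediction, and for check
the state is static so the update is purely observational. Updated beliefs
are clamped into [0, 1] with a 1e-12 tolerance to absorb rounding.

## Solver

The optimal infinite-horizon policy is computed by exact value iteration on
the belief interval. Every candidate value function is a finite set of
lines ("alpha-vectors") over [0, 1]; a Bellman backup maps the upper
envelope of that set through each action: cook and wash have uninformative
observations, so their backup contributes one line per surviving envelope
piece, while check contributes the Minkowski-sum envelope of the two
observation-conditioned back-projections. The pointwise maximum of a
cross-sum factorizes, so building the sum from the two component envelopes
is exact.

Numerical choices:

* **Stopping rule.** Iteration stops when the sup-norm Bellman residual
  falls below tol·(1−γ)/(2γ) with tol = 1e-5 on the normalized reward
  scale, the standard bound placing the value estimate within tol/2 of the
  fixed point. γ = 0 converges after one backup. `max_iter` = 20,000
  (binding only for γ within ~1e-3 of 1); non-convergence is flagged on
  the returned policy and treated as a rejection by the samplers, never
  silently accepted.
* **Envelope simplification.** The exact value function acquires new
  facets at every backup and its piece count grows without bound, so after
  pruning, facets that improve the envelope by ≤ tol·(1−γ)/64 are removed
  (greedy neighbor-gap passes; the two extreme-slope lines are always
  kept). The accumulated value error stays an order of magnitude below the
  stopping accuracy, and the residual floor induced by facet removal stays
  safely below the stopping threshold. Dominance comparisons use a 1e-12
  tolerance.
* **Tie-breaking.** At exact value ties — including queries landing
  exactly on a segment boundary — the fixed action order cook < wash <
  check wins. Ties are measure-zero under continuous parameter sampling;
  the fixed order makes runs bit-reproducible.
* **Discount cap.** Sampled discounts are capped at 0.999 before solving;
  an undiscounted infinite-horizon problem is ill-posed.
* **Screened solving.** Where a required action must be available (world
  acceptance, Simulation 1 stratification), scenarios are first solved at
  a coarse tolerance (1e-2); an action whose backed-up value stays below
  the value envelope by more than that tolerance everywhere on the simplex
  is provably never greedy under the exact optimum, and such candidates
  are rejected without a full-precision solve. Survivors resume value
  iteration from the coarse solution (a warm start changes nothing about
  the stopping guarantee). This is a pure optimization: it never changes
  which candidates are accepted.

The hot loops (envelope sweep, facet simplification, the full backup
cycle, and the trial-by-trial simulation kernel) are JIT-compiled with
numba. Reference implementations of the backup and pruning remain in pure
numpy and back the public API; solver correctness is tested against a
depth-1 expectimax, a finite-horizon dynamic program on a dense belief
grid, Monte-Carlo policy evaluation, and an affine-invariance property.

## Simulation

An agent's behavior is simulated as independent sequences (trials t = 1…N)
in which the action comes from the agent's policy at its current belief,
the next state/observation/reward come from the world tables, and the
belief update uses the agent tables. Initial conditions per sequence:
b₀ ~ Uniform[0, 1] and s₀ ~ Bernoulli(b₀), so the starting belief is
calibrated (an independent fair-coin initial state is available as a
configuration option). Seeding is hierarchical — master seed → world →
agent → sequence, all integer-indexed — so any sequence can be replayed in
isolation and identical seeds give byte-identical outputs.

A **compulsive episode** is a maximal run of non-cook actions containing
at least two washes or at least two checks. Runs truncated by a sequence
boundary qualify if the count criterion holds (the criterion is about
observed repetition, not completion). Episode *duration* counts all
non-cook actions in the qualifying run. Per-agent metrics pool all of an
agent's sequences: episode counts and durations, the percentage of actions
inside episodes, the mean absolute post-wash belief change, the empirical
3×3 action-transition matrix, and the mean belief in clean hands held at
each action. Metrics whose defining events never occur are NaN, never
zero. Group-level values average agent-level means (two-stage averaging).

**Compulsion type.** Agents are typed by which action they *immediately
re-execute* across all episodes: only wash→wash repetitions → pure
washing; only check→check → pure checking; both — or episodes that qualify
only through non-adjacent repetitions such as check–wash–check — → mixed.
The alternative reading (an agent is a pure washer only if no episode
contains any check at all) collapses at realistic sequence lengths: over
25,000 actions virtually every compulsive agent that checks at all
eventually has a check inside some episode, making "pure washing" an
empty category in the all-actions-required design. The adjacency
definition is the reading under which the two designs' type distributions
(overwhelmingly pure washing when checking is not required; a minority of
pure washers when it is) are simultaneously reproducible, but the
all-actions-required share remains the quantity most sensitive to this
genuinely open definitional choice.

## Sampling and experiments

**Worlds.** Parameters are sampled uniformly over their full supports;
costs come from a flat Dirichlet on the 2-simplex, so all
affine-inequivalent reward functions are equally likely. A world enters
the bank only if a veridical agent simulated in it (same sizes as the
experiment) uses all three actions and produces zero compulsive episodes —
environments where repetitive washing/checking would be rational are
excluded, making compulsions attributable to false beliefs. Acceptance is
a rare event (roughly 1–2 per thousand candidates at desk sizes): most
random worlds either never make checking worthwhile or make even truthful
agents repeat actions.

**Simulation 1 (full distortions).** Candidate agents draw all nine
subjective parameters independently by the world scheme, so beliefs span
exactly the true supports. Per world, candidates are simulated until fixed
quotas of compulsive (≥1 episode anywhere) and non-compulsive agents are
collected; variant 1A additionally requires each retained agent's pooled
sequences to contain all three actions, variant 1B requires only cook and
wash. The quota filter is a strong selection device: it compresses the
spread of belief distortions that are incompatible with inclusion (e.g.
subjective check costs, where agents who consider checking overpriced
never check and drop out of 1A), which is visible in the group summaries.

**Simulation 2 (selective distortions).** Agents are veridical except one
parameter resampled over its full support (washing success, threat
magnitude, or threat probability), spread evenly over the bank, all agents
kept. Distorting a single cost breaks the −1 normalization; the distorted
cost is substituted at its raw value and the triple renormalized, which
preserves the untouched costs' ratio and (by affine invariance) is
behaviorally identical to using the unnormalized triple. The untouched
costs' relative weight therefore stays bounded away from zero — an extreme
threat distortion makes washing and checking relatively cheaper but never
free. One consequence of renormalization is that the *recorded* cost
distortions live on the normalized scale, so the threat-magnitude
distortion axis is asymmetric rather than spanning exactly [−1, 1].

**Statistics.** Simulated samples are large enough to make conventional
p-values meaningless, so all tests are bootstrapped: 10,000 (desk: 2,000)
repetitions each draw a small subsample without replacement (20 for
one-sample tests, 20 + 20 for two-sample, 40 for correlations), apply the
standard test, and average the statistics and p-values (medians for the
non-parametric branch). Normality is screened by a bootstrapped
Shapiro–Wilk (median p vs 0.05, capped at 500 repetitions — the gate is a
screen, not an estimate); failures route to Wilcoxon/Mann–Whitney tests.
Cohen's d uses the pooled SD per repetition and is averaged; the
full-sample d is reported alongside since either convention is defensible.
Correlations are Spearman with the usual t-approximation p-value. No
multiple-testing correction is applied; raw p-values are reported.
Zero-variance subsamples are skipped and counted.

## Scales

Two presets bundle the experiment sizes. The `paper` preset is the
full-scale design: 100 accepted worlds, 50 + 50 agents per world, 200
sequences × 1,000 actions, 10,000 bootstrap repetitions. The `desk` preset
(20 worlds, 20 + 20 agents, 50 × 500, 2,000 repetitions) is the default
for tests and for `scripts/acceptance.py`; it preserves all effect
directions and magnitudes at minutes-scale runtime on a single CPU. One
systematic scale sensitivity is worth knowing: world acceptance at desk
sizes screens candidates with 25,000 veridical actions instead of 200,000,
so occasional *marginal* worlds pass — typically worlds with near-chance
observation reliabilities in which small threat distortions create very
long checking runs. These inflate mean (not median) episode durations in
the threat-magnitude experiment; the full-scale screen rejects such worlds
because a weak-observation descent through the checking region forces
consecutive checks somewhere in 200,000 steps.

## What the generator does and does not emulate

All inputs are synthetic by design — the study object is the model itself,
not data from human participants. The generator reproduces the study
conditions: uniform world sampling with rejection filtering, independent
subjective-belief sampling, quota-stratified group collection, and the
episode definition above. It does not model obsessions, distress,
physiological variables, within-lifetime learning, or more than two
states/three actions; passing tests therefore demonstrate properties of
the normative-agent model under these conditions, not clinical claims
about patients.

## Known limitations

* The value function is represented to a finite accuracy (tol = 1e-5);
  greedy boundaries can shift by amounts of that order, which is
  irrelevant for the group statistics but means policies from an external
  exact solver may differ microscopically. The `.pomdp` exporter exists
  for exactly this cross-validation.
* Compulsion-type shares in the all-actions-required design depend
  strongly on the typing definition (see above); treat the pure-washing
  share there as a definition-sensitive quantity.
* At discounts within ~1e-3 of the 0.999 cap, solves take up to a few
  seconds and dominate pipeline runtime; the iteration cap can in
  principle be reached, in which case the candidate is rejected and
  counted, never silently used.
* Bootstrapped p-values inherit the arbitrariness of the subsample sizes
  (n = 20/40); they are comparable across analyses in this package but not
  to conventionally computed p-values.
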