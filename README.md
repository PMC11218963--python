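# compulsim

Simulation and analysis toolkit for studying how **false beliefs produce
compulsive safety behavior** in normative decision-making agents.

Compulsions — repetitive washing or checking that an outside observer would
call irrational — are modeled here as the *optimal* behavior of an agent
that plans perfectly under *distorted beliefs* about its environment. The
package lets you generate environments, endow agents with belief
distortions, simulate their behavior, detect compulsive episodes, and run
the bootstrapped group statistics that identify which distortions drive
compulsions.

## The model

The environment is a two-state, three-action, two-observation POMDP
(a partially observable Markov decision process): hands are hidden in state
*s* ∈ {clean, dirty}; the agent chooses *a* ∈ {cook, wash, check}.

* **cook** yields `reward_DINNER` when clean and `cost_SICKNESS` when
  dirty, and soils clean hands with probability `p_SOILING`;
* **wash** costs `cost_WASH` and cleans dirty hands with probability
  `p_SUCCESS`;
* **check** costs `cost_CHECK`, never changes the state, and yields an
  observation that matches the state with probability `p_DETECT_CLEAN` /
  `p_DETECT_DIRTY` (cook and wash observations are at chance).

The agent cannot see *s*; it carries a scalar belief *b* = P(dirty) on the
1-simplex, updated by Bayes' rule after every action, and follows the
policy π\*(b) maximizing the expected discounted return
Σₜ γᵗ E[R(π(bₜ), sₜ) | bₜ]. Because a policy is invariant under positive
affine reward transformations, outcomes live on a normalized scale:
`reward_DINNER = 0` and `cost_WASH + cost_CHECK + cost_SICKNESS = −1`, so
the absolute costs form a point on the unit 2-simplex.

The crucial construction is the **duplication of all nine parameters**
(transitions, observation reliabilities, outcomes, discount γ) into *world
parameters* (the true contingencies, which generate states, observations
and rewards) and *agent parameters* (subjective beliefs about them, primed
in the notation, which determine the policy and the belief update). Their
difference, Δparams = agent − world, is the agent's belief-distortion
vector — e.g. Δp_SUCCESS < 0 is distrust in the effectiveness of washing.

A **compulsive episode** is a maximal run of non-cook actions containing at
least two washes or at least two checks (cook–check–wash–check–cook
qualifies; cook–wash–check–cook does not).

The solver is exact value iteration on the 1-D belief simplex: alpha-vector
(line) backups with upper-envelope pruning, which for a two-state problem
is fast and deterministic. Policies can also be exported in Cassandra's
`.pomdp` text format for cross-validation with classic POMDP solvers.

## A worked example

```python
import numpy as np
from compulsim import (ScenarioParams, build_tables, solve, SimConfig,
                       run_sequences, compute_metrics, delta_params)

# an environment in which truthful behavior is compulsion-free
world = ScenarioParams(
    p_soiling=0.2, p_success=0.95, p_detect_dirty=0.9, p_detect_clean=0.9,
    cost_sickness=-0.5, cost_wash=-0.3, cost_check=-0.2, gamma=0.8,
)
# an agent that underestimates how well washing works
agent = world.with_(p_success=0.7)
print(round(delta_params(agent, world).d_p_success, 3))   # -0.25

policy = solve(agent)                                # subjectively optimal policy
traces = run_sequences(
    policy, build_tables(agent), build_tables(world),
    SimConfig(n_sequences=50, n_actions=500),
    [np.random.default_rng(k) for k in range(50)],
)
m = compute_metrics(traces)
print(m.is_compulsive)                               # True
print(round(m.pct_actions_compulsive, 1))            # 36.3
print(round(m.belief_update_after_wash, 3))          # 0.622
print(m.compulsion_type)                             # pure_check
```

The veridical agent (`agent = world`) in this environment shows no
compulsive episodes and updates its belief by 0.76 on average after a wash.
Merely lowering the *subjective* washing effectiveness from 0.95 to 0.7 —
the environment itself is unchanged — turns a third of the agent's actions
into compulsive repetition (here repeated checking before it dares to cook)
and slows its post-wash belief updates to 0.62.

## Experiment pipeline

The full study design is scripted behind a CLI (`compulsim --help`):

```bash
compulsim sample-worlds --n 20 --seed 0 --out worlds.csv   # accepted environments
compulsim run --sim 1A --scale desk --seed 0 --out out/    # stratified agents
compulsim analyze --dataset out/sim1A_agents.csv --out out/analysis/
compulsim reproduce --scale desk --seed 0                  # headline numbers
```

*Worlds* are drawn uniformly over the full parameter supports and accepted
only if a truthful agent in them uses all three actions and never produces
a compulsive episode — so any compulsion observed later is attributable to
false beliefs. *Simulation 1A/1B* then collects fixed quotas of compulsive
and non-compulsive agents per world, with all nine subjective parameters
resampled independently (1A additionally requires every agent to check at
least once; 1B drops that requirement). *Simulations 2A/2B/2C* distort a
single belief (washing success, threat magnitude, threat probability) and
trace severity against the distortion. Statistics use the bootstrapped
subsampling scheme (n = 20 per group, t/U tests gated by Shapiro–Wilk,
statistics averaged over repetitions) that keeps p-values meaningful at
simulated sample sizes.

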