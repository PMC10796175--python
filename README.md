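# reactree

Reaction-based phylodynamic simulation: stochastic population trajectories
and the phylogenetic trees of their sampled individuals.

Phylodynamic models tie phylogenies to population processes — transmission
and removal in epidemics, speciation and extinction in macroevolution,
effective population sizes and migration in phylogeography.  Testing
inference methods, running misspecification studies, and checking model
adequacy all need simulated trees and trajectories from these models.
`reactree` lets you write any such model as a set of chemical-kinetics-style
**reactions** over named populations, with *sampling itself expressed as a
reaction* that places individuals into specially marked sample populations:

```
I + S -> I + E          (transmission, rate 0.1 per pair)
E -> I                  (becoming infectious, rate 1.0)
I -> R                  (removal, rate 0.5)
I -> I + sample         (serial sampling, rate "0 1", changeTimes "5")
I -> sample             (punctual sampling, p = 0.1 at times 5 and 10)
```

Rates are per reactant configuration and piecewise-constant in time;
punctual reactions fire at fixed times, with probability *p* per individual
or an exact count *n*.

## The algorithm

For birth–death-type models the simulator proceeds in two exact stages:

1. **Forward**: Gillespie's stochastic simulation algorithm generates a
   complete event log of the population trajectory (waiting times redrawn at
   rate-change and punctual boundaries, which is exact for
   piecewise-constant rates).
2. **Backward**: the reconstructed phylogeny — the tree ancestral to the
   samples only — is simulated by a single reverse sweep over that event
   log.  Per population the sweep tracks the number of sample-ancestral
   lineages k alongside the replayed population size N.  Individuals within
   a population are exchangeable, so a birth event among N individuals
   involves an ancestral pair with probability k(k−1)/(N(N−1)) (a
   coalescence), a transmission seeds an ancestral lineage into the source
   population with probability k/N, and a non-removed sampled individual is
   already ancestral with probability k/N (a **sampled ancestor**, written
   as a zero-length leaf branch).

The full genealogy of unobserved individuals is never built, so the cost is
proportional to the number of events, not the number of lineages ever alive
— while the output tree distribution is identical to
simulate-everything-then-prune (which `reactree.oracles` implements
independently, and the test suite compares against).

Coalescent models are simulated directly backward in time: pair-merging
reactions `2L -> L` driven by constant, exponential, piecewise-constant, or
mean-field-trajectory population functions (per-pair rate 1/Ne(t), or
2b(t)/N(t)² for coalescent approximations to birth–death processes), plus
migration reactions `La -> Lb`, with waiting times drawn exactly by
inverting the cumulative intensity.

## Worked example

```sh
reactree simulate examples/configs/yule_complete_sampling.yaml \
    --seed 1 --out-trees yule.nexus --out-traj yule.tsv
```

writes five NEXUS trees and a trajectory table.  From Python, the packaged
SEIR model (rates 0.1 / 1.0 / 0.5, serial sampling switched on at t = 5,
punctual sampling p = 0.1 at t = 5 and 10):

```python
import importlib.resources as res
import reactree as rt
from reactree.config import load_config
from reactree.jobs import run_job

with res.as_file(res.files("reactree") / "fixtures" / "seir.yaml") as p:
    job = load_config(p)
result = run_job(job, out_trees="seir_trees.nexus",
                 out_trajectory="seir_trajectories.tsv")
for rep, (root,) in enumerate(result.forests):
    print(rep, rt.leaf_count(root), rt.sampled_ancestor_count(root),
          round(rt.tree_height(root), 2))
```

prints (seed 1, three replicates):

```
0 54 33 9.46
1 52 25 8.53
2 74 52 9.72
```

i.e. replicate 0 produced 54 sampled leaves of which 33 are sampled
ancestors (sampled but with sampled descendants), spanning 9.46 time units
from the root of the sampled outbreak to the last sample.  Rerunning with
the same seed reproduces these files byte for byte.

More narrative scripts live in `examples/`: coalescent population models,
the birth–death coalescent approximation, and a timing/exactness comparison
against the full-simulate-and-prune route.

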