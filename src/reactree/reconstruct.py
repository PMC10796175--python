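"""Reconstructed-phylogeny simulation conditional on a trajectory.

Rather than simulating the full genealogy of every individual and pruning
it down to the sampled tips, the sampled tree is drawn directly by a single
backward sweep over the trajectory's event log.  The sweep maintains, per
population, the set of lineages ancestral to samples (k) alongside the
population size (N, replayed backward from the event deltas).  Individuals
within a population are exchangeable, so each event's product individuals
are a uniform draw from the post-event population: a product is ancestral
with probability k/N (sequentially, without replacement, within an event),
and ancestral products sharing a parent reactant merge at the event time.
This yields the reconstructed tree exactly, at a cost proportional to the
number of events rather than the number of individuals ever alive.

Event cases that fall out of the one generic rule:

* removing sample (``I -> sample``): a leaf enters population I as a new
  ancestral lineage;
* non-removing sample (``I -> I + sample``): with probability k/N the leaf
  attaches to an existing lineage as a sampled ancestor;
* within-population birth (``A -> 2A``): both products ancestral with
  probability k(k-1)/(N(N-1)) — a coalescence;
* cross-population birth (transmission ``I + S -> I + E``): an ancestral E
  product either coalesces with an ancestral I lineage or changes type;
* pure conversion (``E -> I``): an ancestral product changes type;
* deaths and events touching no ancestral individual leave the tree alone.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .model import Model, PunctualReaction, Reaction
from .trajectory import Trajectory
from .treeio import TreeNode

__all__ = ["reconstruct_tree", "LineageState", "sample_labels"]


class _Lineage:
    __slots__ = ("node", "pop")

    def __init__(self, node: TreeNode, pop: str) -> None:
        self.node = node
        self.pop = pop


class LineageState:
    """Ancestral lineages and population sizes carried through the backward
    sweep.  The invariant k <= N per population is asserted at every step;
    a violation is a bookkeeping bug, not a user error."""

    def __init__(self, final_counts: dict[str, int]) -> None:
        self.active: dict[str, list[_Lineage]] = {}
        self.N = dict(final_counts)

    def k(self, pop: str) -> int:
        return len(self.active.get(pop, ()))

    def push(self, lin: _Lineage) -> None:
        self.active.setdefault(lin.pop, []).append(lin)

    def pop_uniform(self, pop: str, rng: np.random.Generator) -> _Lineage:
        lins = self.active[pop]
        idx = int(rng.integers(len(lins)))
        lins[idx], lins[-1] = lins[-1], lins[idx]
        return lins.pop()

    def reverse_delta(self, delta: dict[str, int]) -> None:
        for p, c in delta.items():
            self.N[p] = self.N.get(p, 0) - c
            assert self.N[p] >= 0, f"negative replayed count for {p}"
            assert self.k(p) <= self.N[p], (
                f"lineage bookkeeping error: k={self.k(p)} > N={self.N[p]} for {p}"
            )

    def all_lineages(self) -> list[_Lineage]:
        out: list[_Lineage] = []
        for pop in self.active:
            out.extend(self.active[pop])
        return out


def sample_labels(traj: Trajectory, m: Model) -> list[list[list[str]]]:
    """Leaf labels ``<samplePopulation>_<ordinal>`` in forward order of
    creation, grouped per event and per firing within punctual events."""
    sample_pops = m.sample_populations
    ordinals = {p: 0 for p in sample_pops}
    per_event: list[list[list[str]]] = []
    for ev in traj.events:
        r = ev.reaction
        firings: list[list[str]] = []
        if ev.samples_created:
            for _ in range(ev.multiplicity):
                labels = []
                for p in r.products:
                    if p in sample_pops:
                        ordinals[p] += 1
                        labels.append(f"{p}_{ordinals[p]}")
                firings.append(labels)
        per_event.append(firings)
    return per_event


def _per_firing_delta(r: Union[Reaction, PunctualReaction]) -> dict[str, int]:
    return r.delta


def reconstruct_tree(
    traj: Trajectory,
    m: Model,
    rng: Union[int, np.random.Generator],
) -> list[TreeNode]:
    """Simulate the reconstructed tree for ``traj``; returns the forest of
    root nodes (a single-element list when the samples fully coalesce).

    Raises ``ValueError`` when the trajectory contains no samples — callers
    normally avoid this via the model's trajectory-acceptance condition.
    """
    if traj.n_samples == 0:
        raise ValueError("trajectory contains no sample individuals")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sample_pops = m.sample_populations
    labels = sample_labels(traj, m)
    ls = LineageState(traj.final_counts())
    roots: list[TreeNode] = []

    for ev_idx in range(len(traj.events) - 1, -1, -1):
        ev = traj.events[ev_idx]
        if ev.multiplicity == 0:
            continue
        r = ev.reaction
        delta = _per_firing_delta(r)
        ev_labels = labels[ev_idx]
        for f in range(ev.multiplicity - 1, -1, -1):
            _process_firing(
                ls, r, ev.time,
                ev_labels[f] if ev_labels else (),
                sample_pops, roots, rng,
            )
            ls.reverse_delta(delta)

    for lin in ls.all_lineages():
        roots.append(lin.node)
    roots.sort(key=lambda n: n.time)
    return roots


def _process_firing(
    ls: LineageState,
    r: Union[Reaction, PunctualReaction],
    t: float,
    firing_labels,
    sample_pops: frozenset[str],
    roots: list[TreeNode],
    rng: np.random.Generator,
) -> None:
    # Fast path: no samples made here and no ancestral lineage can be hit.
    if not firing_labels and not any(ls.k(p) for p in set(r.products)):
        return

    pending: dict[object, list[tuple[str, object]]] = {}
    inspected: dict[str, int] = {}
    label_iter = iter(firing_labels)

    for j, pop_j in enumerate(r.products):
        par = r.parentage[j]
        if pop_j in sample_pops:
            leaf = TreeNode(t, population=pop_j, label=next(label_iter))
            pending.setdefault(par, []).append(("leaf", leaf))
            continue
        k = ls.k(pop_j)
        seen = inspected.get(pop_j, 0)
        n_pool = ls.N[pop_j] - seen
        assert 0 <= k <= n_pool, (
            f"invalid ancestral probability k={k}, pool={n_pool} for {pop_j}"
        )
        if k > 0 and rng.random() * n_pool < k:
            lin = ls.pop_uniform(pop_j, rng)
            pending.setdefault(par, []).append(("lin", lin))
        inspected[pop_j] = seen + 1

    for par, items in pending.items():
        if par is None:
            # Spontaneous source: ancestral products terminate as roots.
            for kind, obj in items:
                node = obj.node if kind == "lin" else obj
                roots.append(node)
            continue
        i_pop = r.reactants[par]
        lins = [obj for kind, obj in items if kind == "lin"]
        leaves = [obj for kind, obj in items if kind == "leaf"]
        for leaf in leaves:
            leaf.population = i_pop
        if len(lins) == 1 and not leaves:
            lin = lins[0]
            if lin.pop == i_pop:
                ls.push(lin)  # continuation of the same individual
            else:
                node = TreeNode(t, population=i_pop, children=[lin.node])
                ls.push(_Lineage(node, i_pop))  # type-change record
        elif not lins and len(leaves) == 1:
            # Removed sample re-enters its source population backward.
            ls.push(_Lineage(leaves[0], i_pop))
        else:
            node = TreeNode(t, population=i_pop,
                            children=[l.node for l in lins] + leaves)
            ls.push(_Lineage(node, i_pop))
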