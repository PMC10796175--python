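"""Independent oracles for validating the simulation engines.

These implementations deliberately share no event-dispatch code with the
main engines: the full-tree simulator tracks every individual explicitly
and prunes the genealogy down to the sampled tips (the slow, obviously
correct route), and the master-equation solver integrates the truncated
Kolmogorov forward equations by matrix exponentiation.  Statistical tests
elsewhere compare the fast engines against these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.linalg import expm

from .model import (
    Conditions,
    Model,
    Population,
    PunctualReaction,
    Reaction,
    validate_model,
)
from .treeio import TreeNode

__all__ = [
    "FullTree",
    "simulate_full_tree",
    "prune_to_reconstructed",
    "master_equation_distribution",
    "logistic_fixture",
]


class _Individual:
    __slots__ = ("pop", "anchor")

    def __init__(self, pop: str, anchor: TreeNode) -> None:
        self.pop = pop
        self.anchor = anchor  # latest genealogy node on this individual's lineage


@dataclass
class FullTree:
    """Complete genealogy of every individual ever alive."""

    roots: list[TreeNode]
    birth_times: list[float] = field(default_factory=list)
    death_times: list[float] = field(default_factory=list)
    n_samples: int = 0
    final_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_birth_nodes(self) -> int:
        return len(self.birth_times)


def _oracle_propensity(r: Reaction, live: dict[str, list], t: float) -> float:
    a = r.rate.at(t)
    if a == 0.0:
        return 0.0
    for pop, c in r.reactant_counts.items():
        n = len(live.get(pop, ()))
        if n < c:
            return 0.0
        for i in range(c):
            a *= n - i
    return a


def simulate_full_tree(
    m: Model,
    seed: Union[int, np.random.Generator],
    max_events: int = 100_000,
) -> FullTree:
    """Forward simulation tracking individual identities.

    Identical in law to the trajectory engine (reactant individuals are
    drawn uniformly without replacement; each product descends from the
    reactant its parentage names, continuing it when they share a
    population), but materialises the full genealogy.  Guarded by
    ``max_events`` — this oracle is for small models only.
    """
    validate_model(m)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sample_pops = m.sample_populations

    live: dict[str, list[_Individual]] = {p.name: [] for p in m.populations}
    ft = FullTree(roots=[])
    ordinals = {p: 0 for p in sample_pops}
    for p in m.populations:
        for _ in range(p.initial_count):
            node = TreeNode(0.0, population=p.name)
            ft.roots.append(node)
            live[p.name].append(_Individual(p.name, node))

    punctual_at: dict[float, list[PunctualReaction]] = {}
    boundary_times: set[float] = set()
    for r in m.reactions:
        boundary_times.update(ct for ct in r.rate.change_times if 0.0 < ct <= m.t_end)
    for pr in m.punctual_reactions:
        for pt in pr.times:
            if 0.0 <= pt <= m.t_end:
                punctual_at.setdefault(pt, []).append(pr)
                boundary_times.add(pt)
    boundaries = sorted(boundary_times)

    def fire(r: Union[Reaction, PunctualReaction], t: float,
             chosen: list[_Individual]) -> None:
        # chosen: reactant individuals, in reactant declaration order
        per_parent: dict[Optional[int], list[int]] = {}
        for j in range(len(r.products)):
            per_parent.setdefault(r.parentage[j], []).append(j)
        continued: set[int] = set()
        for par, product_idx in per_parent.items():
            if par is None:
                for j in product_idx:
                    pop_j = r.products[j]
                    node = TreeNode(t, population=pop_j)
                    ft.roots.append(node)
                    if pop_j in sample_pops:
                        ordinals[pop_j] += 1
                        node.label = f"{pop_j}_{ordinals[pop_j]}"
                        ft.n_samples += 1
                    else:
                        live[pop_j].append(_Individual(pop_j, node))
                continue
            parent = chosen[par]
            v = TreeNode(t, population=parent.pop)
            parent.anchor.children.append(v)
            cont = None
            for j in product_idx:
                pop_j = r.products[j]
                if pop_j in sample_pops:
                    ordinals[pop_j] += 1
                    ft.n_samples += 1
                    leaf = TreeNode(t, population=parent.pop,
                                    label=f"{pop_j}_{ordinals[pop_j]}")
                    v.children.append(leaf)
                elif cont is None and pop_j == parent.pop:
                    cont = j  # same individual continues
                else:
                    child = _Individual(pop_j, v)
                    live[pop_j].append(child)
            if cont is not None:
                parent.anchor = v
                live[parent.pop].append(parent)  # the individual survives
                continued.add(par)
                ft.birth_times.extend(
                    [t] * (len([j for j in product_idx
                                if r.products[j] not in sample_pops]) - 1)
                )
            else:
                ft.birth_times.extend(
                    [t] * len([j for j in product_idx
                               if r.products[j] not in sample_pops])
                )
        for i, ind in enumerate(chosen):
            if i not in continued:
                ft.death_times.append(t)

    def choose_reactants(r: Union[Reaction, PunctualReaction]) -> list[_Individual]:
        chosen: list[_Individual] = []
        taken: dict[str, list[int]] = {}
        for pop in r.reactants:
            pool = live[pop]
            banned = taken.setdefault(pop, [])
            while True:
                idx = int(rng.integers(len(pool)))
                if idx not in banned:
                    break
            banned.append(idx)
            chosen.append(pool[idx])
        # remove chosen from live (they are replaced by fire() products)
        for pop, idxs in taken.items():
            for idx in sorted(idxs, reverse=True):
                live[pop].pop(idx)
        return chosen

    n_events = 0
    t = 0.0
    b_idx = 0
    reacts = list(m.reactions)
    while True:
        t_next = boundaries[b_idx] if b_idx < len(boundaries) else m.t_end
        while True:
            props = [_oracle_propensity(r, live, t) for r in reacts]
            total = math.fsum(props)
            if total <= 0.0:
                t = t_next
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= t_next:
                t = t_next
                break
            t += dt
            u = rng.random() * total
            acc, k = 0.0, len(props) - 1
            for i, a in enumerate(props):
                acc += a
                if u < acc:
                    k = i
                    break
            fire(reacts[k], t, choose_reactants(reacts[k]))
            n_events += 1
            if n_events > max_events:
                raise RuntimeError(f"oracle event guard exceeded ({max_events})")
        if b_idx >= len(boundaries):
            break
        for pr in punctual_at.get(t, ()):
            pool = live[pr.reactant]
            n_avail = len(pool)
            if pr.p is not None:
                mult = int(rng.binomial(n_avail, pr.p)) if n_avail else 0
            else:
                if pr.n > n_avail:
                    raise RuntimeError(
                        f"punctual count {pr.n} exceeds population {n_avail}"
                    )
                mult = int(pr.n)
            # choose `mult` distinct individuals, then apply one at a time
            picked_idx = rng.choice(n_avail, size=mult, replace=False) if mult else []
            picked = [pool[int(i)] for i in picked_idx]
            for idx in sorted((int(i) for i in picked_idx), reverse=True):
                pool.pop(idx)
            for ind in picked:
                fire(pr, t, [ind])
                n_events += 1
        b_idx += 1
        if t >= m.t_end:
            break

    ft.final_counts = {p: len(v) for p, v in live.items()}
    for p in sample_pops:
        ft.final_counts[p] = ordinals[p]
    return ft


def _contains_sample(node: TreeNode) -> bool:
    return any(n.label for n in node.walk())


def _prune(node: TreeNode) -> Optional[TreeNode]:
    kept = [c2 for c in node.children if (c2 := _prune(c)) is not None]
    if not kept and not node.label:
        return None
    out = TreeNode(node.time, node.population, node.label)
    out.children = kept
    return out


def prune_to_reconstructed(ft: FullTree) -> list[TreeNode]:
    """Reduce the full genealogy to the tree ancestral to samples.

    Unary pass-through nodes are suppressed (branch lengths merge); the
    result is distributed identically to the backward-reconstruction
    engine's output and is returned in the same forest form.
    """
    if ft.n_samples == 0:
        raise ValueError("full tree contains no samples")
    out: list[TreeNode] = []
    for root in ft.roots:
        pruned = _prune(root)
        if pruned is not None:
            out.append(pruned.copy_suppressed())
    out.sort(key=lambda n: n.time)
    return out


def master_equation_distribution(
    m: Model, state_cap: int, t: float, max_mass_loss: float = 1e-6
) -> np.ndarray:
    """Probability vector of a one-population model's count at time ``t``,
    by matrix exponentiation of the truncated master equation.

    Requires constant rates (single-piece rate vectors) and exactly one
    non-sample population.  Probability flowing above ``state_cap`` is an
    error when it exceeds ``max_mass_loss``.
    """
    pops = [p for p in m.populations if not p.is_sample]
    if len(pops) != 1:
        raise ValueError("master-equation oracle requires a one-population model")
    pop = pops[0].name
    n_states = state_cap + 1
    Q = np.zeros((n_states, n_states))
    for r in m.reactions:
        if r.rate.change_times:
            raise ValueError("master-equation oracle requires constant rates")
        rate = r.rate.values[0]
        c = r.reactant_counts.get(pop, 0)
        dn = r.delta.get(pop, 0)
        for n in range(n_states):
            if n < c:
                continue
            a = rate
            for i in range(c):
                a *= n - i
            target = n + dn
            Q[n, n] -= a  # outflow even if the target is truncated away
            if 0 <= target < n_states:
                Q[n, target] += a
    p0 = np.zeros(n_states)
    p0[m.initial_counts[pop]] = 1.0
    pt = p0 @ expm(Q * t)
    loss = 1.0 - pt.sum()
    if loss > max_mass_loss:
        raise ValueError(
            f"truncation at {state_cap} loses probability mass {loss:.2e}"
        )
    return np.clip(pt, 0.0, None)


def logistic_fixture(
    K: float,
    birth_rate: float = 1.0,
    t_end: float = 20.0,
    n_samples: int = 100,
    x0: int = 1,
) -> Model:
    """Stochastic logistic growth with a contemporaneous final sampling.

    Birth ``X -> 2X`` at rate λ and density-dependent death ``2X -> X`` at
    rate λ/K per ordered pair, so the mass-action mean-field equilibrium is
    exactly K; a punctual COUNT reaction samples ``n_samples`` individuals
    at ``t_end``.
    """
    if K <= 1:
        raise ValueError("carrying capacity must exceed 1")
    samples = frozenset({"sample"})
    return validate_model(Model(
        populations=(
            Population("X", initial_count=x0),
            Population("sample", is_sample=True),
        ),
        reactions=(
            Reaction.from_string("X -> 2X", birth_rate, samples, name="birth"),
            Reaction.from_string("2X -> X", birth_rate / K, samples, name="crowding"),
        ),
        punctual_reactions=(
            PunctualReaction.from_string(
                "X -> sample", times=(t_end,), n=n_samples,
                sample_populations=samples, name="final-sampling",
            ),
        ),
        t_end=t_end,
        conditions=Conditions(min_samples=1, max_retries=10_000),
    ))
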