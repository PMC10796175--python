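"""Backward-in-time coalescent simulation with flexible population models.

Lineages ancestral to the sampled taxa merge pairwise at instantaneous rate
``k(k-1)/2 · λ(t)`` where the per-pair rate λ depends on a population
function: ``1/Ne(t)`` for the classical coalescent, or ``2 b(t)/N(t)²`` for
coalescent approximations to birth–death dynamics, with ``b(t)`` the birth
flux and ``N(t)`` the population size taken from the deterministic
(mean-field) trajectory of a reaction model.  Structured models add
migration reactions ``La -> Lb`` (specified backward in time) at
piecewise-constant per-lineage rates.

Waiting times are drawn by time rescaling: an Exp(1) deviate is inverted
through the cumulative intensity, analytically within constant-rate
segments and by bracketed root-finding otherwise.  All node times are
reported in forward time, anchored by the model-specified leaf times.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import Model, RateFunction
from .treeio import TreeNode

__all__ = [
    "PopulationFunction",
    "ConstantPopulation",
    "ExponentialGrowth",
    "PiecewiseConstantPopulation",
    "MeanFieldPopulation",
    "CoalescentReaction",
    "Migration",
    "LeafSchedule",
    "CoalescentModel",
    "CoalescenceError",
    "population_size",
    "pair_coalescent_intensity",
    "draw_next_event_time",
    "simulate_coalescent",
]

# Gauss-Legendre nodes/weights (8-point) on [0, 1], for smooth integrands
# on mean-field grid cells.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(8)
_GL_X = (_GL_X + 1.0) / 2.0
_GL_W = _GL_W / 2.0


class CoalescenceError(RuntimeError):
    """Lineages cannot coalesce (intensity exhausted with >1 remaining)."""


class PopulationFunction:
    """Interface: population size N(t), per-pair coalescent rate λ(t), its
    integral over an interval, and the interior breakpoints of λ."""

    def size(self, t: float) -> float:
        raise NotImplementedError

    def pair_rate(self, t: float) -> float:
        return 1.0 / self.size(t)

    def integral_pair_rate(self, a: float, b: float) -> float:
        raise NotImplementedError

    def breakpoints(self, lo: float, hi: float) -> list[float]:
        return []

    # True when λ is constant between consecutive breakpoints, enabling
    # analytic waiting-time inversion.
    piecewise_flat = False


@dataclass
class ConstantPopulation(PopulationFunction):
    N0: float
    piecewise_flat = True

    def __post_init__(self) -> None:
        if self.N0 <= 0:
            raise ValueError("population size must be positive")

    def size(self, t: float) -> float:
        return self.N0

    def integral_pair_rate(self, a: float, b: float) -> float:
        return (b - a) / self.N0


@dataclass
class ExponentialGrowth(PopulationFunction):
    """N(t) = N0 · exp(r (t − t_ref)) in forward time."""

    N0: float
    r: float
    t_ref: float = 0.0
    piecewise_flat = False

    def __post_init__(self) -> None:
        if self.N0 <= 0:
            raise ValueError("population size must be positive")

    def size(self, t: float) -> float:
        return self.N0 * math.exp(self.r * (t - self.t_ref))

    def integral_pair_rate(self, a: float, b: float) -> float:
        if self.r == 0.0:
            return (b - a) / self.N0
        ea = math.exp(-self.r * (a - self.t_ref))
        eb = math.exp(-self.r * (b - self.t_ref))
        return (ea - eb) / (self.r * self.N0)


@dataclass
class PiecewiseConstantPopulation(PopulationFunction):
    """Right-continuous step function, same convention as rate vectors."""

    values: tuple[float, ...]
    change_times: tuple[float, ...] = ()
    piecewise_flat = True

    def __post_init__(self) -> None:
        self.values = tuple(float(v) for v in self.values)
        self.change_times = tuple(float(t) for t in self.change_times)
        if len(self.change_times) != len(self.values) - 1:
            raise ValueError("need one more value than change times")
        if any(v <= 0 for v in self.values):
            raise ValueError("population sizes must be positive")
        if any(a >= b for a, b in zip(self.change_times, self.change_times[1:])):
            raise ValueError("change times must be strictly increasing")

    def size(self, t: float) -> float:
        return self.values[bisect_right(self.change_times, t)]

    def breakpoints(self, lo: float, hi: float) -> list[float]:
        return [ct for ct in self.change_times if lo < ct < hi]

    def integral_pair_rate(self, a: float, b: float) -> float:
        total = 0.0
        cuts = [a] + self.breakpoints(a, b) + [b]
        for x0, x1 in zip(cuts, cuts[1:]):
            total += (x1 - x0) / self.size(0.5 * (x0 + x1))
        return total


class MeanFieldPopulation(PopulationFunction):
    """Deterministic trajectory of a reaction model's rate equations.

    The ODE uses mass-action kinetics (rate × Π N_j^{c_j}); it is solved
    with an adaptive explicit method and sampled on a dense grid for linear
    interpolation.  With ``bd_approx=True`` the per-pair rate is
    ``2 b(t)/N(t)²`` where ``b(t)`` is the flux of birth reactions that
    create net new individuals of the focal population; otherwise the
    focal population size is used directly as an effective size.  Below the
    trajectory's start the functions extend flat, so lineages that have not
    coalesced within the simulated span keep merging at the initial rate.
    """

    piecewise_flat = False

    def __init__(
        self,
        model: Model,
        population: str,
        bd_approx: bool = False,
        grid_size: int = 1001,
    ) -> None:
        if population not in model.population_names:
            raise ValueError(f"unknown population {population!r}")
        self.model = model
        self.population = population
        self.bd_approx = bd_approx
        pops = [p.name for p in model.populations if not p.is_sample]
        index = {p: i for i, p in enumerate(pops)}

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            dy = np.zeros_like(y)
            for r in model.reactions:
                flux = r.rate.at(t)
                if flux == 0.0:
                    continue
                for pop, c in r.reactant_counts.items():
                    flux *= y[index[pop]] ** c
                for pop, c in r.delta.items():
                    if pop in index:
                        dy[index[pop]] += c * flux
            return dy

        y0 = np.array([float(model.initial_counts[p]) for p in pops])
        change_times = sorted(
            {ct for r in model.reactions for ct in r.rate.change_times
             if 0.0 < ct < model.t_end}
        )
        sol = solve_ivp(
            rhs, (0.0, model.t_end), y0, method="RK45", dense_output=True,
            rtol=1e-9, atol=1e-9, max_step=model.t_end / 100.0,
        )
        if not sol.success:
            raise RuntimeError(f"mean-field ODE failed: {sol.message}")
        self.grid = np.unique(np.concatenate(
            [np.linspace(0.0, model.t_end, grid_size), np.asarray(change_times)]
        ))
        ys = sol.sol(self.grid)
        self.N_grid = ys[index[population]]
        if np.any(self.N_grid <= 0):
            raise ValueError("mean-field population size not strictly positive")

        birth_flux = np.zeros_like(self.grid)
        for r in model.reactions:
            n_new = max(
                0,
                sum(1 for p in r.products if p == population)
                - sum(1 for p in r.reactants if p == population),
            )
            if n_new == 0:
                continue
            rate_t = np.array([r.rate.at(t) for t in self.grid])
            conf = np.ones_like(self.grid)
            for pop, c in r.reactant_counts.items():
                conf *= ys[index[pop]] ** c
            birth_flux += n_new * rate_t * conf
        self.b_grid = birth_flux

    def size(self, t: float) -> float:
        t = min(max(t, self.grid[0]), self.grid[-1])
        return float(np.interp(t, self.grid, self.N_grid))

    def _birth(self, t: float) -> float:
        t = min(max(t, self.grid[0]), self.grid[-1])
        return float(np.interp(t, self.grid, self.b_grid))

    def pair_rate(self, t: float) -> float:
        n = self.size(t)
        if self.bd_approx:
            return 2.0 * self._birth(t) / (n * n)
        return 1.0 / n

    def breakpoints(self, lo: float, hi: float) -> list[float]:
        return [float(g) for g in self.grid if lo < g < hi]

    def integral_pair_rate(self, a: float, b: float) -> float:
        cuts = [a] + self.breakpoints(a, b) + [b]
        total = 0.0
        for x0, x1 in zip(cuts, cuts[1:]):
            h = x1 - x0
            if h <= 0:
                continue
            xs = x0 + h * _GL_X
            total += h * float(sum(w * self.pair_rate(x) for w, x in zip(_GL_W, xs)))
        return total


def population_size(pf: PopulationFunction, t: float) -> float:
    """N(t); raises if the function is not strictly positive there."""
    n = pf.size(t)
    if n <= 0:
        raise ValueError(f"population size {n} not positive at t={t}")
    return n


@dataclass(frozen=True)
class CoalescentReaction:
    """Pair-merging reaction ``2 L -> L`` on one lineage type, driven by a
    population function."""

    lineage_type: str
    population: PopulationFunction


@dataclass(frozen=True)
class Migration:
    """Backward-time type change ``La -> Lb`` at a per-lineage rate."""

    source: str
    dest: str
    rate: RateFunction


@dataclass(frozen=True)
class LeafSchedule:
    time: float
    lineage_type: str
    count: int


@dataclass(frozen=True)
class CoalescentModel:
    types: tuple[str, ...]
    coalescences: tuple[CoalescentReaction, ...]
    migrations: tuple[Migration, ...] = ()
    leaves: tuple[LeafSchedule, ...] = ()

    def __post_init__(self) -> None:
        declared = set(self.types)
        for c in self.coalescences:
            if c.lineage_type not in declared:
                raise ValueError(f"undeclared lineage type {c.lineage_type!r}")
        for mig in self.migrations:
            for ty in (mig.source, mig.dest):
                if ty not in declared:
                    raise ValueError(f"undeclared lineage type {ty!r}")
        if not self.leaves:
            raise ValueError("at least one leaf must be scheduled")
        for leaf in self.leaves:
            if leaf.lineage_type not in declared:
                raise ValueError(f"undeclared leaf type {leaf.lineage_type!r}")
            if leaf.count < 1:
                raise ValueError("leaf counts must be positive")


def _components(model: CoalescentModel, k: dict[str, int]):
    comps = []
    for c in model.coalescences:
        ki = k.get(c.lineage_type, 0)
        npairs = ki * (ki - 1) // 2
        comps.append(("coal", c, npairs))
    for mig in model.migrations:
        comps.append(("mig", mig, k.get(mig.source, 0)))
    return comps


def pair_coalescent_intensity(
    model: CoalescentModel, k: dict[str, int], t: float
) -> float:
    """Total instantaneous event rate at forward time ``t`` given lineage
    counts ``k`` per type."""
    total = 0.0
    for kind, obj, mult in _components(model, k):
        if mult == 0:
            continue
        if kind == "coal":
            total += mult * obj.population.pair_rate(t)
        else:
            total += mult * obj.rate.at(t)
    return total


def _cumulative(model, comps, a: float, b: float) -> float:
    """∫_a^b total intensity dt (a < b)."""
    total = 0.0
    for kind, obj, mult in comps:
        if mult == 0:
            continue
        if kind == "coal":
            total += mult * obj.population.integral_pair_rate(a, b)
        else:
            rf = obj.rate
            cuts = [a] + [ct for ct in rf.change_times if a < ct < b] + [b]
            for x0, x1 in zip(cuts, cuts[1:]):
                total += mult * rf.at(0.5 * (x0 + x1)) * (x1 - x0)
    return total


def _segment_is_flat(comps) -> bool:
    return all(
        (kind == "mig") or obj.population.piecewise_flat
        for kind, obj, mult in comps
        if mult
    )


def draw_next_event_time(
    model: CoalescentModel,
    k: dict[str, int],
    t_current: float,
    t_floor: float,
    rng: np.random.Generator,
) -> tuple[float, Optional[tuple]]:
    """Invert an Exp(1) deviate through the cumulative backward intensity.

    Returns ``(t_event, component)`` with ``component`` ``None`` when the
    floor (next scheduled leaf time, or −∞) is reached first; reaching an
    infinite floor with positive remaining lineage pairs raises
    :class:`CoalescenceError`.
    """
    comps = _components(model, k)
    if all(mult == 0 for _, _, mult in comps):
        return t_floor, None
    target = rng.exponential(1.0)

    # Segment boundaries, scanned downward from t_current.
    bps: set[float] = set()
    lo_for_bps = t_floor if math.isfinite(t_floor) else t_current - 1e9
    for kind, obj, mult in comps:
        if mult == 0:
            continue
        if kind == "coal":
            bps.update(obj.population.breakpoints(lo_for_bps, t_current))
        else:
            bps.update(ct for ct in obj.rate.change_times
                       if lo_for_bps < ct < t_current)
    cuts = sorted(bps, reverse=True)

    hi = t_current
    remaining = target
    for cut in cuts + [t_floor]:
        lo = cut
        if not math.isfinite(lo):
            # Unbounded final segment: expand downward until bracketed.
            lam_hi = pair_coalescent_intensity(model, k, hi)
            step = max(1.0, abs(hi)) if lam_hi == 0 else max(remaining / max(lam_hi, 1e-12), 1e-6)
            lo = hi - step
            for _ in range(200):
                if _cumulative(model, comps, lo, hi) >= remaining:
                    break
                lo = hi - 2.0 * (hi - lo)
            else:
                raise CoalescenceError(
                    "cumulative coalescent intensity exhausted with lineages remaining"
                )
        seg = _cumulative(model, comps, lo, hi)
        if seg >= remaining:
            t_event = _invert_in_segment(model, comps, lo, hi, remaining)
            return t_event, _choose_component(model, comps, t_event, rng)
        remaining -= seg
        hi = lo
        if hi <= t_floor:
            break
    return t_floor, None


def _invert_in_segment(model, comps, lo: float, hi: float, target: float) -> float:
    # Flat segments invert analytically; otherwise bracketed root-finding
    # with relative tolerance 1e-10 on the time variable.
    if _segment_is_flat(comps):
        lam = 0.0
        for kind, obj, mult in comps:
            if mult == 0:
                continue
            mid = 0.5 * (lo + hi)
            lam += mult * (obj.population.pair_rate(mid) if kind == "coal"
                           else obj.rate.at(mid))
        return hi - target / lam

    def g(t: float) -> float:
        return _cumulative(model, comps, t, hi) - target

    xtol = max(1e-12, 1e-10 * max(abs(lo), abs(hi), 1.0))
    return float(brentq(g, lo, hi, xtol=xtol, rtol=1e-12))


def _choose_component(model, comps, t: float, rng: np.random.Generator):
    rates = []
    for kind, obj, mult in comps:
        if mult == 0:
            rates.append(0.0)
        elif kind == "coal":
            rates.append(mult * obj.population.pair_rate(t))
        else:
            rates.append(mult * obj.rate.at(t))
    total = math.fsum(rates)
    u = rng.random() * total
    acc = 0.0
    for comp, rate in zip(comps, rates):
        acc += rate
        if u < acc:
            return comp
    return comps[-1]


def simulate_coalescent(
    model: CoalescentModel, rng: Union[int, np.random.Generator]
) -> TreeNode:
    """Simulate one coalescent tree; returns the root node.

    Leaves are inserted at their scheduled (forward) times during the
    backward sweep; pairs merge and lineages retype until a single lineage
    remains after the earliest leaf has been inserted.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ordinals: dict[str, int] = {}
    schedule: list[tuple[float, str, list[str]]] = []
    for leaf in model.leaves:
        labels = []
        for _ in range(leaf.count):
            ordinals[leaf.lineage_type] = ordinals.get(leaf.lineage_type, 0) + 1
            labels.append(f"{leaf.lineage_type}_{ordinals[leaf.lineage_type]}")
        schedule.append((float(leaf.time), leaf.lineage_type, labels))
    schedule.sort(key=lambda e: -e[0])

    active: dict[str, list[TreeNode]] = {ty: [] for ty in model.types}
    idx = 0
    t = schedule[0][0]
    while idx < len(schedule) and schedule[idx][0] == t:
        _, ty, labels = schedule[idx]
        active[ty].extend(TreeNode(t, population=ty, label=lab) for lab in labels)
        idx += 1

    while True:
        k = {ty: len(active[ty]) for ty in model.types}
        n_lineages = sum(k.values())
        if n_lineages <= 1 and idx >= len(schedule):
            break
        t_floor = schedule[idx][0] if idx < len(schedule) else -math.inf
        if n_lineages <= 1:
            t = t_floor
        else:
            t, comp = draw_next_event_time(model, k, t, t_floor, rng)
            if comp is not None:
                kind, obj, _ = comp
                if kind == "coal":
                    ty = obj.lineage_type
                    lins = active[ty]
                    i, j = rng.choice(len(lins), size=2, replace=False)
                    a, b = lins[int(i)], lins[int(j)]
                    for x in sorted((int(i), int(j)), reverse=True):
                        lins.pop(x)
                    lins.append(TreeNode(t, population=ty, children=[a, b]))
                else:
                    lins = active[obj.source]
                    lin = lins.pop(int(rng.integers(len(lins))))
                    active[obj.dest].append(
                        TreeNode(t, population=obj.dest, children=[lin])
                    )
                continue
        # Reached the floor: insert the leaves scheduled there.
        while idx < len(schedule) and schedule[idx][0] == t:
            _, ty, labels = schedule[idx]
            active[ty].extend(
                TreeNode(t, population=ty, label=lab) for lab in labels
            )
            idx += 1

    roots = [lin for ty in model.types for lin in active[ty]]
    assert len(roots) == 1
    return roots[0]
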