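"""Reaction-based model specification.

Phylodynamic models are written as chemical-kinetics-style reactions acting
on named populations, e.g. ``I + S -> I + E`` for transmission in an SEIR
epidemic.  Samples (future tree leaves) are ordinary individuals placed in
specially marked *sample* populations by reactions such as ``I -> I + sample``.

Two reaction flavours exist:

* :class:`Reaction` — fires continuously at a piecewise-constant
  per-reactant-configuration rate;
* :class:`PunctualReaction` — fires at fixed time points, either with a
  probability ``p`` applied to every eligible individual or an exact count
  ``n`` of individuals drawn without replacement.

Each product instance carries a *parentage* link to the reactant instance it
descends from; this is what makes trees reconstructable from a trajectory.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "ModelError",
    "ParseError",
    "Population",
    "RateFunction",
    "Reaction",
    "PunctualReaction",
    "Model",
    "parse_reaction_string",
    "default_parentage",
    "propensity",
    "validate_model",
]


class ModelError(ValueError):
    """A model specification violates an invariant."""


class ParseError(ModelError):
    """A reaction string or rate vector could not be parsed."""


@dataclass(frozen=True)
class Population:
    """A named population compartment.

    ``is_sample`` marks leaf-producing populations: individuals placed there
    become tips of the reconstructed tree and are inert thereafter.
    """

    name: str
    initial_count: int = 0
    is_sample: bool = False

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", self.name):
            raise ModelError(f"invalid population name {self.name!r}")
        if self.initial_count < 0:
            raise ModelError(f"population {self.name}: negative initial count")
        if self.is_sample and self.initial_count != 0:
            raise ModelError(
                f"sample population {self.name} must start with count 0"
            )


@dataclass(frozen=True)
class RateFunction:
    """Piecewise-constant rate through time.

    ``values[i]`` applies on the half-open interval
    ``[change_times[i-1], change_times[i])``; the function is
    right-continuous, so at a change time the *new* rate already applies
    (a rate vector ``0 1`` with change time 5 is zero strictly before
    time 5 and one from time 5 on).
    """

    values: tuple[float, ...]
    change_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        object.__setattr__(
            self, "change_times", tuple(float(t) for t in self.change_times)
        )
        if not self.values:
            raise ModelError("rate function needs at least one value")
        if any(v < 0 for v in self.values):
            raise ModelError("rates must be non-negative")
        if len(self.change_times) != len(self.values) - 1:
            raise ModelError(
                "rate vector of length %d needs %d change times, got %d"
                % (len(self.values), len(self.values) - 1, len(self.change_times))
            )
        if any(
            a >= b for a, b in zip(self.change_times, self.change_times[1:])
        ):
            raise ModelError("change times must be strictly increasing")

    @classmethod
    def constant(cls, value: float) -> "RateFunction":
        return cls((value,))

    def at(self, t: float) -> float:
        """Rate in effect at time ``t`` (right-continuous)."""
        return self.values[bisect_right(self.change_times, t)]

    @property
    def max_value(self) -> float:
        return max(self.values)


def rate_at(rf: RateFunction, t: float) -> float:
    """Functional alias for :meth:`RateFunction.at`."""
    return rf.at(t)


_TERM_RE = re.compile(r"^(\d+)?\s*([A-Za-z_][A-Za-z0-9_.]*)$")


def _parse_side(side: str, which: str) -> tuple[str, ...]:
    side = side.strip()
    if side in ("", "0"):  # explicit empty side: source or sink
        return ()
    out: list[str] = []
    for raw in side.split("+"):
        term = raw.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise ParseError(f"malformed term {term!r} on {which} side")
        mult = int(m.group(1)) if m.group(1) else 1
        if mult < 1:
            raise ParseError(f"multiplier must be positive in term {term!r}")
        out.extend([m.group(2)] * mult)
    return tuple(out)


def parse_reaction_string(text: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Parse ``"I + S -> I + E"`` into reactant and product instance tuples.

    Multipliers expand (``2A`` is ``A + A``); either side may be empty (or
    the literal ``0``) for spontaneous sources and sinks.  Returns instance
    *lists* (declaration order preserved) from which multisets follow.
    """
    parts = re.split(r"->|→|–>", text)
    if len(parts) != 2:
        raise ParseError(f"reaction {text!r} must contain exactly one '->'")
    return _parse_side(parts[0], "reactant"), _parse_side(parts[1], "product")


def default_parentage(
    reactants: Sequence[str],
    products: Sequence[str],
    sample_populations: frozenset[str] | set[str] = frozenset(),
) -> tuple[Optional[int], ...]:
    """Assign each product instance a parent reactant instance.

    Rule: each non-sample product is matched, in declaration order, to a
    not-yet-matched reactant of the *same* population (that product is the
    continuation of the same individual).  Every remaining product — samples
    included — descends from the first reactant.  Reactions with an empty
    reactant side produce parentless products (``None``), which is an error
    for non-sample products only when validation requires ancestry; for
    spontaneous sources it simply starts a new root lineage.
    """
    available = list(range(len(reactants)))
    parentage: list[Optional[int]] = [None] * len(products)
    for j, pop in enumerate(products):
        if pop in sample_populations:
            continue
        for slot, i in enumerate(available):
            if reactants[i] == pop:
                parentage[j] = i
                del available[slot]
                break
    for j, pop in enumerate(products):
        if parentage[j] is None:
            parentage[j] = 0 if reactants else None
    return tuple(parentage)


@dataclass(frozen=True)
class Reaction:
    """A rate-driven stoichiometric rule.

    ``reactants`` and ``products`` are instance tuples (multisets with
    order); ``parentage[j]`` is the index of the reactant instance that
    product instance ``j`` descends from, or ``None`` for parentless
    products of spontaneous sources.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: RateFunction
    parentage: tuple[Optional[int], ...] = ()
    name: str = ""

    @classmethod
    def from_string(
        cls,
        text: str,
        rate: RateFunction | float,
        sample_populations: frozenset[str] | set[str] = frozenset(),
        parentage: Sequence[Optional[int]] | None = None,
        name: str = "",
    ) -> "Reaction":
        reactants, products = parse_reaction_string(text)
        if isinstance(rate, (int, float)):
            rate = RateFunction.constant(rate)
        if parentage is None:
            parentage = default_parentage(reactants, products, sample_populations)
        return cls(reactants, products, rate, tuple(parentage), name or text.strip())

    def __post_init__(self) -> None:
        if len(self.parentage) != len(self.products):
            raise ModelError(
                f"reaction {self.name or self.format()}: parentage length "
                f"{len(self.parentage)} != product count {len(self.products)}"
            )
        for j, p in enumerate(self.parentage):
            if p is not None and not (0 <= p < len(self.reactants)):
                raise ModelError(
                    f"reaction {self.name}: parent index {p} of product {j} "
                    "out of range"
                )

    def format(self) -> str:
        def side(instances: tuple[str, ...]) -> str:
            if not instances:
                return "0"
            counts = Counter(instances)
            return " + ".join(
                (f"{c}{p}" if c > 1 else p) for p, c in counts.items()
            )

        return f"{side(self.reactants)} -> {side(self.products)}"

    @property
    def reactant_counts(self) -> Counter:
        return Counter(self.reactants)

    @property
    def delta(self) -> dict[str, int]:
        d = Counter(self.products)
        d.subtract(Counter(self.reactants))
        return {p: c for p, c in d.items() if c != 0}


@dataclass(frozen=True)
class PunctualReaction:
    """A reaction applied at fixed time points.

    Exactly one reactant individual per firing.  In PROBABILITY mode the
    rule is applied independently with probability ``p`` to every individual
    of the reactant population present at each listed time; in COUNT mode to
    exactly ``n`` individuals chosen without replacement (an error if fewer
    than ``n`` are present).
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    times: tuple[float, ...]
    p: Optional[float] = None
    n: Optional[int] = None
    parentage: tuple[Optional[int], ...] = ()
    name: str = ""

    @classmethod
    def from_string(
        cls,
        text: str,
        times: Sequence[float],
        p: Optional[float] = None,
        n: Optional[int] = None,
        sample_populations: frozenset[str] | set[str] = frozenset(),
        parentage: Sequence[Optional[int]] | None = None,
        name: str = "",
    ) -> "PunctualReaction":
        reactants, products = parse_reaction_string(text)
        if parentage is None:
            parentage = default_parentage(reactants, products, sample_populations)
        return cls(
            reactants,
            products,
            tuple(float(t) for t in times),
            p,
            n,
            tuple(parentage),
            name or text.strip(),
        )

    def __post_init__(self) -> None:
        if len(self.reactants) != 1:
            raise ModelError(
                f"punctual reaction {self.name}: exactly one reactant "
                f"individual required, got {len(self.reactants)}"
            )
        if (self.p is None) == (self.n is None):
            raise ModelError(
                f"punctual reaction {self.name}: exactly one of p or n required"
            )
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise ModelError(f"punctual reaction {self.name}: p not in [0, 1]")
        if self.n is not None and (self.n < 0 or int(self.n) != self.n):
            raise ModelError(
                f"punctual reaction {self.name}: n must be a non-negative integer"
            )
        if not self.times:
            raise ModelError(f"punctual reaction {self.name}: no times given")
        if any(a >= b for a, b in zip(self.times, self.times[1:])):
            raise ModelError(
                f"punctual reaction {self.name}: times must be strictly increasing"
            )
        if len(self.parentage) != len(self.products):
            raise ModelError(
                f"punctual reaction {self.name}: parentage length mismatch"
            )

    @property
    def reactant(self) -> str:
        return self.reactants[0]

    @property
    def delta(self) -> dict[str, int]:
        d = Counter(self.products)
        d.subtract(Counter(self.reactants))
        return {p: c for p, c in d.items() if c != 0}

    def format(self) -> str:
        counts = Counter(self.products)
        rhs = " + ".join((f"{c}{p}" if c > 1 else p) for p, c in counts.items()) or "0"
        return f"{self.reactants[0]} -> {rhs}"


@dataclass(frozen=True)
class Conditions:
    """Acceptance conditions retried at simulation time."""

    min_samples: int = 1
    max_retries: int = 10_000


@dataclass(frozen=True)
class Model:
    """A complete forward-time simulation model."""

    populations: tuple[Population, ...]
    reactions: tuple[Reaction, ...] = ()
    punctual_reactions: tuple[PunctualReaction, ...] = ()
    t_end: float = 1.0
    conditions: Conditions = field(default_factory=Conditions)

    @property
    def population_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.populations)

    @property
    def sample_populations(self) -> frozenset[str]:
        return frozenset(p.name for p in self.populations if p.is_sample)

    @property
    def initial_counts(self) -> dict[str, int]:
        return {p.name: p.initial_count for p in self.populations}


def propensity(r: Reaction, counts: Mapping[str, int], t: float) -> float:
    """Total firing rate: rate(t) times the number of ordered reactant
    configurations, i.e. the falling factorial ``N (N-1) ... (N-c+1)`` per
    reactant population with multiplicity ``c``.  Zero whenever any reactant
    count is below its multiplicity."""
    a = r.rate.at(t)
    if a == 0.0:
        return 0.0
    for pop, c in r.reactant_counts.items():
        n = counts.get(pop, 0)
        if n < c:
            return 0.0
        for i in range(c):
            a *= n - i
    return a


def validate_model(m: Model) -> Model:
    """Check all model invariants; returns the model unchanged on success."""
    names = [p.name for p in m.populations]
    dupes = [n for n, c in Counter(names).items() if c > 1]
    if dupes:
        raise ModelError(f"duplicate population names: {', '.join(dupes)}")
    declared = set(names)
    samples = m.sample_populations

    if m.t_end <= 0:
        raise ModelError("t_end must be positive")

    for r in list(m.reactions) + list(m.punctual_reactions):
        label = r.name or r.format()
        for pop in set(r.reactants) | set(r.products):
            if pop not in declared:
                raise ModelError(
                    f"reaction {label!r}: population {pop!r} not declared"
                )
        for pop in r.reactants:
            if pop in samples:
                raise ModelError(
                    f"reaction {label!r}: sample population {pop!r} used as reactant"
                )
        for j, parent in enumerate(r.parentage):
            prod = r.products[j]
            if parent is None and prod not in samples and r.reactants:
                raise ModelError(
                    f"reaction {label!r}: non-sample product {prod!r} has no parent"
                )
    for pr in m.punctual_reactions:
        if pr.n is not None and int(pr.n) != pr.n:
            raise ModelError(f"punctual {pr.name}: n must be an integer")
    return m
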