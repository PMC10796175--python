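"""Forward stochastic simulation of reaction models.

Gillespie's direct method, extended with scheduled boundaries: because all
rates are piecewise-constant, an exponential waiting-time draw that crosses
the next rate-change or punctual time is discarded and redrawn from the
boundary (the memoryless property makes this exact).  Every firing is logged
as an :class:`Event`, giving a trajectory that can be replayed forward or
backward exactly — the backward replay is what drives reconstructed-tree
simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .model import Model, PunctualReaction, Reaction, propensity, validate_model

__all__ = [
    "Event",
    "Trajectory",
    "ConditionError",
    "PunctualCountError",
    "simulate_trajectory",
    "apply_punctual_reaction",
    "replay_counts",
    "log_trajectory_grid",
]


class ConditionError(RuntimeError):
    """Retry limit exhausted without meeting the acceptance condition."""


class PunctualCountError(RuntimeError):
    """COUNT-mode punctual reaction demanded more individuals than exist."""


@dataclass
class Event:
    """One reaction firing (or one punctual application to ``multiplicity``
    individuals).  ``delta`` is the total count change; applying it to the
    pre-event state yields the post-event state."""

    time: float
    reaction: Union[Reaction, PunctualReaction]
    multiplicity: int
    delta: dict[str, int]
    samples_created: int = 0
    removes_sampled: bool = False


@dataclass
class Trajectory:
    """Initial state plus a time-ordered event log up to ``t_end``."""

    initial: dict[str, int]
    t0: float
    t_end: float
    events: list[Event] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return sum(ev.samples_created for ev in self.events)

    def final_counts(self) -> dict[str, int]:
        return replay_counts(self, self.t_end)


def _reaction_sample_info(r: Union[Reaction, PunctualReaction],
                          sample_pops: frozenset[str]) -> tuple[int, bool]:
    """(samples per firing, whether the sampled reactant is removed).

    The reactant is "removed" when no product continues it in the same
    population — the distinction between ``I -> sample`` (removal) and
    ``I -> I + sample`` (sampled ancestor possible).
    """
    per_firing = sum(1 for p in r.products if p in sample_pops)
    if per_firing == 0:
        return 0, False
    continues = any(
        p not in sample_pops and parent is not None and r.reactants[parent] == p
        for p, parent in zip(r.products, r.parentage)
    )
    return per_firing, not continues


def apply_punctual_reaction(
    counts: dict[str, int],
    pr: PunctualReaction,
    t: float,
    rng: np.random.Generator,
    sample_pops: frozenset[str] = frozenset(),
) -> tuple[dict[str, int], Event]:
    """Fire a punctual reaction at one of its scheduled times.

    PROBABILITY mode draws the number of firings as Binomial(N, p) over the
    N individuals present; COUNT mode fires exactly n times (error if
    n > N).  Returns the post-event counts and the logged event (which may
    have multiplicity 0).
    """
    pop = pr.reactant
    n_avail = counts.get(pop, 0)
    if pr.p is not None:
        mult = int(rng.binomial(n_avail, pr.p)) if n_avail > 0 else 0
    else:
        n_req = int(pr.n)
        if n_req > n_avail:
            raise PunctualCountError(
                f"punctual reaction {pr.name!r} at t={t}: requested "
                f"{n_req} individuals of {pop!r} but only {n_avail} present"
            )
        mult = n_req
    per = pr.delta
    delta = {p: c * mult for p, c in per.items()} if mult else {}
    new = dict(counts)
    for p, c in delta.items():
        new[p] = new.get(p, 0) + c
        if new[p] < 0:
            raise RuntimeError(f"negative count for {p} after punctual firing")
    s_per, removes = _reaction_sample_info(pr, sample_pops)
    ev = Event(t, pr, mult, delta, s_per * mult, removes)
    return new, ev


def _attempt(m: Model, rng: np.random.Generator) -> Trajectory:
    counts = dict(m.initial_counts)
    sample_pops = m.sample_populations
    t0, t_end = 0.0, float(m.t_end)

    # Scheduled boundaries: rate change times and punctual times within the
    # span.  At a shared boundary the (right-continuous) new rate applies
    # first; punctual reactions then fire in declaration order.
    boundary_times: set[float] = set()
    for r in m.reactions:
        boundary_times.update(ct for ct in r.rate.change_times if t0 < ct <= t_end)
    punctual_at: dict[float, list[PunctualReaction]] = {}
    for pr in m.punctual_reactions:
        for pt in pr.times:
            if t0 <= pt <= t_end:
                punctual_at.setdefault(pt, []).append(pr)
                boundary_times.add(pt)
    boundaries = sorted(boundary_times)

    reacts = list(m.reactions)
    deltas = [r.delta for r in reacts]
    sinfo = [_reaction_sample_info(r, sample_pops) for r in reacts]

    traj = Trajectory(dict(counts), t0, t_end)
    events = traj.events
    t = t0
    b_idx = 0
    while True:
        t_next = boundaries[b_idx] if b_idx < len(boundaries) else t_end
        while True:
            props = [propensity(r, counts, t) for r in reacts]
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
            acc = 0.0
            k = len(props) - 1
            for i, a in enumerate(props):
                acc += a
                if u < acc:
                    k = i
                    break
            for p, c in deltas[k].items():
                counts[p] = counts.get(p, 0) + c
            s_per, removes = sinfo[k]
            events.append(Event(t, reacts[k], 1, deltas[k], s_per, removes))
        if b_idx >= len(boundaries):
            break
        for pr in punctual_at.get(t, ()):
            counts, ev = apply_punctual_reaction(counts, pr, t, rng, sample_pops)
            events.append(ev)
        b_idx += 1
        if t >= t_end:
            break
    return traj


def simulate_trajectory(
    m: Model, seed: Union[int, np.random.Generator]
) -> Trajectory:
    """Simulate one trajectory; retries until the model's acceptance
    condition (minimum total sample count) is met or the retry limit is hit.

    ``seed`` may be an integer or an existing generator; a single generator
    is threaded through all retries so one seed fixes the whole replicate.
    """
    validate_model(m)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cond = m.conditions
    need = cond.min_samples if m.sample_populations else 0
    attempts = 0
    while True:
        attempts += 1
        traj = _attempt(m, rng)
        if sum(ev.samples_created for ev in traj.events) >= need:
            return traj
        if attempts > cond.max_retries:
            raise ConditionError(
                f"no trajectory with >= {need} samples in {attempts} attempts"
            )


def replay_counts(traj: Trajectory, t: float) -> dict[str, int]:
    """Exact population counts at time ``t``⁺ (events at exactly ``t``
    included), by cumulative application of event deltas."""
    if t < traj.t0 or t > traj.t_end:
        raise ValueError(f"t={t} outside trajectory span [{traj.t0}, {traj.t_end}]")
    counts = dict(traj.initial)
    for ev in traj.events:
        if ev.time > t:
            break
        for p, c in ev.delta.items():
            counts[p] = counts.get(p, 0) + c
    return counts


def log_trajectory_grid(traj: Trajectory, n_points: int) -> pd.DataFrame:
    """Population counts on an evenly spaced time grid, as a tidy table
    with a ``t`` column followed by one column per population."""
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    times = np.linspace(traj.t0, traj.t_end, n_points)
    pops = sorted(
        set(traj.initial) | {p for ev in traj.events for p in ev.delta}
    )
    counts = {p: traj.initial.get(p, 0) for p in pops}
    rows = []
    ev_idx = 0
    events = traj.events
    for t in times:
        while ev_idx < len(events) and events[ev_idx].time <= t:
            for p, c in events[ev_idx].delta.items():
                counts[p] = counts.get(p, 0) + c
            ev_idx += 1
        rows.append([t] + [counts[p] for p in pops])
    return pd.DataFrame(rows, columns=["t"] + pops)
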