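"""Declarative YAML configuration for simulation jobs.

The format mirrors the reaction notation directly: numeric vectors are
space-separated strings, and the field names ``rate``, ``changeTimes``,
``p`` and ``times`` are used verbatim.  Unknown keys are errors by default
(silent typos in rate fields are the dominant user failure mode).

A birth–death job::

    populations:
      - {name: S, initial: 99}
      - {name: I, initial: 1}
      - {name: sample, sample: true}
    reactions:
      - {reaction: "I + S -> I + E", rate: "0.1"}
      - {reaction: "I -> I + sample", rate: "0 1", changeTimes: "5"}
    punctual_reactions:
      - {reaction: "I -> sample", p: "0.1", times: "5 10"}
    t_end: 10

A coalescent job sets ``model: coalescent`` and specifies backward-time
reactions (``2L -> L`` with a population function, migrations ``La -> Lb``)
plus a leaf schedule of ``{time, type, count}`` entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Union

import yaml

from .coalescent import (
    CoalescentModel,
    CoalescentReaction,
    ConstantPopulation,
    ExponentialGrowth,
    LeafSchedule,
    MeanFieldPopulation,
    Migration,
    PiecewiseConstantPopulation,
    PopulationFunction,
)
from .model import (
    Conditions,
    Model,
    ModelError,
    Population,
    PunctualReaction,
    RateFunction,
    Reaction,
    parse_reaction_string,
    validate_model,
)

__all__ = ["ConfigError", "SimulationJob", "load_config", "loads_config", "dump_config"]


class ConfigError(ValueError):
    """A configuration file is malformed or violates model invariants."""


@dataclass
class SimulationJob:
    model: Union[Model, CoalescentModel]
    replicates: int = 1
    seed: int = 1
    grid_points: int = 101
    typed_newick: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


def _floats(value: Any, context: str) -> tuple[float, ...]:
    if value is None:
        return ()
    if isinstance(value, str):
        items = value.split()
    elif isinstance(value, (list, tuple)):
        items = value
    else:
        items = [value]
    try:
        return tuple(float(v) for v in items)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: cannot parse numeric list {value!r}") from exc


def _check_keys(mapping: dict, allowed: set[str], context: str,
                strict: bool) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown and strict:
        raise ConfigError(
            f"{context}: unknown key(s) {', '.join(sorted(unknown))} "
            f"(allowed: {', '.join(sorted(allowed))})"
        )


def _load_populations(entries, strict) -> tuple[Population, ...]:
    if not entries:
        raise ConfigError("no populations declared")
    pops = []
    for i, entry in enumerate(entries):
        if isinstance(entry, str):
            entry = {"name": entry}
        _check_keys(entry, {"name", "initial", "sample"}, f"populations[{i}]", strict)
        if "name" not in entry:
            raise ConfigError(f"populations[{i}]: missing name")
        try:
            pops.append(Population(
                str(entry["name"]),
                int(entry.get("initial", 0)),
                bool(entry.get("sample", False)),
            ))
        except ModelError as exc:
            raise ConfigError(f"populations[{i}]: {exc}") from exc
    return tuple(pops)


def _load_rate(entry: dict, context: str) -> RateFunction:
    if "rate" not in entry:
        raise ConfigError(f"{context}: missing rate")
    values = _floats(entry["rate"], context)
    change_times = _floats(entry.get("changeTimes"), context)
    try:
        return RateFunction(values, change_times)
    except ModelError as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def _load_bd_model(doc: dict, strict: bool) -> Model:
    _check_keys(doc, {"model", "populations", "reactions", "punctual_reactions",
                      "t_end", "conditions", "replicates", "seed"},
                "top level", strict)
    pops = _load_populations(doc.get("populations"), strict)
    samples = frozenset(p.name for p in pops if p.is_sample)

    reactions = []
    for i, entry in enumerate(doc.get("reactions") or []):
        ctx = f"reactions[{i}]"
        _check_keys(entry, {"reaction", "rate", "changeTimes", "parentage"},
                    ctx, strict)
        if "reaction" not in entry:
            raise ConfigError(f"{ctx}: missing reaction string")
        try:
            reactions.append(Reaction.from_string(
                entry["reaction"], _load_rate(entry, ctx), samples,
                parentage=entry.get("parentage"),
            ))
        except ModelError as exc:
            raise ConfigError(f"{ctx}: {exc}") from exc

    punctual = []
    for i, entry in enumerate(doc.get("punctual_reactions") or []):
        ctx = f"punctual_reactions[{i}]"
        _check_keys(entry, {"reaction", "p", "n", "times", "parentage"}, ctx, strict)
        if "reaction" not in entry:
            raise ConfigError(f"{ctx}: missing reaction string")
        if "times" not in entry:
            raise ConfigError(f"{ctx}: missing times")
        p = entry.get("p")
        n = entry.get("n")
        try:
            punctual.append(PunctualReaction.from_string(
                entry["reaction"],
                times=_floats(entry["times"], ctx),
                p=float(p) if p is not None else None,
                n=int(n) if n is not None else None,
                sample_populations=samples,
                parentage=entry.get("parentage"),
            ))
        except ModelError as exc:
            raise ConfigError(f"{ctx}: {exc}") from exc

    cond = doc.get("conditions") or {}
    _check_keys(cond, {"min_samples", "max_retries"}, "conditions", strict)
    if "t_end" not in doc:
        raise ConfigError("missing t_end")
    try:
        return validate_model(Model(
            populations=pops,
            reactions=tuple(reactions),
            punctual_reactions=tuple(punctual),
            t_end=float(doc["t_end"]),
            conditions=Conditions(
                int(cond.get("min_samples", 1)),
                int(cond.get("max_retries", 10_000)),
            ),
        ))
    except ModelError as exc:
        raise ConfigError(str(exc)) from exc


def _load_popfn(entry: Any, context: str, strict: bool) -> PopulationFunction:
    if isinstance(entry, (int, float)):
        return ConstantPopulation(float(entry))
    _check_keys(entry, {"kind", "N0", "r", "t_ref", "values", "changeTimes",
                        "population", "bd_approx", "model", "grid_size"},
                context, strict)
    kind = entry.get("kind", "constant")
    try:
        if kind == "constant":
            return ConstantPopulation(float(entry["N0"]))
        if kind == "exponential":
            return ExponentialGrowth(float(entry["N0"]), float(entry["r"]),
                                     float(entry.get("t_ref", 0.0)))
        if kind == "piecewise":
            return PiecewiseConstantPopulation(
                _floats(entry["values"], context),
                _floats(entry.get("changeTimes"), context),
            )
        if kind == "mean_field":
            nested = _load_bd_model(entry["model"], strict)
            return MeanFieldPopulation(
                nested, str(entry["population"]),
                bd_approx=bool(entry.get("bd_approx", False)),
                grid_size=int(entry.get("grid_size", 1001)),
            )
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc
    raise ConfigError(f"{context}: unknown population function kind {kind!r}")


def _load_coalescent_model(doc: dict, strict: bool) -> CoalescentModel:
    _check_keys(doc, {"model", "types", "coalescent_reactions", "migrations",
                      "leaves", "replicates", "seed"}, "top level", strict)
    types = tuple(str(t) for t in (doc.get("types") or ()))
    if not types:
        raise ConfigError("no lineage types declared")

    coalescences = []
    for i, entry in enumerate(doc.get("coalescent_reactions") or []):
        ctx = f"coalescent_reactions[{i}]"
        _check_keys(entry, {"reaction", "population"}, ctx, strict)
        reactants, products = parse_reaction_string(entry.get("reaction", ""))
        if not (len(reactants) == 2 and len(set(reactants)) == 1
                and tuple(products) == (reactants[0],)):
            raise ConfigError(
                f"{ctx}: coalescent reactions must have the form '2L -> L'"
            )
        coalescences.append(CoalescentReaction(
            reactants[0], _load_popfn(entry.get("population"), ctx, strict)
        ))

    migrations = []
    for i, entry in enumerate(doc.get("migrations") or []):
        ctx = f"migrations[{i}]"
        _check_keys(entry, {"reaction", "rate", "changeTimes"}, ctx, strict)
        reactants, products = parse_reaction_string(entry.get("reaction", ""))
        if len(reactants) != 1 or len(products) != 1:
            raise ConfigError(f"{ctx}: migrations must have the form 'La -> Lb'")
        migrations.append(Migration(reactants[0], products[0],
                                    _load_rate(entry, ctx)))

    leaves = []
    for i, entry in enumerate(doc.get("leaves") or []):
        ctx = f"leaves[{i}]"
        _check_keys(entry, {"time", "type", "count"}, ctx, strict)
        try:
            leaves.append(LeafSchedule(float(entry["time"]), str(entry["type"]),
                                       int(entry.get("count", 1))))
        except KeyError as exc:
            raise ConfigError(f"{ctx}: missing {exc}") from exc

    try:
        return CoalescentModel(types, tuple(coalescences), tuple(migrations),
                               tuple(leaves))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def loads_config(text: str, strict: bool = True) -> SimulationJob:
    """Parse a configuration document from a string."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML: {exc}") from exc
    if doc is None:
        raise ConfigError("no populations declared (empty file)")
    if not isinstance(doc, dict):
        raise ConfigError("top level must be a mapping")
    kind = doc.get("model", "birth-death")
    if kind == "coalescent":
        model: Union[Model, CoalescentModel] = _load_coalescent_model(doc, strict)
    elif kind in ("birth-death", "birth_death", "bd"):
        model = _load_bd_model(doc, strict)
    else:
        raise ConfigError(f"unknown model kind {kind!r}")
    return SimulationJob(
        model=model,
        replicates=int(doc.get("replicates", 1)),
        seed=int(doc.get("seed", 1)),
    )


def load_config(path, strict: bool = True) -> SimulationJob:
    """Load and fully validate a simulation job from a YAML file."""
    with open(path) as fh:
        return loads_config(fh.read(), strict=strict)


def dump_config(job: SimulationJob) -> dict:
    """Semantic round-trip representation of a job (YAML-serialisable)."""
    m = job.model
    doc: dict[str, Any] = {"replicates": job.replicates, "seed": job.seed}
    if isinstance(m, Model):
        doc["model"] = "birth-death"
        doc["populations"] = [
            {"name": p.name, "initial": p.initial_count, "sample": p.is_sample}
            for p in m.populations
        ]
        doc["reactions"] = [
            {
                "reaction": r.format(),
                "rate": " ".join(repr(v) for v in r.rate.values),
                "changeTimes": " ".join(repr(t) for t in r.rate.change_times),
                "parentage": list(r.parentage),
            }
            for r in m.reactions
        ]
        doc["punctual_reactions"] = [
            {
                "reaction": pr.format(),
                **({"p": pr.p} if pr.p is not None else {"n": pr.n}),
                "times": " ".join(repr(t) for t in pr.times),
                "parentage": list(pr.parentage),
            }
            for pr in m.punctual_reactions
        ]
        doc["t_end"] = m.t_end
        doc["conditions"] = {
            "min_samples": m.conditions.min_samples,
            "max_retries": m.conditions.max_retries,
        }
    else:
        doc["model"] = "coalescent"
        doc["types"] = list(m.types)
        doc["coalescent_reactions"] = [
            {"reaction": f"2{c.lineage_type} -> {c.lineage_type}",
             "population": _dump_popfn(c.population)}
            for c in m.coalescences
        ]
        doc["migrations"] = [
            {"reaction": f"{g.source} -> {g.dest}",
             "rate": " ".join(repr(v) for v in g.rate.values),
             "changeTimes": " ".join(repr(t) for t in g.rate.change_times)}
            for g in m.migrations
        ]
        doc["leaves"] = [
            {"time": l.time, "type": l.lineage_type, "count": l.count}
            for l in m.leaves
        ]
    return doc


def _dump_popfn(pf: PopulationFunction) -> dict:
    if isinstance(pf, ConstantPopulation):
        return {"kind": "constant", "N0": pf.N0}
    if isinstance(pf, ExponentialGrowth):
        return {"kind": "exponential", "N0": pf.N0, "r": pf.r, "t_ref": pf.t_ref}
    if isinstance(pf, PiecewiseConstantPopulation):
        return {"kind": "piecewise",
                "values": " ".join(repr(v) for v in pf.values),
                "changeTimes": " ".join(repr(t) for t in pf.change_times)}
    if isinstance(pf, MeanFieldPopulation):
        return {"kind": "mean_field", "population": pf.population,
                "bd_approx": pf.bd_approx,
                "model": "<nested model>"}
    raise TypeError(f"cannot serialise {type(pf).__name__}")
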