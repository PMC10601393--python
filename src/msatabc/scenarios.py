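"""Demographic scenarios, priors and parameter draws.

A scenario is a set of sampled lineages (each a constant-size population)
plus a time-ordered list of instantaneous events. Working backward in time,
a *split* event merges one or more derived lineages into their ancestor
(forward in time: the derived lineages diverged from the ancestor at that
time), and an *admixture* event sends each gene lineage of the target
population to one of two source populations, to the first with probability
``ra``. Event times are named parameters (``t1``, ``t2``, ``ta``, ...) drawn
from priors under ordering constraints enforced by rejection sampling.

Scenario sets are read from a sectioned plain-text config; the shipped
``scenarios_caucasus.cfg`` fixture encodes five sampled lineages
(62/72/65/40/27 diploids, nine SSR loci) and eight alternative
divergence/admixture topologies for them.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .containers import LocusSpec

__all__ = [
    "Lineage",
    "DemographicEvent",
    "DemographicScenario",
    "PriorSet",
    "ParameterDraw",
    "ScenarioSet",
    "load_scenario_set",
    "load_default_scenarios",
    "sample_draw",
    "generations_to_years",
]


class ConfigError(ValueError):
    """Malformed scenario/prior configuration."""


class ScenarioValidationError(ValueError):
    """Structurally invalid demographic scenario."""


@dataclass(frozen=True)
class Lineage:
    """A sampled population: label, Ne prior parameter, diploid sample size."""

    id: str
    ne_param: str
    sample_size: int

    def __post_init__(self) -> None:
        if self.sample_size < 0:
            raise ScenarioValidationError(f"lineage {self.id}: negative sample size")


@dataclass(frozen=True)
class DemographicEvent:
    """An instantaneous event at a named time.

    kind="split": ``derived`` lineages merge (backward) into ``ancestor``.
    kind="admixture": ``target``'s lineages move to ``source1`` with
    probability ``ra_param``, otherwise to ``source2``.
    """

    kind: str
    time_param: str
    derived: tuple[str, ...] = ()
    ancestor: str | None = None
    target: str | None = None
    source1: str | None = None
    source2: str | None = None
    ra_param: str | None = None

    def participants(self) -> tuple[str, ...]:
        if self.kind == "split":
            return self.derived + (self.ancestor,)
        return (self.target, self.source1, self.source2)


@dataclass
class DemographicScenario:
    """One divergence/admixture hypothesis over a common lineage set."""

    id: int
    lineages: list[Lineage]
    events: list[DemographicEvent]

    def lineage_ids(self) -> list[str]:
        return [lin.id for lin in self.lineages]

    def time_params(self) -> list[str]:
        seen: list[str] = []
        for ev in self.events:
            if ev.time_param not in seen:
                seen.append(ev.time_param)
        return seen

    def ra_params(self) -> list[str]:
        return [ev.ra_param for ev in self.events if ev.kind == "admixture"]

    def ne_params(self) -> list[str]:
        return [lin.ne_param for lin in self.lineages]

    def param_names(self) -> list[str]:
        return self.ne_params() + self.time_params() + self.ra_params()

    def validate(self, time_order: dict[str, float] | None = None) -> str:
        """Check the event list coalesces every lineage into a single root.

        Performs a symbolic backward traversal with events in the order given
        (or ordered by ``time_order``, a representative draw of the time
        parameters). Returns the root lineage id; raises
        ``ScenarioValidationError`` otherwise.
        """
        ids = self.lineage_ids()
        if len(set(ids)) != len(ids):
            raise ScenarioValidationError(f"scenario {self.id}: duplicate lineage ids")
        events = self.events
        if time_order is not None:
            events = sorted(events, key=lambda ev: time_order[ev.time_param])
        extant = set(ids)
        for ev in events:
            for pid in ev.participants():
                if pid not in ids:
                    raise ScenarioValidationError(
                        f"scenario {self.id}: event at {ev.time_param} references "
                        f"unknown lineage {pid!r}"
                    )
                if pid not in extant:
                    raise ScenarioValidationError(
                        f"scenario {self.id}: event at {ev.time_param} involves "
                        f"lineage {pid!r} which is not extant at that time"
                    )
            if ev.kind == "split":
                for d in ev.derived:
                    if d == ev.ancestor:
                        raise ScenarioValidationError(
                            f"scenario {self.id}: split at {ev.time_param} merges "
                            f"{d!r} into itself"
                        )
                    extant.discard(d)
            else:
                extant.discard(ev.target)
        if len(extant) != 1:
            raise ScenarioValidationError(
                f"scenario {self.id}: {len(extant)} lineages remain after all "
                f"events ({sorted(extant)}); exactly one root expected"
            )
        return next(iter(extant))


@dataclass
class PriorSet:
    """Prior distributions and ordering constraints for scenario parameters.

    ``uniform`` maps a parameter name to its (lo, hi) range. ``constraints``
    is a list of (smaller, larger) parameter-name pairs enforced by rejection.
    Per-locus mutation heterogeneity: locus mutation rates are gamma with
    shape ``mu_shape`` and mean equal to the drawn ``mu_mean``; the geometric
    step parameter analogously with ``p_shape`` (clipped to [0, p_max]).
    """

    uniform: dict[str, tuple[float, float]]
    constraints: list[tuple[str, str]] = field(default_factory=list)
    mu_shape: float = 2.0
    p_shape: float = 2.0
    p_max: float = 0.99
    rejection_cap: int = 1_000_000

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.uniform.items():
            if not lo <= hi:
                raise ConfigError(f"prior {name}: lo {lo} > hi {hi}")
        declared = set(self.uniform)
        for a, b in self.constraints:
            if a not in declared or b not in declared:
                raise ConfigError(f"constraint {a} < {b} references undeclared parameter")


@dataclass
class ParameterDraw:
    """One realisation of all parameters a scenario needs.

    ``values`` holds Ne, event times and admixture proportions plus
    ``mu_mean`` and ``p_mean``; ``mu_l``/``p_l`` are the per-locus vectors.
    """

    scenario_id: int
    values: dict[str, float]
    mu_l: np.ndarray
    p_l: np.ndarray


@dataclass
class ScenarioSet:
    """A parsed configuration: scenarios sharing lineages, priors and loci."""

    scenarios: list[DemographicScenario]
    priors: PriorSet
    loci: list[LocusSpec]

    def get(self, scenario_id: int) -> DemographicScenario:
        for sc in self.scenarios:
            if sc.id == scenario_id:
                return sc
        raise KeyError(f"no scenario with id {scenario_id}")


def generations_to_years(t: float, generation_time: float) -> float:
    """Convert a time in generations to calendar years (t × generation time)."""
    if t < 0:
        raise ValueError("time in generations must be non-negative")
    if generation_time <= 0:
        raise ValueError("generation time must be positive")
    return t * generation_time


# --------------------------------------------------------------------------
# config parsing

_SPLIT_RE = re.compile(r"^split\s+(\w+)\s*:\s*([\w\s]+?)\s*->\s*(\w+)$")
_ADMIX_RE = re.compile(r"^admix\s+(\w+)\s*:\s*(\w+)\s*=\s*(\w+)\s*\*\s*(\w+)\s*\+\s*(\w+)$")


def _parse_sections(text: str) -> list[tuple[str, list[tuple[int, str]]]]:
    sections: list[tuple[str, list[tuple[int, str]]]] = []
    current: list[tuple[int, str]] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = []
            sections.append((line[1:-1].strip().lower(), current))
        elif current is None:
            raise ConfigError(f"line {lineno}: content before any [section] header")
        else:
            current.append((lineno, line))
    return sections


def _parse_chain(expr: str, lineno: int) -> list[tuple[str, str]]:
    parts = [p.strip() for p in expr.split("<")]
    if len(parts) < 2 or any(not p for p in parts):
        raise ConfigError(f"line {lineno}: cannot parse constraint {expr!r}")
    return [(parts[i], parts[i + 1]) for i in range(len(parts) - 1)]


def load_scenario_set(config_text: str) -> ScenarioSet:
    """Parse a scenario-set configuration document.

    The document has sections ``[lineages]``, ``[loci]``, one
    ``[scenario N]`` per scenario, ``[priors]`` and ``[constraints]``; see
    the shipped ``scenarios_caucasus.cfg`` for the full syntax. Every
    scenario is validated (single root, events reference extant lineages)
    against a representative constraint-satisfying time ordering.
    """
    lineages: list[Lineage] = []
    loci_opts: dict[str, str] = {}
    scenario_events: dict[int, list[DemographicEvent]] = {}
    uniform: dict[str, tuple[float, float]] = {}
    gamma_opts: dict[str, float] = {}
    constraints: list[tuple[str, str]] = []

    for name, lines in _parse_sections(config_text):
        if name == "lineages":
            for lineno, line in lines:
                m = re.match(r"^(\w+)\s*:\s*ne\s*=\s*(\w+)\s+sample\s*=\s*(\d+)$", line)
                if not m:
                    raise ConfigError(f"line {lineno}: cannot parse lineage {line!r}")
                lineages.append(Lineage(m.group(1), m.group(2), int(m.group(3))))
        elif name == "loci":
            for lineno, line in lines:
                if "=" not in line:
                    raise ConfigError(f"line {lineno}: expected key = value in [loci]")
                k, v = (s.strip() for s in line.split("=", 1))
                loci_opts[k] = v
        elif name.startswith("scenario"):
            try:
                sid = int(name.split()[1])
            except (IndexError, ValueError) as exc:
                raise ConfigError(f"bad scenario header [{name}]") from exc
            events = scenario_events.setdefault(sid, [])
            for lineno, line in lines:
                m = _SPLIT_RE.match(line)
                if m:
                    derived = tuple(m.group(2).split())
                    events.append(
                        DemographicEvent(
                            kind="split",
                            time_param=m.group(1),
                            derived=derived,
                            ancestor=m.group(3),
                        )
                    )
                    continue
                m = _ADMIX_RE.match(line)
                if m:
                    events.append(
                        DemographicEvent(
                            kind="admixture",
                            time_param=m.group(1),
                            target=m.group(2),
                            source1=m.group(3),
                            ra_param=m.group(4),
                            source2=m.group(5),
                        )
                    )
                    continue
                raise ConfigError(f"line {lineno}: cannot parse event {line!r}")
        elif name == "priors":
            for lineno, line in lines:
                if "=" not in line:
                    raise ConfigError(f"line {lineno}: expected key = value in [priors]")
                k, v = (s.strip() for s in line.split("=", 1))
                toks = v.split()
                if toks[0] == "uniform" and len(toks) == 3:
                    uniform[k] = (float(toks[1]), float(toks[2]))
                elif len(toks) == 1 and k in {"mu_shape", "p_shape", "p_max"}:
                    gamma_opts[k] = float(toks[0])
                else:
                    raise ConfigError(f"line {lineno}: cannot parse prior {line!r}")
        elif name == "constraints":
            for lineno, line in lines:
                constraints.extend(_parse_chain(line, lineno))
        else:
            raise ConfigError(f"unknown section [{name}]")

    if not lineages:
        raise ConfigError("no [lineages] section")
    if not scenario_events:
        raise ConfigError("no [scenario N] sections")

    n_loci = int(loci_opts.get("count", 9))
    anc = int(loci_opts.get("ancestral_size", 20))
    states = int(loci_opts.get("allowed_states", 40))
    motif = int(loci_opts.get("motif", 2))
    loci = [
        LocusSpec(f"L{i + 1}", ancestral_size=anc, allowed_states=states, motif=motif)
        for i in range(n_loci)
    ]

    priors = PriorSet(uniform=uniform, constraints=constraints, **gamma_opts)

    scenarios = []
    for sid in sorted(scenario_events):
        sc = DemographicScenario(id=sid, lineages=list(lineages), events=scenario_events[sid])
        for p in sc.param_names() + ["mu_mean", "p_mean"]:
            if p not in uniform:
                raise ConfigError(f"scenario {sid}: parameter {p!r} has no prior")
        order = _representative_times(sc, priors)
        sc.validate(time_order=order)
        sc.events.sort(key=lambda ev: order[ev.time_param])
        scenarios.append(sc)
    return ScenarioSet(scenarios=scenarios, priors=priors, loci=loci)


def _closure(pairs: list[tuple[str, str]]) -> set[tuple[str, str]]:
    """Transitive closure of the ``<`` relation over constraint pairs."""
    closed = set(pairs)
    changed = True
    while changed:
        changed = False
        for a, b in list(closed):
            for c, d in list(closed):
                if b == c and (a, d) not in closed:
                    if a == d:
                        raise ConfigError(f"cyclic ordering constraint through {a!r}")
                    closed.add((a, d))
                    changed = True
    return closed


def _scenario_constraints(scenario: DemographicScenario, priors: PriorSet) -> list[tuple[str, str]]:
    """Ordering constraints restricted to parameters this scenario draws.

    The transitive closure is taken first so that a chain like ta < t1 < t2
    still implies ta < t2 in a scenario that does not use t1.
    """
    names = set(scenario.param_names())
    return sorted(
        (a, b) for a, b in _closure(priors.constraints) if a in names and b in names
    )


def _representative_times(scenario: DemographicScenario, priors: PriorSet) -> dict[str, float]:
    """A deterministic constraint-satisfying assignment of time parameters.

    Uses midpoints of the uniform ranges, then iteratively nudges values to
    satisfy the ordering constraints (topological adjustment).
    """
    times = {p: 0.5 * sum(priors.uniform[p]) for p in scenario.time_params()}
    cons = [(a, b) for a, b in _scenario_constraints(scenario, priors) if a in times and b in times]
    for _ in range(len(cons) + 1):
        for a, b in cons:
            if times[a] >= times[b]:
                times[a] = times[b] * 0.5
    for a, b in cons:
        if times[a] >= times[b]:
            raise ScenarioValidationError(
                f"scenario {scenario.id}: cannot satisfy ordering {a} < {b}"
            )
    return times


def load_default_scenarios() -> ScenarioSet:
    """Load the shipped eight-scenario Caucasus study design."""
    text = (
        resources.files("msatabc.data").joinpath("scenarios_caucasus.cfg").read_text()
    )
    return load_scenario_set(text)


# --------------------------------------------------------------------------
# sampling

def sample_draw(
    priors: PriorSet,
    scenario: DemographicScenario,
    rng: np.random.Generator,
    n_loci: int = 9,
) -> ParameterDraw:
    """Draw one parameter set for ``scenario`` from ``priors``.

    Scalar parameters come from their uniform priors; ordering constraints
    (restricted to the parameters this scenario uses) are enforced by
    rejection. Per-locus mutation rates ``mu_l`` are gamma distributed with
    shape ``priors.mu_shape`` and mean equal to the drawn ``mu_mean``;
    per-locus geometric parameters ``p_l`` analogously, clipped to
    ``[0, priors.p_max]``.
    """
    names = scenario.param_names() + ["mu_mean", "p_mean"]
    cons = _scenario_constraints(scenario, priors)
    for attempt in range(priors.rejection_cap):
        values = {
            name: rng.uniform(*priors.uniform[name]) if priors.uniform[name][0] < priors.uniform[name][1]
            else priors.uniform[name][0]
            for name in names
        }
        if all(values[a] < values[b] for a, b in cons):
            break
    else:
        raise RuntimeError(
            f"scenario {scenario.id}: no constraint-satisfying draw in "
            f"{priors.rejection_cap} attempts (constraints {cons})"
        )
    mu_mean, p_mean = values["mu_mean"], values["p_mean"]
    mu_l = rng.gamma(priors.mu_shape, mu_mean / priors.mu_shape, size=n_loci)
    if p_mean > 0:
        p_l = rng.gamma(priors.p_shape, p_mean / priors.p_shape, size=n_loci)
    else:
        p_l = np.zeros(n_loci)
    p_l = np.clip(p_l, 0.0, priors.p_max)
    return ParameterDraw(scenario_id=scenario.id, values=values, mu_l=mu_l, p_l=p_l)
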