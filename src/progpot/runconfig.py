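"""Structured-text (YAML) run configuration: parsing and serialization.

A run config bundles a system section (entities, switched terms with
their rules and smoothing), an integrator section, an optional initial
placement section, an optional analysis section, a unit preset and a
single seed.  Parsing is strict: unknown keys are rejected with the
offending location, and the self-reference rule for logic expressions
is enforced at parse time.  ``parse_config(dump_config(rc))`` is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .assembly import Confinement, Entity, System
from .dynamics import IntegratorParams
from .logic import AtomPair, Configuration, pair
from .potentials import Harmonic, Morse, PairPotential, RepulsiveMorse, Tabulated
from .rules import format_logic, parse_logic
from .smoothing import SmoothNear
from .units import get_units

__all__ = [
    "RunConfig",
    "InitialSpec",
    "AnalysisSpec",
    "ConfigError",
    "parse_config",
    "dump_config",
    "initial_configuration",
    "split_seed",
]


class ConfigError(ValueError):
    """Invalid run configuration, with the offending key in the message."""


@dataclass
class InitialSpec:
    kind: str = "random"                  # "random" or "explicit"
    box: float = 10.0
    min_separation: float = 4.0
    preformed: list[tuple[AtomPair, float]] = field(default_factory=list)
    positions: list[list[float]] | None = None


@dataclass
class AnalysisSpec:
    monitor_pairs: list[AtomPair] = field(default_factory=list)
    r_on: float = 2.4
    r_off: float = 4.0


@dataclass
class RunConfig:
    system: System
    integrator: IntegratorParams
    integrator_kind: str = "langevin"     # "langevin" or "verlet"
    initial: InitialSpec = field(default_factory=InitialSpec)
    analysis: AnalysisSpec | None = None
    seed: int = 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RunConfig):
            return NotImplemented
        return (
            self.system == other.system
            and self.integrator == other.integrator
            and self.integrator_kind == other.integrator_kind
            and self.initial == other.initial
            and self.analysis == other.analysis
            and self.seed == other.seed
        )


def _take(mapping: dict, allowed: set[str], required: set[str], where: str) -> dict:
    if not isinstance(mapping, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise ConfigError(f"{where}: missing required key(s) {sorted(missing)}")
    return mapping


def _pair(value, where: str) -> AtomPair:
    if (
        not isinstance(value, (list, tuple))
        or len(value) != 2
        or not all(isinstance(v, int) for v in value)
    ):
        raise ConfigError(f"{where}: a pair is a two-integer list, got {value!r}")
    try:
        return pair(*value)
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from None


def _potential(d: dict, where: str) -> PairPotential:
    _take(d, {"kind", "D", "a", "r_eq", "k", "r0", "r", "phi"}, {"kind"}, where)
    kind = d["kind"]
    try:
        if kind == "morse":
            return Morse(D=d["D"], a=d["a"], r_eq=d["r_eq"])
        if kind == "repulsive_morse":
            return RepulsiveMorse(D=d["D"], a=d["a"], r_eq=d["r_eq"])
        if kind == "harmonic":
            return Harmonic(k=d["k"], r0=d["r0"])
        if kind == "tabulated":
            return Tabulated(d["r"], d["phi"])
    except KeyError as exc:
        raise ConfigError(f"{where}: missing parameter {exc.args[0]!r} for {kind}") from None
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from None
    raise ConfigError(f"{where}: unknown potential kind {kind!r}")


def _potential_dict(p: PairPotential, where: str) -> dict:
    if isinstance(p, Morse):
        return {"kind": "morse", "D": p.D, "a": p.a, "r_eq": p.r_eq}
    if isinstance(p, RepulsiveMorse):
        return {"kind": "repulsive_morse", "D": p.D, "a": p.a, "r_eq": p.r_eq}
    if isinstance(p, Harmonic):
        return {"kind": "harmonic", "k": p.k, "r0": p.r0}
    if isinstance(p, Tabulated):
        return {
            "kind": "tabulated",
            "r": [float(v) for v in p.r_grid],
            "phi": [float(v) for v in p.phi_grid],
        }
    raise ConfigError(f"{where}: cannot serialize potential {type(p).__name__}")


def parse_config(text: str) -> RunConfig:
    """Parse YAML run-config text into validated objects."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"not valid YAML: {exc}") from None
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    _take(
        raw,
        {"units", "seed", "system", "integrator", "initial", "analysis"},
        {"system", "integrator"},
        "config",
    )
    units = get_units(raw.get("units", "reduced"))
    seed = int(raw.get("seed", 0))

    sysd = _take(
        raw["system"],
        {"dim", "force_mode", "confinement", "entities", "terms"},
        {"entities", "terms"},
        "system",
    )
    if not sysd["entities"]:
        raise ConfigError("system.entities: at least one entity is required")

    entities = []
    for k, ed in enumerate(sysd["entities"]):
        where = f"system.entities[{k}]"
        _take(ed, {"name", "particles", "masses", "bonds", "reference"},
              {"name", "particles", "masses"}, where)
        bonds = []
        for bk, bd in enumerate(ed.get("bonds") or []):
            bwhere = f"{where}.bonds[{bk}]"
            _take(bd, {"pair", "k", "r0"}, {"pair", "k", "r0"}, bwhere)
            bonds.append((_pair(bd["pair"], bwhere), Harmonic(k=bd["k"], r0=bd["r0"])))
        ref = ed.get("reference")
        try:
            entities.append(
                Entity(
                    name=str(ed["name"]),
                    particles=tuple(ed["particles"]),
                    masses=tuple(ed["masses"]),
                    bonds=tuple(bonds),
                    reference=tuple(tuple(row) for row in ref) if ref else None,
                )
            )
        except ValueError as exc:
            raise ConfigError(f"{where}: {exc}") from None

    confinement = None
    if sysd.get("confinement") is not None:
        cd = _take(sysd["confinement"], {"k", "radius", "center"}, {"k", "radius"},
                   "system.confinement")
        confinement = Confinement(
            k=float(cd["k"]),
            radius=float(cd["radius"]),
            center=tuple(cd["center"]) if cd.get("center") else None,
        )

    try:
        system = System(
            entities=entities,
            dim=int(sysd.get("dim", 2)),
            force_mode=sysd.get("force_mode", "full"),
            confinement=confinement,
            units=units,
        )
    except ValueError as exc:
        raise ConfigError(f"system: {exc}") from None
    if system.force_mode not in ("full", "frozen_switch"):
        raise ConfigError(f"system.force_mode: unknown mode {system.force_mode!r}")

    for k, td in enumerate(sysd["terms"]):
        where = f"system.terms[{k}]"
        _take(td, {"pair", "potential", "logic", "n", "n_overrides"},
              {"pair", "potential", "logic"}, where)
        p = _pair(td["pair"], where)
        pot = _potential(td["potential"], f"{where}.potential")
        try:
            logic = parse_logic(str(td["logic"]))
        except ValueError as exc:
            raise ConfigError(f"{where}.logic: {exc}") from None
        overrides = {}
        for ok_, od in enumerate(td.get("n_overrides") or []):
            owhere = f"{where}.n_overrides[{ok_}]"
            _take(od, {"pair", "n"}, {"pair", "n"}, owhere)
            overrides[_pair(od["pair"], owhere)] = int(od["n"])
        try:
            system.add_term(p, pot, logic, n_default=int(td.get("n", 6)),
                            n_overrides=overrides or None)
        except ValueError as exc:
            raise ConfigError(f"{where}: {exc}") from None

    intd = _take(
        raw["integrator"],
        {"kind", "dt", "n_steps", "temperature", "friction", "stride", "force_mode"},
        {"dt", "n_steps"},
        "integrator",
    )
    integrator_kind = intd.get("kind", "langevin")
    if integrator_kind not in ("langevin", "verlet"):
        raise ConfigError(f"integrator.kind: unknown integrator {integrator_kind!r}")
    try:
        integrator = IntegratorParams(
            dt=float(intd["dt"]),
            n_steps=int(intd["n_steps"]),
            temperature=float(intd.get("temperature", 1.0)),
            friction=float(intd.get("friction", 1.0)),
            seed=seed,
            force_mode=intd.get("force_mode"),
            stride=int(intd.get("stride", 10)),
        )
    except ValueError as exc:
        raise ConfigError(f"integrator: {exc}") from None

    initial = InitialSpec()
    if raw.get("initial") is not None:
        ind = _take(
            raw["initial"],
            {"kind", "box", "min_separation", "preformed", "positions"},
            set(),
            "initial",
        )
        kind = ind.get("kind", "random")
        if kind not in ("random", "explicit"):
            raise ConfigError(f"initial.kind: unknown kind {kind!r}")
        preformed = []
        for pk, pd in enumerate(ind.get("preformed") or []):
            pwhere = f"initial.preformed[{pk}]"
            _take(pd, {"pair", "r"}, {"pair", "r"}, pwhere)
            preformed.append((_pair(pd["pair"], pwhere), float(pd["r"])))
        positions = ind.get("positions")
        if kind == "explicit" and positions is None:
            raise ConfigError("initial.positions: required for kind 'explicit'")
        initial = InitialSpec(
            kind=kind,
            box=float(ind.get("box", 10.0)),
            min_separation=float(ind.get("min_separation", 4.0)),
            preformed=preformed,
            positions=[[float(c) for c in row] for row in positions]
            if positions is not None
            else None,
        )

    analysis = None
    if raw.get("analysis") is not None:
        and_ = _take(raw["analysis"], {"monitor_pairs", "r_on", "r_off"}, set(),
                     "analysis")
        analysis = AnalysisSpec(
            monitor_pairs=[
                _pair(v, f"analysis.monitor_pairs[{k}]")
                for k, v in enumerate(and_.get("monitor_pairs") or [])
            ],
            r_on=float(and_.get("r_on", 2.4)),
            r_off=float(and_.get("r_off", 4.0)),
        )
        if analysis.r_off <= analysis.r_on:
            raise ConfigError("analysis: r_off must exceed r_on")

    return RunConfig(
        system=system,
        integrator=integrator,
        integrator_kind=integrator_kind,
        initial=initial,
        analysis=analysis,
        seed=seed,
    )


def _term_smoothing(term) -> tuple[int, list[dict]]:
    """Recover (n_default, overrides) from a compiled encoding tree."""
    ns: dict[AtomPair, int] = {}
    stack = [term.encoding]
    while stack:
        node = stack.pop()
        if isinstance(node, SmoothNear):
            ns[node.pair] = node.spec.n
        elif hasattr(node, "terms"):
            stack.extend(node.terms)
        elif hasattr(node, "term"):
            stack.append(node.term)
    if not ns:
        return 6, []
    values = list(ns.values())
    n_default = max(set(values), key=values.count)
    overrides = [
        {"pair": [q.i, q.j], "n": n}
        for q, n in sorted(ns.items())
        if n != n_default
    ]
    return n_default, overrides


def dump_config(rc: RunConfig) -> str:
    """Serialize a run config back to YAML text."""
    system = rc.system
    sysd: dict = {"dim": system.dim, "force_mode": system.force_mode}
    if system.confinement is not None:
        c = system.confinement
        cd = {"k": c.k, "radius": c.radius}
        if c.center is not None:
            cd["center"] = list(c.center)
        sysd["confinement"] = cd
    sysd["entities"] = []
    for ent in system.entities:
        ed: dict = {
            "name": ent.name,
            "particles": list(ent.particles),
            "masses": list(ent.masses),
        }
        if ent.bonds:
            ed["bonds"] = [
                {"pair": [p.i, p.j], "k": b.k, "r0": b.r0} for p, b in ent.bonds
            ]
        if ent.reference is not None:
            ed["reference"] = [list(row) for row in ent.reference]
        sysd["entities"].append(ed)
    sysd["terms"] = []
    for t in system.terms:
        n_default, overrides = _term_smoothing(t)
        td: dict = {
            "pair": [t.pair.i, t.pair.j],
            "potential": _potential_dict(t.potential, t.label),
            "logic": format_logic(t.logic),
            "n": n_default,
        }
        if overrides:
            td["n_overrides"] = overrides
        sysd["terms"].append(td)

    intd = {
        "kind": rc.integrator_kind,
        "dt": rc.integrator.dt,
        "n_steps": rc.integrator.n_steps,
        "temperature": rc.integrator.temperature,
        "friction": rc.integrator.friction,
        "stride": rc.integrator.stride,
    }
    if rc.integrator.force_mode is not None:
        intd["force_mode"] = rc.integrator.force_mode

    out: dict = {
        "units": system.units.name,
        "seed": rc.seed,
        "system": sysd,
        "integrator": intd,
    }
    ind: dict = {"kind": rc.initial.kind}
    if rc.initial.kind == "explicit":
        ind["positions"] = rc.initial.positions
    else:
        ind["box"] = rc.initial.box
        ind["min_separation"] = rc.initial.min_separation
        if rc.initial.preformed:
            ind["preformed"] = [
                {"pair": [p.i, p.j], "r": r} for p, r in rc.initial.preformed
            ]
    out["initial"] = ind
    if rc.analysis is not None:
        out["analysis"] = {
            "monitor_pairs": [[p.i, p.j] for p in rc.analysis.monitor_pairs],
            "r_on": rc.analysis.r_on,
            "r_off": rc.analysis.r_off,
        }
    return yaml.safe_dump(out, sort_keys=False, default_flow_style=None)


def split_seed(seed: int) -> tuple[int, int]:
    """Derive independent (placement, integration) seeds from the config seed."""
    children = np.random.SeedSequence(seed).spawn(2)
    return tuple(int(c.generate_state(1)[0] % (2**31)) for c in children)


def initial_configuration(rc: RunConfig) -> Configuration:
    """Build the starting configuration a run config describes."""
    from .examples import random_initial_config

    if rc.initial.kind == "explicit":
        pos = np.asarray(rc.initial.positions, dtype=float)
        return Configuration(pos)
    placement_seed, _ = split_seed(rc.seed)
    return random_initial_config(
        rc.system,
        box=rc.initial.box,
        min_separation=rc.initial.min_separation,
        seed=placement_seed,
        preformed=rc.initial.preformed,
    )
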