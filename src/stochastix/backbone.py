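"""Module networks ("backbones") and their state networks.

A backbone is the coarse blueprint of a simulated dynamic process: a small
network of gene *modules* connected by signed regulatory interactions, plus a
*state network* describing which modules switch on or off along each
transition of the process.  Modules marked ``burn`` establish expression
during an initial warm-up phase from which no cells are ever sampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Module",
    "ModuleInteraction",
    "StateEdge",
    "Backbone",
    "predefined_backbone",
    "list_backbones",
    "validate_backbone",
]


@dataclass(frozen=True)
class Module:
    """A gene module: a set of co-regulated transcription factors.

    Parameters
    ----------
    name:
        Unique module identifier.
    basal:
        Basal expression strength in [0, 1]: how strongly genes of this
        module are transcribed with no transcription factor bound.
    burn:
        Whether the module is active during the burn (warm-up) phase.
    """

    name: str
    basal: float = 0.0
    burn: bool = False


@dataclass(frozen=True)
class ModuleInteraction:
    """Signed regulatory interaction between two modules.

    ``effect`` is +1 (upregulating) or -1 (downregulating); ``strength`` is a
    positive integer scaling how sensitive the target is to the regulator.
    """

    from_module: str
    to_module: str
    effect: int = 1
    strength: int = 1


@dataclass(frozen=True)
class StateEdge:
    """A transition of the state network.

    ``modules_on`` / ``modules_off`` list the modules whose regulation is
    switched on / off while traversing this edge; ``length`` is the relative
    duration (geodesic length) of the transition.
    """

    from_state: str
    to_state: str
    modules_on: frozenset[str] = frozenset()
    modules_off: frozenset[str] = frozenset()
    length: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules_on", frozenset(self.modules_on))
        object.__setattr__(self, "modules_off", frozenset(self.modules_off))

    @property
    def key(self) -> str:
        return f"{self.from_state}->{self.to_state}"


@dataclass
class Backbone:
    """A module network plus its ground-truth state network."""

    name: str
    modules: list[Module]
    module_interactions: list[ModuleInteraction]
    state_network: list[StateEdge]
    start_state: str

    @property
    def module_names(self) -> list[str]:
        return [m.name for m in self.modules]

    def module(self, name: str) -> Module:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "start_state": self.start_state,
            "modules": [
                {"name": m.name, "basal": m.basal, "burn": m.burn}
                for m in self.modules
            ],
            "module_interactions": [
                {
                    "from": i.from_module,
                    "to": i.to_module,
                    "effect": i.effect,
                    "strength": i.strength,
                }
                for i in self.module_interactions
            ],
            "state_network": [
                {
                    "from": e.from_state,
                    "to": e.to_state,
                    "on": sorted(e.modules_on),
                    "off": sorted(e.modules_off),
                    "length": e.length,
                }
                for e in self.state_network
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Backbone":
        return cls(
            name=d.get("name", "custom"),
            modules=[
                Module(m["name"], float(m.get("basal", 0.0)), bool(m.get("burn", False)))
                for m in d["modules"]
            ],
            module_interactions=[
                ModuleInteraction(
                    i["from"], i["to"], int(i.get("effect", 1)), int(i.get("strength", 1))
                )
                for i in d["module_interactions"]
            ],
            state_network=[
                StateEdge(
                    e["from"],
                    e["to"],
                    frozenset(e.get("on", [])),
                    frozenset(e.get("off", [])),
                    float(e.get("length", 1.0)),
                )
                for e in d["state_network"]
            ],
            start_state=d["start_state"],
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Backbone":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    # ------------------------------------------------------------------
    # derived structure
    # ------------------------------------------------------------------
    def burn_modules(self) -> set[str]:
        return {m.name for m in self.modules if m.burn}

    def state_module_sets(self) -> dict[str, set[str]]:
        """Active-module set of every state, propagated from ``start_state``.

        The start state carries the burn modules; traversing an edge adds its
        ``modules_on`` and removes its ``modules_off``.
        """
        active: dict[str, set[str]] = {self.start_state: set(self.burn_modules())}
        frontier = [self.start_state]
        edges_by_src: dict[str, list[StateEdge]] = {}
        for e in self.state_network:
            edges_by_src.setdefault(e.from_state, []).append(e)
        while frontier:
            s = frontier.pop()
            for e in edges_by_src.get(s, []):
                nxt = (active[s] | e.modules_on) - e.modules_off
                if e.to_state not in active:
                    active[e.to_state] = nxt
                    frontier.append(e.to_state)
        return active


def validate_backbone(b: Backbone) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    violations: list[str] = []
    names = [m.name for m in b.modules]
    if len(set(names)) != len(names):
        violations.append("module names are not unique")
    nameset = set(names)
    for m in b.modules:
        if not 0.0 <= m.basal <= 1.0:
            violations.append(f"module {m.name}: basal {m.basal} outside [0, 1]")
    for i in b.module_interactions:
        if i.effect not in (1, -1):
            violations.append(f"interaction {i.from_module}->{i.to_module}: effect must be +1/-1")
        if not (isinstance(i.strength, int) and i.strength >= 1):
            violations.append(
                f"interaction {i.from_module}->{i.to_module}: strength must be a positive integer"
            )
        for end in (i.from_module, i.to_module):
            if end not in nameset:
                violations.append(f"interaction references unknown module {end!r}")
    states = {b.start_state}
    for e in b.state_network:
        states.update((e.from_state, e.to_state))
        if e.modules_on & e.modules_off:
            violations.append(f"state edge {e.key}: modules_on and modules_off overlap")
        if not e.length > 0:
            violations.append(f"state edge {e.key}: length must be > 0")
        for m in e.modules_on | e.modules_off:
            if m not in nameset:
                violations.append(f"state edge {e.key} references unknown module {m!r}")
    # connectivity from start_state
    reached = {b.start_state}
    changed = True
    while changed:
        changed = False
        for e in b.state_network:
            if e.from_state in reached and e.to_state not in reached:
                reached.add(e.to_state)
                changed = True
    unreachable = states - reached
    if unreachable:
        violations.append(
            "states not reachable from start_state: " + ", ".join(sorted(unreachable))
        )
    return violations


# ----------------------------------------------------------------------
# catalogue construction helpers
# ----------------------------------------------------------------------

def _chain_modules(names: Sequence[str], burn_first: bool = True) -> tuple[list, list]:
    """Linear chain of modules, each upregulating the next; the first module
    has basal expression 1 and is active during burn."""
    modules = [Module(names[0], basal=1.0, burn=burn_first)]
    modules += [Module(n) for n in names[1:]]
    inter = [
        ModuleInteraction(a, b, effect=1, strength=1)
        for a, b in zip(names[:-1], names[1:])
    ]
    return modules, inter


def _chain_states(names: Sequence[str], prefix: str = "S") -> list[StateEdge]:
    """State network turning on one chain module per transition."""
    return [
        StateEdge(f"{prefix}{i}", f"{prefix}{i + 1}", modules_on={names[i + 1]})
        for i in range(len(names) - 1)
    ]


def _mutual_repression(a: str, b: str, strength: int = 4) -> list[ModuleInteraction]:
    return [
        ModuleInteraction(a, b, effect=-1, strength=strength),
        ModuleInteraction(b, a, effect=-1, strength=strength),
    ]


def _bb_linear(num_modules: int = 5) -> Backbone:
    names = [f"M{i + 1}" for i in range(num_modules)]
    modules, inter = _chain_modules(names)
    return Backbone("linear", modules, inter, _chain_states(names), "S0")


def _bb_linear_simple() -> Backbone:
    b = _bb_linear(3)
    b.name = "linear_simple"
    return b


def _bb_cyclic(num_modules: int = 4) -> Backbone:
    names = [f"M{i + 1}" for i in range(num_modules)]
    modules, inter = _chain_modules(names)
    # the last module represses the first, resetting the cycle
    inter.append(ModuleInteraction(names[-1], names[0], effect=-1, strength=2))
    states = _chain_states(names)
    # closing edge: everything but the basal module switches off
    states[-1] = StateEdge(
        states[-1].from_state, states[-1].to_state,
        modules_on={names[-1]}, modules_off={names[0]},
    )
    states.append(
        StateEdge(
            f"S{num_modules - 1}", "S0",
            modules_on={names[0]}, modules_off=set(names[1:]),
        )
    )
    return Backbone("cyclic", modules, inter, states, "S0")


def _bb_cycle_simple() -> Backbone:
    b = _bb_cyclic(3)
    b.name = "cycle_simple"
    return b


def _branch(stem: str, label: str, depth: int) -> list[str]:
    return [f"{stem}{label}{i + 1}" for i in range(depth)]


def _bb_bifurcating(depth: int = 2) -> Backbone:
    """Chain into two mutually repressing fate modules, each with a
    downstream chain (mutual antagonism drives the fate decision)."""
    stem = ["M1", "M2"]
    a = _branch("A", "", depth + 1)
    b = _branch("B", "", depth + 1)
    modules, inter = _chain_modules(stem)
    modules += [Module(n) for n in a + b]
    inter += [ModuleInteraction("M2", a[0]), ModuleInteraction("M2", b[0])]
    inter += _mutual_repression(a[0], b[0])
    for chain in (a, b):
        inter += [ModuleInteraction(x, y) for x, y in zip(chain[:-1], chain[1:])]
    states = [StateEdge("S0", "S1", modules_on={"M2"})]
    for lbl, chain, other in (("A", a, b), ("B", b, a)):
        states.append(
            StateEdge("S1", f"{lbl}1", modules_on={chain[0]}, modules_off={other[0]})
        )
        for i in range(1, len(chain)):
            states.append(
                StateEdge(f"{lbl}{i}", f"{lbl}{i + 1}", modules_on={chain[i]})
            )
    return Backbone("bifurcating", modules, inter, states, "S0")


def _bb_converging() -> Backbone:
    """A fate decision during the burn phase, after which both branches
    converge onto the same downstream programme."""
    modules = [
        Module("M1", basal=1.0, burn=True),
        Module("A1", basal=0.5, burn=True),
        Module("B1", basal=0.5, burn=True),
        Module("C1"),
        Module("C2"),
        Module("C3"),
    ]
    inter = (
        [ModuleInteraction("M1", "A1"), ModuleInteraction("M1", "B1")]
        + _mutual_repression("A1", "B1")
        + [
            ModuleInteraction("A1", "C1"),
            ModuleInteraction("B1", "C1"),
            ModuleInteraction("C1", "C2"),
            ModuleInteraction("C2", "C3"),
        ]
    )
    states = [
        StateEdge("S0", "S1", modules_on={"C1"}, modules_off={"A1", "B1"}),
        StateEdge("S1", "S2", modules_on={"C2"}),
        StateEdge("S2", "S3", modules_on={"C3"}),
    ]
    return Backbone("converging", modules, inter, states, "S0")


def _bb_disconnected() -> Backbone:
    """Two regulatorily independent programmes; cells commit to one of them
    straight from the start state, yielding disconnected expression manifolds."""
    a = ["A1", "A2", "A3"]
    b = ["B1", "B2", "B3"]
    modules = [Module(a[0], basal=1.0, burn=True), Module(b[0], basal=1.0, burn=True)]
    modules += [Module(n) for n in a[1:] + b[1:]]
    inter = [ModuleInteraction(x, y) for x, y in zip(a[:-1], a[1:])]
    inter += [ModuleInteraction(x, y) for x, y in zip(b[:-1], b[1:])]
    states = [
        StateEdge("S0", "A1s", modules_on={"A2"}, modules_off={"B1"}),
        StateEdge("A1s", "A2s", modules_on={"A3"}),
        StateEdge("S0", "B1s", modules_on={"B2"}, modules_off={"A1"}),
        StateEdge("B1s", "B2s", modules_on={"B3"}),
    ]
    return Backbone("disconnected", modules, inter, states, "S0")


def _bb_bifurcating_cycle() -> Backbone:
    """A bifurcation in which one fate loops back to the decision state."""
    bb = _bb_bifurcating(depth=1)
    bb.name = "bifurcating_cycle"
    # branch A returns to the decision state S1
    bb.module_interactions.append(ModuleInteraction("A2", "M2", effect=-1, strength=2))
    bb.state_network.append(
        StateEdge("A2", "S1", modules_on=set(), modules_off={"A1", "A2"})
    )
    return bb


def _bb_bifurcating_loop() -> Backbone:
    """A bifurcation in which one fate loops back to the trajectory start."""
    bb = _bb_bifurcating(depth=1)
    bb.name = "bifurcating_loop"
    bb.module_interactions.append(ModuleInteraction("A2", "M2", effect=-1, strength=2))
    bb.state_network.append(
        StateEdge("A2", "S0", modules_on=set(), modules_off={"M2", "A1", "A2"})
    )
    return bb


def _bb_bifurcating_converging() -> Backbone:
    bb = _bb_bifurcating(depth=1)
    bb.name = "bifurcating_converging"
    bb.modules.append(Module("C1"))
    bb.module_interactions += [
        ModuleInteraction("A2", "C1"),
        ModuleInteraction("B2", "C1"),
    ]
    bb.state_network += [
        StateEdge("A2", "SF", modules_on={"C1"}, modules_off={"A1", "A2"}),
        StateEdge("B2", "SF", modules_on={"C1"}, modules_off={"B1", "B2"}),
    ]
    return bb


def _bb_trifurcating() -> Backbone:
    stem = ["M1", "M2"]
    fates = ["A1", "B1", "C1"]
    tails = {"A1": "A2", "B1": "B2", "C1": "C2"}
    modules, inter = _chain_modules(stem)
    modules += [Module(n) for n in fates + list(tails.values())]
    for f in fates:
        inter.append(ModuleInteraction("M2", f))
        inter.append(ModuleInteraction(f, tails[f]))
        for g in fates:
            if g != f:
                inter.append(ModuleInteraction(f, g, effect=-1, strength=4))
    states = [StateEdge("S0", "S1", modules_on={"M2"})]
    for f in fates:
        others = {g for g in fates if g != f}
        states.append(StateEdge("S1", f"{f}s", modules_on={f}, modules_off=others))
        states.append(StateEdge(f"{f}s", f"{tails[f]}s", modules_on={tails[f]}))
    return Backbone("trifurcating", modules, inter, states, "S0")


def _bb_binary_tree() -> Backbone:
    """Two consecutive fate decisions: a bifurcation on each branch."""
    bb = _bb_bifurcating(depth=1)
    bb.name = "binary_tree"
    for parent, lbl in (("A2", "A"), ("B2", "B")):
        x, y = f"{lbl}L", f"{lbl}R"
        bb.modules += [Module(x), Module(y)]
        bb.module_interactions += [
            ModuleInteraction(parent, x),
            ModuleInteraction(parent, y),
        ]
        bb.module_interactions += _mutual_repression(x, y)
        bb.state_network += [
            StateEdge(parent, f"{x}s", modules_on={x}, modules_off={y}),
            StateEdge(parent, f"{y}s", modules_on={y}, modules_off={x}),
        ]
    return bb


def _bb_consecutive_bifurcating() -> Backbone:
    """A bifurcation followed by a second bifurcation on one branch only."""
    bb = _bb_bifurcating(depth=1)
    bb.name = "consecutive_bifurcating"
    bb.modules += [Module("AL"), Module("AR")]
    bb.module_interactions += [
        ModuleInteraction("A2", "AL"),
        ModuleInteraction("A2", "AR"),
    ]
    bb.module_interactions += _mutual_repression("AL", "AR")
    bb.state_network += [
        StateEdge("A2", "ALs", modules_on={"AL"}, modules_off={"AR"}),
        StateEdge("A2", "ARs", modules_on={"AR"}, modules_off={"AL"}),
    ]
    return bb


def _bb_branching() -> Backbone:
    """Immediate fate decision from the start state, no shared stem."""
    modules = [Module("M1", basal=1.0, burn=True)]
    inter: list[ModuleInteraction] = []
    states: list[StateEdge] = []
    for lbl in ("A", "B", "C"):
        chain = [f"{lbl}1", f"{lbl}2"]
        modules += [Module(n) for n in chain]
        inter.append(ModuleInteraction("M1", chain[0]))
        inter.append(ModuleInteraction(chain[0], chain[1]))
        others = {f"{o}1" for o in "ABC" if o != lbl}
        states.append(StateEdge("S0", f"{lbl}1s", modules_on={chain[0]}, modules_off=others))
        states.append(StateEdge(f"{lbl}1s", f"{lbl}2s", modules_on={chain[1]}))
    for lbl in ("A", "B", "C"):
        for o in ("A", "B", "C"):
            if o != lbl:
                inter.append(ModuleInteraction(f"{lbl}1", f"{o}1", effect=-1, strength=4))
    return Backbone("branching", modules, inter, states, "S0")


_CATALOGUE = {
    "linear": _bb_linear,
    "linear_simple": _bb_linear_simple,
    "cyclic": _bb_cyclic,
    "cycle_simple": _bb_cycle_simple,
    "bifurcating": _bb_bifurcating,
    "bifurcating_converging": _bb_bifurcating_converging,
    "bifurcating_cycle": _bb_bifurcating_cycle,
    "bifurcating_loop": _bb_bifurcating_loop,
    "binary_tree": _bb_binary_tree,
    "branching": _bb_branching,
    "consecutive_bifurcating": _bb_consecutive_bifurcating,
    "converging": _bb_converging,
    "disconnected": _bb_disconnected,
    "trifurcating": _bb_trifurcating,
}


def list_backbones() -> list[str]:
    """Names of the predefined backbones in the catalogue."""
    return sorted(_CATALOGUE)


def predefined_backbone(name: str, **params) -> Backbone:
    """Build a predefined backbone by name.

    ``params`` are forwarded to the constructor where supported (e.g.
    ``num_modules`` for ``linear`` and ``cyclic``). Deterministic per
    (name, params).
    """
    try:
        factory = _CATALOGUE[name]
    except KeyError:
        raise ValueError(
            f"unknown backbone {name!r}; available: {', '.join(list_backbones())}"
        ) from None
    return factory(**params)
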