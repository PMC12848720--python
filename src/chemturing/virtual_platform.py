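"""Digital twin of a Chemputer-style liquid-handling platform.

The platform is a set of vessels (vials, reagent stock flasks, a waste
container) connected through a backbone of pumps and valves.  Vessels hold
colored solutions; a virtual camera reads the dominant color of a vial, and
virtual probes read temperature, pH and volume.  This is the physical
substrate on which compiled chemical programs run: a row of tape vials, a row
of head-marker vials and two state vials encode a Turing-machine
configuration as liquid colors.

Volumes are tracked with :class:`decimal.Decimal` so that conservation of
liquid is exact and testable with equality; no binary floating-point drift
can accumulate over long runs.

All mutating operations are transactional: every precondition is checked
before the first drop moves, so a failed operation leaves the state exactly
as it was.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Mapping

import networkx as nx
import yaml

# -- fixed conventions -------------------------------------------------------

#: Colors a solution may have.  ``white`` is reserved: it denotes the absence
#: of liquid (an empty vial) and is never a solution color.
SOLUTION_COLORS = ("orange", "blue", "green")
WHITE = "white"

#: A vial whose total content is below this volume reads ``white`` on the
#: camera (real cameras have a detection floor; this also makes
#: empty-after-drain robust to any residue accounting).
DETECTION_THRESHOLD = Decimal("0.1")

#: Volume written per tape/head/state write, and default vial capacity.
UNIT_VOLUME = Decimal("1.0")
VIAL_CAPACITY = Decimal("10")
DEFAULT_STOCK_VOLUME = Decimal("50")

QUANTITIES = ("color", "temperature", "pH", "volume")


class PlatformError(Exception):
    """Base class for runtime failures of the virtual platform."""


class UnknownVesselError(PlatformError):
    pass


class InsufficientVolumeError(PlatformError):
    pass


class CapacityError(PlatformError):
    pass


class UnreachableError(PlatformError):
    pass


class SensorError(PlatformError):
    pass


@dataclass(frozen=True)
class Solution:
    """A liquid reagent identified by id and its (single, stable) color."""

    id: str
    color: str

    def __post_init__(self) -> None:
        if self.color not in SOLUTION_COLORS:
            raise ValueError(f"invalid solution color {self.color!r}")


@dataclass
class Vessel:
    """A container on the platform.

    ``capacity`` is in mL; ``None`` means unbounded (the waste container).
    ``contents`` maps solution id -> volume (mL, Decimal, > 0).
    """

    id: str
    capacity: Decimal | None = VIAL_CAPACITY
    contents: dict[str, Decimal] = field(default_factory=dict)
    temperature: float = 25.0
    ph: float = 7.0

    def total_volume(self) -> Decimal:
        return sum(self.contents.values(), Decimal(0))

    def free_capacity(self) -> Decimal | None:
        if self.capacity is None:
            return None
        return self.capacity - self.total_volume()


@dataclass(frozen=True)
class SensorReading:
    vessel: str
    quantity: str
    value: object  # color label, °C, pH units or mL


WASTE_ID = "waste"


class PlatformState:
    """Vessels, reagent stocks, waste and the pump/valve backbone graph."""

    def __init__(
        self,
        vessels: Iterable[Vessel],
        solutions: Iterable[Solution],
        graph: nx.Graph,
        waste_id: str = WASTE_ID,
    ) -> None:
        self.vessels: dict[str, Vessel] = {v.id: v for v in vessels}
        self.solutions: dict[str, Solution] = {s.id: s for s in solutions}
        self.graph = graph
        self.waste_id = waste_id
        self.event_counter = 0
        if waste_id not in self.vessels:
            raise ValueError(f"waste vessel {waste_id!r} not declared")
        if self.vessels[waste_id].capacity is not None:
            raise ValueError("waste capacity must be unbounded")
        for v in self.vessels.values():
            for sol_id, vol in v.contents.items():
                if sol_id not in self.solutions:
                    raise ValueError(f"unknown solution {sol_id!r} in {v.id}")
                if vol <= 0:
                    raise ValueError(f"non-positive content volume in {v.id}")

    # -- introspection helpers ----------------------------------------------

    def vessel(self, vessel_id: str) -> Vessel:
        try:
            return self.vessels[vessel_id]
        except KeyError:
            raise UnknownVesselError(f"unknown vessel {vessel_id!r}") from None

    def stock_for(self, color: str) -> Vessel:
        vid = f"stock_{color}"
        if vid not in self.vessels:
            raise UnknownVesselError(f"no stock flask for color {color!r}")
        return self.vessels[vid]

    def connected(self, a: str, b: str) -> bool:
        if a not in self.graph or b not in self.graph:
            return False
        return nx.has_path(self.graph, a, b)

    def total_liquid(self) -> Decimal:
        return sum((v.total_volume() for v in self.vessels.values()), Decimal(0))

    def snapshot(self) -> dict:
        """A plain-data copy of the full liquid state, for exact comparison."""
        return {
            vid: {
                "contents": dict(v.contents),
                "temperature": v.temperature,
                "ph": v.ph,
            }
            for vid, v in sorted(self.vessels.items())
        }


# -- operations --------------------------------------------------------------


def transfer(state: PlatformState, src: str, dst: str, volume: Decimal) -> PlatformState:
    """Move ``volume`` mL from ``src`` to ``dst`` through the backbone.

    Solution proportions are preserved; total liquid on the platform is
    conserved exactly.  Transactional: any error leaves the state untouched.
    """
    volume = Decimal(volume)
    if volume <= 0:
        raise PlatformError(f"transfer volume must be positive, got {volume}")
    if src == dst:
        raise PlatformError(f"cannot transfer {src!r} onto itself")
    source = state.vessel(src)
    dest = state.vessel(dst)
    if not state.connected(src, dst):
        raise UnreachableError(f"no backbone path between {src!r} and {dst!r}")
    total = source.total_volume()
    if total < volume:
        raise InsufficientVolumeError(
            f"{src!r} holds {total} mL, cannot draw {volume} mL"
        )
    free = dest.free_capacity()
    if free is not None and free < volume:
        raise CapacityError(f"{dst!r} has {free} mL free, cannot accept {volume} mL")
    # all checks passed -- now mutate
    if total == volume:
        moved = dict(source.contents)
        source.contents.clear()
    else:
        moved = {}
        frac = volume / total
        drawn = Decimal(0)
        items = list(source.contents.items())
        for i, (sol_id, vol) in enumerate(items):
            part = vol * frac if i < len(items) - 1 else volume - drawn
            drawn += part
            if part > 0:
                moved[sol_id] = part
                remaining = vol - part
                if remaining > 0:
                    source.contents[sol_id] = remaining
                else:
                    del source.contents[sol_id]
    for sol_id, vol in moved.items():
        dest.contents[sol_id] = dest.contents.get(sol_id, Decimal(0)) + vol
    state.event_counter += 1
    return state


def empty_to_waste(state: PlatformState, vessel_id: str) -> PlatformState:
    """Drain a vessel completely into the waste.  Emptying an empty vessel
    is a no-op."""
    vessel = state.vessel(vessel_id)
    if vessel_id == state.waste_id:
        raise PlatformError("cannot empty the waste into itself")
    total = vessel.total_volume()
    if total == 0:
        state.event_counter += 1
        return state
    return transfer(state, vessel_id, state.waste_id, total)


def add_from_stock(
    state: PlatformState, color: str, vessel_id: str, volume: Decimal = UNIT_VOLUME
) -> PlatformState:
    """Dispense ``volume`` mL of the stock solution of a given color."""
    if color not in SOLUTION_COLORS:
        raise PlatformError(f"no stock of color {color!r}")
    stock = state.stock_for(color)
    state.vessel(vessel_id)  # raise UnknownVesselError before touching stock
    return transfer(state, stock.id, vessel_id, Decimal(volume))


def sense(state: PlatformState, vessel_id: str, quantity: str) -> SensorReading:
    """Read a virtual sensor.  Pure: never mutates the state.

    ``color`` is the dominant solution color by volume; a vessel whose total
    volume is below :data:`DETECTION_THRESHOLD` reads ``white``.  Volume ties
    are broken by lexicographically smallest color label so readings are
    reproducible.
    """
    vessel = state.vessel(vessel_id)
    if quantity == "color":
        total = vessel.total_volume()
        if total < DETECTION_THRESHOLD:
            return SensorReading(vessel_id, quantity, WHITE)
        by_color: dict[str, Decimal] = {}
        for sol_id, vol in vessel.contents.items():
            color = state.solutions[sol_id].color
            by_color[color] = by_color.get(color, Decimal(0)) + vol
        # largest volume wins; ties broken by smallest color label
        dominant = sorted(by_color.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        return SensorReading(vessel_id, quantity, dominant)
    if quantity == "temperature":
        return SensorReading(vessel_id, quantity, vessel.temperature)
    if quantity == "pH":
        return SensorReading(vessel_id, quantity, vessel.ph)
    if quantity == "volume":
        return SensorReading(vessel_id, quantity, float(vessel.total_volume()))
    raise SensorError(f"unknown quantity {quantity!r}")


# -- platform construction ---------------------------------------------------


def default_platform(
    tape_length: int = 8,
    stock_volume: Decimal = DEFAULT_STOCK_VOLUME,
    vial_capacity: Decimal = VIAL_CAPACITY,
) -> PlatformState:
    """The standard rig: a tape row and a head row of ``tape_length`` vials,
    two state vials, one stock flask per color, waste, and a backbone of
    three pumps and five valves with full reachability.
    """
    vessels: list[Vessel] = []
    solutions = [Solution(c, c) for c in SOLUTION_COLORS]
    for i in range(1, tape_length + 1):
        vessels.append(Vessel(f"tape_{i}", capacity=vial_capacity))
        vessels.append(Vessel(f"head_{i}", capacity=vial_capacity))
    vessels.append(Vessel("state_1", capacity=vial_capacity))
    vessels.append(Vessel("state_2", capacity=vial_capacity))
    for c in SOLUTION_COLORS:
        vol = Decimal(stock_volume)
        vessels.append(Vessel(f"stock_{c}", capacity=vol, contents={c: vol}))
    vessels.append(Vessel(WASTE_ID, capacity=None))

    graph = nx.Graph()
    pumps = [f"pump_{i}" for i in (1, 2, 3)]
    valves = [f"valve_{i}" for i in (1, 2, 3, 4, 5)]
    graph.add_nodes_from(pumps)
    graph.add_nodes_from(valves)
    # backbone chain: valves in series, pumps strapped across it
    for a, b in zip(valves, valves[1:]):
        graph.add_edge(a, b)
    graph.add_edge("pump_1", "valve_1")
    graph.add_edge("pump_2", "valve_3")
    graph.add_edge("pump_3", "valve_5")
    # vessels hang off valves
    attach = {
        "valve_1": [f"stock_{c}" for c in SOLUTION_COLORS],
        "valve_2": [f"tape_{i}" for i in range(1, tape_length + 1)][: tape_length // 2],
        "valve_3": [f"tape_{i}" for i in range(1, tape_length + 1)][tape_length // 2:],
        "valve_4": [f"head_{i}" for i in range(1, tape_length + 1)],
        "valve_5": ["state_1", "state_2", WASTE_ID],
    }
    for valve, ids in attach.items():
        for vid in ids:
            graph.add_edge(valve, vid)
    return PlatformState(vessels, solutions, graph)


def platform_from_config(config: Mapping) -> PlatformState:
    """Build a platform from a plain mapping (parsed YAML/JSON).

    Schema::

        vessels: [{id, capacity|null, temperature?, ph?, contents?: {sol: vol}}]
        stocks:  [{color, volume}]            # shorthand for stock flasks
        edges:   [[a, b], ...]                # backbone graph
    """
    solutions = [Solution(c, c) for c in SOLUTION_COLORS]
    vessels = []
    for spec in config.get("vessels", []):
        cap = spec.get("capacity", float(VIAL_CAPACITY))
        contents = {
            sol: Decimal(str(vol)) for sol, vol in (spec.get("contents") or {}).items()
        }
        vessels.append(
            Vessel(
                spec["id"],
                capacity=None if cap is None else Decimal(str(cap)),
                contents=contents,
                temperature=float(spec.get("temperature", 25.0)),
                ph=float(spec.get("ph", 7.0)),
            )
        )
    for spec in config.get("stocks", []):
        vol = Decimal(str(spec.get("volume", DEFAULT_STOCK_VOLUME)))
        vessels.append(
            Vessel(f"stock_{spec['color']}", capacity=vol, contents={spec["color"]: vol})
        )
    graph = nx.Graph()
    graph.add_nodes_from(v.id for v in vessels)
    for a, b in config.get("edges", []):
        graph.add_edge(a, b)
    return PlatformState(vessels, solutions, graph)


def load_platform(path: str) -> PlatformState:
    with open(path) as fh:
        return platform_from_config(yaml.safe_load(fh))
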