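"""Domain model for activity-network (DSM) process simulation.

A surgical procedure (or any sequential process) is decomposed into
*activities* executed in a declared order.  Directed dependencies between
activities carry a *rework probability*: the chance that a deviation in the
provider activity forces the consumer activity to be repeated.  Mutually
dependent activities form *rework loops* — strongly connected components of
the dependency graph — which the simulation engine treats as units that may
iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "TriangularDuration",
    "Activity",
    "Edge",
    "DSM",
    "Partition",
    "DSMValidationError",
    "build_dsm",
    "partition",
]


class DSMValidationError(ValueError):
    """Raised when an activity table or dependency set is structurally invalid."""


@dataclass(frozen=True)
class TriangularDuration:
    """Three-point duration estimate in minutes.

    ``bcv`` is the best (optimistic) case, ``mlv`` the most likely value
    (the mode), ``wcv`` the worst (pessimistic) case.  The degenerate case
    ``bcv == mlv == wcv`` encodes a deterministic duration.
    """

    bcv: float
    mlv: float
    wcv: float

    def __post_init__(self) -> None:
        if not (0 <= self.bcv <= self.mlv <= self.wcv):
            raise DSMValidationError(
                f"triangular duration requires 0 <= bcv <= mlv <= wcv, "
                f"got ({self.bcv}, {self.mlv}, {self.wcv})"
            )

    @property
    def mean(self) -> float:
        """Expected value of the triangular distribution, (bcv + mlv + wcv)/3."""
        return (self.bcv + self.mlv + self.wcv) / 3.0

    @property
    def is_degenerate(self) -> bool:
        return self.bcv == self.wcv


@dataclass(frozen=True)
class Activity:
    """One decomposed process step (a *surgeme* in the surgical setting).

    Parameters
    ----------
    id:
        Short unique identifier, e.g. ``"A6"``.
    label:
        Free-text description, e.g. ``"dissection and clipping the cystic artery"``.
    duration:
        Triangular three-point duration estimate in minutes.
    rework_impact:
        Fraction RI in [0, 1] of the activity's work that must be repeated
        when rework is triggered.
    improvement_curve:
        Ordered multipliers IC_i in (0, 1], one per successive rework
        iteration; a single value means a constant learning effect (1.0 =
        no improvement, the fully-trained-surgeon case).
    """

    id: str
    label: str
    duration: TriangularDuration
    rework_impact: float
    improvement_curve: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rework_impact <= 1.0:
            raise DSMValidationError(
                f"activity {self.id!r}: rework_impact must be in [0, 1], "
                f"got {self.rework_impact}"
            )
        if len(self.improvement_curve) == 0:
            raise DSMValidationError(
                f"activity {self.id!r}: improvement_curve must be non-empty"
            )
        for ic in self.improvement_curve:
            if not 0.0 < ic <= 1.0:
                raise DSMValidationError(
                    f"activity {self.id!r}: improvement-curve multiplier {ic} "
                    f"outside (0, 1]"
                )
        object.__setattr__(self, "improvement_curve", tuple(self.improvement_curve))

    def ic_at(self, iteration: int) -> float:
        """Improvement multiplier for the i-th rework iteration (1-based).

        A finite list extends by repeating its last value.
        """
        if iteration < 1:
            raise ValueError("iteration is 1-based")
        idx = min(iteration, len(self.improvement_curve)) - 1
        return self.improvement_curve[idx]


@dataclass(frozen=True)
class Edge:
    """Directed dependency: a deviation in ``provider`` may rework ``consumer``."""

    provider: str
    consumer: str
    rework_probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rework_probability <= 1.0:
            raise DSMValidationError(
                f"edge {self.provider}->{self.consumer}: rework probability "
                f"{self.rework_probability} outside [0, 1]"
            )


class DSM:
    """Square dependency structure over an ordered list of activities.

    The declared activity order is the intended execution sequence.  Edges
    are provider -> consumer with a per-edge rework probability P_ir; the
    diagonal is blank (self-edges are rejected) and absent or zero entries
    mean no dependency.
    """

    def __init__(self, activities: Sequence[Activity], edges: Iterable[Edge]):
        self.activities: tuple[Activity, ...] = tuple(activities)
        ids = [a.id for a in self.activities]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise DSMValidationError(f"duplicate activity id(s): {sorted(dup)}")
        self._index: dict[str, int] = {a.id: k for k, a in enumerate(self.activities)}
        kept: dict[tuple[str, str], Edge] = {}
        for e in edges:
            for endpoint in (e.provider, e.consumer):
                if endpoint not in self._index:
                    raise DSMValidationError(
                        f"edge {e.provider}->{e.consumer}: unknown activity "
                        f"{endpoint!r}"
                    )
            if e.provider == e.consumer:
                raise DSMValidationError(
                    f"self-edge {e.provider}->{e.consumer} not allowed "
                    f"(diagonal is blank)"
                )
            key = (e.provider, e.consumer)
            if key in kept:
                raise DSMValidationError(
                    f"duplicate edge {e.provider}->{e.consumer}"
                )
            kept[key] = e
        # drop zero-probability edges: a 0 cell means "no dependency"
        self.edges: tuple[Edge, ...] = tuple(
            e for e in kept.values() if e.rework_probability > 0.0
        )

    # -- lookups -----------------------------------------------------------

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.activities)

    @property
    def n(self) -> int:
        return len(self.activities)

    def index(self, activity_id: str) -> int:
        return self._index[activity_id]

    def activity(self, activity_id: str) -> Activity:
        return self.activities[self._index[activity_id]]

    def edge(self, provider: str, consumer: str) -> Edge | None:
        for e in self.edges:
            if e.provider == provider and e.consumer == consumer:
                return e
        return None

    def providers_of(self, consumer: str) -> list[Edge]:
        return [e for e in self.edges if e.consumer == consumer]

    def graph(self) -> nx.DiGraph:
        """Dependency graph with nodes in declared order."""
        g = nx.DiGraph()
        g.add_nodes_from(self.ids)
        g.add_edges_from(
            (e.provider, e.consumer, {"p": e.rework_probability}) for e in self.edges
        )
        return g

    # -- equality / serialisation -----------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DSM):
            return NotImplemented
        return self.activities == other.activities and set(self.edges) == set(
            other.edges
        )

    def __repr__(self) -> str:
        return f"DSM(n={self.n}, edges={len(self.edges)})"

    def to_dict(self) -> dict:
        """JSON-ready form: activity table plus provider->consumer edge list."""
        return {
            "activities": [
                {
                    "id": a.id,
                    "label": a.label,
                    "bcv": a.duration.bcv,
                    "mlv": a.duration.mlv,
                    "wcv": a.duration.wcv,
                    "rework_impact": a.rework_impact,
                    "improvement_curve": list(a.improvement_curve),
                }
                for a in self.activities
            ],
            "edges": [
                {"from": e.provider, "to": e.consumer, "p": e.rework_probability}
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DSM":
        acts = [
            Activity(
                id=str(a["id"]),
                label=str(a.get("label", "")),
                duration=TriangularDuration(
                    float(a["bcv"]), float(a["mlv"]), float(a["wcv"])
                ),
                rework_impact=float(a["rework_impact"]),
                improvement_curve=tuple(
                    float(x) for x in a.get("improvement_curve", [1.0])
                ),
            )
            for a in d["activities"]
        ]
        edges = [
            Edge(str(e["from"]), str(e["to"]), float(e["p"])) for e in d["edges"]
        ]
        return cls(acts, edges)


def build_dsm(activities: Sequence[Activity], edges: Iterable[Edge]) -> DSM:
    """Validate and assemble a DSM.

    The given activity order is preserved as the execution sequence.
    Raises :class:`DSMValidationError` naming the offending entry for
    duplicate ids, dangling edge endpoints, self-edges, or out-of-range
    probabilities.
    """
    return DSM(activities, edges)


@dataclass(frozen=True)
class Partition:
    """Sequencing analysis of a DSM.

    ``order`` is a topological order of the loop-condensed graph with ties
    broken by the declared activity order; loop members stay contiguous in
    their declared internal order.  ``loops`` are the strongly connected
    components of size >= 2 (rework loops).  ``active_sets`` partition the
    order into maximal consecutive runs executable before an activity that
    still depends on a not-yet-executed provider.
    """

    order: tuple[str, ...]
    loops: tuple[tuple[str, ...], ...]
    active_sets: tuple[tuple[str, ...], ...] = field(default=())

    def loop_of(self, activity_id: str) -> tuple[str, ...] | None:
        for loop in self.loops:
            if activity_id in loop:
                return loop
        return None


def partition(dsm: DSM) -> Partition:
    """Partition a DSM into execution order, rework loops, and active sets.

    Loops are SCCs of size >= 2 of the dependency graph.  The order is a
    deterministic topological sort of the condensation (Kahn's algorithm
    with the declared activity order as tie-break); within a loop, members
    keep their declared order.  Active sets are found by scanning the order
    and cutting whenever the next activity has an unexecuted upstream
    dependency.
    """
    g = dsm.graph()
    declared = {a: k for k, a in enumerate(dsm.ids)}

    sccs = [tuple(sorted(c, key=declared.get)) for c in nx.strongly_connected_components(g)]
    loops = tuple(
        sorted((c for c in sccs if len(c) >= 2), key=lambda c: declared[c[0]])
    )

    # condensation: one node per SCC, ordered by earliest declared member
    comp_of: dict[str, int] = {}
    for ci, comp in enumerate(sccs):
        for a in comp:
            comp_of[a] = ci
    cond = nx.DiGraph()
    cond.add_nodes_from(range(len(sccs)))
    for e in dsm.edges:
        u, v = comp_of[e.provider], comp_of[e.consumer]
        if u != v:
            cond.add_edge(u, v)

    # Kahn's algorithm; among ready components pick the one whose earliest
    # declared member comes first, so acyclic DSMs keep their declared order
    indeg = {c: cond.in_degree(c) for c in cond.nodes}
    ready = sorted(
        (c for c in cond.nodes if indeg[c] == 0), key=lambda c: declared[sccs[c][0]]
    )
    order: list[str] = []
    while ready:
        c = min(ready, key=lambda c: declared[sccs[c][0]])
        ready.remove(c)
        order.extend(sccs[c])
        for nxt in cond.successors(c):
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                ready.append(nxt)

    # active sets: cut before any activity with an unexecuted provider
    executed: set[str] = set()
    active_sets: list[tuple[str, ...]] = []
    current: list[str] = []
    for a in order:
        pending = any(e.provider not in executed for e in dsm.providers_of(a))
        if pending and current:
            active_sets.append(tuple(current))
            current = []
        current.append(a)
        executed.add(a)
    if current:
        active_sets.append(tuple(current))

    return Partition(order=tuple(order), loops=loops, active_sets=tuple(active_sets))
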