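"""Monte Carlo engine for total process duration with rework.

Each run draws one duration per activity from its triangular distribution,
then walks the partitioned execution order.  Every dependency carrying a
rework probability P_ir may trigger repetitions of its consumer: the number
of repeats nr follows a truncated geometric law (consecutive uniform draws
below P_ir), and each repeat costs ``D0 * RI * IC_i`` minutes — the run's
drawn first-trial duration scaled by the consumer's rework impact and
improvement-curve multiplier for that iteration.  Rework loops (mutually
dependent activity groups) are walked edge by edge around the cycle; all
other dependencies contribute single-edge rework.  The per-run total obeys
the accounting identity

    total = first-trial sum + sum of all rework durations

exactly, not approximately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .model import DSM, Activity, Partition, TriangularDuration, partition as _partition

__all__ = [
    "SimulationConfig",
    "RunRecord",
    "SimulationResult",
    "sample_duration",
    "rework_duration",
    "sample_rework_count",
    "count_reworks",
    "expected_rework_count",
    "effective_cap",
    "simulate_loop",
    "simulate_run",
    "run_monte_carlo",
    "expected_duration",
    "rework_edge_order",
]

#: probabilities at or above this are treated as observed certainty: the
#: rework happens, once per pass, rather than looping without bound
CERTAINTY_THRESHOLD = 0.999


@dataclass(frozen=True)
class SimulationConfig:
    """Controls for the Monte Carlo engine.

    ``max_reworks_per_edge`` caps the geometric repeat count nr on every
    dependency (default 25; with P = 0.1 the probability of ever hitting
    the cap is 1e-25).  ``rework_trigger`` selects the repeat criterion:
    ``"standard"`` repeats while the uniform draw falls *below* P_ir, so
    P_ir keeps its meaning as a probability of rework; ``"literal"``
    repeats while the draw *exceeds* P_ir, provided for fidelity
    experiments with legacy macro conventions.  ``duration_source``
    chooses between sampled triangular durations and the deterministic
    most-likely values.
    """

    n_runs: int = 10_000
    seed: int = 0
    max_reworks_per_edge: int = 25
    rework_trigger: Literal["standard", "literal"] = "standard"
    duration_source: Literal["sampled", "mlv_only"] = "sampled"

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.max_reworks_per_edge < 1:
            raise ValueError("max_reworks_per_edge must be >= 1")
        if self.rework_trigger not in ("standard", "literal"):
            raise ValueError(f"unknown rework_trigger {self.rework_trigger!r}")
        if self.duration_source not in ("sampled", "mlv_only"):
            raise ValueError(f"unknown duration_source {self.duration_source!r}")


# ---------------------------------------------------------------------------
# elementary operations


def sample_duration(d: TriangularDuration, u):
    """Map a uniform variate u in [0, 1] to a triangular draw (inverse CDF).

    Accepts a scalar or an array of variates; the result always lies in
    [bcv, wcv].  Degenerate estimates (bcv == wcv) return the point mass.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0.0) | (u_arr > 1.0)):
        raise ValueError("uniform variate outside [0, 1]")
    span = d.wcv - d.bcv
    if span == 0.0:
        out = np.full_like(u_arr, d.bcv)
        return float(out) if np.isscalar(u) else out
    c = (d.mlv - d.bcv) / span
    left = d.bcv + np.sqrt(u_arr * c) * span
    right = d.wcv - np.sqrt((1.0 - u_arr) * (1.0 - c)) * span
    # clip: the subtraction form can land one ulp outside the support
    out = np.clip(np.where(u_arr < c, left, right), d.bcv, d.wcv)
    return float(out) if np.isscalar(u) else out


def rework_duration(d0: float, ri: float, ic: float) -> float:
    """Duration of one rework iteration: D0 * RI * IC."""
    if d0 < 0:
        raise ValueError(f"original duration {d0} must be >= 0")
    if not 0.0 <= ri <= 1.0:
        raise ValueError(f"rework impact {ri} outside [0, 1]")
    if not 0.0 < ic <= 1.0:
        raise ValueError(f"improvement multiplier {ic} outside (0, 1]")
    return d0 * ri * ic


def effective_cap(p: float, cap: int) -> int:
    """Truncation for the repeat count on an edge with probability ``p``.

    A probability at (or numerically indistinguishable from) 1 encodes an
    observed certainty — the rework happened — not an infinite loop, so
    the count is capped at one repeat per pass.
    """
    return 1 if p >= CERTAINTY_THRESHOLD else cap


def count_reworks(
    uniforms: np.ndarray,
    p: float,
    cap: int,
    trigger: str = "standard",
) -> int:
    """Repeat count nr from a block of uniform draws.

    Under the standard convention nr is the number of consecutive draws
    below ``p`` from the start of the block, truncated at ``cap``; uncapped
    this is geometric with P(nr = k) = p^k (1 - p).  The literal
    convention counts draws above ``p`` instead.
    """
    if trigger == "standard":
        hits = uniforms < p
    elif trigger == "literal":
        hits = uniforms > p
    else:
        raise ValueError(f"unknown rework trigger {trigger!r}")
    nr = 0
    for h in hits:
        if not h or nr >= cap:
            break
        nr += 1
    return min(nr, cap)


def sample_rework_count(
    p: float,
    rng: np.random.Generator,
    cap: int,
    trigger: str = "standard",
    block: int | None = None,
) -> int:
    """Draw a truncated-geometric repeat count.

    Always consumes ``block`` (default ``cap``) uniforms from ``rng``
    regardless of the outcome, so the position of later draws in the
    stream does not depend on ``p`` — this keeps paired comparisons
    between configurations aligned on a common random-number stream.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    n_draw = block if block is not None else cap
    if n_draw < cap:
        raise ValueError("block must be >= cap")
    u = rng.random(n_draw)
    return count_reworks(u, p, cap, trigger)


def expected_rework_count(p: float, cap: int, trigger: str = "standard") -> float:
    """E[nr] for the truncated geometric count: sum_{k=1..cap} q^k.

    ``q`` is the per-iteration repeat probability (``p`` under the
    standard trigger, ``1 - p`` under the literal one).
    """
    q = p if trigger == "standard" else 1.0 - p
    if q == 1.0:
        return float(cap)
    # sum_{k=1..cap} q^k = q (1 - q^cap) / (1 - q)
    return q * (1.0 - q**cap) / (1.0 - q)


def _ic_sum(activity: Activity, nr: int) -> float:
    """Sum of improvement multipliers over nr successive rework iterations."""
    return math.fsum(activity.ic_at(i) for i in range(1, nr + 1))


def _expected_ic_weighted_count(
    activity: Activity, p: float, cap: int, trigger: str = "standard"
) -> float:
    """E[sum_{i=1..nr} IC_i] = sum_{k=1..cap} IC_k P(nr >= k) = sum IC_k q^k."""
    q = p if trigger == "standard" else 1.0 - p
    return math.fsum(activity.ic_at(k) * q**k for k in range(1, cap + 1))


# ---------------------------------------------------------------------------
# run-level machinery


def loop_edges_of(dsm: DSM, loop: Sequence[str]) -> list[tuple[str, str]]:
    """Deterministic ordering of the dependencies inside one rework loop.

    The cyclic consecutive pairs present in the DSM come first, walked
    consumer-by-consumer around the loop; any further intra-loop
    dependencies (chords of the cycle) follow, sorted by (consumer
    position, provider position).  Raises if the members are not in fact
    mutually dependent through intra-loop edges.
    """
    members = set(loop)
    intra = {
        (e.provider, e.consumer)
        for e in dsm.edges
        if e.provider in members and e.consumer in members
    }
    sub = nx.DiGraph()
    sub.add_nodes_from(loop)
    sub.add_edges_from(intra)
    if len(loop) < 2 or not nx.is_strongly_connected(sub):
        missing = next(
            (
                f"{loop[k]}->{loop[(k + 1) % len(loop)]}"
                for k in range(len(loop))
                if (loop[k], loop[(k + 1) % len(loop)]) not in intra
            ),
            "?",
        )
        raise ValueError(
            f"rework loop {tuple(loop)} is missing its cyclic edge {missing} "
            f"(members are not mutually dependent)"
        )
    ordered: list[tuple[str, str]] = []
    for k, provider in enumerate(loop):
        pair = (provider, loop[(k + 1) % len(loop)])
        if pair in intra:
            ordered.append(pair)
    chords = sorted(
        intra - set(ordered), key=lambda pc: (dsm.index(pc[1]), dsm.index(pc[0]))
    )
    return ordered + chords


def rework_edge_order(
    dsm: DSM, part: Partition
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Deterministic ordering of rework-bearing dependencies.

    Returns ``(loop_edges, single_edges)``: first each rework loop's
    internal dependencies (loops in partition order), then every
    remaining dependency sorted by (consumer position, provider
    position) in the declared activity order.
    """
    loop_edges: list[tuple[str, str]] = []
    for loop in part.loops:
        loop_edges.extend(loop_edges_of(dsm, loop))
    loop_edge_set = set(loop_edges)
    single = [
        (e.provider, e.consumer)
        for e in dsm.edges
        if (e.provider, e.consumer) not in loop_edge_set
    ]
    single.sort(key=lambda pc: (dsm.index(pc[1]), dsm.index(pc[0])))
    return loop_edges, single


def simulate_loop(
    loop: Sequence[str],
    dsm: DSM,
    d0: Mapping[str, float],
    rng: np.random.Generator,
    cfg: SimulationConfig,
) -> tuple[float, dict[tuple[str, str], int]]:
    """Simulate one pass of a rework loop.

    Walks the loop's dependencies edge by edge (the cycle first, then any
    chords): for each directed dependency (provider -> consumer), draws
    the repeat count nr and accrues
    ``D0_consumer * RI_consumer * sum_{i=1..nr} IC_i``.  Returns the
    loop's total rework duration and the per-edge counts.
    """
    total = 0.0
    counts: dict[tuple[str, str], int] = {}
    for provider, consumer in loop_edges_of(dsm, loop):
        edge = dsm.edge(provider, consumer)
        cap = effective_cap(edge.rework_probability, cfg.max_reworks_per_edge)
        nr = sample_rework_count(
            edge.rework_probability,
            rng,
            cap,
            cfg.rework_trigger,
            block=cfg.max_reworks_per_edge,
        )
        counts[(provider, consumer)] = nr
        act = dsm.activity(consumer)
        total += d0[consumer] * act.rework_impact * _ic_sum(act, nr)
    return total, counts


@dataclass(frozen=True)
class RunRecord:
    """One Monte Carlo run: sampled durations and every rework contribution."""

    d0: dict[str, float]
    first_trial_total: float
    loop_durations: tuple[float, ...]
    edge_rework_durations: tuple[float, ...]
    rework_counts: dict[tuple[str, str], int]
    total: float


def simulate_run(
    dsm: DSM,
    part: Partition,
    rng: np.random.Generator,
    cfg: SimulationConfig,
) -> RunRecord:
    """Execute one simulated pass through the procedure.

    Durations are drawn once per activity in declared order (or taken as
    the MLV in ``mlv_only`` mode); rework loops are then walked in
    partition order and every remaining dependency applies single-edge
    rework of its consumer.  The returned record satisfies
    ``total == first_trial_total + sum(loop_durations) +
    sum(edge_rework_durations)`` exactly.
    """
    d0: dict[str, float] = {}
    for act in dsm.activities:
        if cfg.duration_source == "mlv_only":
            d0[act.id] = act.duration.mlv
        else:
            d0[act.id] = sample_duration(act.duration, float(rng.random()))
    first_trial = math.fsum(d0[a] for a in dsm.ids)

    counts: dict[tuple[str, str], int] = {}
    loop_durs: list[float] = []
    for loop in part.loops:
        dur, loop_counts = simulate_loop(loop, dsm, d0, rng, cfg)
        loop_durs.append(dur)
        counts.update(loop_counts)

    _, single_edges = rework_edge_order(dsm, part)
    edge_durs: list[float] = []
    for provider, consumer in single_edges:
        edge = dsm.edge(provider, consumer)
        cap = effective_cap(edge.rework_probability, cfg.max_reworks_per_edge)
        nr = sample_rework_count(
            edge.rework_probability,
            rng,
            cap,
            cfg.rework_trigger,
            block=cfg.max_reworks_per_edge,
        )
        counts[(provider, consumer)] = nr
        act = dsm.activity(consumer)
        edge_durs.append(d0[consumer] * act.rework_impact * _ic_sum(act, nr))

    total = first_trial + math.fsum(loop_durs) + math.fsum(edge_durs)
    return RunRecord(
        d0=d0,
        first_trial_total=first_trial,
        loop_durations=tuple(loop_durs),
        edge_rework_durations=tuple(edge_durs),
        rework_counts=counts,
        total=total,
    )


@dataclass(frozen=True)
class SimulationResult:
    """Monte Carlo output: per-run records plus summary statistics.

    ``totals`` are total durations in minutes, one per run.
    ``rework_counts[r][k]`` is the repeat count in run r on the k-th
    rework edge (order given by ``edge_order``); ``loop_durations`` and
    ``edge_rework_durations`` hold per-run rework time by loop and by
    single edge; ``first_trial_totals`` the rework-free sums.
    """

    totals: np.ndarray
    first_trial_totals: np.ndarray
    loop_durations: np.ndarray
    edge_rework_durations: np.ndarray
    rework_counts: np.ndarray
    edge_order: tuple[tuple[str, str], ...]
    loop_order: tuple[tuple[str, ...], ...]
    config: SimulationConfig
    summary: dict = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationResult):
            return NotImplemented
        return (
            self.edge_order == other.edge_order
            and self.loop_order == other.loop_order
            and self.config == other.config
            and np.array_equal(self.totals, other.totals)
            and np.array_equal(self.first_trial_totals, other.first_trial_totals)
            and np.array_equal(self.loop_durations, other.loop_durations)
            and np.array_equal(
                self.edge_rework_durations, other.edge_rework_durations
            )
            and np.array_equal(self.rework_counts, other.rework_counts)
            and self.summary == other.summary
        )


def _summarize(totals: np.ndarray, cfg: SimulationConfig) -> dict:
    return {
        "mean": float(np.mean(totals)),
        "sd": float(np.std(totals, ddof=1)) if totals.size > 1 else 0.0,
        "min": float(np.min(totals)),
        "max": float(np.max(totals)),
        "p5": float(np.percentile(totals, 5)),
        "p50": float(np.percentile(totals, 50)),
        "p95": float(np.percentile(totals, 95)),
        "n_runs": int(totals.size),
        "seed": int(cfg.seed),
    }


def run_monte_carlo(dsm: DSM, cfg: SimulationConfig) -> SimulationResult:
    """Run the full Monte Carlo study: n_runs independent simulated passes.

    A single seeded generator drives every draw, consumed in a fixed
    activity-then-edge order within each run, so an identical seed yields
    a bit-identical result.
    """
    part = _partition(dsm)
    loop_edges, single_edges = rework_edge_order(dsm, part)
    edge_order = tuple(loop_edges + single_edges)

    rng = np.random.default_rng(cfg.seed)
    totals = np.empty(cfg.n_runs)
    first = np.empty(cfg.n_runs)
    loop_d = np.zeros((cfg.n_runs, len(part.loops)))
    edge_d = np.zeros((cfg.n_runs, len(single_edges)))
    counts = np.zeros((cfg.n_runs, len(edge_order)), dtype=int)

    for r in range(cfg.n_runs):
        rec = simulate_run(dsm, part, rng, cfg)
        totals[r] = rec.total
        first[r] = rec.first_trial_total
        loop_d[r, :] = rec.loop_durations
        edge_d[r, :] = rec.edge_rework_durations
        counts[r, :] = [rec.rework_counts[e] for e in edge_order]

    return SimulationResult(
        totals=totals,
        first_trial_totals=first,
        loop_durations=loop_d,
        edge_rework_durations=edge_d,
        rework_counts=counts,
        edge_order=edge_order,
        loop_order=part.loops,
        config=cfg,
        summary=_summarize(totals, cfg),
    )


def expected_duration(
    dsm: DSM,
    cap: int = 25,
    trigger: str = "standard",
) -> float:
    """Deterministic expected total using most-likely durations.

    Sums every activity's MLV, then adds for each rework-bearing
    dependency the consumer's expected rework time
    ``MLV * RI * sum_{k=1..cap'} IC_k q^k`` where q is the per-iteration
    repeat probability and cap' the edge's effective truncation.  Equals
    the mean of the Monte Carlo engine in ``mlv_only`` mode.
    """
    part = _partition(dsm)
    loop_edges, single_edges = rework_edge_order(dsm, part)
    total = math.fsum(a.duration.mlv for a in dsm.activities)
    for provider, consumer in loop_edges + single_edges:
        edge = dsm.edge(provider, consumer)
        act = dsm.activity(consumer)
        ecap = effective_cap(edge.rework_probability, cap)
        total += (
            act.duration.mlv
            * act.rework_impact
            * _expected_ic_weighted_count(act, edge.rework_probability, ecap, trigger)
        )
    return total
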