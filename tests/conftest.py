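"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: loop
detection is checked against a reachability-matrix SCC computation, and
the truncated-geometric repeat count against exhaustive pmf summation.
"""

from __future__ import annotations

import numpy as np
import pytest

from dsmsim import DSM, make_amis_fixture, make_aplt_fixture


@pytest.fixture(scope="session")
def amis() -> DSM:
    return make_amis_fixture()


@pytest.fixture(scope="session")
def aplt() -> DSM:
    return make_aplt_fixture()


def brute_force_loops(dsm: DSM) -> set[frozenset[str]]:
    """SCCs of size >= 2 via boolean reachability closure (no graph library).

    Two activities are in the same loop iff each reaches the other.
    """
    n = dsm.n
    reach = np.zeros((n, n), dtype=bool)
    for e in dsm.edges:
        reach[dsm.index(e.provider), dsm.index(e.consumer)] = True
    for _ in range(n):  # closure stabilizes within n squarings-ish passes
        reach = reach | (reach @ reach)
    mutual = reach & reach.T
    loops: set[frozenset[str]] = set()
    for i in range(n):
        # i belongs to a loop only if mutually reachable with someone else
        partners = {dsm.ids[j] for j in range(n) if j != i and mutual[i, j]}
        if partners:
            loops.add(frozenset(partners | {dsm.ids[i]}))
    return loops


def truncated_geometric_pmf(p: float, cap: int) -> np.ndarray:
    """Exhaustive pmf of the repeat count: P(k) = p^k (1-p) for k < cap, p^cap at cap."""
    pmf = np.array([p**k * (1.0 - p) for k in range(cap)] + [p**cap])
    assert abs(pmf.sum() - 1.0) < 1e-12
    return pmf


def truncated_geometric_mean(p: float, cap: int) -> float:
    pmf = truncated_geometric_pmf(p, cap)
    return float(np.dot(np.arange(cap + 1), pmf))
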