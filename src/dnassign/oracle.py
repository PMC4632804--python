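"""Exhaustive combinatorial solver used to cross-check the strand pipeline.

The oracle never touches the strand machinery: it enumerates the m^n
job -> individual mappings directly, keeps the onto ones (every
individual gets at least one job), and minimizes the summed cost.  That
independence is what makes agreement with the molecular pipeline a
genuine correctness check.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable

import numpy as np

from .pipeline import Assignment, CostMatrix

__all__ = [
    "brute_force_min",
    "surjection_count",
    "stage_counts",
    "is_feasible",
]


def brute_force_min(costs) -> tuple:
    """Minimum total cost and the set of all optimal assignments.

    Accepts a :class:`~dnassign.pipeline.CostMatrix` or any real-valued
    m x n array with m < n (the oracle, unlike the strand encoding, does
    not need integer costs).
    """
    arr = costs.costs if isinstance(costs, CostMatrix) else np.asarray(costs)
    if arr.ndim != 2:
        raise ValueError("cost matrix must be two-dimensional")
    m, n = arr.shape
    if m >= n:
        raise ValueError("oracle requires an unbalanced instance (m < n)")
    best = None
    optima: list = []
    individuals = range(m)
    for mapping in itertools.product(individuals, repeat=n):
        if len(set(mapping)) != m:  # not onto
            continue
        z = sum(arr[i, j] for j, i in enumerate(mapping))
        if best is None or z < best:
            best = z
            optima = [mapping]
        elif z == best:
            optima.append(mapping)
    best = best.item() if hasattr(best, "item") else best
    out = frozenset(
        Assignment(tuple(i + 1 for i in mapping), best) for mapping in optima
    )
    return best, out


def surjection_count(m: int, n: int) -> int:
    """Number of onto mappings from n jobs to m individuals.

    Inclusion-exclusion: S(m, n) = sum_{k=0..m} (-1)^k C(m, k) (m-k)^n.
    Returns 0 when m > n.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be positive")
    if m > n:
        return 0
    return sum(
        (-1) ** k * math.comb(m, k) * (m - k) ** n for k in range(m + 1)
    )


def stage_counts(m: int, n: int) -> dict:
    """Closed-form tube sizes after the first three pipeline steps.

    pool: (mn)^n strands; jobs_filtered: n! m^n (orderings of the n jobs
    times a free individual per edge); individuals_filtered:
    n! S(m, n) (orderings times onto mappings).
    """
    if m >= n:
        raise ValueError("requires an unbalanced instance (m < n)")
    return {
        "pool": (m * n) ** n,
        "jobs_filtered": math.factorial(n) * m**n,
        "individuals_filtered": math.factorial(n) * surjection_count(m, n),
    }


def is_feasible(assignment: Assignment, m: int, n: int) -> bool:
    """Whether an assignment satisfies the UAP constraints.

    Each of the jobs 1..n is mapped to exactly one individual in 1..m and
    every individual's load lies in [1, n - m + 1] (the upper bound is
    implied: loads are >= 1 and sum to n).
    """
    jti = assignment.job_to_individual
    if len(jti) != n:
        raise ValueError(f"assignment covers {len(jti)} jobs, expected {n}")
    if any(not (1 <= i <= m) for i in jti):
        return False
    loads = assignment.loads(m)
    return all(1 <= load <= n - m + 1 for load in loads)
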