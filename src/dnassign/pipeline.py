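"""Five-step DNA strand pipeline for the unbalanced assignment problem.

The unbalanced assignment problem (UAP) assigns n jobs to m < n
individuals so that every job is done exactly once, every individual
receives at least one job, and the total cost sum c_{i(j),j} is minimal.
The molecular algorithm solves it by brute-force parallelism:

1. build the pool of all (mn)^n strands spelling n edges ``s A_i e B_j``
   (job j assigned to individual i), each edge 4t mer long;
2. keep strands that contain every job word ``B_k`` (on n-edge strands
   this forces each job exactly once);
3. keep strands that contain every individual motif ``s A_i e`` (each
   individual gets at least one job);
4. append, for every edge (i, j) present, a weight word ``w_ij`` of
   length c_ij * u mer, so strand length = 4tn + u * (assignment cost);
5. extract the shortest strands — they spell the optimal assignments.

All steps are assembled from :mod:`dnassign.strands` primitives, so the
operation counter measures the claimed O(mn) step complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .strands import (
    OpCounter,
    SymbolAtom,
    SymbolicStrand,
    Tube,
    TubeUsageError,
    anneal_ligate_pool,
    append_tail,
    copy,
    detect,
    discard,
    merge,
    read,
    separation,
    sort_split,
)

__all__ = [
    "CostMatrix",
    "Assignment",
    "SolveResult",
    "generate_pool",
    "filter_jobs",
    "filter_individuals",
    "append_weights",
    "select_shortest",
    "decode_assignment",
    "solve",
]

#: Refuse strand-pipeline runs whose pool would exceed this many strands.
DEFAULT_POOL_CAP = 10_000_000


@dataclass(frozen=True, eq=False)
class CostMatrix:
    """An m x n integer cost matrix for an unbalanced instance (m < n).

    Rows are individuals, columns are jobs; entry c_ij is the cost of
    assigning job j to individual i.  Strand-length encoding requires
    nonnegative integer costs.
    """

    costs: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.costs)
        if arr.ndim != 2:
            raise ValueError("cost matrix must be two-dimensional")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("strand-length encoding needs integer costs")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("costs must be nonnegative")
        m, n = arr.shape
        if m < 1:
            raise ValueError("need at least one individual")
        if n <= m:
            raise ValueError(
                f"not an unbalanced instance: need more jobs than individuals "
                f"(got m={m}, n={n})"
            )
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "costs", arr)

    @property
    def m(self) -> int:
        return self.costs.shape[0]

    @property
    def n(self) -> int:
        return self.costs.shape[1]

    def c(self, i: int, j: int) -> int:
        """Cost c_ij with 1-based indices."""
        return int(self.costs[i - 1, j - 1])

    @property
    def max_cost(self) -> int:
        return int(self.costs.max())

    def tolist(self) -> list:
        return self.costs.tolist()


@dataclass(frozen=True)
class Assignment:
    """A complete job -> individual mapping and its total cost.

    ``job_to_individual[j - 1]`` is the (1-based) individual doing job j.
    """

    job_to_individual: tuple
    cost: int

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], costs: CostMatrix | None = None,
                   cost: int | None = None) -> "Assignment":
        """Build from (i, j) pairs; jobs must be exactly 1..n, each once."""
        mapping: dict = {}
        for i, j in edges:
            if j in mapping:
                raise ValueError(f"job {j} assigned more than once")
            mapping[j] = i
        n = len(mapping)
        if set(mapping) != set(range(1, n + 1)):
            raise ValueError("jobs must be exactly 1..n")
        jti = tuple(mapping[j] for j in range(1, n + 1))
        if cost is None:
            if costs is None:
                raise ValueError("need a cost matrix or an explicit cost")
            cost = sum(costs.c(i, j) for j, i in enumerate(jti, start=1))
        return cls(jti, cost)

    @property
    def n(self) -> int:
        return len(self.job_to_individual)

    def as_dict(self) -> dict:
        return {j: i for j, i in enumerate(self.job_to_individual, start=1)}

    def loads(self, m: int) -> list:
        """Jobs per individual, index i-1."""
        out = [0] * m
        for i in self.job_to_individual:
            out[i - 1] += 1
        return out

    def __str__(self) -> str:
        inner = ", ".join(
            f"j{j}->i{i}" for j, i in enumerate(self.job_to_individual, start=1)
        )
        return "{" + inner + "}" + f" cost={self.cost}"


@dataclass(frozen=True)
class SolveResult:
    """Outcome of a pipeline run."""

    min_cost: int
    optimal_assignments: frozenset
    solution_strand_count: int
    stage_counts: Mapping[str, int]
    op_count: int
    exemplar: SymbolicStrand = field(compare=False, default=None)

    def to_dict(self) -> dict:
        return {
            "min_cost": self.min_cost,
            "assignments": sorted(
                a.as_dict() for a in self.optimal_assignments
            ) if self.optimal_assignments else [],
            "solution_strand_count": self.solution_strand_count,
            "stage_counts": dict(self.stage_counts),
            "op_count": self.op_count,
            "exemplar_strand": str(self.exemplar) if self.exemplar else None,
        }


# ----------------------------------------------------------------------
# Pipeline steps
# ----------------------------------------------------------------------

def _unit_length(tube: Tube, t: int | None) -> int:
    if t is not None:
        return t
    for strand in tube:
        return strand.atoms[0].length_mer
    return 5


def generate_pool(m: int, n: int, t: int = 5) -> Tube:
    """Step 1: the pool of all (mn)^n strands of n edges, each 4nt mer long."""
    if m < 1:
        raise TubeUsageError("need at least one individual")
    if m >= n:
        raise TubeUsageError("not an unbalanced instance (need m < n)")
    s, e = SymbolAtom.s(t), SymbolAtom.e(t)
    edges = [
        SymbolicStrand([s, SymbolAtom.individual(i, t), e, SymbolAtom.job(j, t)])
        for i in range(1, m + 1)
        for j in range(1, n + 1)
    ]
    return anneal_ligate_pool(edges, n)


def filter_jobs(tube: Tube, n: int, t: int | None = None) -> Tube:
    """Step 2: keep strands containing every job word ``B_k``, k = 1..n.

    On n-edge pool strands containing all n jobs forces each exactly
    once.  Mirrors the laboratory loop: separate on the motif ``e B_k``,
    discard the remainder, copy the matched tube back, discard the
    intermediate — four primitives per job.
    """
    t = _unit_length(tube, t)
    e = SymbolAtom.e(t)
    for k in range(1, n + 1):
        motif = (e, SymbolAtom.job(k, t))
        remainder, matched = separation(tube, [motif])
        discard(remainder)
        tube = copy(matched)
        discard(matched)
    return tube


def filter_individuals(tube: Tube, m: int, t: int | None = None) -> Tube:
    """Step 3: keep strands containing ``s A_i e`` for every individual i."""
    t = _unit_length(tube, t)
    s, e = SymbolAtom.s(t), SymbolAtom.e(t)
    for i in range(1, m + 1):
        motif = (s, SymbolAtom.individual(i, t), e)
        remainder, matched = separation(tube, [motif])
        discard(remainder)
        tube = copy(matched)
        discard(matched)
    return tube


def append_weights(
    tube: Tube, costs: CostMatrix, u: int = 1, t: int | None = None
) -> Tube:
    """Step 4: append one weight word ``w_ij`` per edge (i, j) present.

    The double loop over individuals then jobs separates the strands
    containing edge (i, j), appends ``w_ij`` of length c_ij * u mer, and
    merges them back — at most five primitives per matrix cell.
    """
    if u < 1:
        raise TubeUsageError("mer-per-cost unit u must be >= 1")
    t = _unit_length(tube, t)
    s, e = SymbolAtom.s(t), SymbolAtom.e(t)
    for i in range(1, costs.m + 1):
        a_i = SymbolAtom.individual(i, t)
        for j in range(1, costs.n + 1):
            motif = (s, a_i, e, SymbolAtom.job(j, t))
            tube, matched = separation(tube, [motif])
            if detect(matched):
                append_tail(matched, SymbolAtom.weight(i, j, costs.c(i, j) * u))
                merge(tube, matched)
                discard(matched)
    return tube


def select_shortest(tube: Tube) -> Tube:
    """Step 5: the tube of all strands attaining the minimal length."""
    if not tube.contents:
        raise TubeUsageError("no feasible assignment: empty tube")
    _, shortest, _ = sort_split(tube)
    return shortest


def decode_assignment(
    strand: SymbolicStrand, costs: CostMatrix | None = None, u: int = 1
) -> Assignment:
    """Read the job -> individual mapping off a solution strand.

    All orderings of the same edge set decode to the same
    :class:`Assignment`.  The cost comes from the cost matrix when
    given, otherwise from the total length of the strand's weight tail
    divided by ``u``.
    """
    try:
        edges = strand.edges()
    except ValueError as exc:
        raise ValueError(f"not a valid assignment strand: {exc}") from exc
    seen = set()
    for _, j in edges:
        if j in seen:
            raise ValueError("not a valid assignment strand: duplicate job")
        seen.add(j)
    if costs is not None:
        return Assignment.from_edges(edges, costs=costs)
    tail = strand.weight_atoms()
    cost = sum(a.length_mer for a in tail) // u if tail else 0
    return Assignment.from_edges(edges, cost=cost)


def solve(
    costs: CostMatrix,
    t: int = 5,
    u: int = 1,
    pool_cap: int = DEFAULT_POOL_CAP,
) -> SolveResult:
    """Run the five molecular steps and decode the optimal assignments.

    Exhaustive by construction: the pool holds (mn)^n strands, so the
    run is refused above ``pool_cap`` (use the brute-force oracle for
    larger instances — it enumerates m^n mappings instead).
    """
    m, n = costs.m, costs.n
    pool_size = (m * n) ** n
    if pool_size > pool_cap:
        raise TubeUsageError(
            f"pool of {pool_size} strands exceeds the cap of {pool_cap}; "
            "use the exact oracle for instances this large"
        )
    stage_counts: dict = {}
    tube = generate_pool(m, n, t)
    stage_counts["pool"] = len(tube)
    tube = filter_jobs(tube, n, t)
    stage_counts["jobs_filtered"] = len(tube)
    tube = filter_individuals(tube, m, t)
    stage_counts["individuals_filtered"] = len(tube)
    tube = append_weights(tube, costs, u, t)
    stage_counts["weighted"] = len(tube)
    solution = select_shortest(tube)
    stage_counts["solution"] = len(solution)
    exemplar = read(solution)
    assignments = frozenset(
        decode_assignment(s, costs=costs, u=u) for s in solution
    )
    min_cost = min(a.cost for a in assignments)
    return SolveResult(
        min_cost=min_cost,
        optimal_assignments=assignments,
        solution_strand_count=len(solution),
        stage_counts=stage_counts,
        op_count=solution.op_count,
        exemplar=exemplar,
    )
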