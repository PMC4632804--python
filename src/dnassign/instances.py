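"""Cost-matrix I/O, bundled demo instances and the synthetic generator.

File format: CSV or TSV with one row per individual and one column per
job; an optional header row (``j1..jn``) and row-label column
(``i1..im``) are detected and dropped.  Entries must be nonnegative
integers and the matrix must be unbalanced (fewer individuals than
jobs).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .pipeline import Assignment, CostMatrix, SolveResult

__all__ = [
    "EXAMPLE_3X5",
    "EXAMPLE_2X3",
    "read_cost_matrix",
    "write_cost_matrix",
    "random_instance",
    "result_to_dict",
    "write_result_json",
    "read_result_json",
]

#: 3 individuals x 5 jobs demo instance (optimum 17).
EXAMPLE_3X5 = CostMatrix(
    np.array(
        [
            [5, 9, 1, 2, 7],
            [9, 8, 6, 4, 4],
            [4, 7, 8, 5, 2],
        ]
    )
)

#: 2 individuals x 3 jobs walk-through instance (optimum 4).
EXAMPLE_2X3 = CostMatrix(np.array([[2, 4, 1], [1, 2, 3]]))


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_cost_matrix(path) -> CostMatrix:
    """Read an m x n integer cost matrix from CSV/TSV.

    Header rows and label columns are detected by their non-numeric
    content and dropped.  Ragged rows, negative or non-integer entries
    and balanced (m >= n) shapes raise descriptive errors.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty cost-matrix file")
    delimiter = "\t" if "\t" in lines[0] else ","
    rows = [
        [cell.strip() for cell in row]
        for row in csv.reader(lines, delimiter=delimiter)
    ]
    # drop a header row / label column when their cells are not numeric
    if rows and any(not _is_number(c) for c in rows[0][1:]):
        rows = rows[1:]
    if rows and any(not _is_number(r[0]) for r in rows if r):
        rows = [r[1:] for r in rows]
    if not rows or not rows[0]:
        raise ValueError(f"{path}: no numeric data found")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: ragged rows (expected {width} columns)")
    values = []
    for r_idx, row in enumerate(rows):
        out_row = []
        for c_idx, cell in enumerate(row):
            if not _is_number(cell):
                raise ValueError(
                    f"{path}: non-numeric entry {cell!r} at row {r_idx + 1}, "
                    f"column {c_idx + 1}"
                )
            value = float(cell)
            if value < 0:
                raise ValueError(f"{path}: negative cost {cell} is not allowed")
            if value != int(value):
                raise ValueError(
                    f"{path}: cost {cell} is not an integer "
                    "(strand lengths are integral)"
                )
            out_row.append(int(value))
        values.append(out_row)
    arr = np.array(values, dtype=np.int64)
    if arr.shape[0] >= arr.shape[1]:
        raise ValueError(
            f"{path}: not an unbalanced instance "
            f"(rows/individuals m={arr.shape[0]} must be fewer than "
            f"columns/jobs n={arr.shape[1]})"
        )
    return CostMatrix(arr)


def write_cost_matrix(costs: CostMatrix, path, header: bool = True) -> None:
    """Write a cost matrix as CSV with j1..jn / i1..im labels."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        if header:
            writer.writerow(["cost"] + [f"j{j}" for j in range(1, costs.n + 1)])
            for i in range(1, costs.m + 1):
                writer.writerow([f"i{i}"] + list(costs.costs[i - 1]))
        else:
            writer.writerows(costs.tolist())


def random_instance(
    m: int, n: int, cost_lo: int = 0, cost_hi: int = 9, seed: int = 0
) -> CostMatrix:
    """A seeded uniform-integer cost matrix; same seed, same matrix."""
    if m >= n:
        raise ValueError("not an unbalanced instance (need m < n)")
    if not (0 <= cost_lo <= cost_hi):
        raise ValueError("need 0 <= cost_lo <= cost_hi")
    rng = np.random.default_rng(seed)
    return CostMatrix(rng.integers(cost_lo, cost_hi + 1, size=(m, n), dtype=np.int64))


# ----------------------------------------------------------------------
# Result serialization
# ----------------------------------------------------------------------

def result_to_dict(result: SolveResult, costs: CostMatrix) -> dict:
    record = result.to_dict()
    record["m"] = costs.m
    record["n"] = costs.n
    # JSON keys must be strings
    record["assignments"] = [
        {str(j): i for j, i in a.items()} for a in record["assignments"]
    ]
    return record


def write_result_json(result: SolveResult, costs: CostMatrix, path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result, costs), indent=2) + "\n")


def read_result_json(path) -> dict:
    record = json.loads(Path(path).read_text())
    record["assignments"] = [
        {int(j): i for j, i in a.items()} for a in record["assignments"]
    ]
    return record
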