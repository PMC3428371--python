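"""Benchmark harness comparing the solver families on random LP grids.

For every grid cell ``(n, k, sparsity)`` and replicate, an LP is generated,
each requested method is run from the origin, and the objective, status,
and iteration-style counters (fixations and advances for conic sampling,
pivots for simplex, iterations for affine scaling) are recorded in a tidy
table.  Iteration counts are the primary comparison — they are hardware
independent — while wall time is recorded informationally.

All exact methods must agree on the optimal objective (affine scaling to a
looser relative tolerance, since it stops at an approximate interior
point); a disagreement flags the row and makes :func:`run_benchmark` raise.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import RULE_RANDOM, RULE_STEEPEST, affine_scaling_solve, simplex_solve
from .conic import solve_lp
from .generators import LpGenSpec, gen_random_lp
from .problems import LinearProgram, SolveResult, STATUS_OPTIMAL, STATUS_UNBOUNDED

METHODS = ("conic", "simplex-steepest", "simplex-random", "affine")

#: relative agreement tolerances per method against the exact consensus
AGREEMENT_RTOL = {"conic": 1e-6, "simplex-steepest": 1e-6,
                  "simplex-random": 1e-6, "affine": 1e-4}


class BenchmarkDisagreementError(RuntimeError):
    """Two methods returned incompatible objectives on the same instance."""


@dataclass
class BenchSpec:
    grid: list[tuple[int, int, float]]
    replicates: int = 3
    methods: tuple[str, ...] = METHODS
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")


def cell_seed(base: int, n: int, k: int, sparsity: float, rep: int) -> int:
    """Stable per-cell seed derived from the base seed (replayable)."""
    key = f"{n}:{k}:{sparsity:.6f}:{rep}".encode()
    return (int(base) + zlib.crc32(key)) % (2**31 - 1)


def _run_method(method: str, P: LinearProgram, seed: int) -> SolveResult:
    if method == "conic":
        return solve_lp(P, seed=seed)
    if method == "simplex-steepest":
        return simplex_solve(P, rule=RULE_STEEPEST, seed=seed)
    if method == "simplex-random":
        return simplex_solve(P, rule=RULE_RANDOM, seed=seed)
    if method == "affine":
        return affine_scaling_solve(P)
    raise ValueError(f"unknown method {method!r}")


def _counter(method: str, res: SolveResult) -> int:
    return res.fixations if method == "conic" else res.iterations


def run_benchmark(spec: BenchSpec, strict: bool = True) -> pd.DataFrame:
    """Run the grid; returns a tidy table, one row per (cell, replicate, method).

    Columns: n, k, sparsity, replicate, seed, method, status, objective,
    iterations (method-specific counter), advances, wall_time_s, agree.
    With ``strict`` (default) a cross-method disagreement raises after the
    table is complete, so the offending rows are still inspectable.
    """
    records = []
    disagreements = []
    for (n, k, sparsity) in spec.grid:
        for rep in range(spec.replicates):
            seed = cell_seed(spec.base_seed, n, k, sparsity, rep)
            P = gen_random_lp(LpGenSpec(n=n, k=k, sparsity=sparsity, seed=seed))
            cell_rows = []
            for method in spec.methods:
                t0 = time.perf_counter()
                res = _run_method(method, P, seed)
                wall = time.perf_counter() - t0
                cell_rows.append({
                    "n": n, "k": k, "sparsity": sparsity, "replicate": rep,
                    "seed": seed, "method": method, "status": res.status,
                    "objective": res.objective,
                    "iterations": _counter(method, res),
                    "advances": res.advances, "wall_time_s": wall,
                })
            exact = [r for r in cell_rows
                     if r["method"] != "affine"
                     and r["status"] in (STATUS_OPTIMAL, STATUS_UNBOUNDED)]
            agree = _cell_agreement(cell_rows, exact)
            for r in cell_rows:
                r["agree"] = agree
            if not agree:
                disagreements.append((n, k, sparsity, rep))
            records.extend(cell_rows)
    table = pd.DataFrame.from_records(records)
    if strict and disagreements:
        raise BenchmarkDisagreementError(
            f"objective disagreement in cells {disagreements}")
    return table


def _cell_agreement(cell_rows: list[dict], exact: list[dict]) -> bool:
    if not exact:
        return True
    statuses = {r["status"] for r in exact}
    if len(statuses) > 1:
        return False
    if STATUS_UNBOUNDED in statuses:
        # affine scaling must not claim a finite optimum on an unbounded LP
        return all(r["status"] != STATUS_OPTIMAL or not np.isfinite(r["objective"])
                   for r in cell_rows if r["method"] == "affine")
    ref = float(np.median([r["objective"] for r in exact]))
    scale = 1.0 + abs(ref)
    for r in cell_rows:
        if r["status"] != STATUS_OPTIMAL:
            return False
        rtol = AGREEMENT_RTOL[r["method"]]
        if abs(r["objective"] - ref) > rtol * scale:
            return False
    return True


def fixation_trend(table: pd.DataFrame) -> pd.DataFrame:
    """Median conic fixation count per (n, sparsity, k) — the scaling trend.

    Highly constrained polytopes have exponentially many vertices; if the
    sampled jumps winnow the superior-vertex set roughly uniformly, the
    expected fixation count grows only logarithmically with the vertex
    count, so the medians should rise far slower than k.
    """
    sub = table[table["method"] == "conic"]
    return (sub.groupby(["n", "sparsity", "k"])["iterations"]
            .median().rename("median_fixations").reset_index())
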