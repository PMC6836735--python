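"""PhISCS-I: exact genotype correction as a mixed-integer linear program.

The shared clause/cardinality encoding is translated literal-by-literal
into 0/1 linear constraints (a clause becomes "sum of its literal values
>= 1") and the real-valued soft terms become the linear objective, which
equals the log-likelihood of the corrected matrix (with eliminated columns
zeroed).  The model is solved to proven optimality with HiGHS via
``scipy.optimize.milp``.
"""

from __future__ import annotations

import time

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .bulk import BulkProfile
from .conflicts import is_conflict_free
from .encoding import (
    ConstraintEncoding,
    SolverConfig,
    augment_with_root,
    build_encoding,
    is_root_augmented,
    strip_root,
)
from .likelihood import objective_with_elimination
from .matrix import MISSING, GenotypeMatrix, NoiseModel
from .result import SolveResult


class InfeasibleError(RuntimeError):
    """The hard constraints are contradictory.

    Without bulk data a conflict-free completion always exists, so this can
    only be raised when the VAF lineage constraints are unsatisfiable at
    the given delta and k_max.
    """


def _clauses_to_linear(
    clauses: list[tuple[int, ...]], num_vars: int
) -> LinearConstraint | None:
    rows, cols, vals, lb = [], [], [], []
    for r, clause in enumerate(clauses):
        neg = 0
        for lit in clause:
            v = abs(lit) - 1
            rows.append(r)
            cols.append(v)
            if lit > 0:
                vals.append(1.0)
            else:
                vals.append(-1.0)
                neg += 1
        lb.append(1.0 - neg)
    if not rows:
        return None
    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(clauses), num_vars)
    )
    return LinearConstraint(A, np.array(lb), np.full(len(clauses), np.inf))


def _objective_vector(enc: ConstraintEncoding) -> tuple[np.ndarray, float]:
    """Maximization coefficients c and constant so that obj = c.x + const."""
    c = np.zeros(enc.num_vars)
    const = enc.offset
    for lit, w in enc.soft_terms:
        v = abs(lit) - 1
        if lit > 0:
            c[v] += w
        else:
            c[v] -= w
            const += w
    return c, const


def solve_encoding_ilp(
    enc: ConstraintEncoding, time_limit: float | None = None
) -> tuple[np.ndarray | None, float, str]:
    """Solve an encoding as a MILP; returns (assignment, objective, status).

    The assignment is 1-indexed (index 0 unused) to match the encoding's
    DIMACS-style variable numbering.
    """
    c, const = _objective_vector(enc)
    constraints = []
    lin = _clauses_to_linear(enc.hard_clauses, enc.num_vars)
    if lin is not None:
        constraints.append(lin)
    if enc.cardinality is not None:
        xs, k = enc.cardinality
        row = np.zeros((1, enc.num_vars))
        for v in xs:
            row[0, v - 1] = 1.0
        constraints.append(LinearConstraint(row, -np.inf, float(k)))
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        -c,  # milp minimizes
        constraints=constraints,
        integrality=np.ones(enc.num_vars),
        bounds=Bounds(0.0, 1.0),
        options=options,
    )
    if res.status == 2:
        return None, float("-inf"), "infeasible"
    if res.x is None:
        return None, float("-inf"), "timeout"
    status = "optimal" if res.status == 0 else "feasible"
    assignment = np.zeros(enc.num_vars + 1, dtype=bool)
    assignment[1:] = np.round(res.x).astype(bool)
    return assignment, float(c @ assignment[1:].astype(float) + const), status


def _decode_result(
    I: GenotypeMatrix,
    noise: NoiseModel,
    enc: ConstraintEncoding,
    assignment: np.ndarray,
    status: str,
    backend: str,
    elapsed: float,
) -> SolveResult:
    """Turn a satisfying assignment into a SolveResult over the original matrix."""
    Y = enc.decode_y(assignment)
    elim = enc.decode_eliminated(assignment)
    if enc.augmented:
        Y = strip_root(Y)
        elim = frozenset(q - 1 for q in elim if q > 0)
        obs = I.entries[1:, 1:]
        cell_ids = I.cell_ids[1:]
        mutation_ids = I.mutation_ids[1:]
        I = GenotypeMatrix(cell_ids, mutation_ids, obs)
    keep = np.array([j not in elim for j in range(I.m)])
    observed = I.observed & keep[None, :]
    flips01 = int(((I.entries == 0) & (Y == 1) & observed).sum())
    flips10 = int(((I.entries == 1) & (Y == 0) & observed).sum())
    assigned = int(((I.entries == MISSING) & keep[None, :]).sum())
    return SolveResult(
        Y=Y,
        eliminated=elim,
        objective=objective_with_elimination(I, Y, elim, noise),
        flips_0_to_1=flips01,
        flips_1_to_0=flips10,
        assigned_missing=assigned,
        status=status,
        cell_ids=list(I.cell_ids),
        mutation_ids=list(I.mutation_ids),
        backend=backend,
        solve_seconds=elapsed,
    )


def solve_phiscs_i(
    I: GenotypeMatrix,
    noise: NoiseModel,
    config: SolverConfig | None = None,
    bulk: BulkProfile | None = None,
) -> SolveResult:
    """Maximum-likelihood conflict-free correction of ``I`` (ILP route).

    Returns the corrected matrix, the set of eliminated ISA-violating
    mutations (at most ``config.k_max``) and the exact log-likelihood
    objective.  With ``bulk`` supplied, root augmentation and the VAF
    lineage constraints are applied internally and stripped from the
    reported output.
    """
    config = config or SolverConfig()
    t0 = time.perf_counter()
    work = I
    if bulk is not None and not is_root_augmented(I):
        work, bulk = augment_with_root(I, bulk)
    enc = build_encoding(work, noise, config, bulk)
    assignment, _, status = solve_encoding_ilp(enc, config.time_limit)
    if assignment is None:
        if status == "infeasible":
            raise InfeasibleError(
                "hard constraints unsatisfiable: VAF lineage constraints "
                f"contradictory at delta={config.delta}, k_max={config.k_max}"
            )
        raise TimeoutError("solver hit the time limit with no feasible solution")
    result = _decode_result(work, noise, enc, assignment, status, "ilp",
                            time.perf_counter() - t0)
    assert is_conflict_free(result.Y, result.eliminated)
    return result


def export_lp(enc: ConstraintEncoding, path) -> None:
    """Write the encoding in CPLEX LP format for external inspection."""
    c, const = _objective_vector(enc)
    lines = ["Maximize", " obj:"]
    terms = [f" {'+' if c[v] >= 0 else '-'} {abs(c[v]):.12g} x{v + 1}"
             for v in range(enc.num_vars) if c[v] != 0.0]
    lines += ["   " + " ".join(terms) if terms else "   0 x1"]
    lines.append("Subject To")
    for r, clause in enumerate(enc.hard_clauses):
        lhs, rhs = [], 1
        for lit in clause:
            if lit > 0:
                lhs.append(f"+ x{lit}")
            else:
                lhs.append(f"- x{-lit}")
                rhs -= 1
        lines.append(f" c{r}: {' '.join(lhs)} >= {rhs}")
    if enc.cardinality is not None:
        xs, k = enc.cardinality
        lines.append(
            " card: " + " ".join(f"+ x{v}" for v in xs) + f" <= {k}"
        )
    lines.append("Binary")
    lines.append(" " + " ".join(f"x{v + 1}" for v in range(enc.num_vars)))
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
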