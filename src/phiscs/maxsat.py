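"""PhISCS-B: genotype correction as weighted partial Max-SAT.

The shared encoding's hard clauses (conflict-freeness, elimination logic,
root facts, VAF gates) are kept verbatim; the cardinality bound
sum(K) <= k_max becomes a sequential-counter clause block; and the real
log-likelihood soft terms are sign-normalized (a negative-weight literal
becomes its negation with the absolute weight, recording the dropped
constant) and scaled to positive integers.  The result is a standard
weighted partial CNF, exportable as DIMACS-WCNF for any competition
Max-SAT engine.

The built-in engine solves the WCNF exactly by translating its clauses to
0/1 linear constraints for HiGHS; the decoded model's objective is then
recomputed in exact real arithmetic, so weight discretization never leaks
into reported likelihoods.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

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
)
from .ilp import InfeasibleError, _decode_result
from .matrix import GenotypeMatrix, NoiseModel

_MAX_TOTAL_WEIGHT = 2**62


class WeightOverflowError(OverflowError):
    """Scaled soft weights exceed the engine-safe integer range."""


@dataclass
class WeightedCnf:
    """Weighted partial CNF in DIMACS conventions (1-indexed variables).

    ``offset`` records the constants dropped during sign normalization plus
    the encoding's own offset, so that

        offset + (satisfied soft weight sum) / scale

    reproduces the real log-likelihood objective to within 1/scale per
    soft clause.
    """

    num_vars: int
    hard_clauses: list[tuple[int, ...]] = field(default_factory=list)
    soft_clauses: list[tuple[tuple[int, ...], int]] = field(default_factory=list)
    top_weight: int = 1
    scale: int = 10**6
    offset: float = 0.0
    encoding: ConstraintEncoding | None = field(default=None, repr=False)

    def to_dimacs(self) -> str:
        """Serialize as DIMACS-WCNF text."""
        lines = [
            f"p wcnf {self.num_vars} "
            f"{len(self.hard_clauses) + len(self.soft_clauses)} {self.top_weight}"
        ]
        for clause in self.hard_clauses:
            lines.append(f"{self.top_weight} " + " ".join(map(str, clause)) + " 0")
        for clause, w in self.soft_clauses:
            lines.append(f"{w} " + " ".join(map(str, clause)) + " 0")
        return "\n".join(lines) + "\n"

    def write_dimacs(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_dimacs())


def wcnf_from_encoding(enc: ConstraintEncoding, scale: int) -> WeightedCnf:
    """Realize an encoding as weighted partial CNF.

    Soft unit terms with weight w < 0 on literal L become (-L, |w|) plus a
    recorded constant w: satisfying L then simply fails to earn |w|, which
    is the same objective up to the constant.  Zero-rounded weights are
    dropped.
    """
    wcnf = WeightedCnf(num_vars=enc.num_vars, scale=scale,
                       offset=enc.offset, encoding=enc)
    wcnf.hard_clauses = list(enc.hard_clauses) + enc.cardinality_clauses()
    wcnf.num_vars = enc.num_vars  # cardinality may have allocated counters
    total = 0
    for lit, w in enc.soft_terms:
        scaled = round(w * scale)
        if scaled == 0:
            continue
        if scaled < 0:
            wcnf.offset += w
            lit, scaled = -lit, -scaled
        wcnf.soft_clauses.append(((lit,), scaled))
        total += scaled
    if total >= _MAX_TOTAL_WEIGHT:
        raise WeightOverflowError(
            f"total scaled soft weight {total} exceeds the safe integer "
            "range; reduce weight_scale"
        )
    wcnf.top_weight = total + 1
    return wcnf


def encode_wcnf(
    I: GenotypeMatrix,
    noise: NoiseModel,
    config: SolverConfig | None = None,
    bulk: BulkProfile | None = None,
) -> WeightedCnf:
    """Build the weighted partial CNF for an input instance."""
    config = config or SolverConfig()
    if bulk is not None and not is_root_augmented(I):
        I, bulk = augment_with_root(I, bulk)
    enc = build_encoding(I, noise, config, bulk)
    return wcnf_from_encoding(enc, config.weight_scale)


def solve_wcnf(
    wcnf: WeightedCnf, time_limit: float | None = None
) -> tuple[np.ndarray | None, int, str]:
    """Exact weighted partial Max-SAT solve.

    Returns (1-indexed boolean model, satisfied soft weight, status).  The
    clause system is translated to a 0/1 integer program: every hard clause
    requires at least one satisfied literal; each soft clause contributes
    its weight through an indicator bounded by the clause's literal sum.
    """
    nv = wcnf.num_vars
    n_soft = len(wcnf.soft_clauses)
    n_tot = nv + n_soft
    rows, cols, vals, lb = [], [], [], []

    def emit(r, clause, extra=None):
        neg = 0
        for lit in clause:
            rows.append(r)
            cols.append(abs(lit) - 1)
            if lit > 0:
                vals.append(1.0)
            else:
                vals.append(-1.0)
                neg += 1
        if extra is not None:
            rows.append(r)
            cols.append(extra)
            vals.append(-1.0)
        lb.append((1.0 if extra is None else 0.0) - neg)

    r = 0
    for clause in wcnf.hard_clauses:
        emit(r, clause)
        r += 1
    c = np.zeros(n_tot)
    for s, (clause, w) in enumerate(wcnf.soft_clauses):
        z = nv + s
        c[z] = float(w)
        emit(r, clause, extra=z)  # sum(lits) - z >= 0
        r += 1
    constraints = []
    if rows:
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, n_tot))
        constraints.append(
            LinearConstraint(A, np.array(lb), np.full(r, np.inf))
        )
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        -c,
        constraints=constraints,
        integrality=np.ones(n_tot),
        bounds=Bounds(0.0, 1.0),
        options=options,
    )
    if res.status == 2:
        return None, 0, "infeasible"
    if res.x is None:
        return None, 0, "timeout"
    status = "optimal" if res.status == 0 else "feasible"
    model = np.zeros(nv + 1, dtype=bool)
    model[1:] = np.round(res.x[:nv]).astype(bool)
    satisfied = sum(
        w for clause, w in wcnf.soft_clauses
        if any((lit > 0) == bool(model[abs(lit)]) for lit in clause)
    )
    return model, int(satisfied), status


def solve_phiscs_b(
    I: GenotypeMatrix,
    noise: NoiseModel,
    config: SolverConfig | None = None,
    bulk: BulkProfile | None = None,
):
    """Maximum-likelihood conflict-free correction of ``I`` (Max-SAT route).

    Mirrors :func:`phiscs.ilp.solve_phiscs_i`; the two back-ends agree on
    the objective up to the soft-weight rounding resolution (n*m /
    weight_scale in the worst case) and may differ in which of several
    co-optimal matrices they report.
    """
    config = config or SolverConfig()
    t0 = time.perf_counter()
    work = I
    if bulk is not None and not is_root_augmented(I):
        work, bulk = augment_with_root(I, bulk)
    enc = build_encoding(work, noise, config, bulk)
    wcnf = wcnf_from_encoding(enc, config.weight_scale)
    model, _, status = solve_wcnf(wcnf, config.time_limit)
    if model is None:
        if status == "infeasible":
            raise InfeasibleError(
                "hard clauses unsatisfiable: VAF lineage constraints "
                f"contradictory at delta={config.delta}, k_max={config.k_max}"
            )
        raise TimeoutError("solver hit the time limit with no feasible model")
    result = _decode_result(work, noise, enc, model, status, "maxsat",
                            time.perf_counter() - t0)
    assert is_conflict_free(result.Y, result.eliminated)
    return result


def solve(
    I: GenotypeMatrix,
    noise: NoiseModel,
    config: SolverConfig | None = None,
    bulk: BulkProfile | None = None,
):
    """Dispatch to the back-end named in ``config.backend``."""
    config = config or SolverConfig()
    if config.backend == "maxsat":
        return solve_phiscs_b(I, noise, config, bulk)
    return solve_phiscs_i(I, noise, config, bulk)
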