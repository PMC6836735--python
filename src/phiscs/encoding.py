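"""Shared constraint system consumed by both exact back-ends.

The decision variables are

* ``Y(i, j)`` — true state of mutation j in cell i;
* ``B(p, q, a, b)`` for (a, b) in {(0,1), (1,0), (1,1)} — witness that some
  row of Y exhibits the configuration (a, b) on the column pair (p, q);
* ``K(j)`` — mutation j is eliminated as an ISA violator (only when
  ``k_max > 0``);
* ``X(i, j)`` — auxiliary conjunction Y(i,j) AND K(j) used to linearize the
  objective under elimination;
* ``a(p, q)`` — p is an ancestor of q in the implied clonal tree (only when
  bulk VAF data is supplied).

All hard constraints are expressible as disjunctive clauses over these
binary variables plus a single cardinality bound sum(K) <= k_max, so one
encoding serves both the MILP and the weighted Max-SAT realization.  The
soft side is a list of (literal, real weight) unit terms whose satisfied
sum, plus a recorded constant offset, equals the log-likelihood objective.

When bulk data is supplied, the matrix must first be augmented with a root
row (genotype of a healthy cell, all real mutations absent) and a null
mutation column M0 (germline SNP present in every cell, vaf = 1 in every
sample, never eliminable), which anchors the ancestor relation at the tree
root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bulk import BulkProfile
from .matrix import MISSING, GenotypeMatrix, NoiseModel

#: Reserved identifiers introduced by root augmentation.
ROOT_CELL_ID = "ROOT"
NULL_MUTATION_ID = "M0"

_B_STATES = ((0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class SolverConfig:
    """Solver-facing knobs shared by both back-ends.

    Parameters
    ----------
    k_max
        Maximum number of mutations that may be eliminated as ISA
        violators.  0 demands a plain perfect phylogeny.
    delta
        Multiplicative tolerance of the VAF lineage inequalities; absorbs
        coverage-driven VAF noise.  Default 0.1 (about 10% slack, ample at
        the coverages bulk experiments typically reach).
    weight_scale
        Integer scale applied to the real log-likelihood weights when they
        are rounded to the positive integer weights a Max-SAT engine
        requires; the objective is preserved to within 1/weight_scale per
        soft term.
    backend
        "ilp" or "maxsat".
    time_limit
        Wall-clock budget in seconds for a single solve, or None.
    seed
        Seed recorded for provenance; the exact solves themselves are
        deterministic.
    """

    k_max: int = 0
    delta: float = 0.1
    weight_scale: int = 10**6
    backend: str = "ilp"
    time_limit: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_max < 0:
            raise ValueError("k_max must be nonnegative")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.weight_scale <= 0:
            raise ValueError("weight_scale must be positive")
        if self.backend not in ("ilp", "maxsat"):
            raise ValueError(f"unknown backend {self.backend!r}")


def augment_with_root(
    I: GenotypeMatrix, bulk: BulkProfile
) -> tuple[GenotypeMatrix, BulkProfile]:
    """Prepend the healthy-cell root row and the null-mutation column M0.

    The root row is all-zero over real mutations; the M0 column is all-one
    (germline, present in every cell including the root) with vaf fixed at
    1 in every bulk sample.
    """
    if ROOT_CELL_ID in I.cell_ids:
        raise ValueError(f"cell id {ROOT_CELL_ID!r} is reserved for the root row")
    if NULL_MUTATION_ID in I.mutation_ids:
        raise ValueError(f"mutation id {NULL_MUTATION_ID!r} is reserved for the null mutation")
    bulk = bulk.aligned_to(I.mutation_ids)
    entries = np.ones((I.n + 1, I.m + 1), dtype=np.int8)
    entries[0, 1:] = 0
    entries[1:, 1:] = I.entries
    aug_matrix = GenotypeMatrix(
        cell_ids=[ROOT_CELL_ID, *I.cell_ids],
        mutation_ids=[NULL_MUTATION_ID, *I.mutation_ids],
        entries=entries,
    )
    vaf = np.hstack([np.ones((bulk.h, 1)), bulk.vaf])
    if bulk.var_reads is not None:
        depth = np.maximum(
            (bulk.var_reads + bulk.ref_reads).mean(axis=1).round().astype(np.int64), 2
        )
        half = depth // 2
        var0 = half[:, None]
        ref0 = (depth - half)[:, None]
        # force exact vaf 1 for M0 regardless of rounding
        var0 = np.maximum(var0, 1)
        ref0 = var0.copy()
        var = np.hstack([var0, bulk.var_reads])
        ref = np.hstack([ref0, bulk.ref_reads])
    else:
        var = ref = None
    aug_bulk = BulkProfile(
        [NULL_MUTATION_ID, *bulk.mutation_ids], list(bulk.sample_ids), vaf, var, ref
    )
    return aug_matrix, aug_bulk


def strip_root(Y: np.ndarray) -> np.ndarray:
    """Remove the augmented root row and null-mutation column."""
    return np.asarray(Y)[1:, 1:]


def is_root_augmented(I: GenotypeMatrix) -> bool:
    return (
        bool(I.cell_ids) and I.cell_ids[0] == ROOT_CELL_ID
        and bool(I.mutation_ids) and I.mutation_ids[0] == NULL_MUTATION_ID
    )


def compute_pvaf(bulk: BulkProfile, delta: float) -> np.ndarray:
    """Pairwise predicate: pvaf[p, q] iff vaf_l(p)*(1+delta) >= vaf_l(q) in
    every sample l.  An ancestor must satisfy it toward each descendant."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    v = bulk.vaf  # (h, m)
    return np.all(
        v[:, :, None] * (1.0 + delta) >= v[:, None, :] - 1e-12, axis=0
    )


def compute_tvaf(bulk: BulkProfile, delta: float, p: int, q: int, r: int) -> bool:
    """Triple predicate: vaf_l(p)*(1+delta) >= vaf_l(q) + vaf_l(r) in every
    sample; required when q and r are incomparable descendants of p."""
    if len({p, q, r}) != 3:
        raise ValueError("p, q, r must be distinct")
    for idx in (p, q, r):
        if not (0 <= idx < bulk.m):
            raise IndexError(f"mutation index {idx} out of range")
    v = bulk.vaf
    return bool(np.all(v[:, p] * (1.0 + delta) >= v[:, q] + v[:, r] - 1e-12))


def _tvaf_table(bulk: BulkProfile, delta: float) -> np.ndarray:
    v = bulk.vaf
    return np.all(
        v[:, :, None, None] * (1.0 + delta)
        >= v[:, None, :, None] + v[:, None, None, :] - 1e-12,
        axis=0,
    )


@dataclass
class ConstraintEncoding:
    """Variable catalog + clause system shared by the two back-ends.

    Clauses are tuples of nonzero signed integers (DIMACS convention:
    positive literal = variable true).  ``soft_terms`` are (literal, weight)
    units with real weights; ``offset`` is the constant completing the
    log-likelihood.  ``cardinality`` is (K-variable list, k_max), realized
    by each back-end in its native form.
    """

    n: int
    m: int
    k_max: int
    uses_bulk: bool
    augmented: bool
    num_vars: int = 0
    y_vars: dict[tuple[int, int], int] = field(default_factory=dict)
    b_vars: dict[tuple[int, int, int, int], int] = field(default_factory=dict)
    k_vars: dict[int, int] = field(default_factory=dict)
    x_vars: dict[tuple[int, int], int] = field(default_factory=dict)
    a_vars: dict[tuple[int, int], int] = field(default_factory=dict)
    hard_clauses: list[tuple[int, ...]] = field(default_factory=list)
    cardinality: tuple[list[int], int] | None = None
    soft_terms: list[tuple[int, float]] = field(default_factory=list)
    offset: float = 0.0

    def new_var(self) -> int:
        self.num_vars += 1
        return self.num_vars

    def y(self, i: int, j: int) -> int:
        return self.y_vars[(i, j)]

    def b(self, p: int, q: int, a: int, bb: int) -> int:
        """B variable with canonical p < q storage; B(q,p,a,b) = B(p,q,b,a)."""
        if p > q:
            p, q, a, bb = q, p, bb, a
        return self.b_vars[(p, q, a, bb)]

    def add_clause(self, *lits: int) -> None:
        self.hard_clauses.append(tuple(lits))

    # -- decoding -----------------------------------------------------------
    def decode_y(self, assignment: np.ndarray) -> np.ndarray:
        """Extract the Y matrix from a 1-indexed truth assignment."""
        Y = np.zeros((self.n, self.m), dtype=np.int8)
        for (i, j), v in self.y_vars.items():
            Y[i, j] = int(assignment[v])
        return Y

    def decode_eliminated(self, assignment: np.ndarray) -> frozenset[int]:
        return frozenset(j for j, v in self.k_vars.items() if assignment[v])

    def decode_ancestry(self, assignment: np.ndarray) -> set[tuple[int, int]]:
        return {pq for pq, v in self.a_vars.items() if assignment[v]}

    # -- cardinality as clauses (sequential counter) ------------------------
    def cardinality_clauses(self) -> list[tuple[int, ...]]:
        """Clause realization of sum(K) <= k_max (sequential counter).

        Allocates auxiliary variables; call at most once per encoding.
        """
        if self.cardinality is None:
            return []
        xs, k = self.cardinality
        nvars = len(xs)
        if k >= nvars:
            return []
        if k == 0:
            return [(-x,) for x in xs]
        s = [[self.new_var() for _ in range(k)] for _ in range(nvars - 1)]
        clauses: list[tuple[int, ...]] = [(-xs[0], s[0][0])]
        clauses += [(-s[0][j],) for j in range(1, k)]
        for i in range(1, nvars - 1):
            clauses.append((-xs[i], s[i][0]))
            clauses.append((-s[i - 1][0], s[i][0]))
            for j in range(1, k):
                clauses.append((-xs[i], -s[i - 1][j - 1], s[i][j]))
                clauses.append((-s[i - 1][j], s[i][j]))
            clauses.append((-xs[i], -s[i - 1][k - 1]))
        clauses.append((-xs[-1], -s[-1][k - 1]))
        return clauses


def build_encoding(
    I: GenotypeMatrix,
    noise: NoiseModel,
    config: SolverConfig,
    bulk: BulkProfile | None = None,
) -> ConstraintEncoding:
    """Construct the full hard/soft constraint system for ``I``.

    With ``bulk`` supplied the matrix must already be root-augmented (see
    :func:`augment_with_root`); ancestor variables and VAF constraints are
    then emitted in addition to the conflict-freeness core.
    """
    n, m = I.n, I.m
    if config.k_max > m:
        raise ValueError(f"k_max={config.k_max} exceeds number of mutations {m}")
    augmented = is_root_augmented(I)
    if bulk is not None and not augmented:
        raise ValueError("bulk constraints require a root-augmented matrix; "
                         "call augment_with_root first")
    if bulk is not None:
        bulk = bulk.aligned_to(I.mutation_ids)

    enc = ConstraintEncoding(
        n=n, m=m, k_max=config.k_max,
        uses_bulk=bulk is not None, augmented=augmented,
    )
    for i in range(n):
        for j in range(m):
            enc.y_vars[(i, j)] = enc.new_var()
    for p in range(m):
        for q in range(p + 1, m):
            for a, bb in _B_STATES:
                enc.b_vars[(p, q, a, bb)] = enc.new_var()
    use_k = config.k_max > 0
    # real (non-null) columns and entries; the null column/root row are
    # forced by hard facts and never contribute to the objective
    first_col = 1 if augmented else 0
    first_row = 1 if augmented else 0
    if use_k:
        for j in range(m):
            enc.k_vars[j] = enc.new_var()
        for i in range(first_row, n):
            for j in range(first_col, m):
                enc.x_vars[(i, j)] = enc.new_var()
        enc.cardinality = ([enc.k_vars[j] for j in range(first_col, m)], config.k_max)
    if bulk is not None:
        for p in range(m):
            for q in range(1, m):  # a(p, 0) is identically false
                if p != q:
                    enc.a_vars[(p, q)] = enc.new_var()

    # --- conflict-freeness core -------------------------------------------
    for p in range(m):
        for q in range(p + 1, m):
            b01 = enc.b(p, q, 0, 1)
            b10 = enc.b(p, q, 1, 0)
            b11 = enc.b(p, q, 1, 1)
            for i in range(n):
                yp, yq = enc.y(i, p), enc.y(i, q)
                enc.add_clause(-yp, -yq, b11)
                enc.add_clause(yp, -yq, b01)
                enc.add_clause(-yp, yq, b10)
            if use_k:
                enc.add_clause(enc.k_vars[p], enc.k_vars[q], -b01, -b10, -b11)
            else:
                enc.add_clause(-b01, -b10, -b11)

    # --- elimination plumbing: X = Y AND K --------------------------------
    for (i, j), x in sorted(enc.x_vars.items()):
        y = enc.y(i, j)
        k = enc.k_vars[j]
        enc.add_clause(-y, -k, x)
        enc.add_clause(y, -x)
        enc.add_clause(k, -x)

    # --- root facts and VAF lineage constraints ---------------------------
    if augmented:
        for i in range(n):
            enc.add_clause(enc.y(i, 0))
        for j in range(1, m):
            enc.add_clause(-enc.y(0, j))
        if use_k:
            enc.add_clause(-enc.k_vars[0])
    if bulk is not None:
        _emit_vaf_constraints(enc, bulk, config)

    # --- soft terms: per-entry log-likelihood weights ---------------------
    alpha, beta = noise.alpha, noise.beta
    coef = {0: math.log(beta / (1.0 - alpha)), 1: math.log((1.0 - beta) / alpha)}
    const = {0: math.log(1.0 - alpha), 1: math.log(alpha)}
    if use_k:
        col_const = dict.fromkeys(range(first_col, m), 0.0)
        for i in range(first_row, n):
            for j in range(first_col, m):
                o = int(I.entries[i, j])
                if o == MISSING:
                    continue
                enc.soft_terms.append((enc.y(i, j), coef[o]))
                enc.soft_terms.append((enc.x_vars[(i, j)], -coef[o]))
                col_const[j] += const[o]
        for j in range(first_col, m):
            # aggregated per-column constant, paid unless j is eliminated
            enc.soft_terms.append((-enc.k_vars[j], col_const[j]))
    else:
        for i in range(first_row, n):
            for j in range(first_col, m):
                o = int(I.entries[i, j])
                if o == MISSING:
                    continue
                enc.soft_terms.append((enc.y(i, j), coef[o]))
                enc.offset += const[o]
    return enc


def _emit_vaf_constraints(
    enc: ConstraintEncoding, bulk: BulkProfile, config: SolverConfig
) -> None:
    m = enc.m
    use_k = config.k_max > 0
    k = enc.k_vars

    def K(j: int) -> list[int]:
        return [k[j]] if use_k else []

    # pairwise structure of the ancestor relation
    for p in range(m):
        for q in range(p + 1, m):
            apq = enc.a_vars.get((p, q))
            aqp = enc.a_vars.get((q, p))
            b11 = enc.b(p, q, 1, 1)
            if apq is not None and aqp is not None:
                enc.add_clause(-apq, -aqp)  # antisymmetry
            # co-occurrence forces comparability (K-relaxed)
            occ = [a for a in (apq, aqp) if a is not None]
            enc.add_clause(-b11, *occ, *K(p), *K(q))
            if use_k:
                for a in occ:
                    enc.add_clause(-a, -k[p])
                    enc.add_clause(-a, -k[q])
    # every non-eliminated real mutation has an ancestor (possibly M0)
    for q in range(1, m):
        anc = [enc.a_vars[(p, q)] for p in range(m) if p != q]
        enc.add_clause(*anc, *K(q))
    # ancestor implies column domination and is implied by strict containment
    for p in range(m):
        for q in range(m):
            if p == q:
                continue
            apq = enc.a_vars.get((p, q))
            b10 = enc.b(p, q, 1, 0)
            b11 = enc.b(p, q, 1, 1)
            if apq is not None:
                enc.add_clause(-apq, -enc.b(p, q, 0, 1), *K(p), *K(q))
                enc.add_clause(-b10, -b11, apq, *K(p), *K(q))
            else:  # q == 0: a(p, 0) identically false
                enc.add_clause(-b10, -b11, *K(p))
    # VAF pair gate: a(p,q) only where the pairwise predicate allows it
    pvaf = compute_pvaf(bulk, config.delta)
    for (p, q), a in sorted(enc.a_vars.items()):
        if not pvaf[p, q]:
            enc.add_clause(-a)
    # transitivity
    for p in range(m):
        for q in range(1, m):
            if q == p:
                continue
            for r in range(1, m):
                if r == p or r == q:
                    continue
                enc.add_clause(
                    -enc.a_vars[(p, q)], -enc.a_vars[(q, r)], enc.a_vars[(p, r)]
                )
    # triple-VAF gate on incomparable sibling lineages
    tvaf = _tvaf_table(bulk, config.delta)
    for p in range(m):
        for q in range(1, m):
            if q == p:
                continue
            for r in range(q + 1, m):
                if r == p:
                    continue
                if not tvaf[p, q, r]:
                    enc.add_clause(
                        -enc.a_vars[(p, q)], -enc.a_vars[(p, r)],
                        enc.a_vars[(q, r)], enc.a_vars[(r, q)],
                    )
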