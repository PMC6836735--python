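"""Constraint-encoding semantics: root augmentation, VAF predicates, clause
structure, and the conflict-freeness guarantee of the hard system."""

import itertools

import numpy as np
import pytest

from conftest import random_ternary_matrix
from phiscs import (
    BulkProfile,
    GenotypeMatrix,
    NoiseModel,
    SolverConfig,
    augment_with_root,
    build_encoding,
    compute_pvaf,
    compute_tvaf,
    is_conflict_free,
)
from phiscs.encoding import NULL_MUTATION_ID, ROOT_CELL_ID, strip_root
from phiscs.ilp import solve_encoding_ilp
from phiscs.simulate import SimulationParams, simulate_dataset


def small_bulk(vafs, sample_ids=("S1",)):
    vaf = np.atleast_2d(np.asarray(vafs, dtype=float))
    return BulkProfile(
        [f"m{j}" for j in range(vaf.shape[1])], list(sample_ids), vaf
    )


class TestAugmentWithRoot:
    def setup_method(self):
        self.I = GenotypeMatrix(
            ["c0", "c1"], ["m0", "m1"], np.array([[1, 0], [0, 1]])
        )
        self.bulk = BulkProfile.from_counts(
            ["m0", "m1"], ["S1"], np.array([[40, 30]]), np.array([[60, 70]])
        )

    def test_adds_root_row_and_null_column(self):
        aug, aug_bulk = augment_with_root(self.I, self.bulk)
        assert aug.entries[0].tolist() == [1, 0, 0]
        assert aug.entries[:, 0].tolist() == [1, 1, 1]
        assert aug.cell_ids[0] == ROOT_CELL_ID
        assert aug_bulk.mutation_ids[0] == NULL_MUTATION_ID
        assert np.all(aug_bulk.vaf[:, 0] == 1.0)

    def test_strip_inverts_augmentation(self):
        aug, _ = augment_with_root(self.I, self.bulk)
        assert np.array_equal(strip_root(aug.entries), self.I.entries)

    def test_reserved_id_clash(self):
        clash = GenotypeMatrix(["c0"], [NULL_MUTATION_ID], np.array([[1]]))
        bulk = small_bulk([0.5])
        bulk.mutation_ids[0] = NULL_MUTATION_ID
        with pytest.raises(ValueError, match="reserved"):
            augment_with_root(clash, bulk)


class TestVafPredicates:
    def test_pvaf_tolerance(self):
        pv = compute_pvaf(small_bulk([0.5, 0.5]), delta=0.1)
        assert pv[0, 1] and pv[1, 0] and pv[0, 0]

    def test_pvaf_rejects_larger_descendant(self):
        pv = compute_pvaf(small_bulk([0.3, 0.4]), delta=0.1)
        assert not pv[0, 1] and pv[1, 0]

    def test_pvaf_requires_all_samples(self):
        bulk = BulkProfile(
            ["m0", "m1"], ["S1", "S2"],
            np.array([[0.6, 0.4], [0.3, 0.5]]),
        )
        pv = compute_pvaf(bulk, delta=0.0)
        assert not pv[0, 1]  # wins in sample 1, loses in sample 2

    @pytest.mark.parametrize(
        "vafs,expected", [([0.6, 0.3, 0.2], True), ([0.4, 0.3, 0.2], False)]
    )
    def test_tvaf_sum_rule(self, vafs, expected):
        assert compute_tvaf(small_bulk(vafs), 0.0, 0, 1, 2) is expected

    def test_tvaf_with_clonal_parent(self):
        assert compute_tvaf(small_bulk([1.0, 0.55, 0.45]), 0.0, 0, 1, 2)

    def test_tvaf_argument_contracts(self):
        with pytest.raises(ValueError, match="distinct"):
            compute_tvaf(small_bulk([0.5, 0.4, 0.3]), 0.0, 0, 0, 1)
        with pytest.raises(IndexError):
            compute_tvaf(small_bulk([0.5, 0.4, 0.3]), 0.0, 0, 1, 9)


class TestEncodingStructure:
    def test_minimal_instance_counts(self, noise):
        I = GenotypeMatrix(["c0"], ["m0", "m1"], np.array([[1, 0]]))
        enc = build_encoding(I, noise, SolverConfig())
        assert len(enc.b_vars) == 3
        # 3 B-linking clauses for the single cell plus the pair clause
        assert len(enc.hard_clauses) == 4
        assert len(enc.soft_terms) == I.observed.sum() == 2
        assert not enc.k_vars and not enc.x_vars and not enc.a_vars

    def test_elimination_relaxes_pair_clause(self, noise):
        I = GenotypeMatrix(["c0"], ["m0", "m1"], np.array([[1, 0]]))
        enc = build_encoding(I, noise, SolverConfig(k_max=1))
        pair_clauses = [cl for cl in enc.hard_clauses if len(cl) == 5]
        assert len(pair_clauses) == 1
        kp, kq = enc.k_vars[0], enc.k_vars[1]
        assert set(pair_clauses[0]) >= {kp, kq}
        assert enc.cardinality == ([kp, kq], 1)
        assert len(enc.x_vars) == 2  # only with k_max > 0

    def test_deterministic_construction(self, noise):
        rng = np.random.default_rng(5)
        I = random_ternary_matrix(rng, 4, 3)
        enc1 = build_encoding(I, noise, SolverConfig(k_max=1))
        enc2 = build_encoding(I, noise, SolverConfig(k_max=1))
        assert enc1.hard_clauses == enc2.hard_clauses
        assert enc1.y_vars == enc2.y_vars
        assert enc1.soft_terms == enc2.soft_terms

    def test_bulk_without_augmentation_rejected(self, noise):
        I = GenotypeMatrix(["c0"], ["m0"], np.array([[1]]))
        with pytest.raises(ValueError, match="augment"):
            build_encoding(I, noise, SolverConfig(), small_bulk([0.5]))

    def test_kmax_exceeding_columns_rejected(self, noise):
        I = GenotypeMatrix(["c0"], ["m0"], np.array([[1]]))
        with pytest.raises(ValueError, match="k_max"):
            build_encoding(I, noise, SolverConfig(k_max=2))


def _satisfies(clauses, assignment):
    return all(
        any(assignment[abs(l)] == (l > 0) for l in clause) for clause in clauses
    )


class TestHardSystemSemantics:
    def test_every_satisfying_assignment_is_conflict_free(self, noise):
        """Exhaustive check on a small encoding: hard clauses admit exactly
        the conflict-free matrices."""
        rng = np.random.default_rng(7)
        I = random_ternary_matrix(rng, 3, 2, missing_rate=0.0)
        enc = build_encoding(I, noise, SolverConfig())
        seen_cf = 0
        for bits in itertools.product((False, True), repeat=enc.num_vars):
            assignment = np.array((False,) + bits)
            if _satisfies(enc.hard_clauses, assignment):
                Y = enc.decode_y(assignment)
                assert is_conflict_free(Y)
                seen_cf += 1
        assert seen_cf > 0

    def test_satisfying_assignments_with_elimination(self, noise):
        rng = np.random.default_rng(11)
        I = random_ternary_matrix(rng, 2, 2, missing_rate=0.0)
        enc = build_encoding(I, noise, SolverConfig(k_max=1))
        clauses = enc.hard_clauses + enc.cardinality_clauses()
        k_list, k_max = enc.cardinality
        found_elim = False
        for bits in itertools.product((False, True), repeat=enc.num_vars):
            assignment = np.array((False,) + bits)
            if not _satisfies(clauses, assignment):
                continue
            elim = enc.decode_eliminated(assignment)
            assert len(elim) <= k_max
            assert is_conflict_free(enc.decode_y(assignment), elim)
            # X must equal Y AND K
            for (i, j), x in enc.x_vars.items():
                assert assignment[x] == (
                    assignment[enc.y_vars[(i, j)]] and assignment[enc.k_vars[j]]
                )
            found_elim = found_elim or bool(elim)
        assert found_elim

    def test_sequential_counter_is_exact(self):
        """The cardinality clauses admit an assignment extension iff the
        K-popcount respects the bound."""
        from phiscs.encoding import ConstraintEncoding

        for nk, bound in [(3, 0), (3, 1), (4, 2), (4, 3)]:
            enc = ConstraintEncoding(n=0, m=0, k_max=bound, uses_bulk=False,
                                     augmented=False)
            ks = [enc.new_var() for _ in range(nk)]
            enc.cardinality = (ks, bound)
            clauses = enc.cardinality_clauses()
            n_aux = enc.num_vars - nk
            for kbits in itertools.product((False, True), repeat=nk):
                extendable = False
                for aux in itertools.product((False, True), repeat=n_aux):
                    assignment = np.array((False,) + kbits + aux)
                    if _satisfies(clauses, assignment):
                        extendable = True
                        break
                assert extendable == (sum(kbits) <= bound)


class TestAncestryRelation:
    def test_solver_ancestry_is_strict_partial_order(self, noise):
        """On solved instances with bulk, the a-relation is irreflexive,
        antisymmetric, transitive, and covers co-occurring pairs."""
        for seed in range(3):
            truth = simulate_dataset(SimulationParams(
                n_cells=12, m_mutations=5, s_clones=4, beta=0.1, seed=seed))
            aug, aug_bulk = augment_with_root(truth.noisy_matrix, truth.bulk)
            enc = build_encoding(aug, noise, SolverConfig(delta=0.1), aug_bulk)
            assignment, _, status = solve_encoding_ilp(enc)
            assert status == "optimal"
            anc = enc.decode_ancestry(assignment)
            assert all(p != q for p, q in anc)
            assert not any((q, p) in anc for p, q in anc)
            for p, q in anc:
                for r, s in anc:
                    if q == r:
                        assert (p, s) in anc
            Y = enc.decode_y(assignment)
            for p in range(enc.m):
                for q in range(p + 1, enc.m):
                    if np.any((Y[:, p] == 1) & (Y[:, q] == 1)):
                        assert (p, q) in anc or (q, p) in anc
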