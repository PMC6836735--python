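"""Simulator: determinism, stated parameter regimes, noise calibration,
ISA-violation injection and bulk read-count generation."""

import numpy as np
import pytest

from phiscs import (
    NoiseModel,
    SimulationParams,
    SolverConfig,
    apply_noise,
    find_conflicts,
    inject_isa_violations,
    is_conflict_free,
    mltsm_normalized,
    simulate_bulk,
    simulate_dataset,
    simulate_truth,
    solve_phiscs_i,
)
from phiscs.matrix import MISSING
from phiscs.tree import build_clonal_tree


class TestSimulateTruth:
    def test_same_seed_reproduces_everything(self):
        p = SimulationParams(n_cells=20, m_mutations=8, s_clones=5, seed=11)
        a, b = simulate_dataset(p), simulate_dataset(p)
        assert np.array_equal(a.true_matrix, b.true_matrix)
        assert a.noisy_matrix == b.noisy_matrix
        assert a.bulk == b.bulk
        assert a.tree.labels == b.tree.labels and a.tree.parent == b.tree.parent

    def test_two_clones_single_shared_genotype(self):
        truth = simulate_truth(SimulationParams(
            n_cells=10, m_mutations=3, s_clones=2, seed=0))
        sampled = truth.true_matrix[truth.cell_nodes == 1]
        assert len(np.unique(sampled, axis=0)) == 1
        assert sampled[0].sum() == 3  # all mutations on the single clone

    @pytest.mark.parametrize("seed", range(5))
    def test_prevalence_floor_respected(self, seed):
        truth = simulate_truth(SimulationParams(
            n_cells=50, m_mutations=10, s_clones=10,
            min_prevalence=0.05, h_samples=2, seed=seed))
        assert truth.prevalences.min() >= 0.05
        assert np.allclose(truth.prevalences.sum(axis=1), 1.0)

    def test_every_clone_carries_a_mutation(self):
        truth = simulate_truth(SimulationParams(
            n_cells=30, m_mutations=9, s_clones=10, seed=3))
        assert all(truth.tree.labels[k] for k in range(1, 10))

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError, match="per non-root clone"):
            SimulationParams(n_cells=10, m_mutations=3, s_clones=10)
        with pytest.raises(RuntimeError, match="infeasible"):
            simulate_truth(SimulationParams(
                n_cells=10, m_mutations=30, s_clones=30,
                min_prevalence=0.05, seed=0))

    def test_clean_matrix_admits_perfect_phylogeny(self):
        truth = simulate_truth(SimulationParams(
            n_cells=40, m_mutations=12, s_clones=6, seed=5))
        assert is_conflict_free(truth.true_matrix)


class TestApplyNoise:
    def test_zero_rates_are_identity(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 2, (10, 6))
        out = apply_noise(true, 0.0, 0.0, 0.0, seed_or_rng=1)
        assert np.array_equal(out.entries, true)

    def test_all_missing(self):
        out = apply_noise(np.ones((4, 4), dtype=int), 0.0, 0.0, 1.0, seed_or_rng=1)
        assert (out.entries == MISSING).all()

    def test_false_negative_rate_calibration(self):
        """Observed dropout fraction lands within 3 sigma of beta."""
        beta = 0.15
        true = np.ones((100, 100), dtype=int)
        out = apply_noise(true, 0.0, beta, 0.0, seed_or_rng=123)
        dropped = (out.entries == 0).mean()
        sigma = np.sqrt(beta * (1 - beta) / true.size)
        assert abs(dropped - beta) < 3 * sigma


class TestIsaViolations:
    def test_loss_creates_three_gametes_conflict(self):
        truth = simulate_truth(SimulationParams(
            n_cells=60, m_mutations=10, s_clones=6, seed=5))
        assert is_conflict_free(truth.true_matrix)
        truth = inject_isa_violations(truth, count=1, mode="loss")
        j = next(iter(truth.violating_mutations))
        conflicts = find_conflicts(truth.true_matrix)
        assert any(j in pair for pair in conflicts)

    def test_recurrence_creates_conflict(self):
        truth = simulate_truth(SimulationParams(
            n_cells=60, m_mutations=10, s_clones=6, seed=4))
        truth = inject_isa_violations(truth, count=1, mode="recurrence")
        j = next(iter(truth.violating_mutations))
        assert any(j in pair for pair in find_conflicts(truth.true_matrix))

    def test_cna_vaf_distorts_vaf_only(self):
        truth = simulate_truth(SimulationParams(
            n_cells=40, m_mutations=8, s_clones=5, seed=6))
        before = truth.true_matrix.copy()
        truth = inject_isa_violations(truth, count=2, mode="cna_vaf")
        assert np.array_equal(truth.true_matrix, before)
        assert len(truth.violating_mutations) == 2
        kappa = truth.vaf_distortion
        for j in truth.violating_mutations:
            assert kappa[j] in (1.5, 2.0)  # 3 copies/2 or 4 copies/2


class TestSimulateBulk:
    def test_clonal_mutation_vaf_near_one(self):
        truth = simulate_truth(SimulationParams(
            n_cells=20, m_mutations=5, s_clones=2, coverage=10_000, seed=1))
        bulk = simulate_bulk(truth)
        clonal = truth.node_genotypes[1:].all(axis=0)
        prevalence = truth.prevalences[0] @ truth.node_genotypes
        for j in np.flatnonzero(clonal & (prevalence > 0.99)):
            assert bulk.vaf[0, j] == pytest.approx(prevalence[j], abs=0.05)

    def test_absent_mutation_gives_zero(self):
        truth = simulate_truth(SimulationParams(
            n_cells=10, m_mutations=4, s_clones=3, seed=1))
        truth.node_genotypes[:, 2] = 0
        bulk = simulate_bulk(truth)
        assert bulk.var_reads[0, 2] == 0 and bulk.vaf[0, 2] == 0.0

    def test_ancestor_vaf_dominates_descendant(self):
        """At deep coverage the ancestor/descendant VAF ordering holds in
        >= 95% of draws (Monte-Carlo over seeds)."""
        truth = simulate_truth(SimulationParams(
            n_cells=20, m_mutations=8, s_clones=5, coverage=10_000, seed=0))
        tree = truth.tree
        pairs = [
            (p, q)
            for p in range(8) for q in range(8) if p != q
            and tree.is_ancestor(tree.node_of_label(f"mut{p}"),
                                 tree.node_of_label(f"mut{q}"))
        ]
        assert pairs
        rng = np.random.default_rng(77)
        ok = total = 0
        for _ in range(40):
            bulk = simulate_bulk(truth, rng=rng)
            for p, q in pairs:
                total += 1
                ok += bulk.vaf[0, p] >= bulk.vaf[0, q]
        assert ok / total >= 0.95


class TestEndToEndIdentity:
    @pytest.mark.parametrize("seed", range(3))
    def test_zero_noise_recovers_truth_tree(self, seed):
        """No noise, no ISA violations: the solver flips nothing and the
        rebuilt tree matches the ground truth label partition."""
        p = SimulationParams(n_cells=50, m_mutations=10, s_clones=6,
                             alpha=1e-4, beta=0.1, missing_rate=0.0, seed=seed)
        truth = simulate_truth(p)
        clean = apply_noise(truth.true_matrix, 0.0, 0.0, 0.0, seed_or_rng=0)
        res = solve_phiscs_i(clean, NoiseModel(alpha=1e-4, beta=0.1),
                             SolverConfig())
        assert res.flips_0_to_1 == res.flips_1_to_0 == 0
        inferred = build_clonal_tree(res.Y, res.eliminated,
                                     res.cell_ids, res.mutation_ids)
        assert mltsm_normalized(inferred, truth.tree) == 1.0


class TestParameterRecovery:
    def test_corrections_reflect_injected_dropout_rate(self):
        """The solver's 0->1 corrections quantitatively track the injected
        dropout noise: nearly every correction is a genuine dropout
        (precision >= 0.9), and the implied dropout rate (observed zeros
        among fitted-1 entries) recovers the right order of beta without
        ever overshooting it.

        The implied rate systematically *under*-estimates beta: a dropout
        of a clone's deepest distinguishing mutation is invisible, because
        attaching the cell to the ancestor clone has higher likelihood
        than flipping the entry, so such dropouts leave both the flip
        count and the fitted-1 pool.
        """
        beta = 0.15
        noise = NoiseModel(alpha=1e-4, beta=beta)
        flips = fitted_ones = genuine = 0
        for seed in range(10):
            truth = simulate_dataset(SimulationParams(
                n_cells=100, m_mutations=20, s_clones=10, alpha=1e-4,
                beta=beta, missing_rate=0.05, seed=seed))
            res = solve_phiscs_i(truth.noisy_matrix, noise)
            obs = truth.noisy_matrix.observed
            flips += res.flips_0_to_1
            fitted_ones += int((obs & (res.Y == 1)).sum())
            genuine += int((obs & (truth.noisy_matrix.entries == 0)
                            & (res.Y == 1) & (truth.true_matrix == 1)).sum())
        assert genuine / flips >= 0.9
        implied = flips / fitted_ones
        assert beta / 2 < implied <= beta
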