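# phiscs

Exact subperfect tumor phylogeny inference from single-cell genotype
matrices, optionally constrained by bulk-sequencing variant allele
frequencies (VAFs).

## The problem

Single-cell DNA sequencing yields, per tumor, a ternary matrix *I* of *n*
cells × *m* somatic mutations with entries 0 (absent), 1 (present) or `?`
(missing).  The data are noisy: a truly present mutation drops out with
probability β (allele dropout, typically 0.05–0.25) and a truly absent one
is called present with probability α (read errors, ~10⁻⁴).  Under the
infinite sites assumption (ISA) the true genotypes admit a *perfect
phylogeny*: no pair of mutation columns may exhibit the three row
configurations (1,0), (0,1), (1,1) — the three-gametes rule.  Real tumors
violate ISA for a few mutations (deletions, LOH, convergent evolution,
mis-estimated copy number), so a bounded number of columns may have to be
eliminated before a perfect phylogeny exists.

`phiscs` solves the resulting *optimal subperfect phylogeny* problem to
**proven optimality**: find a conflict-free binary matrix *Y* and an
eliminated-mutation set *K*, |*K*| ≤ k_max, maximizing

```
log P(I | Y, K) = Σ_{(i,j) observed, j ∉ K} log P(I(i,j) | Y(i,j))
```

with  P(0|0)=1−α, P(0|1)=β, P(1|0)=α, P(1|1)=1−β, missing entries free.

When matched bulk sequencing is available, each mutation's
prevalence-scaled VAF, vaf = 2v/(v+r) for v variant and r reference reads
(a diploid heterozygous proxy for the fraction of cells carrying the
mutation), imposes hard *lineage constraints* on the tree: an ancestor p of
q must satisfy vaf(p)(1+δ) ≥ vaf(q) in every bulk sample, and an ancestor
of two incomparable descendants q, r must satisfy
vaf(p)(1+δ) ≥ vaf(q)+vaf(r).  These are enforced through an explicit
ancestor relation a(p,q) anchored at an artificial root (null mutation M0,
vaf = 1).

Two interchangeable exact back-ends realize one shared constraint system:

* **ILP** (`solve_phiscs_i`) — direct 0/1 integer program;
* **weighted Max-SAT** (`solve_phiscs_b`) — weighted partial CNF with
  sign-normalized integer clause weights and a sequential-counter
  cardinality encoding, exportable as DIMACS-WCNF.

Both are solved with HiGHS (`scipy.optimize.milp`) and return the same
objective up to the Max-SAT weight-rounding resolution (≤ nm/10⁶ nats).
The corrected matrix yields a clonal tree (identical columns merge into
multi-label nodes; cells attach to their clone), and inferred trees are
compared to ground truth with MLTD/MLTSM, TPTED and normalized
Robinson-Foulds distances.  A simulator generates benchmark data: random
clonal trees, Dirichlet subclone prevalences with a minimum-prevalence
floor, FP/FN/missing noise, injected ISA violations (mutation loss,
parallel recurrence, copy-number VAF distortion) and binomial bulk read
counts.

## Worked example

Simulate 100 cells from 8 subclones with 12 mutations (one of which is
lost in a subtree, violating ISA), then solve with elimination and bulk
VAFs enabled:

```sh
$ phiscs simulate -n 100 -m 12 -s 8 --fn 0.15 --isa 1 --isa-mode loss \
      --seed 1 --out sim
wrote simulation to sim

$ phiscs solve sim/noisy_matrix.tsv --fn 0.15 --fp 0.0001 --kmax 1 \
      --bulk sim/bulk.tsv --out run
status=optimal objective=-100.004413 flips 0->1=31 1->0=0 \
missing assigned=52 eliminated=['mut2']

$ phiscs compare run/tree.nwk sim/truth_tree.nwk --metric mltsm
mltsm = 0.9166666666666666
```

The solver proved optimality, corrected 31 dropout entries (0→1), assigned
the 52 missing entries, and eliminated `mut2` — exactly the mutation the
simulator had marked as the ISA violator (see `sim/manifest.json`).  The
inferred tree shares 11 of the 12 truth mutations in a maximum common tree
(MLTSM 11/12 ≈ 0.917; the eliminated violator is absent by design).
`run/` also contains the corrected matrix, the tree in DOT and Newick
form, the cell attachments and a JSON run report.

The same workflow is available from Python:

```python
from phiscs import (NoiseModel, SolverConfig, SimulationParams,
                    simulate_dataset, solve_phiscs_b, build_clonal_tree)

truth = simulate_dataset(SimulationParams(n_cells=100, m_mutations=12,
                                          s_clones=8, beta=0.15, seed=1))
res = solve_phiscs_b(truth.noisy_matrix, NoiseModel(alpha=1e-4, beta=0.15),
                     SolverConfig(k_max=1, delta=0.1), truth.bulk)
tree = build_clonal_tree(res.Y, res.eliminated, res.cell_ids, res.mutation_ids)
```

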