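# Methods

## Noise model and objective

Each observed entry of the ternary cell × mutation matrix *I* is an
independent read-out of an unknown true binary state *Y(i,j)*:

    P(I=0 | Y=0) = 1−α     P(I=0 | Y=1) = β
    P(I=1 | Y=0) = α       P(I=1 | Y=1) = 1−β

α is the false positive (read error) rate, β the false negative (allele
dropout) rate; both must lie in (0, 0.5) so that leaving an entry
unchanged is entrywise optimal.  Missing entries are noninformative: they
receive a state in the solution but contribute nothing to the objective.
All logarithms are natural; objectives are reported in nats.

The solver maximizes Σ log P(I(i,j) | Y(i,j)) over observed entries,
subject to *Y* being conflict-free (three-gametes rule) on non-eliminated
columns.  With elimination enabled (k_max > 0), a binary indicator K(j)
zeroes the j-th column's contribution and the pair constraints are relaxed
for pairs involving eliminated columns; Σ K ≤ k_max.  Because every kept
column contributes negatively, elimination never decreases the objective —
k_max is a hard budget, not a penalty, and with k_max > 0 the optimum
always uses the full budget.  A practical consequence (visible in the
simulations): the gain from eliminating a column is its entire likelihood
mass, so a clonal, high-prevalence column (many observed 1s, each costing
log(1−β) when kept) can compete with a genuine ISA violator whose
conflicts are cheap to repair.  Recovery of an injected violator is
therefore a stochastic outcome (~70–90% per seed batch at 100 cells, 10
mutations, β = 0.15), not an identity.

## One encoding, two exact back-ends

All hard constraints are expressible as disjunctive clauses over binary
variables plus one cardinality bound, so a single encoding feeds both
solvers:

* Y(i,j) — true states; B(p,q,a,b) for (a,b) ∈ {(0,1),(1,0),(1,1)} —
  witnesses that some row shows pattern (a,b) on column pair (p,q),
  lower-bounded by three linking clauses per cell and pair; the pair
  clause forbids all three witnesses simultaneously (relaxed by K
  literals when elimination is on).
* X(i,j) = Y(i,j) ∧ K(j) linearizes the product in the elimination
  objective (three clauses per real entry).
* a(p,q) — ancestor indicators, emitted only when bulk data is present:
  antisymmetry, transitivity, "co-occurrence implies comparability",
  "ancestor implies column domination" (no (0,1) row), and "strict
  containment implies ancestry", each with K escapes when elimination is
  enabled.
* VAF gates: a(p,q) is forced off unless vaf_ℓ(p)(1+δ) ≥ vaf_ℓ(q) in
  every bulk sample ℓ (pairwise predicate); for every triple with p above
  incomparable q, r, the triple inequality vaf_ℓ(p)(1+δ) ≥
  vaf_ℓ(q)+vaf_ℓ(r) is enforced by emitting a clause only for triples
  whose predicate fails, keeping the system O(m²) clauses in benign data.
* Root augmentation: with bulk data the matrix gains a healthy-cell row
  and a null-mutation column M0 (present in every cell, vaf ≡ 1, never
  eliminable), fixed by unit clauses; every real mutation must have an
  ancestor (possibly M0).  The augmentation is internal and stripped from
  all outputs.

The **ILP back-end** translates each clause to "sum of literal values
≥ 1", keeps the cardinality bound as a single linear row, and uses the
real-valued soft terms as the objective.  The **Max-SAT back-end** builds
a weighted partial CNF: the cardinality bound becomes a sequential-counter
clause block; each soft unit term with negative weight w on literal L is
sign-normalized to (¬L, |w|) with the constant recorded, and all weights
are scaled by S_w = 10⁶ and rounded to integers (the argmax is preserved
to 1/S_w per term; the engine's objective resolution is nm/S_w, and the
reported objective is always recomputed in exact real arithmetic from the
decoded matrix).  Per-entry ¬K(j) constants are aggregated into one
weighted unit clause per column.  The WCNF is exportable as DIMACS-WCNF.

Both systems are solved to proven optimality with HiGHS
(`scipy.optimize.milp`); for the WCNF the clauses are translated to 0/1
linear constraints.  The two routes are distinct encodings of the same
optimum and are cross-checked against each other and against exhaustive
enumeration in the test suite.  Ties among co-optimal matrices are broken
by the engine; equality of objectives, not of matrices, is the
cross-backend contract.

Infeasibility cannot arise without bulk data (a conflict-free completion
always exists); an infeasible model therefore signals contradictory VAF
constraints at the given δ and k_max and is raised as an explicit error.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| α | 10⁻⁴ | false positive rate (read errors are rare) |
| β | 0.05–0.25 | false negative rate; set per data set (dropout dominates) |
| k_max | 0 | elimination budget; 0 demands a plain perfect phylogeny |
| δ | 0.1 | multiplicative VAF slack; ~10% absorbs coverage noise at the simulated depths (binomial sd of vaf at 10,000× is ≈0.01, at 100× ≈0.1) |
| S_w | 10⁶ | integer weight scale of the Max-SAT route |

VAFs are *not* clamped to [0,1]: 2v/(v+r) ranges over [0,2] and values
above 1 (copy-number gains) are passed through; the null mutation's vaf is
exactly 1, so a mutation with vaf > 1+δ can have no ancestor and must be
eliminated or the model is infeasible — by design, since such columns are
exactly the copy-number-distorted ones.

## Clonal tree construction

A conflict-free matrix's column supports form a laminar family.  Columns
are deduplicated (identical columns share one multi-label node), ordered
by descending 1-count (ties by original column order), and linked to the
minimal strict superset; each cell attaches to the node whose root-path
label union equals its genotype (for conflict-free input this always
exists; a permissive fallback attaches to the deepest compatible node,
and `strict=True` raises instead).  Serialization: Graphviz DOT, Newick
(multi-labels joined by `+`, round-trippable), and a cell-attachment TSV.

## Tree comparison

*MLTD* — minimum label deletions (empty-leaf deletions and vertex
expansions free) until both trees reach a maximum common tree; *MLTSM* is
the common-tree label count, normalized by the larger tree's label count.
Computed exactly: a label pair's relation (same node / strict ancestor /
incomparable) is taken in both trees; "same node" joins with either strict
order (expansion can split a node), incomparability only with itself; a
subset of shared labels is realizable iff all pairs join and every label's
strict ancestors are mutually comparable.  Maximum feasible subsets are
found by branch-and-bound over labels — worst-case exponential but fast at
clonal-tree scale; trees over 64 labels are rejected rather than
approximated.

*TPTED* — edit distance with unit-cost node deletions after expanding
multi-label nodes into chains.  The within-node expansion order is chosen
optimally (the distance is then invariant to label order inside nodes),
which makes the feasibility relation coincide with MLTD's; on unique-label
trees TPTED ≤ MLTD consequently holds with equality.  This is this
package's interpretation of a measure whose published definition is not
fully specified; the implemented variant satisfies the documented ordering
and identity properties.

*Normalized RF* — cell-lineage trees (cells as leaf children of their
clones, mutation labels dropped, cell-free subtrees pruned) are compared
by the symmetric difference of nontrivial unrooted leaf bipartitions,
divided by the total nontrivial bipartition count of both trees (0 for
two stars).  Bipartition handling uses dendropy.

## Simulator

The generator emulates the standard benchmark regime for this problem
class.  Defaults: 100 cells, 40 mutations, 10 tree nodes (root = healthy),
α = 10⁻⁴, β = 0.15, 5% missing entries, one bulk sample at 10,000×
coverage, 5% minimum subclone prevalence, no ISA violations.

* **Topology** — random recursive tree: each new node picks a uniform
  existing parent.  Every non-root node receives one mutation; remaining
  mutations are spread uniformly.
* **Prevalences** — per bulk sample, a flat Dirichlet over nodes,
  rejection-sampled until the minimum prevalence floor holds.
* **Cells** — multinomial by sample-1 prevalence, rejection-sampled (when
  n ≥ s) until every clone is represented: the prevalence floor exists so
  that subclones are observable, and without the guarantee exact-recovery
  checks would fail by sampling accident alone.
* **Noise** — independent per entry: missing with the stated rate,
  otherwise 1→0 with probability β and 0→1 with probability α.
* **ISA violations** — *loss*: a mutation's 1-entries are zeroed in a
  random subtree at least two edges below its origin (a mutated node
  remains strictly between, so the violation is guaranteed to manifest as
  a three-gametes conflict; shallower losses are invisible to any
  conflict-based method and are not drawn); *recurrence*: a second gain at
  an incomparable node that has a non-root strict ancestor outside the
  origin's lineage (same observability argument); *cna_vaf*: genotypes
  untouched, the mutation's bulk success probability is scaled by
  variant-copies/2 for a clonal copy number in {3, 4}.
* **Bulk** — per sample and mutation, variant reads ~
  Binomial(coverage, c/2 · κ) with c the summed prevalence of
  genotype-carrying nodes and κ the copy-number distortion; vaf =
  2v/(v+r).
* **Reproducibility** — one RNG stream per artifact (topology,
  prevalences, cells, ISA, noise, bulk), all spawned from the master seed,
  so regenerating one artifact leaves the others fixed.

What the simulator does **not** emulate: doublets (assumed removed
upstream), subclonal (branch-restricted) copy-number events, locus- or
cell-specific error rates, and correlated dropout.  Passing tests
therefore demonstrate correctness of the optimization and the claimed
behavior under the stated noise regime, not robustness to every artifact
of real single-cell data.

## Verification strategy and problem sizes

The test suite checks both back-ends against exhaustive enumeration (all
2^16 completions of 4×4 matrices, with and without elimination), checks
cross-backend objective equality on instances up to 8×6 with and without
bulk constraints, verifies conflict-freeness and zero lineage violations
for every solver output, exact recovery on clean 50×10 data over 20
seeds, elimination of injected loss-type violators at 100×10 (a ≥8/10
stochastic bound), and the paired benefit of one bulk sample at 100×20,
β = 0.2 (at these sizes both arms typically recover the tree exactly, so
the paired comparison holds at saturation).  These sizes keep a full run
in well under two minutes on one CPU while every check remains exact;
`scripts/acceptance.py` re-measures the same quantities end to end.

## Known limitations

* The exact MLTD/TPTED search is exponential in the worst case and capped
  at 64 labels; the polynomial MLTD algorithm is an acknowledged future
  optimization.
* The generalized multi-child VAF constraint (a parent's VAF bounding the
  sum over three or more incomparable children) is intentionally not
  enforced; the pairwise and triple constraints are.
* Solver-internal tie-breaking among co-optimal solutions is not seeded;
  the objective value is deterministic, the reported matrix may vary
  across library versions.
* k_max is a user input; no automatic estimation is performed.
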