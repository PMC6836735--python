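"""Ground-truth simulator: clonal trees, noisy single-cell matrices with
ISA violations, and binomial bulk read counts.

The generator emulates the canonical benchmark regime for single-cell
phylogeny methods: a random recursive clonal tree whose nodes acquire one
or more mutations, per-sample subclonal prevalences drawn from a flat
Dirichlet with a rejection-enforced minimum-prevalence floor, multinomial
cell sampling, independent per-entry false positive / false negative /
missing noise, optional ISA-violating mutations (loss, parallel
recurrence, or copy-number VAF distortion), and bulk variant read counts
binomial at a stated coverage.

Default parameters are the benchmark conditions: 100 cells from 10
subclones carrying 40 mutations, false positive rate 1e-4, false negative
rate 0.15, missing rate 0.05, a 5% prevalence floor, one bulk sample at
10,000x coverage, and no ISA violations unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bulk import BulkProfile
from .matrix import MISSING, GenotypeMatrix
from .tree import ClonalTree


@dataclass(frozen=True)
class SimulationParams:
    n_cells: int = 100
    m_mutations: int = 40
    s_clones: int = 10  # tree nodes including the healthy root
    alpha: float = 1e-4
    beta: float = 0.15
    missing_rate: float = 0.05
    h_samples: int = 1
    coverage: int = 10_000
    min_prevalence: float = 0.05
    isa_count: int = 0
    isa_mode: str = "loss"  # loss | recurrence | cna_vaf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_clones < 2:
            raise ValueError("need at least one non-root clone")
        if self.m_mutations < self.s_clones - 1:
            raise ValueError("need at least one mutation per non-root clone")
        if self.isa_count >= self.m_mutations:
            raise ValueError("isa_count must be below the mutation count")
        if self.isa_mode not in ("loss", "recurrence", "cna_vaf"):
            raise ValueError(f"unknown isa_mode {self.isa_mode!r}")


@dataclass
class SimulationTruth:
    """Everything the generator knows: tree, prevalences, matrices, bulk."""

    params: SimulationParams
    tree: ClonalTree
    prevalences: np.ndarray = field(repr=False)  # (h_samples, s_clones)
    node_genotypes: np.ndarray = field(repr=False)  # (s_clones, m) binary
    cell_nodes: np.ndarray = field(repr=False)  # (n_cells,) node index
    true_matrix: np.ndarray = field(repr=False)  # (n_cells, m) binary
    noisy_matrix: GenotypeMatrix | None = None
    bulk: BulkProfile | None = None
    violating_mutations: set[int] = field(default_factory=set)
    vaf_distortion: np.ndarray | None = field(default=None, repr=False)

    @property
    def cell_ids(self) -> list[str]:
        return [f"cell{i}" for i in range(self.params.n_cells)]

    @property
    def mutation_ids(self) -> list[str]:
        return [f"mut{j}" for j in range(self.params.m_mutations)]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """One RNG stream per artifact, all derived from the master seed, so
    e.g. regenerating noise leaves the topology untouched."""
    names = ("topology", "prevalence", "cells", "isa", "noise", "bulk")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}


def simulate_truth(params: SimulationParams) -> SimulationTruth:
    """Draw the ground-truth tree, prevalences, cells and clean matrix."""
    rngs = _streams(params.seed)
    s, m, n, h = params.s_clones, params.m_mutations, params.n_cells, params.h_samples

    # random recursive tree: each new node picks a uniform existing parent
    rng = rngs["topology"]
    parent: list[int | None] = [None]
    for k in range(1, s):
        parent.append(int(rng.integers(0, k)))

    # one mutation per non-root node, remainder spread uniformly
    owner = np.empty(m, dtype=np.int64)
    owner[: s - 1] = np.arange(1, s)
    owner[s - 1:] = rng.integers(1, s, size=m - (s - 1))

    labels: list[list[str]] = [[]] + [[] for _ in range(s - 1)]
    for j in range(m):
        labels[owner[j]].append(f"mut{j}")
    tree = ClonalTree(labels=labels, parent=parent)

    node_genotypes = np.zeros((s, m), dtype=np.int8)
    for v in range(s):
        for lab in tree.path_labels(v):
            node_genotypes[v, int(lab[3:])] = 1

    # per-sample prevalences: flat Dirichlet, rejected until the floor holds
    rng = rngs["prevalence"]
    prevalences = np.empty((h, s))
    for ell in range(h):
        for attempt in range(10_000):
            draw = rng.dirichlet(np.ones(s))
            if draw.min() >= params.min_prevalence:
                prevalences[ell] = draw
                break
        else:
            raise RuntimeError(
                f"min_prevalence={params.min_prevalence} infeasible for "
                f"{s} clones (rejection cap reached)"
            )

    # multinomial cell sampling by sample-1 prevalence; when enough cells are
    # drawn, reject assignments that leave a clone unsampled — the
    # prevalence floor exists so that every subclone is observable
    rng = rngs["cells"]
    for attempt in range(10_000):
        cell_nodes = rng.choice(s, size=n, p=prevalences[0])
        if n < s or len(np.unique(cell_nodes)) == s:
            break
    else:
        raise RuntimeError("could not sample every clone (rejection cap reached)")
    tree.attachments = {f"cell{i}": int(v) for i, v in enumerate(cell_nodes)}
    true_matrix = node_genotypes[cell_nodes].copy()
    truth = SimulationTruth(
        params=params,
        tree=tree,
        prevalences=prevalences,
        node_genotypes=node_genotypes,
        cell_nodes=cell_nodes,
        true_matrix=true_matrix,
    )
    if params.isa_count:
        truth = inject_isa_violations(truth, params.isa_count, params.isa_mode,
                                      rng=rngs["isa"])
    return truth


def inject_isa_violations(
    truth: SimulationTruth,
    count: int,
    mode: str = "loss",
    rng: np.random.Generator | None = None,
) -> SimulationTruth:
    """Make ``count`` mutations violate the infinite sites assumption.

    * ``loss`` — the mutation's 1-entries are zeroed in a random proper
      subtree below its node of origin (deletion / LOH);
    * ``recurrence`` — the mutation is additionally gained at a random node
      incomparable to its origin (convergent evolution);
    * ``cna_vaf`` — genotypes untouched; the mutation's bulk VAF is scaled
      by variant_copies/2 for a random clonal copy-number state in {3, 4}
      (undetected gain distorting the VAF only).
    """
    if rng is None:
        rng = _streams(truth.params.seed)["isa"]
    s = truth.params.s_clones
    tree = truth.tree
    owner = {j: tree.node_of_label(f"mut{j}")
             for j in range(truth.params.m_mutations)}
    kappa = (np.ones(truth.params.m_mutations)
             if truth.vaf_distortion is None else truth.vaf_distortion.copy())

    def descendants(v: int) -> list[int]:
        return [u for u in range(s) if tree.is_ancestor(v, u)]

    def incomparable(v: int) -> list[int]:
        return [
            u for u in range(1, s)
            if u != v and not tree.is_ancestor(v, u) and not tree.is_ancestor(u, v)
        ]

    chosen: set[int] = set(truth.violating_mutations)
    candidates = [j for j in range(truth.params.m_mutations) if j not in chosen]
    rng.shuffle(candidates)
    for j in candidates:
        if len(chosen) - len(truth.violating_mutations) == count:
            break
        v = owner[j]
        if mode == "loss":
            # the lost subtree must sit >= 2 edges below the origin, so a
            # mutation-bearing node remains strictly between them and the
            # violation manifests as a three-gametes conflict
            below = [
                d for d in descendants(v)
                if tree.parent[d] is not None and tree.is_ancestor(v, tree.parent[d])
            ]
            if not below:
                continue
            lost_root = int(rng.choice(below))
            lost_nodes = [lost_root] + descendants(lost_root)
            truth.node_genotypes[lost_nodes, j] = 0
        elif mode == "recurrence":
            # the second gain must have a non-root strict ancestor outside
            # the origin's lineage, which guarantees an observable conflict
            others = [
                u for u in incomparable(v)
                if any(
                    w != 0 and not tree.is_ancestor(w, v) and w != v
                    for w in range(1, s) if tree.is_ancestor(w, u)
                )
            ]
            if not others:
                continue
            gained = int(rng.choice(others))
            gain_nodes = [gained] + descendants(gained)
            truth.node_genotypes[gain_nodes, j] = 1
        else:  # cna_vaf
            total_copies = int(rng.choice((3, 4)))
            variant_copies = int(rng.integers(2, total_copies + 1))
            kappa[j] = variant_copies / 2.0
        chosen.add(j)
    newly = len(chosen) - len(truth.violating_mutations)
    if newly < count:
        raise RuntimeError(
            f"only {newly} of {count} requested ISA violations had an "
            "eligible subtree/node"
        )
    truth.true_matrix = truth.node_genotypes[truth.cell_nodes].copy()
    truth.violating_mutations = chosen
    truth.vaf_distortion = kappa
    return truth


def apply_noise(
    true_matrix: np.ndarray,
    alpha: float,
    beta: float,
    missing_rate: float,
    seed_or_rng,
    cell_ids=None,
    mutation_ids=None,
) -> GenotypeMatrix:
    """Independent per-entry observation noise.

    Each entry goes missing with probability ``missing_rate``; otherwise a
    true 1 is read as 0 with probability ``beta`` and a true 0 as 1 with
    probability ``alpha``.
    """
    for name, rate in (("alpha", alpha), ("beta", beta),
                       ("missing_rate", missing_rate)):
        if not (0.0 <= rate < 1.0 or (name == "missing_rate" and rate == 1.0)):
            raise ValueError(f"{name} must be in [0, 1)")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    true_matrix = np.asarray(true_matrix)
    n, m = true_matrix.shape
    obs = true_matrix.astype(np.int8).copy()
    u = rng.random((n, m))
    obs[(true_matrix == 1) & (u < beta)] = 0
    obs[(true_matrix == 0) & (u < alpha)] = 1
    obs[rng.random((n, m)) < missing_rate] = MISSING
    return GenotypeMatrix(
        cell_ids=list(cell_ids) if cell_ids else [f"cell{i}" for i in range(n)],
        mutation_ids=list(mutation_ids) if mutation_ids else [f"mut{j}" for j in range(m)],
        entries=obs,
    )


def simulate_bulk(
    truth: SimulationTruth,
    coverage: int | None = None,
    h_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> BulkProfile:
    """Binomial bulk read counts from the truth's cellular prevalences.

    For mutation q in sample l, the cellular prevalence c is the summed
    prevalence of nodes whose genotype carries q; variant reads are
    Binomial(coverage, c/2 * kappa_q) where kappa_q is the copy-number VAF
    distortion (1 without one), reference reads make up the coverage, and
    vaf = 2v/(v+r).
    """
    params = truth.params
    coverage = coverage if coverage is not None else params.coverage
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    h = h_samples if h_samples is not None else params.h_samples
    if h > truth.prevalences.shape[0]:
        raise ValueError("more samples requested than prevalence draws")
    if rng is None:
        rng = _streams(params.seed)["bulk"]
    kappa = (np.ones(params.m_mutations)
             if truth.vaf_distortion is None else truth.vaf_distortion)
    prevalence = truth.prevalences[:h] @ truth.node_genotypes  # (h, m)
    p = np.clip(prevalence / 2.0 * kappa[None, :], 0.0, 1.0)
    var = rng.binomial(coverage, p)
    ref = coverage - var
    return BulkProfile.from_counts(
        truth.mutation_ids,
        [f"sample{ell + 1}" for ell in range(h)],
        var,
        ref,
    )


def simulate_dataset(params: SimulationParams) -> SimulationTruth:
    """One-call pipeline: truth + noisy matrix + bulk profile."""
    rngs = _streams(params.seed)
    truth = simulate_truth(params)
    truth.noisy_matrix = apply_noise(
        truth.true_matrix, params.alpha, params.beta, params.missing_rate,
        rngs["noise"], truth.cell_ids, truth.mutation_ids,
    )
    truth.bulk = simulate_bulk(truth, rng=rngs["bulk"])
    return truth
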