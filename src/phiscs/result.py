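"""Solve result container shared by both back-ends."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SolveResult:
    """Outcome of a genotype-correction solve.

    ``Y`` is the corrected binary matrix over the original (unaugmented)
    cells and mutations; ``eliminated`` holds original column indices of
    mutations removed as ISA violators.  ``objective`` is the log-likelihood
    (nats) of ``Y`` given the input matrix, with eliminated columns zeroed,
    recomputed exactly from the decoded solution.  Flip and assignment
    counts are taken over non-eliminated columns only.
    """

    Y: np.ndarray = field(repr=False)
    eliminated: frozenset[int]
    objective: float
    flips_0_to_1: int
    flips_1_to_0: int
    assigned_missing: int
    status: str  # optimal | feasible | infeasible | timeout
    cell_ids: list[str] = field(default_factory=list, repr=False)
    mutation_ids: list[str] = field(default_factory=list, repr=False)
    backend: str = ""
    solve_seconds: float = 0.0

    @property
    def eliminated_ids(self) -> list[str]:
        return [self.mutation_ids[q] for q in sorted(self.eliminated)]
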