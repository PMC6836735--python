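"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phiscs import GenotypeMatrix, NoiseModel
from phiscs.matrix import MISSING


@pytest.fixture
def noise() -> NoiseModel:
    return NoiseModel(alpha=0.01, beta=0.2)


def random_ternary_matrix(
    rng: np.random.Generator, n: int, m: int, missing_rate: float = 0.1
) -> GenotypeMatrix:
    entries = rng.integers(0, 2, (n, m)).astype(np.int8)
    entries[rng.random((n, m)) < missing_rate] = MISSING
    return GenotypeMatrix(
        cell_ids=[f"c{i}" for i in range(n)],
        mutation_ids=[f"m{j}" for j in range(m)],
        entries=entries,
    )


# ---------------------------------------------------------------------------
# independent brute-force oracle: exhaustive enumeration of all binary
# matrices, filtered to conflict-free, maximizing the entrywise likelihood


def enumerate_binary(n: int, m: int) -> np.ndarray:
    """All 2^(n*m) binary matrices, shape (2^(n*m), n, m)."""
    nm = n * m
    codes = np.arange(2**nm, dtype=np.uint32)
    bits = (codes[:, None] >> np.arange(nm)) & 1
    return bits.reshape(-1, n, m).astype(np.int8)


def conflict_free_mask(Ys: np.ndarray) -> np.ndarray:
    """Vectorized three-gametes check over a stack of binary matrices."""
    _, n, m = Ys.shape
    ok = np.ones(len(Ys), dtype=bool)
    for p in range(m):
        for q in range(p + 1, m):
            a = Ys[:, :, p].astype(bool)
            b = Ys[:, :, q].astype(bool)
            conflict = (
                (a & b).any(axis=1)
                & (a & ~b).any(axis=1)
                & (~a & b).any(axis=1)
            )
            ok &= ~conflict
    return ok


def likelihood_vector(I: GenotypeMatrix, Ys: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Log-likelihood of each stacked Y given I (missing entries skipped)."""
    c0 = np.zeros(I.entries.shape)
    c1 = np.zeros(I.entries.shape)
    obs0 = I.entries == 0
    obs1 = I.entries == 1
    c0[obs0] = np.log(1 - noise.alpha)
    c1[obs0] = np.log(noise.beta)
    c0[obs1] = np.log(noise.alpha)
    c1[obs1] = np.log(1 - noise.beta)
    return c0.sum() + np.tensordot(Ys, c1 - c0, axes=([1, 2], [0, 1]))


def brute_force_optimum(I: GenotypeMatrix, noise: NoiseModel, k_max: int = 0) -> float:
    """Exact maximum of the elimination objective by full enumeration.

    Enumerates every conflict-free binary completion; with k_max = 1 also
    every single-column elimination (recursively reusing the k_max = 0
    enumeration on the reduced matrix).  Independent of the solver path.
    """
    Ys = enumerate_binary(I.n, I.m)
    mask = conflict_free_mask(Ys)
    best = likelihood_vector(I, Ys, noise)[mask].max()
    if k_max >= 1:
        for j in range(I.m):
            keep = [c for c in range(I.m) if c != j]
            sub = GenotypeMatrix(
                I.cell_ids, [I.mutation_ids[c] for c in keep], I.entries[:, keep]
            )
            best = max(best, brute_force_optimum(sub, noise, k_max - 1))
    return float(best)
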