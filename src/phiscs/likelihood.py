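"""Log-likelihood of a corrected genotype matrix under the FP/FN noise model.

Each observed entry I(i,j) is an independent noisy read-out of the true
state Y(i,j):

    P(I=0 | Y=0) = 1 - alpha      P(I=0 | Y=1) = beta
    P(I=1 | Y=0) = alpha          P(I=1 | Y=1) = 1 - beta

Missing entries are noninformative and contribute nothing.  The solvers
maximize the sum of the entrywise log probabilities over the observed index
set S; with column elimination, terms of eliminated columns are zeroed.
All logarithms are natural (objectives in nats).
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import numpy as np

from .matrix import MISSING, GenotypeMatrix, NoiseModel


def entry_log_prob(observed: int, true_state: int, noise: NoiseModel) -> float:
    """Log probability of one observed binary entry given its true state."""
    if observed not in (0, 1) or true_state not in (0, 1):
        raise ValueError("observed and true_state must be binary")
    if observed == 0:
        return math.log(1.0 - noise.alpha) if true_state == 0 else math.log(noise.beta)
    return math.log(noise.alpha) if true_state == 0 else math.log(1.0 - noise.beta)


def _log_prob_table(noise: NoiseModel) -> np.ndarray:
    # table[observed, true]
    return np.log(np.array([
        [1.0 - noise.alpha, noise.beta],
        [noise.alpha, 1.0 - noise.beta],
    ]))


def log_likelihood(I: GenotypeMatrix, Y: np.ndarray, noise: NoiseModel) -> float:
    """Log P(I | Y) summed over non-missing entries of ``I``."""
    Y = np.asarray(Y)
    if Y.shape != I.entries.shape:
        raise ValueError(f"Y shape {Y.shape} != I shape {I.entries.shape}")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("Y must be binary")
    table = _log_prob_table(noise)
    obs = I.observed
    return float(table[I.entries[obs], Y[obs]].sum())


def objective_with_elimination(
    I: GenotypeMatrix,
    Y: np.ndarray,
    eliminated: Iterable[int],
    noise: NoiseModel,
) -> float:
    """Log-likelihood with the terms of eliminated columns zeroed out.

    ``eliminated`` holds column indices; with an empty set this reduces to
    :func:`log_likelihood`.
    """
    Y = np.asarray(Y)
    if Y.shape != I.entries.shape:
        raise ValueError(f"Y shape {Y.shape} != I shape {I.entries.shape}")
    elim = set(int(q) for q in eliminated)
    if elim and not all(0 <= q < I.m for q in elim):
        raise ValueError("eliminated column index out of range")
    table = _log_prob_table(noise)
    keep = np.array([j not in elim for j in range(I.m)])
    obs = I.observed & keep[None, :]
    return float(table[I.entries[obs], Y[obs]].sum())
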