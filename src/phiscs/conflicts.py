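"""Three-gametes conflict detection.

A binary matrix admits a perfect phylogeny iff no pair of columns (p, q)
has three rows exhibiting the configurations (1,0), (0,1) and (1,1).  Such
a pair is a *conflict*; a conflict-free matrix is exactly a perfect-
phylogeny matrix.  Columns eliminated as ISA violators are excluded from
the rule.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np


def find_conflicts(
    Y: np.ndarray, eliminated: Iterable[int] = ()
) -> list[tuple[int, int]]:
    """All conflicting column pairs (p, q), p < q, sorted, both non-eliminated."""
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D")
    if Y.size and not np.isin(Y, (0, 1)).all():
        raise ValueError("Y must be binary")
    elim = set(int(q) for q in eliminated)
    keep = [j for j in range(Y.shape[1]) if j not in elim]
    ones = Y.astype(bool)
    out = []
    for a, p in enumerate(keep):
        cp = ones[:, p]
        for q in keep[a + 1:]:
            cq = ones[:, q]
            if (cp & cq).any() and (cp & ~cq).any() and (~cp & cq).any():
                out.append((p, q))
    return out


def is_conflict_free(Y: np.ndarray, eliminated: Iterable[int] = ()) -> bool:
    """True iff ``Y`` restricted to non-eliminated columns has no conflict."""
    return not find_conflicts(Y, eliminated)
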