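"""Ternary single-cell genotype matrices and their TSV serialization.

The observed matrix ``I`` has one row per sequenced cell and one column per
candidate somatic mutation.  Entries are 0 (mutation absent), 1 (mutation
present) or missing (site not covered / amplification failure).  Missing
entries are noninformative: genotype correction may assign them either state
at no cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Internal sentinel for a missing entry.  On disk the canonical symbol is
#: "?"; the value 3 is a common convention in single-cell genotype matrices
#: and is accepted on read.
MISSING: int = 3

DEFAULT_MISSING_SYMBOLS = frozenset({"?", "3"})


class MatrixParseError(ValueError):
    """Raised when a genotype-matrix TSV is malformed."""


@dataclass(frozen=True)
class NoiseModel:
    """Single-cell genotyping error rates.

    Parameters
    ----------
    alpha
        False positive rate: probability that a truly absent mutation is
        observed as present (sequencing read errors).  Typically ~1e-4.
    beta
        False negative rate: probability that a truly present mutation is
        observed as absent (allele dropout, uneven coverage).  Typically
        0.05-0.25, much larger than ``alpha``.

    Both rates must lie strictly between 0 and 0.5 so that keeping an
    observed entry unchanged is always at least as likely as flipping it.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 0.5):
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if not (0.0 < self.beta < 0.5):
            raise ValueError(f"beta must be in (0, 0.5), got {self.beta}")


@dataclass
class GenotypeMatrix:
    """Observed ternary cell-by-mutation matrix.

    ``entries`` is an ``(n_cells, n_mutations)`` integer array over
    ``{0, 1, MISSING}``.  Row/column identifiers are unique strings.
    """

    cell_ids: list[str]
    mutation_ids: list[str]
    entries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.ndim != 2:
            raise ValueError("entries must be a 2-D array")
        n, m = self.entries.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.mutation_ids) != m:
            raise ValueError(f"{len(self.mutation_ids)} mutation ids for {m} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.mutation_ids)) != m:
            raise ValueError("duplicate mutation ids")
        bad = ~np.isin(self.entries, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"entry ({self.cell_ids[i]}, {self.mutation_ids[j]}) is "
                f"{self.entries[i, j]}; must be 0, 1 or MISSING"
            )

    @property
    def n(self) -> int:
        """Number of cells (rows)."""
        return self.entries.shape[0]

    @property
    def m(self) -> int:
        """Number of mutations (columns)."""
        return self.entries.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing entries (the index set S)."""
        return self.entries != MISSING

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.mutation_ids == other.mutation_ids
            and np.array_equal(self.entries, other.entries)
        )


def read_genotype_matrix(
    path,
    missing_symbols=DEFAULT_MISSING_SYMBOLS,
    transpose: bool = False,
) -> GenotypeMatrix:
    """Read a genotype matrix from TSV.

    Expected layout: header row ``cell_id<TAB>mut1<TAB>...``, one row per
    cell, body tokens in ``{0, 1}`` or one of ``missing_symbols``.  With
    ``transpose=True`` the file is interpreted as mutations-by-cells and
    transposed on read.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, index_col=0,
                         keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"{path}: {exc}") from None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header) or df.index.has_duplicates:
        raise MatrixParseError(f"{path}: duplicate row or column identifiers")
    tokens = df.to_numpy(dtype=object)
    entries = np.empty(tokens.shape, dtype=np.int8)
    mapping = {"0": 0, "1": 1, **{s: MISSING for s in missing_symbols}}
    for (i, j), tok in np.ndenumerate(tokens):
        tok = str(tok).strip()
        try:
            entries[i, j] = mapping[tok]
        except KeyError:
            raise MatrixParseError(
                f"{path}: unknown token {tok!r} at line {i + 2}, column {j + 2}"
            ) from None
    gm = GenotypeMatrix(
        cell_ids=[str(c) for c in df.index],
        mutation_ids=[str(c) for c in df.columns],
        entries=entries,
    )
    if transpose:
        gm = GenotypeMatrix(
            cell_ids=gm.mutation_ids, mutation_ids=gm.cell_ids,
            entries=gm.entries.T,
        )
    return gm


def write_genotype_matrix(matrix: GenotypeMatrix, path) -> None:
    """Write a genotype matrix as TSV; missing entries are emitted as "?"."""
    body = matrix.entries.astype(object)
    body[matrix.entries == MISSING] = "?"
    df = pd.DataFrame(body, index=matrix.cell_ids, columns=matrix.mutation_ids)
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t")
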