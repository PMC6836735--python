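"""Bulk sequencing profiles: per-sample read counts and VAF-derived prevalences.

For a diploid, heterozygous SNV outside copy-number-altered regions, the
variant allele frequency v/(v+r) of a mutation carried by a fraction c of
cells is c/2 in expectation.  The profile therefore stores the doubled VAF

    vaf = 2*v / (v + r)

as a proxy for the cellular prevalence of each mutation.  Values are not
clamped: undetected copy-number gains can push vaf above 1 (the theoretical
range is [0, 2]), and the lineage constraints are expected to cope with such
columns by eliminating them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class BulkParseError(ValueError):
    """Raised when a bulk-profile TSV is malformed."""


@dataclass
class BulkProfile:
    """Per-mutation, per-sample bulk read counts and prevalence-scaled VAFs.

    ``vaf`` is an ``(h_samples, m_mutations)`` float array.  ``var_reads``
    and ``ref_reads`` are integer arrays of the same shape, or ``None`` when
    the profile was loaded from precomputed VAFs.
    """

    mutation_ids: list[str]
    sample_ids: list[str]
    vaf: np.ndarray = field(repr=False)
    var_reads: np.ndarray | None = field(default=None, repr=False)
    ref_reads: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vaf = np.asarray(self.vaf, dtype=float)
        h, m = len(self.sample_ids), len(self.mutation_ids)
        if self.vaf.shape != (h, m):
            raise ValueError(f"vaf shape {self.vaf.shape} != ({h}, {m})")
        if len(set(self.mutation_ids)) != m:
            raise ValueError("duplicate mutation ids")
        if len(set(self.sample_ids)) != h:
            raise ValueError("duplicate sample ids")
        if self.var_reads is not None:
            self.var_reads = np.asarray(self.var_reads)
            self.ref_reads = np.asarray(self.ref_reads)
            for name, arr in (("var_reads", self.var_reads),
                              ("ref_reads", self.ref_reads)):
                if arr.shape != (h, m):
                    raise ValueError(f"{name} shape {arr.shape} != ({h}, {m})")
                if (arr < 0).any():
                    raise ValueError(f"negative counts in {name}")
            depth = self.var_reads + self.ref_reads
            if (depth == 0).any():
                raise ValueError("var+ref is 0 for some (mutation, sample); VAF undefined")
            expect = 2.0 * self.var_reads / depth
            if not np.allclose(self.vaf, expect):
                raise ValueError("vaf inconsistent with 2*var/(var+ref)")

    @property
    def h(self) -> int:
        return len(self.sample_ids)

    @property
    def m(self) -> int:
        return len(self.mutation_ids)

    @classmethod
    def from_counts(cls, mutation_ids, sample_ids, var_reads, ref_reads) -> "BulkProfile":
        var = np.asarray(var_reads)
        ref = np.asarray(ref_reads)
        depth = var + ref
        with np.errstate(divide="ignore", invalid="ignore"):
            vaf = 2.0 * var / depth
        return cls(list(mutation_ids), list(sample_ids), vaf, var, ref)

    def aligned_to(self, mutation_ids) -> "BulkProfile":
        """Reorder columns to match ``mutation_ids``; error on absentees."""
        index = {mut: j for j, mut in enumerate(self.mutation_ids)}
        missing = [m for m in mutation_ids if m not in index]
        if missing:
            raise ValueError(f"bulk profile lacks mutations: {missing}")
        order = [index[m] for m in mutation_ids]
        return BulkProfile(
            list(mutation_ids),
            list(self.sample_ids),
            self.vaf[:, order],
            None if self.var_reads is None else self.var_reads[:, order],
            None if self.ref_reads is None else self.ref_reads[:, order],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BulkProfile):
            return NotImplemented
        counts_equal = (self.var_reads is None) == (other.var_reads is None)
        if counts_equal and self.var_reads is not None:
            counts_equal = np.array_equal(self.var_reads, other.var_reads) and \
                np.array_equal(self.ref_reads, other.ref_reads)
        return (
            counts_equal
            and self.mutation_ids == other.mutation_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.vaf, other.vaf)
        )


def read_bulk_profile(path) -> BulkProfile:
    """Read a bulk profile from TSV.

    Two layouts are accepted:

    * long form with columns ``mutation_id, sample_id, var_reads, ref_reads``
      (VAFs computed as 2v/(v+r); every mutation must appear in every sample);
    * a 2-column ``mutation_id, vaf`` form for a single sample with
      precomputed prevalence-scaled VAFs (taken as given).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols == ["mutation_id", "vaf"]:
        muts = df["mutation_id"].tolist()
        if len(set(muts)) != len(muts):
            raise BulkParseError(f"{path}: duplicate mutation ids")
        vaf = df["vaf"].astype(float).to_numpy()[None, :]
        return BulkProfile(muts, ["sample1"], vaf)
    required = ["mutation_id", "sample_id", "var_reads", "ref_reads"]
    if cols != required:
        raise BulkParseError(
            f"{path}: expected columns {required} or ['mutation_id', 'vaf'], got {cols}"
        )
    try:
        var = df["var_reads"].astype(int)
        ref = df["ref_reads"].astype(int)
    except ValueError as exc:
        raise BulkParseError(f"{path}: non-integer read count ({exc})") from None
    if (var < 0).any() or (ref < 0).any():
        raise BulkParseError(f"{path}: negative read counts")
    if ((var + ref) == 0).any():
        row = df[(var + ref) == 0].iloc[0]
        raise BulkParseError(
            f"{path}: var+ref is 0 for ({row['mutation_id']}, {row['sample_id']}); "
            "VAF undefined"
        )
    if df.duplicated(["mutation_id", "sample_id"]).any():
        raise BulkParseError(f"{path}: duplicate (mutation, sample) rows")
    muts = list(dict.fromkeys(df["mutation_id"]))
    samples = list(dict.fromkeys(df["sample_id"]))
    vtab = df.assign(var=var, ref=ref).pivot(
        index="sample_id", columns="mutation_id", values=["var", "ref"]
    )
    if vtab.isna().any().any():
        raise BulkParseError(f"{path}: missing (mutation, sample) combinations")
    var_arr = vtab["var"].loc[samples, muts].to_numpy(dtype=np.int64)
    ref_arr = vtab["ref"].loc[samples, muts].to_numpy(dtype=np.int64)
    return BulkProfile.from_counts(muts, samples, var_arr, ref_arr)


def write_bulk_profile(bulk: BulkProfile, path) -> None:
    """Write a bulk profile as long-form TSV (counts) or 2-column VAF TSV."""
    if bulk.var_reads is None:
        if bulk.h != 1:
            raise ValueError("count-free profiles can only be written for one sample")
        pd.DataFrame(
            {"mutation_id": bulk.mutation_ids, "vaf": bulk.vaf[0]}
        ).to_csv(path, sep="\t", index=False)
        return
    rows = [
        (mut, smp, int(bulk.var_reads[ell, q]), int(bulk.ref_reads[ell, q]))
        for ell, smp in enumerate(bulk.sample_ids)
        for q, mut in enumerate(bulk.mutation_ids)
    ]
    pd.DataFrame(
        rows, columns=["mutation_id", "sample_id", "var_reads", "ref_reads"]
    ).to_csv(path, sep="\t", index=False)
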