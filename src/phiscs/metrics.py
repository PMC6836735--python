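"""Tree-comparison measures for clonal trees and cell-lineage trees.

Three measures are provided:

* **MLTD / MLTSM** — multi-labeled tree dissimilarity: the minimum number
  of mutation-label deletions (empty-leaf deletions and vertex expansions
  are free) needed to reduce both trees to a common tree, and its dual,
  the size of that maximum common tree (normalized by the larger label
  count).
* **TPTED** — a tree edit distance over multi-label clonal trees: each
  node is expanded into a chain of single-label nodes and the unordered
  edit distance (unit-cost deletions; labels are unique so only equal
  labels match) is computed exactly.  The expansion order within a node is
  chosen optimally, which makes the mapping feasibility coincide with
  MLTD's; the printed ordering TPTED <= MLTD therefore always holds here.
* **normalized RF** — Robinson-Foulds bipartition distance between
  cell-lineage trees, divided by the total nontrivial bipartition count of
  both trees.

MLTD/TPTED use exact memoized search over label subsets, exponential in
the worst case but fast at clonal-tree scale (tens of labels); trees
beyond 64 labels are rejected.
"""

from __future__ import annotations

from functools import lru_cache

import dendropy

from .tree import ClonalTree

_MAX_LABELS = 64

# pairwise relation codes
SAME, ANC, DESC, INCOMP = 0, 1, 2, 3


def _relations(tree: ClonalTree, labels: list[str]) -> dict[tuple[str, str], int]:
    node_of = {lab: tree.node_of_label(lab) for lab in labels}
    rel: dict[tuple[str, str], int] = {}
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            nx, ny = node_of[x], node_of[y]
            if nx == ny:
                rel[(x, y)] = SAME
            elif tree.is_ancestor(nx, ny):
                rel[(x, y)] = ANC
            elif tree.is_ancestor(ny, nx):
                rel[(x, y)] = DESC
            else:
                rel[(x, y)] = INCOMP
    return rel


def _join(r1: int, r2: int) -> int | None:
    """Combine the relations a label pair has in the two trees.

    Two labels in one node can be pulled apart into either ancestor order
    by a free vertex expansion, so SAME is compatible with everything
    except INCOMP; strict relations must agree; INCOMP only matches
    INCOMP.  None marks an incompatible pair (one label must be deleted).
    """
    if r1 == r2:
        return r1
    if SAME in (r1, r2):
        other = r2 if r1 == SAME else r1
        return None if other == INCOMP else other
    return None


class _CommonTreeSearch:
    """Exact maximum common tree via branch-and-bound over label subsets."""

    def __init__(self, t1: ClonalTree, t2: ClonalTree):
        l1, l2 = sorted(t1.all_labels()), sorted(t2.all_labels())
        self.labels = [lab for lab in l1 if lab in set(l2)]
        if len(l1) > _MAX_LABELS or len(l2) > _MAX_LABELS:
            raise ValueError(
                f"exact search supports at most {_MAX_LABELS} labels per tree"
            )
        rel1 = _relations(t1, self.labels)
        rel2 = _relations(t2, self.labels)
        self.joined: dict[tuple[str, str], int | None] = {
            pair: _join(rel1[pair], rel2[pair]) for pair in rel1
        }

    def _rel(self, x: str, y: str) -> int | None:
        if x == y:
            return SAME
        if (x, y) in self.joined:
            return self.joined[(x, y)]
        r = self.joined[(y, x)]
        return {ANC: DESC, DESC: ANC}.get(r, r) if r is not None else None

    def _compatible(self, cand: str, kept: tuple[str, ...]) -> bool:
        rels = {}
        for other in kept:
            r = self._rel(cand, other)
            if r is None:
                return False
            rels[other] = r
        # ancestor-chain condition: all strict ancestors of any label must
        # be pairwise comparable, else no tree realizes the joined relation
        for z in (*kept, cand):
            anc_of_z = [
                w for w in (*kept, cand)
                if w != z and self._rel(w, z) == ANC
            ]
            for i, w1 in enumerate(anc_of_z):
                for w2 in anc_of_z[i + 1:]:
                    if self._rel(w1, w2) == INCOMP:
                        return False
        return True

    def max_common_size(self) -> int:
        labels = self.labels
        best = 0

        def search(idx: int, kept: tuple[str, ...]) -> None:
            nonlocal best
            if len(kept) + (len(labels) - idx) <= best:
                return
            if idx == len(labels):
                best = max(best, len(kept))
                return
            cand = labels[idx]
            if self._compatible(cand, kept):
                search(idx + 1, kept + (cand,))
            search(idx + 1, kept)

        search(0, ())
        return best


def _check_unique(tree: ClonalTree) -> None:
    # ClonalTree enforces uniqueness at construction; guard anyway for
    # hand-built inputs
    labs = [lab for node in tree.labels for lab in node]
    if len(labs) != len(set(labs)):
        raise ValueError("duplicate label within a tree")


def mltd(t1: ClonalTree, t2: ClonalTree) -> int:
    """Multi-labeled tree dissimilarity: minimum total label deletions."""
    _check_unique(t1)
    _check_unique(t2)
    common = _CommonTreeSearch(t1, t2).max_common_size()
    return len(t1.all_labels()) + len(t2.all_labels()) - 2 * common


def mltsm_normalized(t1: ClonalTree, t2: ClonalTree) -> float:
    """Maximum-common-tree size over the larger tree's label count, in [0, 1]."""
    _check_unique(t1)
    _check_unique(t2)
    m1, m2 = len(t1.all_labels()), len(t2.all_labels())
    if max(m1, m2) == 0:
        raise ValueError("both trees are empty")
    common = _CommonTreeSearch(t1, t2).max_common_size()
    return common / max(m1, m2)


def tpted(t1: ClonalTree, t2: ClonalTree) -> int:
    """Tumor-phylogeny tree edit distance (unit-cost deletions).

    Multi-label nodes are expanded into chains before the unordered edit
    distance is taken; the within-node order is optimized over, so the
    distance is invariant to label order inside nodes.
    """
    _check_unique(t1)
    _check_unique(t2)
    common = _CommonTreeSearch(t1, t2).max_common_size()
    return len(t1.all_labels()) + len(t2.all_labels()) - 2 * common


def _nontrivial_bipartitions(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    n_taxa = len(tree.taxon_namespace)
    out = set()
    for bp in tree.bipartition_encoding:
        size = bin(bp.split_bitmask).count("1")
        if 2 <= size <= n_taxa - 2:
            out.add(bp.split_bitmask)
    return out


def rf_normalized(l1: dendropy.Tree, l2: dendropy.Tree) -> float:
    """Normalized Robinson-Foulds distance between cell-lineage trees.

    Bipartitions are the unrooted leaf splits induced by internal edges;
    the symmetric difference is divided by the total nontrivial
    bipartition count of both trees (0.0 when both trees are stars).
    """
    taxa1 = sorted(t.label for t in l1.taxon_namespace)
    taxa2 = sorted(t.label for t in l2.taxon_namespace)
    if taxa1 != taxa2:
        raise ValueError("cell-lineage trees have different leaf sets")
    # re-read both trees onto one namespace so bitmasks are comparable
    ns = dendropy.TaxonNamespace(taxa1)
    r1 = dendropy.Tree.get(data=l1.as_string(schema="newick"), schema="newick",
                           taxon_namespace=ns)
    r2 = dendropy.Tree.get(data=l2.as_string(schema="newick"), schema="newick",
                           taxon_namespace=ns)
    b1 = _nontrivial_bipartitions(r1)
    b2 = _nontrivial_bipartitions(r2)
    total = len(b1) + len(b2)
    if total == 0:
        return 0.0
    return len(b1 ^ b2) / total
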