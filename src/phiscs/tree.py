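"""Clonal trees: construction from conflict-free matrices, cell attachment,
VAF lineage verification, and DOT/Newick serialization.

A conflict-free binary matrix admits a unique perfect phylogeny in which
every mutation arises exactly once.  Mutations with identical columns are
indistinguishable and share a node (multi-label nodes); the tree root is
the healthy founder (no somatic labels, or the null mutation M0 when built
from an augmented matrix).  Each cell attaches to the node whose root path
collects exactly the cell's mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .bulk import BulkProfile
from .conflicts import find_conflicts


@dataclass
class ClonalTree:
    """Rooted mutation tree with multi-label nodes and cell attachments.

    ``labels[k]`` is the (possibly empty, for the root) list of mutation
    identifiers carried by node k; ``parent[k]`` is the parent index or
    ``None`` for the root (always node 0).  ``attachments`` maps cell id to
    node index.
    """

    labels: list[list[str]]
    parent: list[int | None]
    attachments: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.parent and self.parent[0] is not None:
            raise ValueError("node 0 must be the root")
        seen: set[str] = set()
        for labs in self.labels:
            for lab in labs:
                if lab in seen:
                    raise ValueError(f"label {lab!r} appears in more than one node")
                seen.add(lab)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def children(self, k: int) -> list[int]:
        return [c for c, p in enumerate(self.parent) if p == k]

    def path_labels(self, k: int) -> set[str]:
        """Union of labels on the root-to-k path (the clone's genotype)."""
        out: set[str] = set()
        node: int | None = k
        while node is not None:
            out.update(self.labels[node])
            node = self.parent[node]
        return out

    def all_labels(self) -> set[str]:
        return {lab for labs in self.labels for lab in labs}

    def node_of_label(self, label: str) -> int:
        for k, labs in enumerate(self.labels):
            if label in labs:
                return k
        raise KeyError(label)

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff node a lies strictly above node b."""
        node = self.parent[b]
        while node is not None:
            if node == a:
                return True
            node = self.parent[node]
        return False

    def label_partition(self) -> set[frozenset[str]]:
        return {frozenset(labs) for labs in self.labels if labs}


def build_clonal_tree(
    Y: np.ndarray,
    eliminated=(),
    cell_ids=None,
    mutation_ids=None,
    strict: bool = False,
) -> ClonalTree:
    """Perfect-phylogeny reconstruction from a conflict-free matrix.

    Eliminated columns are dropped; identical columns merge into one
    multi-label node; columns are processed by descending 1-count (ties by
    original column order), and containment of supports yields the parent
    structure.  Cells attach to the node whose root-path labels equal their
    genotype; in permissive mode (default) a cell with no exact clone —
    possible for user-supplied matrices, never for solver output — attaches
    to the deepest node whose path labels are a subset of its genotype.
    """
    Y = np.asarray(Y)
    n, m = Y.shape
    cell_ids = list(cell_ids) if cell_ids is not None else [f"cell{i}" for i in range(n)]
    mutation_ids = (
        list(mutation_ids) if mutation_ids is not None else [f"mut{j}" for j in range(m)]
    )
    elim = set(int(q) for q in eliminated)
    conflicts = find_conflicts(Y, elim)
    if conflicts:
        raise ValueError(f"matrix has three-gametes conflicts {conflicts[:3]}; solve first")
    keep = [j for j in range(m) if j not in elim]
    # group identical non-empty columns
    groups: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for j in keep:
        key = tuple(Y[:, j].tolist())
        if not any(key):
            continue  # mutation absent everywhere: no node
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(j)
    # descending support size, ties by first column index
    order.sort(key=lambda key: (-sum(key), min(groups[key])))
    labels: list[list[str]] = [[]]
    parent: list[int | None] = [None]
    supports: list[np.ndarray] = [np.ones(n, dtype=bool)]
    for key in order:
        sup = np.array(key, dtype=bool)
        node_parent = 0
        best = n + 1
        for k in range(len(supports) - 1, 0, -1):
            if supports[k][sup].all() and supports[k].sum() < best:
                node_parent = k
                best = int(supports[k].sum())
        labels.append([mutation_ids[j] for j in sorted(groups[key])])
        parent.append(node_parent)
        supports.append(sup)
    tree = ClonalTree(labels=labels, parent=parent)
    # attach cells
    path_map = {frozenset(tree.path_labels(k)): k for k in range(tree.n_nodes)}
    depth = [0] * tree.n_nodes
    for k in range(1, tree.n_nodes):
        depth[k] = depth[parent[k]] + 1
    for i, cid in enumerate(cell_ids):
        geno = frozenset(mutation_ids[j] for j in keep if Y[i, j])
        node = path_map.get(geno)
        if node is None:
            if strict:
                raise ValueError(f"cell {cid!r} matches no clone genotype")
            compatible = [
                k for k in range(tree.n_nodes)
                if tree.path_labels(k) <= geno
            ]
            node = max(compatible, key=lambda k: (depth[k], -k))
        tree.attachments[cid] = node
    return tree


def check_lineage_constraints(
    tree: ClonalTree, bulk: BulkProfile, delta: float
) -> list[str]:
    """Verify the VAF lineage inequalities on a tree; returns violations.

    Every strict ancestor-descendant label pair must satisfy
    vaf_l(p)*(1+delta) >= vaf_l(q) in every sample, and every (ancestor,
    two incomparable descendants) triple the corresponding triple
    inequality.  An empty list means the tree is consistent with the bulk
    profile at tolerance delta.
    """
    labels = sorted(tree.all_labels())
    index = {mut: j for j, mut in enumerate(bulk.mutation_ids)}
    missing = [lab for lab in labels if lab not in index]
    if missing:
        raise ValueError(f"bulk profile lacks tree labels: {missing}")
    node_of = {lab: tree.node_of_label(lab) for lab in labels}
    vaf = bulk.vaf
    eps = 1e-12

    def anc(p: str, q: str) -> bool:
        np_, nq = node_of[p], node_of[q]
        return tree.is_ancestor(np_, nq)

    violations: list[str] = []
    for p in labels:
        for q in labels:
            if p != q and anc(p, q):
                bad = vaf[:, index[p]] * (1 + delta) < vaf[:, index[q]] - eps
                for ell in np.flatnonzero(bad):
                    violations.append(
                        f"pair {p}->{q} sample {bulk.sample_ids[ell]}: "
                        f"{vaf[ell, index[p]]:.4f}*(1+{delta}) < {vaf[ell, index[q]]:.4f}"
                    )
    for p in labels:
        for a_i, q in enumerate(labels):
            for r in labels[a_i + 1:]:
                if p in (q, r):
                    continue
                if not (anc(p, q) and anc(p, r)):
                    continue
                if node_of[q] == node_of[r] or anc(q, r) or anc(r, q):
                    continue
                bad = (
                    vaf[:, index[p]] * (1 + delta)
                    < vaf[:, index[q]] + vaf[:, index[r]] - eps
                )
                for ell in np.flatnonzero(bad):
                    violations.append(
                        f"triple {p}->({q},{r}) sample {bulk.sample_ids[ell]}: "
                        f"{vaf[ell, index[p]]:.4f}*(1+{delta}) < "
                        f"{vaf[ell, index[q]]:.4f}+{vaf[ell, index[r]]:.4f}"
                    )
    return violations


# ---------------------------------------------------------------------------
# serialization


def _node_name(tree: ClonalTree, k: int) -> str:
    return "+".join(tree.labels[k]) if tree.labels[k] else "root"


def to_dot(tree: ClonalTree) -> str:
    """Graphviz DOT text: one box per clone listing labels and cell count."""
    counts = {k: 0 for k in range(tree.n_nodes)}
    for node in tree.attachments.values():
        counts[node] += 1
    lines = ["digraph clonal_tree {", "  node [shape=box];"]
    for k in range(tree.n_nodes):
        lab = ",".join(tree.labels[k]) if tree.labels[k] else "root"
        lines.append(f'  n{k} [label="{lab}\\n({counts[k]} cells)"];')
    for k in range(1, tree.n_nodes):
        lines.append(f"  n{tree.parent[k]} -> n{k};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_newick(tree: ClonalTree) -> str:
    """Newick text of the mutation tree; multi-labels joined by '+'.

    Cell attachments are not embedded (see :func:`write_attachments`);
    :func:`from_newick` inverts this serialization.
    """

    def render(k: int) -> str:
        kids = tree.children(k)
        name = _node_name(tree, k)
        if not kids:
            return name
        return "(" + ",".join(render(c) for c in kids) + ")" + name

    return render(0) + ";"


def from_newick(text: str) -> ClonalTree:
    """Parse a mutation tree written by :func:`to_newick`."""
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=False)
    labels: list[list[str]] = []
    parent: list[int | None] = []
    index: dict[int, int] = {}
    for node in dtree.preorder_node_iter():
        name = node.taxon.label if node.taxon else node.label
        name = (name or "").replace(" ", "_")
        labs = [] if name in ("", "root") else name.split("+")
        index[id(node)] = len(labels)
        labels.append(labs)
        parent.append(index[id(node.parent_node)] if node.parent_node else None)
    return ClonalTree(labels=labels, parent=parent)


def write_attachments(tree: ClonalTree, path) -> None:
    """Cell-to-clone attachments as 2-column TSV (cell_id, clone label)."""
    with open(path, "w") as fh:
        fh.write("cell_id\tclone\n")
        for cid, k in tree.attachments.items():
            fh.write(f"{cid}\t{_node_name(tree, k)}\n")


def read_attachments(tree: ClonalTree, path) -> ClonalTree:
    """Load attachments written by :func:`write_attachments` into ``tree``."""
    name_to_node = {_node_name(tree, k): k for k in range(tree.n_nodes)}
    import csv

    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            clone = row["clone"]
            if clone not in name_to_node:
                raise ValueError(f"unknown clone {clone!r} in {path}")
            tree.attachments[row["cell_id"]] = name_to_node[clone]
    return tree


def to_cell_lineage_tree(tree: ClonalTree) -> dendropy.Tree:
    """Leaf-labeled tree over cells: each cell becomes a leaf child of its
    clone; mutation labels are dropped and cell-free subtrees pruned."""
    if not tree.attachments:
        raise ValueError("tree has no cell attachments")
    taxa = dendropy.TaxonNamespace(sorted(tree.attachments))
    dtree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [dendropy.Node() for _ in range(tree.n_nodes)]
    dtree.seed_node = nodes[0]
    for k in range(1, tree.n_nodes):
        nodes[tree.parent[k]].add_child(nodes[k])
    for cid in sorted(tree.attachments):
        leaf = dendropy.Node(taxon=taxa.get_taxon(cid))
        nodes[tree.attachments[cid]].add_child(leaf)
    # prune clone nodes with no cells anywhere below them
    changed = True
    while changed:
        changed = False
        for node in list(dtree.leaf_node_iter()):
            if node.taxon is None and node.parent_node is not None:
                node.parent_node.remove_child(node)
                changed = True
    return dtree
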