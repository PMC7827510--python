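"""Allele-sharing distances and neighbor-joining trees.

The distance is the mean per-site dosage difference |d_i - d_j| / 2 over
co-called sites — a similarity dendrogram input, not a substitution-model
distance. NJ is the Saitou-Nei agglomeration with the Studier-Keppler
Q-criterion; on additive matrices the reconstructed path lengths equal
the input exactly. Negative branch-length estimates are clamped to 0 and
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sweepscan.model import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be nonnegative")


@dataclass
class TreeNode:
    """Node of an unrooted NJ tree (root is the final trifurcation)."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float = 0.0  # length of the edge to the parent
    clamped: bool = False  # True when a negative NJ estimate was clamped to 0

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


def pairwise_distance(
    gm: GenotypeMatrix, site_subset: np.ndarray | None = None
) -> DistanceMatrix:
    """Allele-sharing distance between all sample pairs.

    d(i, j) = mean over co-called sites of |dosage_i - dosage_j| / 2;
    sites missing in either sample are excluded pairwise. ``site_subset``
    (boolean mask or index array) restricts to e.g. sweep-region SNPs.
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    G = gm.genotypes
    if site_subset is not None:
        sub = np.asarray(site_subset)
        G = G[:, sub] if sub.dtype == bool else G[:, sub]
    n = gm.n_samples
    D = np.zeros((n, n))
    called = G != MISSING
    Gf = G.astype(float)
    for i in range(n):
        for j in range(i + 1, n):
            co = called[i] & called[j]
            n_co = int(co.sum())
            if n_co == 0:
                raise ValueError(
                    f"samples {gm.samples[i]} and {gm.samples[j]} share no called sites"
                )
            d = float(np.abs(Gf[i, co] - Gf[j, co]).mean() / 2.0)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids=list(gm.samples), matrix=D)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q_ij = (n-2) d_ij - r_i - r_j is
    joined; ties break on the smallest (i, j) index pair in current
    order. Branch lengths from the standard formulas; negatives clamped
    to 0 with the node flagged. Returns the trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dm.matrix.astype(float).copy()
    nodes = [TreeNode(name=s) for s in dm.ids]
    active = list(range(n))

    def clamp(node: TreeNode, length: float):
        if length < 0:
            node.branch_length = 0.0
            node.clamped = True
        else:
            node.branch_length = float(length)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_q = np.inf
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        u = TreeNode(children=[nodes[i], nodes[j]])
        clamp(nodes[i], li)
        clamp(nodes[j], lj)
        # distances from the new node to the remaining taxa
        newd = np.zeros(D.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            newd[k] = (D[i, k] + D[j, k] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newd) - 1] = newd[:-1]
        D[: len(newd) - 1, -1] = newd[:-1]
        nodes.append(u)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    clamp(nodes[i], (D[i, j] + D[i, k] - D[j, k]) / 2.0)
    clamp(nodes[j], (D[i, j] + D[j, k] - D[i, k]) / 2.0)
    clamp(nodes[k], (D[i, k] + D[j, k] - D[i, j]) / 2.0)
    return root


def _newick_label(name: str) -> str:
    if any(c in name for c in " \t(),:;'[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode, is_root: bool) -> str:
    if node.children:
        inner = ",".join(_newick_node(c, False) for c in node.children)
        s = f"({inner})"
        if node.name:
            s += _newick_label(node.name)
    else:
        s = _newick_label(node.name or "")
    if not is_root:
        s += f":{node.branch_length:.10g}"
    return s


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree as Newick with branch lengths."""
    return _newick_node(tree, True) + ";"


def tree_path_lengths(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix implied by the tree."""
    leaves = tree.leaves()
    names = [l.name for l in leaves]
    idx = {id(l): i for i, l in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))

    def walk(node):
        """Return {leaf index: distance to this node}, filling D."""
        if not node.children:
            return {idx[id(node)]: 0.0}
        below = []
        for c in node.children:
            sub = walk(c)
            below.append({k: v + c.branch_length for k, v in sub.items()})
        for a in range(len(below)):
            for b in range(a + 1, len(below)):
                for la, da in below[a].items():
                    for lb, db in below[b].items():
                        D[la, lb] = D[lb, la] = da + db
        merged = {}
        for d in below:
            merged.update(d)
        return merged

    walk(tree)
    return names, D


def tree_splits(tree: TreeNode) -> list[frozenset[str]]:
    """Leaf-name bipartitions (one side each) induced by internal edges."""
    all_leaves = frozenset(tree.leaf_names())
    splits = []

    def walk(node):
        if not node.children:
            below = frozenset([node.name])
        else:
            below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree and 0 < len(below) < len(all_leaves):
            splits.append(below)
        return below

    walk(tree)
    return splits


def groups_are_separated(tree: TreeNode, groups: dict[str, str]) -> bool:
    """True when some edge of the unrooted tree splits the leaves exactly
    into the two groups (both groups monophyletic)."""
    group_a = frozenset(s for s in tree.leaf_names() if groups.get(s) == "A")
    group_b = frozenset(s for s in tree.leaf_names() if groups.get(s) == "B")
    for side in tree_splits(tree):
        if side == group_a or side == group_b:
            return True
    return False


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Square TSV with a header row and a leading id column."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(dm.ids) + "\n")
        for i, s in enumerate(dm.ids):
            fh.write(s + "\t" + "\t".join(repr(float(v)) for v in dm.matrix[i]) + "\n")
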