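"""Neighbor-joining trees from distance matrices, with bootstrap support.

The species-level morphometric tree is built by the Saitou-Nei
neighbor-joining algorithm from the Mahalanobis distance matrix between
group means; on additive distance matrices NJ recovers the generating
tree exactly.  Node robustness is assessed by resampling specimens with
replacement within each species, rebuilding the distance matrix and the
tree, and reporting for each internal edge the percentage of replicate
trees containing the same leaf bipartition.

Trees are dendropy objects throughout; Newick serialization carries
branch lengths and internal-node support labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over ordered labels."""
    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")
        if np.abs(self.values - self.values.T).max() > 1e-8:
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(self.values)).max() > 1e-12:
            raise ValueError("diagonal must be zero")
        self.values = (self.values + self.values.T) / 2


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing the Q criterion
    ``(r - 2) d_ij - R_i - R_j`` (ties broken by lowest index pair),
    assigns branch lengths by the standard formulas with negative
    lengths clamped to zero, and reduces the matrix.  Returns an
    unrooted dendropy tree whose seed node is the final trifurcation.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    ns = dendropy.TaxonNamespace([str(lab) for lab in dm.labels])
    nodes = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=ns.get_taxon(str(lab)))
        nodes.append(node)
    D = dm.values.copy()

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) among minima: flatten scan finds the first
        flat = int(np.argmin(Q))
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        bi = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        bj = dij - bi
        parent = dendropy.Node()
        nodes[i].edge.length = max(0.0, bi)
        nodes[j].edge.length = max(0.0, bj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [m for m in range(r) if m not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[m] for m in keep] + [parent]

    # final three branches around the central node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [0.5 * (d01 + d02 - d12),
               0.5 * (d01 + d12 - d02),
               0.5 * (d02 + d12 - d01)]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    for node, length in zip(nodes, lengths):
        node.edge.length = max(0.0, length)
        tree.seed_node.add_child(node)
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# bipartitions and bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> dict:
    """Map non-trivial leaf bipartitions to their (internal) nodes.

    Keys are frozensets of leaf labels on the side not containing a
    fixed reference label, so they are rooting-independent.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    all_labels = frozenset(leaves)
    ref = leaves[0]
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if 2 <= len(side) <= len(leaves) - 2:
            out[side] = node
    return out


def bootstrap_support(shapes, labels, builder, n_reps: int = 1000,
                      seed: int | None = None) -> dendropy.Tree:
    """NJ tree with bootstrap supports from specimen resampling.

    ``builder(shapes, labels) -> DistanceMatrix`` maps specimen-level
    data to group distances (typically CVA Mahalanobis distances).  Each
    replicate resamples specimens with replacement within their group,
    rebuilds the distance matrix and the NJ tree; an internal edge's
    support is the percentage of successful replicates whose tree
    contains the same leaf bipartition, written to the node label of the
    full-data tree.  Failed replicates are skipped with a warning and
    removed from the denominator.
    """
    shapes = np.asarray(shapes, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    full_tree = neighbor_joining(builder(shapes, labels))
    target = _bipartitions(full_tree)
    counts = {key: 0 for key in target}
    group_idx = {g: np.flatnonzero(labels == g) for g in np.unique(labels)}
    n_ok = 0
    failures = 0
    for _ in range(n_reps):
        take = np.concatenate([
            rng.choice(idx, size=len(idx), replace=True)
            for idx in group_idx.values()])
        try:
            rep_tree = neighbor_joining(builder(shapes[take], labels[take]))
        except Exception:
            failures += 1
            continue
        n_ok += 1
        rep_bip = _bipartitions(rep_tree)
        for key in counts:
            if key in rep_bip:
                counts[key] += 1
    if failures:
        warnings.warn(f"{failures} bootstrap replicate(s) failed and were "
                      "skipped")
    if n_ok == 0:
        raise RuntimeError("all bootstrap replicates failed")
    for key, node in target.items():
        node.label = f"{100.0 * counts[key] / n_ok:g}"
    return full_tree


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths and internal support labels."""
    return tree.as_string(schema="newick",
                          suppress_rooting=True).strip()


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into an unrooted dendropy tree."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick string: {exc}") from None
    tree.is_rooted = False
    return tree
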