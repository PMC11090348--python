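"""Neighbor-joining trees from model-model RMSD matrices.

A pairwise RMSD matrix over an ensemble can be rendered as a
"structure-based phylogenetic tree": leaves are models, and path lengths
through the tree approximate the RMSD between them.  For a tight ordered
ensemble the tree is star-like with sub-Å branches; a disordered ensemble
spreads into long branches of several Å.

The construction is the standard Saitou–Nei neighbor joining with the
Studier–Keppler Q-criterion, which reconstructs additive (tree-like)
matrices exactly.  RMSD matrices are generally not additive, so two
conventions are fixed for reproducibility:

* ties in the Q-minimization break toward the lexicographically smallest
  label pair (internal nodes inherit the smallest leaf label below them);
* a negative limb length is clamped to zero and the deficit transferred to
  its sibling limb, keeping the pair's summed length intact — the convention
  of mainstream phylogenetics tools.
"""

from __future__ import annotations

import io

import numpy as np
from skbio import TreeNode

from .ensemble_geometry import RMSDMatrix

__all__ = ["neighbor_joining", "write_newick", "cophenetic_check",
           "cophenetic_table"]


def _validate(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(m < 0):
        raise ValueError("distance matrix entries must be non-negative")
    if np.any(np.diag(m) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    return 0.5 * (m + m.T)


def neighbor_joining(dist: RMSDMatrix | np.ndarray,
                     labels: list[str] | None = None) -> TreeNode:
    """Build an unrooted NJ tree from a symmetric distance matrix.

    Accepts an :class:`RMSDMatrix` or a bare matrix plus labels.  Returns a
    :class:`skbio.TreeNode` whose root is the final trifurcation (or the
    2-leaf edge split at its midpoint).
    """
    if isinstance(dist, RMSDMatrix):
        labels = list(dist.labels)
        matrix = dist.matrix
    else:
        if labels is None:
            raise ValueError("labels are required with a bare matrix")
        labels = list(labels)
        matrix = dist
    if len(set(labels)) != len(labels):
        raise ValueError("leaf labels must be unique")
    d = _validate(matrix)
    n = d.shape[0]
    if n != len(labels):
        raise ValueError("label count does not match matrix size")
    if n < 2:
        raise ValueError("need at least 2 taxa")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    # Sort key of a working node = smallest leaf label beneath it; used only
    # to break exact ties deterministically.
    keys: list[str] = list(labels)
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> None:
        ni, nj = nodes[i], nodes[j]
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni.length = max(li, 0.0)
        nj.length = max(lj, 0.0)
        parent = TreeNode(children=[ni, nj])
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # Deterministic tie-break: lexicographically smallest key pair.
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    ka, kb = keys[active[a]], keys[active[b]]
                    pair_key = (min(ka, kb), max(ka, kb))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, a, b)
        assert best is not None
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        # Distances from the new node u (stored in slot i) to the rest.
        others = [k for k in active if k not in (i, j)]
        for k in others:
            d_new = 0.5 * (d[i, k] + d[j, k] - dij)
            d[i, k] = d[k, i] = max(d_new, 0.0)
        join(i, j, li, lj)
        active.remove(j)

    i, j = active
    dij = d[i, j]
    ni, nj = nodes[i], nodes[j]
    if ni.is_tip() and nj.is_tip():
        # Two taxa: a single edge, rendered as a midpoint split.
        ni.length = nj.length = 0.5 * dij
        return TreeNode(children=[ni, nj])
    # Attach the remaining node to the internal one (root = trifurcation).
    if nj.is_tip():
        internal, leaf = ni, nj
    elif ni.is_tip():
        internal, leaf = nj, ni
    else:
        internal, leaf = ni, nj
    leaf.length = max(dij, 0.0)
    internal.append(leaf)
    return internal


def _format_length(value: float) -> str:
    return f"{value:.6g}"


def _newick_recurse(node: TreeNode) -> str:
    if node.is_tip():
        base = node.name or ""
    else:
        base = "(" + ",".join(_newick_recurse(c) for c in node.children) + ")"
        if node.name:
            base += node.name
    if node.length is not None:
        base += f":{_format_length(float(node.length))}"
    return base


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize a tree to Newick with 6-significant-digit branch lengths."""
    text = _newick_recurse(tree) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_newick(text: str) -> TreeNode:
    """Parse Newick text back into a tree (round-trip partner)."""
    return TreeNode.read(io.StringIO(text), format="newick")


def _tip_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    dm = tree.tip_tip_distances()
    return list(dm.ids), dm.data


def cophenetic_check(tree: TreeNode, dist: RMSDMatrix | np.ndarray,
                     labels: list[str] | None = None) -> float:
    """Max |tree path length − input distance| over all leaf pairs, in Å.

    Zero (to numerical precision) iff the input matrix was additive; for
    RMSD matrices this measures how faithfully the tree rendering represents
    the ensemble's pairwise deviations.
    """
    if isinstance(dist, RMSDMatrix):
        labels = list(dist.labels)
        matrix = dist.matrix
    else:
        if labels is None:
            raise ValueError("labels are required with a bare matrix")
        matrix = np.asarray(dist, dtype=float)
    ids, tree_d = _tip_distances(tree)
    if sorted(ids) != sorted(labels):
        raise ValueError("tree leaves do not match distance-matrix labels")
    order = [ids.index(lab) for lab in labels]
    tree_d = tree_d[np.ix_(order, order)]
    return float(np.max(np.abs(tree_d - matrix)))


def cophenetic_table(tree: TreeNode) -> list[tuple[str, str, float]]:
    """Flat (leaf_i, leaf_j, path length) table for export."""
    ids, tree_d = _tip_distances(tree)
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            out.append((ids[i], ids[j], float(tree_d[i, j])))
    return out
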