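"""Neighbour-joining trees from strain distance matrices.

The agglomeration uses the Q criterion with the Studier-Keppler distance
update, deterministic lexicographic tie-breaking on taxon labels, and clamps
negative branch-length estimates to zero.  Trees are held as
:class:`skbio.TreeNode` and serialized to Newick.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = ["validate_distance_matrix", "nj_tree", "root_at_outgroup", "write_newick", "read_newick"]


def validate_distance_matrix(dm: pd.DataFrame) -> pd.DataFrame:
    """Check symmetry, zero diagonal, non-negativity and label uniqueness."""
    if list(dm.index) != list(dm.columns):
        raise ValueError("distance matrix row and column labels differ")
    if dm.index.duplicated().any():
        raise ValueError("duplicate taxon labels")
    x = dm.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("distance matrix has non-finite entries")
    if np.any(x < 0):
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(x, x.T, rtol=0, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.abs(np.diag(x)) > 1e-12):
        raise ValueError("distance matrix diagonal is not zero")
    return dm


def _canon(node: TreeNode) -> str:
    """Canonical label of a subtree: its smallest leaf name."""
    if node.is_tip():
        return str(node.name)
    return min(_canon(c) for c in node.children)


def _attach(children: list[tuple[TreeNode, float]]) -> TreeNode:
    """New internal node with children sorted by canonical label."""
    parent = TreeNode()
    for child, length in sorted(children, key=lambda cl: _canon(cl[0])):
        child.length = float(length)
        parent.append(child)
    return parent


def _clamp(length: float) -> float:
    if length < 0:
        warnings.warn("negative branch-length estimate clamped to 0", stacklevel=3)
        return 0.0
    return float(length)


def nj_tree(dm: pd.DataFrame) -> TreeNode:
    """Neighbour-joining tree (unrooted; trifurcation at the last join).

    On an additive (tree-metric) matrix the generating tree is recovered
    exactly.  Ties in the Q criterion are broken by the lexicographically
    smallest pair of canonical labels, so the result is independent of input
    taxon order.
    """
    validate_distance_matrix(dm)
    taxa = [str(t) for t in dm.index]
    if len(taxa) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    # work in canonical label order so ties resolve identically for any input order
    order = sorted(range(len(taxa)), key=lambda i: taxa[i])
    d = dm.to_numpy(dtype=float)[np.ix_(order, order)].copy()
    nodes: list[TreeNode] = [TreeNode(name=taxa[i]) for i in order]
    labels: list[str] = [taxa[i] for i in order]

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        cand = np.argwhere(q <= qmin + tol)
        pairs = {tuple(sorted((int(i), int(j)))) for i, j in cand}
        i, j = min(pairs, key=lambda ij: (labels[ij[0]], labels[ij[1]]))
        li = _clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2)))
        lj = _clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))))
        new = _attach([(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])  # Studier-Keppler
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    (a, b, c) = range(3)
    va = _clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    vb = _clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    vc = _clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    return _attach([(nodes[a], va), (nodes[b], vb), (nodes[c], vc)])


def _adjacency(tree: TreeNode) -> tuple[dict[int, list[tuple[int, float]]], dict[int, str]]:
    """Undirected edge list of a tree, with leaf names."""
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}
    for node in tree.traverse(include_self=True):
        adj.setdefault(id(node), [])
        if node.is_tip():
            names[id(node)] = str(node.name)
        for child in node.children:
            length = float(child.length if child.length is not None else 0.0)
            adj[id(node)].append((id(child), length))
            adj.setdefault(id(child), []).append((id(node), length))
    return adj, names


def _build_rooted(
    adj: dict[int, list[tuple[int, float]]],
    names: dict[int, str],
    node: int,
    parent: int,
) -> TreeNode:
    children = [(nbr, length) for nbr, length in adj[node] if nbr != parent]
    if not children:
        return TreeNode(name=names.get(node))
    built = [(_build_rooted(adj, names, nbr, node), length) for nbr, length in children]
    sub = _attach(built)
    sub.name = names.get(node)
    return sub


def root_at_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root a tree at the midpoint of the outgroup's pendant edge.

    Total branch length is conserved: the outgroup edge of length L becomes
    two edges of length L/2 on either side of the new root.
    """
    tips = {str(t.name): t for t in tree.tips()}
    if outgroup not in tips:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    adj, names = _adjacency(tree)
    tip = tips[outgroup]
    ((pid, length),) = adj[id(tip)]
    rest = _build_rooted(adj, names, pid, id(tip))
    out_leaf = TreeNode(name=outgroup)
    return _attach([(out_leaf, length / 2.0), (rest, length / 2.0)])


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
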