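"""Distance-based comparison of SAG libraries.

Builds Jukes-Cantor distances from mismatch proportions, a Saitou-Nei
neighbor-joining tree, abundance-weighted (normalized) UniFrac distances
between libraries on that tree, and classical PCoA ordination of the
resulting distance matrix.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "jc_distance",
    "SaturationError",
    "nj_tree",
    "weighted_unifrac",
    "pcoa",
]


class SaturationError(ValueError):
    """Raised when a mismatch proportion is at or beyond the JC69 saturation point."""


def jc_distance(p_mismatch: float) -> float:
    """Jukes-Cantor (JC69) distance d = -(3/4) ln(1 - 4p/3), substitutions/site."""
    if not 0.0 <= p_mismatch:
        raise ValueError("mismatch proportion must be >= 0")
    if p_mismatch >= 0.75:
        raise SaturationError(
            f"mismatch proportion {p_mismatch} is saturated under JC69 (p >= 0.75)"
        )
    return -0.75 * math.log1p(-4.0 * p_mismatch / 3.0)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative estimated branch clamped to 0, deficit moved to the sister
    # branch so the joined pair's path length is preserved
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Q-matrix selection with ties broken by the lexicographically smallest
    pair of subtree labels (the smallest tip name under each active node), so
    the result does not depend on input row order.  The returned tree is
    unrooted, represented with a trifurcating root.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes = [TreeNode(name=name) for name in labels]
    keys = list(labels)  # smallest tip name under each active node

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and pair_key < best[1]
                ):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj

        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_row[keep]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    # three-point closure: root with three children
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = (dab + dac - dbc) / 2.0
    lb = dab - la
    lc = dac - la
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[a, b, c])
    return root


# ---------------------------------------------------------------------------
# weighted UniFrac
# ---------------------------------------------------------------------------


def _rooted_copy(tree: TreeNode, outgroup: str | None) -> TreeNode:
    t = tree.copy()
    if outgroup is not None:
        node = t.find(outgroup)
        t = t.root_at(node.parent) if node.parent is not None else t
    elif len(t.children) > 2:
        t = t.root_at_midpoint()
    return t


def weighted_unifrac(
    tree: TreeNode,
    abund_a: Mapping[str, float],
    abund_b: Mapping[str, float],
    normalized: bool = True,
    outgroup: str | None = None,
) -> float:
    """Abundance-weighted UniFrac distance between two samples on a tree.

    Raw value: sum over branches of branch_length * |p_i - q_i|, where p_i
    (q_i) is the fraction of sample a's (b's) total abundance descending
    from the branch.  When ``normalized`` (default) the raw value is divided
    by D = sum over leaves of root-to-leaf distance * (p_j + q_j), bounding
    the distance to [0, 1].

    The tree is midpoint-rooted first when it is unrooted (trifurcating
    root); pass ``outgroup`` to root at a named outgroup instead.
    """
    for name, sample in (("a", abund_a), ("b", abund_b)):
        for leaf, w in sample.items():
            if w < 0:
                raise ValueError(f"negative weight for leaf {leaf!r} in sample {name}")
    total_a = float(sum(abund_a.values()))
    total_b = float(sum(abund_b.values()))
    if total_a <= 0 or total_b <= 0:
        raise ValueError("each sample must have positive total abundance")

    t = _rooted_copy(tree, outgroup)
    tip_names = {tip.name for tip in t.tips()}
    for sample in (abund_a, abund_b):
        missing = {leaf for leaf, w in sample.items() if w > 0} - tip_names
        if missing:
            raise KeyError(f"weighted leaves absent from tree: {sorted(missing)}")

    u_raw = 0.0
    masses: dict[int, tuple[float, float]] = {}
    for node in t.postorder(include_self=True):
        if node.is_tip():
            ma = float(abund_a.get(node.name, 0.0)) / total_a
            mb = float(abund_b.get(node.name, 0.0)) / total_b
        else:
            ma = sum(masses[id(c)][0] for c in node.children)
            mb = sum(masses[id(c)][1] for c in node.children)
        masses[id(node)] = (ma, mb)
        if node.parent is not None:
            u_raw += (node.length or 0.0) * abs(ma - mb)

    if not normalized:
        return u_raw
    scale = 0.0
    for tip in t.tips():
        depth = tip.accumulate_to_ancestor(t)
        pa, pb = masses[id(tip)]
        scale += depth * (pa + pb)
    return u_raw / scale if scale > 0 else 0.0


# ---------------------------------------------------------------------------
# principal coordinate analysis
# ---------------------------------------------------------------------------


def pcoa(dm: DistanceMatrix, k: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric multidimensional scaling of a distance matrix.

    Eigendecomposition of the double-centered -D^2/2 matrix; axes are sorted
    by descending eigenvalue, axes with negative eigenvalues are dropped
    (all eigenvalues are still returned), and each retained axis is oriented
    so its first nonzero loading is positive.

    Returns ``(coordinates, eigenvalues)`` with coordinates indexed by the
    matrix ids and columns ``PC1..PCk``.
    """
    labels = list(dm.ids)
    d = np.array(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if k is None:
        k = n - 1
    if k > n - 1:
        raise ValueError("k must be <= n - 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = 1e-10 * max(1.0, float(np.abs(evals).max(initial=0.0)))
    keep = [i for i in range(min(k, n)) if evals[i] > tol]
    coords = np.zeros((n, len(keep)))
    for out_idx, i in enumerate(keep):
        axis = evecs[:, i] * math.sqrt(evals[i])
        nz = np.nonzero(np.abs(axis) > tol)[0]
        if nz.size and axis[nz[0]] < 0:
            axis = -axis
        coords[:, out_idx] = axis
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"PC{i + 1}" for i in range(len(keep))]
    )
    return frame, evals
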