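"""Distance-matrix trees (BioNJ), outgroup rooting and Robinson-Foulds.

BioNJ is the variance-weighted variant of neighbor joining (Gascuel 1997):
it uses the classical NJ selection criterion but, when reducing the matrix
after each agglomeration, weights the two merged rows so as to minimize the
variance of the new distance estimates.  On additive (four-point-condition)
matrices it recovers the generating topology and branch lengths exactly,
like NJ; on noisy matrices its estimates have lower variance.

Trees are ``skbio.TreeNode`` objects throughout, serialized as Newick.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode


class LeafSetMismatchError(ValueError):
    """Two trees do not share the same leaf set."""


# ---------------------------------------------------------------------------
# BioNJ


class _Cluster:
    """Live node during agglomeration; ``key`` is the smallest leaf name
    underneath, used for deterministic tie-breaking."""

    __slots__ = ("node", "key")

    def __init__(self, node: TreeNode, key: str):
        self.node = node
        self.key = key


def bionj(dm: DistanceMatrix) -> TreeNode:
    """Build an unrooted BioNJ tree from a distance matrix.

    The returned tree has a trifurcating root (unrooted convention).
    Negative branch-length estimates are set to zero and the deficit is
    transferred to the sister branch, preserving path lengths through the
    joined node.  Ties in the selection criterion are broken by the
    lexicographically smallest pair of subtree labels.

    Raises for fewer than three taxa or non-finite entries.
    """
    d = np.array(dm.data, dtype=float)
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("BioNJ needs at least three taxa")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite values")

    clusters = [_Cluster(TreeNode(name=gid), gid) for gid in ids]
    v = d.copy()  # variance estimates, initialized to the distances

    while len(clusters) > 3:
        r = len(clusters)
        sums = d.sum(axis=1)
        # NJ selection criterion
        best = None
        for i, j in itertools.combinations(range(r), 2):
            q = (r - 2) * d[i, j] - sums[i] - sums[j]
            key = tuple(sorted((clusters[i].key, clusters[j].key)))
            cand = (q, key, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, i, j = best

        bi = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        bj = d[i, j] - bi

        # variance-minimizing weight for the matrix reduction
        if v[i, j] > 0 and r > 3:
            others = [k for k in range(r) if k not in (i, j)]
            lam = 0.5 + (v[j, others].sum() - v[i, others].sum()) / (
                2.0 * (r - 2) * v[i, j]
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        ci, cj = clusters[i], clusters[j]
        # raw estimates drive the reduction; stored lengths are clamped
        ci.node.length, cj.node.length = _clamp_sisters(bi, bj)
        parent = TreeNode(children=[ci.node, cj.node])
        new = _Cluster(parent, min(ci.key, cj.key))

        keep = [k for k in range(r) if k not in (i, j)]
        du = lam * d[i, keep] + (1 - lam) * d[j, keep] - lam * bi - (1 - lam) * bj
        vu = lam * v[i, keep] + (1 - lam) * v[j, keep] - lam * (1 - lam) * v[i, j]
        du = np.maximum(du, 0.0)
        vu = np.maximum(vu, 0.0)

        d = np.vstack([np.column_stack([d[np.ix_(keep, keep)], du]),
                       np.append(du, 0.0)])
        v = np.vstack([np.column_stack([v[np.ix_(keep, keep)], vu]),
                       np.append(vu, 0.0)])
        clusters = [clusters[k] for k in keep] + [new]

    # closing three-point formulas
    (a, b, c) = clusters
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for cl, ln in ((a, la), (b, lb), (c, lc)):
        cl.node.length = max(ln, 0.0)
    root = TreeNode(children=[a.node, b.node, c.node])
    return root


def _clamp_sisters(bi: float, bj: float) -> tuple[float, float]:
    """Zero a negative branch estimate, moving the deficit to its sister."""
    if bi < 0:
        bj += bi
        bi = 0.0
    if bj < 0:
        bi = max(bi + bj, 0.0)
        bj = 0.0
    return bi, bj


def nj_classic(dm: DistanceMatrix) -> TreeNode:
    """Classical (Saitou-Nei) neighbor joining via scikit-bio.

    Exposed for cross-checks: on clean matrices BioNJ and NJ agree on the
    topology.
    """
    from skbio.tree import nj

    return nj(dm)


# ---------------------------------------------------------------------------
# rooting


def root_at(tree: TreeNode, outgroup_leaf: str) -> TreeNode:
    """Root a tree at the midpoint of an outgroup's pendant edge.

    The outgroup becomes one of the two children of the new root; the
    unrooted topology is unchanged.
    """
    try:
        leaf = tree.find(outgroup_leaf)
    except Exception as exc:
        raise ValueError(f"outgroup leaf {outgroup_leaf!r} not in tree") from exc
    if not leaf.is_tip():
        raise ValueError(f"{outgroup_leaf!r} is not a leaf")
    return tree.root_at(leaf, above=True, branch_attrs=[])


def unroot(tree: TreeNode) -> TreeNode:
    """Collapse a bifurcating root into the unrooted (trifurcating) form."""
    out = tree.copy()
    out.unroot()  # in place
    return out


# ---------------------------------------------------------------------------
# Robinson-Foulds


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, as canonical sides.

    Each internal edge splits the leaves in two; the side not containing the
    lexicographically smallest leaf is the canonical representative.  The
    root edge of a rooted tree yields no bipartition (both root children
    induce the same split, which is deduplicated), so rooted and unrooted
    versions of the same topology give identical sets.
    """
    leaves = sorted(l.name for l in tree.tips())
    if len(leaves) != len(set(leaves)):
        raise ValueError("duplicate leaf labels")
    full = frozenset(leaves)
    anchor = leaves[0]
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            parts.add(side)
    return parts


def robinson_foulds(
    t1: TreeNode,
    t2: TreeNode,
    normalized: bool = True,
    denominator: str = "union",
) -> float:
    """Robinson-Foulds distance between two trees on the same leaves.

    The unnormalized value counts non-trivial bipartitions present in
    exactly one tree.  The normalized form divides by the total number of
    non-trivial bipartitions across both trees (``denominator="union"``,
    the default, which is multifurcation-safe and reads as "the fraction of
    partitions present in only one tree"), or by ``2 * (n - 3)``
    (``denominator="max"``).  Identical star trees give 0.
    """
    leaves1 = {l.name for l in t1.tips()}
    leaves2 = {l.name for l in t2.tips()}
    if leaves1 != leaves2:
        only1 = sorted(leaves1 - leaves2)
        only2 = sorted(leaves2 - leaves1)
        raise LeafSetMismatchError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    b1 = bipartitions(t1)
    b2 = bipartitions(t2)
    sym = len(b1 ^ b2)
    if not normalized:
        return float(sym)
    if denominator == "union":
        denom = len(b1) + len(b2)
    elif denominator == "max":
        denom = 2 * max(len(leaves1) - 3, 0)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return sym / denom if denom else 0.0


def rf_table(trees: dict[str, TreeNode], normalized: bool = True):
    """All-pairs RF values as a labeled pandas DataFrame."""
    import pandas as pd

    names = list(trees)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        val = robinson_foulds(trees[a], trees[b], normalized=normalized)
        out.loc[a, b] = out.loc[b, a] = val
    return out


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(path: str | Path) -> TreeNode:
    """Read a Newick tree, rejecting duplicate leaf labels."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValueError(f"{path}: Newick parse error: {exc}") from exc
    names = [l.name for l in tree.tips()]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate leaf labels {dupes}")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def newick_str(tree: TreeNode) -> str:
    import io

    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
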