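"""Identity-by-state distances and neighbor-joining trees.

The pairwise distance between two samples is 1 − IBS: the mean over called
diploid sites of |dosage_i − dosage_j| / 2, i.e. the fraction of allele
copies not shared identical-by-state.  Neighbor joining (Saitou–Nei, with
the standard Q-matrix agglomeration) turns the distance matrix into an
unrooted tree that exactly recovers any additive distance matrix; rooting
by an outgroup places the root on the branch leading to the outgroup leaf.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .genotype_data import GenotypeMatrix, GenotypeDataError


def ibs_distance(gm: GenotypeMatrix, include_x: bool = False) -> DistanceMatrix:
    """Pairwise 1 − IBS distances over autosomal diploid sites.

    X sites are excluded by default (mixed male/female ploidy makes the
    per-site sharing scale inhomogeneous); with ``include_x`` they enter
    normalized by each pair's summed ploidy.  Missing entries are handled
    pairwise-complete; a pair with no shared called sites is an error.
    """
    keep = gm.sites["chrom_class"] == "autosome"
    if include_x:
        keep = keep | (gm.sites["chrom_class"] == "X")
    sub_idx = keep.to_numpy()
    dosage = gm.dosage[sub_idx].astype(float)
    ploidy = gm.ploidy[sub_idx].astype(float)
    called = gm.called[sub_idx]
    n = gm.n_samples
    ids = list(gm.samples["sample_id"])
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            if not both.any():
                raise GenotypeDataError(
                    f"no shared called sites for pair ({ids[i]}, {ids[j]})")
            diff = np.abs(dosage[both, i] / ploidy[both, i]
                          - dosage[both, j] / ploidy[both, j])
            D[i, j] = D[j, i] = float(diff.mean())
    return DistanceMatrix(D, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Pairs minimizing the Q criterion are tied-broken lexicographically by
    the (sorted) label pair.  Negative branch lengths are clamped to zero.
    Returns an unrooted tree (trifurcating at the final join) over the
    matrix labels; additive matrices are recovered exactly.
    """
    D = np.asarray(dm.data, dtype=float)
    if D.shape[0] < 3:
        raise GenotypeDataError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T) or (D < 0).any():
        raise GenotypeDataError("distance matrix must be symmetric nonnegative")
    nodes: list[TreeNode] = [TreeNode(name=str(l)) for l in dm.ids]
    labels: list[str] = [str(l) for l in dm.ids]
    D = D.copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D_next = np.zeros((len(keep) + 1, len(keep) + 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = D_next[:-1, -1] = d_new[keep]
        D = D_next
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # final trifurcation via the three-point formulas
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, length in zip((a, b, c), (la, lb, lc)):
        node.length = max(length, 0.0)
    return TreeNode(children=[a, b, c])


def root_by_outgroup(tree: TreeNode, label: str) -> TreeNode:
    """Reroot on the branch leading to the outgroup leaf.

    The root is placed at the midpoint of the outgroup's terminal branch, so
    the ingroup becomes a clade; idempotent up to branch bookkeeping.
    """
    try:
        tip = tree.find(label)
    except Exception:
        raise GenotypeDataError(f"outgroup {label!r} not found in tree") \
            from None
    if not tip.is_tip():
        raise GenotypeDataError(f"outgroup {label!r} is not a leaf")
    length = tip.length if tip.length is not None else 0.0
    rooted = tree.root_at(tip, branch_attrs=[])
    # root_at makes the tip itself the (nameless) root over one child that
    # carries the tip's branch; re-hang the outgroup as a proper leaf under
    # a new root splitting that branch at its midpoint.
    children = list(rooted.children)
    if len(children) == 1:
        inner = children[0]
        inner.length = length / 2
    else:
        inner = TreeNode(length=length / 2, children=children)
    out_tip = TreeNode(name=str(label), length=length / 2)
    return TreeNode(children=[out_tip, inner])
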