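"""Neighbor joining on observed distances, with column-resampling bootstrap.

The initial clade-hypothesis tree is built by Saitou–Nei neighbor joining on
an "observed distance" matrix in which gap sites are data: a gap opposite a
base counts as a difference, gap opposite gap as a match, and only ``?``
(and unresolvable ambiguity codes) are skipped pairwise.  Bootstrap support
resamples alignment columns with replacement, recomputes the NJ tree per
replicate, and annotates each internal edge of the reference tree with the
percentage of replicates containing the same bipartition.

The per-replicate distance matrices are obtained in bulk: with the per-pair
difference and validity indicators precomputed as (n_pairs x n_sites)
matrices, every replicate's difference/valid counts are a single matrix
product against the resampled column multiplicities, so a thousand
replicates cost a couple of BLAS calls plus the NJ agglomerations.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .errors import GcpsrError, ValidationError
from .metrics import DistanceMatrix
from .seqio import Alignment, CODE_MISSING
from .treeops import _split_nodes, bipartitions, leaf_labels

logger = logging.getLogger(__name__)

_REP_CHUNK = 256  # bootstrap replicates per BLAS batch


def observed_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise observed distances with gap sites retained.

    Per pair: sites where either row has ``?`` (or an ambiguity code) are
    skipped; a gap against a base is a difference; gap against gap a match;
    distance = differences / counted sites.  Pairs with no counted site get
    NaN (neighbor joining refuses such matrices).
    """
    if aln.n_taxa < 2:
        raise ValidationError("observed distance needs at least 2 taxa")
    codes = aln.to_codes()
    usable = codes != CODE_MISSING
    n = aln.n_taxa
    values = np.zeros((n, n))
    counted = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = usable[i] & usable[i + 1 :]
        diff = (codes[i] != codes[i + 1 :]) & both
        nc = both.sum(axis=1)
        nd = diff.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(nc > 0, nd / np.maximum(nc, 1), np.nan)
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        counted[i, i + 1 :] = nc
        counted[i + 1 :, i] = nc
    return DistanceMatrix(aln.taxa, values, counted)


# Saitou-Nei agglomeration --------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Unrooted NJ tree from a fully defined distance matrix.

    Deterministic: Q-matrix ties are broken by the smallest (i, j) index
    pair in the current matrix order (merged nodes are appended at the end).
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling edge; raw values are logged at DEBUG.
    """
    if dm.n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if dm.has_undefined():
        raise ValidationError("distance matrix has undefined (NaN) entries")
    D = dm.values.astype(float).copy()
    tns = dendropy.TaxonNamespace(list(dm.labels))
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        node.support = None
        nodes.append(node)

    def _join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        if li < 0:
            logger.debug("clamping negative limb %g", li)
            lj, li = lj + li, 0.0
        if lj < 0:
            logger.debug("clamping negative limb %g", lj)
            li, lj = max(li + lj, 0.0), 0.0
        parent = dendropy.Node()
        parent.support = None
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        return parent

    while len(nodes) > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        k = int(np.argmin(Q[iu]))  # first minimum = smallest (i, j)
        i, j = int(iu[0][k]), int(iu[1][k])
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        parent = _join(i, j, li, dij - li)
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]

    # final trifurcation with closed-form limb lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    limbs = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    center = dendropy.Node()
    center.support = None
    for node, limb in zip(nodes, limbs):
        center.add_child(node)
        node.edge.length = max(limb, 0.0)
        if limb < 0:
            logger.debug("clamping negative limb %g", limb)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    tree.support_scale = "percent"
    return tree


# Bootstrap -----------------------------------------------------------------


def _pair_indicators(
    aln: Alignment, distance: str
) -> tuple[np.ndarray, np.ndarray]:
    """(n_pairs x L) float32 difference/validity indicators, pairs in i<j order."""
    codes = aln.to_codes()
    if distance == "observed":
        ok = codes != CODE_MISSING
    elif distance == "pdist":
        ok = codes < 4
    else:
        raise ValidationError(f"unknown distance flavor {distance!r}")
    n, L = codes.shape
    n_pairs = n * (n - 1) // 2
    diffs = np.empty((n_pairs, L), dtype=np.float32)
    valid = np.empty((n_pairs, L), dtype=np.float32)
    pos = 0
    for i in range(n - 1):
        block = n - 1 - i
        both = ok[i] & ok[i + 1 :]
        diffs[pos : pos + block] = ((codes[i] != codes[i + 1 :]) & both)
        valid[pos : pos + block] = both
        pos += block
    return diffs, valid


def _square(flat: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = flat
    out.T[iu] = flat
    return out


def bootstrap_support(
    aln: Alignment,
    reference: dendropy.Tree,
    n_reps: int = 1000,
    seed: int = 0,
    distance: str = "observed",
) -> dendropy.Tree:
    """Annotate the reference tree's internal edges with bootstrap percentages.

    Columns are resampled with replacement (same length) per replicate; each
    replicate's observed-distance NJ tree contributes to every reference
    bipartition it contains.  One root seed spawns per-replicate substreams,
    so results do not depend on batching.  Replicates with an undefined pair
    are discarded; more than 10% discarded is an error.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    ref_leaves = leaf_labels(reference)
    missing = ref_leaves - set(aln.taxa)
    if missing:
        raise ValidationError(f"reference leaves absent from alignment: {sorted(missing)}")
    sub = aln.subset_taxa([t for t in aln.taxa if t in ref_leaves])
    n, L = sub.n_taxa, sub.length
    diffs, valid = _pair_indicators(sub, distance)
    streams = np.random.SeedSequence(seed).spawn(n_reps)

    ref_splits = list(bipartitions(reference))
    counts = {s: 0 for s in ref_splits}
    kept = 0
    discarded = 0
    for start in range(0, n_reps, _REP_CHUNK):
        chunk = streams[start : start + _REP_CHUNK]
        W = np.empty((L, len(chunk)), dtype=np.float32)
        for b, ss in enumerate(chunk):
            rng = np.random.default_rng(ss)
            W[:, b] = np.bincount(rng.integers(0, L, L), minlength=L)
        nd = diffs @ W
        nc = valid @ W
        for b in range(len(chunk)):
            if (nc[:, b] == 0).any():
                discarded += 1
                logger.warning("bootstrap replicate %d discarded (undefined pair)", start + b)
                continue
            dmat = DistanceMatrix(
                sub.taxa, _square(nd[:, b] / nc[:, b], n), _square(nc[:, b], n)
            )
            kept += 1
            for s in bipartitions(neighbor_joining(dmat)):
                if s in counts:
                    counts[s] += 1
    if discarded > 0.1 * n_reps:
        raise GcpsrError(
            f"{discarded}/{n_reps} bootstrap replicates discarded (undefined pairs)"
        )
    annotated = reference.clone(depth=1)
    for split, node_list in _split_nodes(annotated).items():
        sup = 100.0 * counts[split] / kept if kept else 0.0
        for node in node_list:
            node.support = sup
    annotated.support_scale = "percent"
    return annotated


# Rooting -------------------------------------------------------------------


def _distances_from(
    start: dendropy.Node,
) -> tuple[dict[dendropy.Node, float], dict[dendropy.Node, dendropy.Node]]:
    """Path lengths (and predecessors) from ``start`` over the whole tree."""
    dist = {start: 0.0}
    prev: dict[dendropy.Node, dendropy.Node] = {}
    stack = [start]
    while stack:
        u = stack.pop()
        neighbors = list(u.child_nodes())
        if u.parent_node is not None:
            neighbors.append(u.parent_node)
        for v in neighbors:
            if v in dist:
                continue
            w = v.edge.length if v.parent_node is u else u.edge.length
            dist[v] = dist[u] + w
            prev[v] = u
            stack.append(v)
    return dist, prev


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Branch lengths must be present on every non-root edge.  Edge supports
    are carried over by bipartition (the split set is unchanged by rooting).
    When the midpoint falls exactly on an existing internal node the tree is
    rooted at that node; otherwise the spanning edge is split.
    """
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValidationError("midpoint rooting requires branch lengths")
    saved = {
        split: getattr(nodes[0], "support", None)
        for split, nodes in _split_nodes(tree).items()
    }
    rooted = tree.clone(depth=1)
    leaves = [lf for lf in rooted.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValidationError("midpoint rooting needs at least 2 leaves")
    # double sweep: farthest leaf from an arbitrary leaf, then farthest from it
    d0, _ = _distances_from(leaves[0])
    tip_a = max(leaves, key=lambda l: d0[l])
    da, prev = _distances_from(tip_a)
    tip_b = max(leaves, key=lambda l: da[l])
    diameter = da[tip_b]
    path = [tip_b]
    while path[-1] is not tip_a:
        path.append(prev[path[-1]])
    path.reverse()  # tip_a ... tip_b
    target = diameter / 2.0
    eps = 1e-12 * max(diameter, 1.0)
    acc = 0.0
    for u, v in zip(path, path[1:]):
        child = v if v.parent_node is u else u
        w = child.edge.length
        if acc + w >= target - eps:
            into = target - acc  # distance from u along the edge
            if into <= eps and not u.is_leaf():
                rooted.reroot_at_node(u, update_bipartitions=False)
            elif w - into <= eps and not v.is_leaf():
                rooted.reroot_at_node(v, update_bipartitions=False)
            else:
                from_parent = into if child is v else w - into
                rooted.reroot_at_edge(
                    child.edge,
                    length1=from_parent,
                    length2=w - from_parent,
                    update_bipartitions=False,
                )
            break
        acc += w
    rooted.is_rooted = True
    for node in rooted.preorder_node_iter():
        node.support = getattr(node, "support", None)
    for split, nodes in _split_nodes(rooted).items():
        if split in saved:
            for node in nodes:
                node.support = saved[split]
    rooted.support_scale = getattr(tree, "support_scale", None)
    return rooted
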