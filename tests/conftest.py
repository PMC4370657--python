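"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gcpsr import Alignment, LocusSet, parse_newick


# -- random object generators ----------------------------------------------


def random_alignment(
    rng: np.random.Generator,
    n_taxa: int,
    length: int,
    alphabet: str = "ACGT",
    prefix: str = "t",
) -> Alignment:
    chars = np.array(list(alphabet))
    rows = tuple(
        "".join(chars[rng.integers(0, len(chars), length)]) for _ in range(n_taxa)
    )
    return Alignment(tuple(f"{prefix}{i}" for i in range(n_taxa)), rows)


def random_locus_set(rng: np.random.Generator, n_taxa: int = 8, n_loci: int = 3) -> LocusSet:
    """Loci of random lengths; each locus drops a random strain subset."""
    taxa = [f"s{i}" for i in range(n_taxa)]
    loci = {}
    for k in range(n_loci):
        length = int(rng.integers(5, 40))
        n_present = int(rng.integers(2, n_taxa + 1))
        present = sorted(rng.choice(n_taxa, size=n_present, replace=False))
        sub = random_alignment(rng, len(present), length)
        loci[f"L{k}"] = Alignment(
            tuple(taxa[i] for i in present), sub.rows
        )
    return LocusSet(loci)


def random_binary_newick(rng: np.random.Generator, labels: list[str]) -> str:
    """Random unrooted binary topology with unit branch lengths."""
    items = [f"{l}:1" for l in labels]
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = f"({items[i]},{items[j]}):1"
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    return f"({items[0]},{items[1]},{items[2]});"


def random_tree(rng: np.random.Generator, n_leaves: int, prefix: str = "x"):
    labels = [f"{prefix}{i}" for i in range(n_leaves)]
    return parse_newick(random_binary_newick(rng, labels))


# -- independent oracles ----------------------------------------------------


def oracle_splits(tree) -> set[frozenset[str]]:
    """Nontrivial splits via dendropy's own bipartition encoding."""
    tree = tree.clone(depth=1)
    tree.encode_bipartitions()
    tns = tree.taxon_namespace
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_leaves)
    out = set()
    for bp in tree.bipartition_encoding:
        side = frozenset(t.label for t in tns.bitmask_taxa_list(bp.leafset_bitmask))
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        out.add(side if ref not in side else all_leaves - side)
    return out


def oracle_monophyletic(tree, taxa: set[str]) -> bool:
    """Edge-removal test: some edge's below-leafset equals taxa or complement."""
    all_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if len(taxa) in (1, len(all_leaves)):
        return True
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        if below == taxa or all_leaves - below == taxa:
            return True
    return False


def enumerate_topologies(labels: tuple[str, ...]) -> list[set[frozenset[str]]]:
    """All unrooted binary topologies on 4 or 5 labels, as canonical split sets."""
    ref = min(labels)
    others = [l for l in labels if l != ref]
    if len(labels) == 4:
        # canonical side omits ref, so each 2-subset of the others is a topology
        return [{frozenset(p)} for p in itertools.combinations(others, 2)]
    if len(labels) == 5:
        pairs = list(itertools.combinations(labels, 2))
        topos = []
        for a, b in itertools.combinations(pairs, 2):
            sa, sb = set(a), set(b)
            if sa & sb:
                continue
            full = frozenset(labels)
            ca = frozenset(sa) if ref not in sa else full - frozenset(sa)
            cb = frozenset(sb) if ref not in sb else full - frozenset(sb)
            topos.append({ca, cb})
        return topos
    raise ValueError("only 4 or 5 labels supported")


def least_squares_topology(labels, dist) -> tuple[set[frozenset[str]], float]:
    """Best-fit topology by OLS over all 4/5-taxon trees; returns (splits, SSR)."""
    labels = tuple(labels)
    idx = {l: i for i, l in enumerate(labels)}
    pairs = list(itertools.combinations(labels, 2))
    d = np.array([dist[idx[a], idx[b]] for a, b in pairs])
    best = None
    for splits in enumerate_topologies(labels):
        edges: list[frozenset[str]] = [frozenset((l,)) for l in labels] + list(splits)
        A = np.zeros((len(pairs), len(edges)))
        for r, (a, b) in enumerate(pairs):
            for c, side in enumerate(edges):
                if (a in side) != (b in side):
                    A[r, c] = 1.0
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        ssr = float(((A @ x - d) ** 2).sum())
        if best is None or ssr < best[1]:
            best = (splits, ssr)
    return best


def brute_force_nj_splits(labels, dist) -> set[frozenset[str]]:
    """Plain-loop re-implementation of the Saitou-Nei agglomeration trace.

    Same tie rule (first minimal (i, j) in current order, merged cluster
    appended); returns the final topology as canonical splits.
    """
    clusters = [frozenset((l,)) for l in labels]
    D = [[float(dist[i][j]) for j in range(len(labels))] for i in range(len(labels))]
    full = frozenset(labels)
    ref = min(labels)
    splits: set[frozenset[str]] = set()
    while len(clusters) > 3:
        m = len(clusters)
        r = [sum(row) for row in D]
        best_q, bi, bj = None, None, None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i][j] - r[i] - r[j]
                if best_q is None or q < best_q:
                    best_q, bi, bj = q, i, j
        merged = clusters[bi] | clusters[bj]
        if 2 <= len(merged) <= len(full) - 2:
            splits.add(merged if ref not in merged else full - merged)
        newrow = [
            0.5 * (D[bi][k] + D[bj][k] - D[bi][bj])
            for k in range(m)
            if k not in (bi, bj)
        ]
        keep = [k for k in range(m) if k not in (bi, bj)]
        D = [[D[a][b] for b in keep] for a in keep]
        for row, v in zip(D, newrow):
            row.append(v)
        D.append(newrow + [0.0])
        clusters = [clusters[k] for k in keep] + [merged]
    return splits


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)
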