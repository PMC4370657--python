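"""Tree operations for genealogical-concordance assessment.

Trees are held as :class:`dendropy.Tree` objects; this module adds the split
(bipartition) machinery the concordance analysis needs and the clade
assignment rule itself: a candidate clade is accepted for a locus when it is
recovered as a distinct group in the strict-consensus parsimony tree and has
support strictly above the threshold (default 80%) in each of the NJ, ML and
Bayesian trees.  Bayesian posteriors are compared on the percent scale
(posterior x 100), so PP > 0.80 passes the default rule.

Splits are canonicalised as the frozenset of leaf labels on the side *not*
containing the lexicographically smallest leaf, which makes them comparable
across rootings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .errors import FormatError, ValidationError

METHODS = ("NJ", "MP_strict", "ML", "BI")
SUPPORT_SCALES = ("percent", "posterior")


# Newick I/O ----------------------------------------------------------------


def parse_newick(
    text: str, support_scale: str | None = None
) -> dendropy.Tree:
    """Parse one newick tree; internal node labels become edge supports.

    The support scale is auto-detected (any value > 1 implies percent,
    otherwise posterior) unless ``support_scale`` overrides it.  The scale is
    stored on the tree as ``tree.support_scale``.
    """
    if support_scale is not None and support_scale not in SUPPORT_SCALES:
        raise ValidationError(f"unknown support scale {support_scale!r}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise FormatError(f"duplicate leaf {dup!r} in newick")
    supports: list[float] = []
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf():
            continue
        if node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass  # a genuine internal node name; keep as label
            else:
                node.label = None
                supports.append(node.support)
    if support_scale is None and supports:
        support_scale = "percent" if any(s > 1 for s in supports) else "posterior"
    tree.support_scale = support_scale
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise with supports as internal node labels and branch lengths."""
    saved = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        saved.append((node, node.label))
        sup = getattr(node, "support", None)
        if sup is not None:
            node.label = f"{sup:g}"
    try:
        out = tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip() + "\n"
    finally:
        for node, label in saved:
            node.label = label
    return out


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


# Splits --------------------------------------------------------------------


def _split_nodes(tree: dendropy.Tree) -> dict[frozenset[str], list[dendropy.Node]]:
    """Map each nontrivial canonical split to the node(s) inducing it."""
    all_leaves = leaf_labels(tree)
    if not all_leaves:
        return {}
    ref = min(all_leaves)
    below: dict[dendropy.Node, frozenset[str]] = {}
    out: dict[frozenset[str], list[dendropy.Node]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset((node.taxon.label,))
            continue
        bs = frozenset().union(*(below[c] for c in node.child_nodes()))
        below[node] = bs
        if node is tree.seed_node:
            continue
        if len(bs) < 2 or len(all_leaves - bs) < 2:
            continue
        canon = bs if ref not in bs else all_leaves - bs
        out.setdefault(canon, []).append(node)
    return out


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial splits of the (possibly rooted) tree, canonicalised."""
    return set(_split_nodes(tree))


def strict_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Tree containing exactly the splits present in every input tree."""
    if not trees:
        raise ValidationError("strict consensus of an empty tree list")
    leaves = leaf_labels(trees[0])
    for t in trees[1:]:
        if leaf_labels(t) != leaves:
            raise ValidationError("strict consensus requires identical leaf sets")
    shared = set.intersection(*(bipartitions(t) for t in trees))
    return tree_from_clusters(leaves, shared)


def tree_from_clusters(
    leaves: Iterable[str], clusters: Iterable[frozenset[str]]
) -> dendropy.Tree:
    """Build an unrooted tree realising a compatible set of canonical splits.

    The canonical sides never contain the reference leaf, so they nest; each
    cluster (and leaf) attaches to the smallest cluster strictly containing
    it, or to the root.
    """
    leaves = sorted(set(leaves))
    tns = dendropy.TaxonNamespace(leaves)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    root = tree.seed_node
    root.support = None
    ordered = sorted(clusters, key=len, reverse=True)
    nodes: list[dendropy.Node] = []
    for i, cl in enumerate(ordered):
        parent = root
        for j in range(i - 1, -1, -1):
            if cl < ordered[j]:
                parent = nodes[j]
                break
        node = dendropy.Node()
        node.support = None
        parent.add_child(node)
        nodes.append(node)
    for lab in leaves:
        parent = root
        best = None
        for j, cl in enumerate(ordered):
            if lab in cl and (best is None or len(cl) < len(ordered[best])):
                best = j
        if best is not None:
            parent = nodes[best]
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        parent.add_child(leaf)
    return tree


def is_monophyletic(tree: dendropy.Tree, taxa: Iterable[str]) -> bool:
    """Does ``taxa`` induce a split of the (unrooted) tree?

    Singletons, the full leaf set, and complements of singletons are
    monophyletic by convention (their splits are trivial edges).
    """
    taxa = frozenset(taxa)
    leaves = leaf_labels(tree)
    unknown = taxa - leaves
    if unknown:
        raise ValidationError(f"unknown taxa {sorted(unknown)}")
    if not taxa:
        raise ValidationError("empty taxon set")
    if len(taxa) in (1, len(leaves) - 1, len(leaves)):
        return True
    ref = min(leaves)
    canon = taxa if ref not in taxa else leaves - taxa
    return canon in bipartitions(tree)


def clade_support(tree: dendropy.Tree, taxa: Iterable[str]) -> float | None:
    """Support of the edge inducing the split ``taxa`` | rest, if any.

    Returns None when the set is not monophyletic, the split is trivial, or
    the inducing edge carries no annotation.  The value is returned on the
    tree's native scale.
    """
    taxa = frozenset(taxa)
    leaves = leaf_labels(tree)
    unknown = taxa - leaves
    if unknown:
        raise ValidationError(f"unknown taxa {sorted(unknown)}")
    if len(taxa) < 2 or not taxa < leaves:
        return None
    complement = leaves - taxa
    fallback = None
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        sup = getattr(node, "support", None)
        if sup is None:
            continue
        subtree = frozenset(l.taxon.label for l in node.leaf_iter())
        if subtree == taxa:
            # the clade's own stem edge
            return float(sup)
        if subtree == complement:
            # same unrooted edge seen from the other side
            fallback = float(sup)
    return fallback


def support_as_percent(value: float | None, scale: str) -> float | None:
    if value is None:
        return None
    if scale == "posterior":
        return value * 100.0
    return value


# Gene tree sets and the concordance rule -----------------------------------


@dataclass
class GeneTreeEntry:
    locus: str
    method: str
    tree: dendropy.Tree
    support_scale: str = "percent"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.support_scale not in SUPPORT_SCALES:
            raise ValidationError(f"unknown support scale {self.support_scale!r}")


@dataclass
class GeneTreeSet:
    entries: list[GeneTreeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(e.locus, e.method) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate (locus, method) entry")

    def loci(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.locus)
        return tuple(seen)

    def get(self, locus: str, method: str) -> GeneTreeEntry | None:
        for e in self.entries:
            if e.locus == locus and e.method == method:
                return e
        return None


@dataclass(frozen=True)
class ConcordanceRule:
    """Clade acceptance rule across methods for a single locus."""

    support_threshold_percent: float = 80.0
    supported_methods: tuple[str, ...] = ("NJ", "ML", "BI")
    recovery_method: str = "MP_strict"

    def __post_init__(self) -> None:
        if not 0 < self.support_threshold_percent < 100:
            raise ValidationError("threshold must lie in (0, 100)")


@dataclass
class ConcordanceCell:
    clade: str
    locus: str
    evaluable: bool
    recovered_mp: bool | None = None
    supports: dict[str, float | None] = field(default_factory=dict)
    passed: bool | None = None
    failures: tuple[str, ...] = ()


@dataclass
class ConcordanceReport:
    """clade x locus grid plus per-clade verdicts.

    Verdicts: ``concordant`` (recovered and supported in every evaluable
    locus — conventionally drawn as a black dot), ``partial`` (>= 2 but not
    all loci — a grey dot), ``discordant`` otherwise.
    """

    clades: tuple[str, ...]
    loci: tuple[str, ...]
    cells: list[ConcordanceCell]
    verdicts: dict[str, str]
    n_loci_passed: dict[str, int]
    exceptions: list[tuple[str, str, tuple[str, ...]]]

    def cell(self, clade: str, locus: str) -> ConcordanceCell:
        for c in self.cells:
            if c.clade == clade and c.locus == locus:
                return c
        raise KeyError((clade, locus))

    def to_dict(self) -> dict:
        return {
            "clades": list(self.clades),
            "loci": list(self.loci),
            "cells": [
                {
                    "clade": c.clade,
                    "locus": c.locus,
                    "evaluable": c.evaluable,
                    "recovered_mp": c.recovered_mp,
                    "supports": c.supports,
                    "passed": c.passed,
                    "failures": list(c.failures),
                }
                for c in self.cells
            ],
            "verdicts": self.verdicts,
            "n_loci_passed": self.n_loci_passed,
            "exceptions": [
                {"clade": cl, "locus": lo, "failures": list(fs)}
                for cl, lo, fs in self.exceptions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConcordanceReport":
        return cls(
            clades=tuple(d["clades"]),
            loci=tuple(d["loci"]),
            cells=[
                ConcordanceCell(
                    clade=c["clade"],
                    locus=c["locus"],
                    evaluable=c["evaluable"],
                    recovered_mp=c["recovered_mp"],
                    supports=dict(c["supports"]),
                    passed=c["passed"],
                    failures=tuple(c["failures"]),
                )
                for c in d["cells"]
            ],
            verdicts=dict(d["verdicts"]),
            n_loci_passed=dict(d["n_loci_passed"]),
            exceptions=[
                (e["clade"], e["locus"], tuple(e["failures"]))
                for e in d["exceptions"]
            ],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ConcordanceReport":
        return cls.from_dict(json.loads(text))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "clade": c.clade,
                "locus": c.locus,
                "evaluable": c.evaluable,
                "recovered_mp": c.recovered_mp,
                "passed": c.passed,
                "failures": ";".join(c.failures),
            }
            for m, s in c.supports.items():
                row[f"support_{m}"] = s
            rows.append(row)
        return pd.DataFrame(rows)


def assess_concordance(
    trees: GeneTreeSet,
    hypothesis: Mapping[str, str],
    rule: ConcordanceRule = ConcordanceRule(),
) -> ConcordanceReport:
    """Fill the clade x locus concordance grid and derive verdicts.

    A clade passes a locus iff it is recovered in the strict-consensus
    parsimony tree and every supported method annotates its split with
    support strictly above the threshold (posteriors compared as PP x 100).
    Taxa absent from a locus's trees are dropped from the clade for that
    locus; a clade reduced below two members is not evaluable there.
    """
    clade_order: dict[str, None] = {}
    members: dict[str, set[str]] = {}
    for strain, clade in hypothesis.items():
        clade_order.setdefault(clade)
        members.setdefault(clade, set()).add(strain)
    clades = tuple(clade_order)
    loci = trees.loci()
    if not clades or not loci:
        raise ValidationError("need at least one clade and one locus")

    cells: list[ConcordanceCell] = []
    for clade in clades:
        for locus in loci:
            entries = {
                m: trees.get(locus, m)
                for m in (rule.recovery_method, *rule.supported_methods)
            }
            locus_leaves: set[str] = set()
            for e in entries.values():
                if e is not None:
                    locus_leaves |= leaf_labels(e.tree)
            local = members[clade] & locus_leaves
            if len(local) < 2:
                cells.append(ConcordanceCell(clade, locus, evaluable=False))
                continue
            failures: list[str] = []
            mp = entries[rule.recovery_method]
            if mp is None:
                recovered = None
                failures.append(f"{rule.recovery_method}:missing")
            else:
                sub = members[clade] & leaf_labels(mp.tree)
                recovered = bool(sub) and is_monophyletic(mp.tree, sub)
                if not recovered:
                    failures.append(f"{rule.recovery_method}:not_recovered")
            supports: dict[str, float | None] = {}
            for m in rule.supported_methods:
                e = entries[m]
                if e is None:
                    supports[m] = None
                    failures.append(f"{m}:missing")
                    continue
                sub = members[clade] & leaf_labels(e.tree)
                sup = (
                    clade_support(e.tree, sub)
                    if len(sub) >= 2
                    else None
                )
                sup_pct = support_as_percent(sup, e.support_scale)
                supports[m] = sup_pct
                if sup_pct is None:
                    failures.append(f"{m}:unsupported")
                elif not sup_pct > rule.support_threshold_percent:
                    failures.append(
                        f"{m}:support<={rule.support_threshold_percent:g}"
                    )
            passed = not failures
            cells.append(
                ConcordanceCell(
                    clade,
                    locus,
                    evaluable=True,
                    recovered_mp=recovered,
                    supports=supports,
                    passed=passed,
                    failures=tuple(failures),
                )
            )

    verdicts: dict[str, str] = {}
    n_passed: dict[str, int] = {}
    exceptions: list[tuple[str, str, tuple[str, ...]]] = []
    for clade in clades:
        evaluable = [c for c in cells if c.clade == clade and c.evaluable]
        passed = [c for c in evaluable if c.passed]
        n_passed[clade] = len(passed)
        if evaluable and len(passed) == len(evaluable):
            verdicts[clade] = "concordant"
        elif len(passed) >= 2:
            verdicts[clade] = "partial"
        else:
            verdicts[clade] = "discordant"
        for c in evaluable:
            if not c.passed:
                exceptions.append((c.clade, c.locus, c.failures))
    return ConcordanceReport(
        clades=clades,
        loci=loci,
        cells=cells,
        verdicts=verdicts,
        n_loci_passed=n_passed,
        exceptions=exceptions,
    )


# Candidate clades from the initial tree ------------------------------------


def node_height(node: dendropy.Node) -> float:
    """Max path length from ``node`` down to a leaf (unit edges if lengths absent)."""
    if node.is_leaf():
        return 0.0
    return max(
        node_height(c) + (c.edge.length if c.edge.length is not None else 1.0)
        for c in node.child_nodes()
    )


def propose_clades_from_tree(
    tree: dendropy.Tree, min_size: int = 2
) -> list[tuple[str, ...]]:
    """Candidate clades of the rooted tree, shallowest (most recent) first.

    Each internal non-root node of height h contributes its leaf set if the
    set has at least ``min_size`` members; candidates are ordered by
    increasing height (ties: smaller clade, then labels), mirroring a sweep
    from the tips toward the root.
    """
    cands: list[tuple[float, int, tuple[str, ...]]] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        labels = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
        if len(labels) < min_size:
            continue
        cands.append((node_height(node), len(labels), labels))
    cands.sort()
    return [labels for _, _, labels in cands]
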