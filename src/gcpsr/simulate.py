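"""Seedable multi-locus scenario simulator for the species-complex pipeline.

The generator emulates the study design the pipeline targets: five clades —
four closely related clades of a cryptic species complex radiating near one
another, plus one distant species attached on a long branch — sampled at
five loci of unequal length, with locus-specific whole-sequence dropout
(an ITS-like marker missing for ~22% of strains, an RPB2-like marker for
~6%).  Sequences evolve down a composite ultrametric tree under K80 with
discrete-gamma rate heterogeneity (8 categories); branch lengths are in
expected substitutions per site, so configured depths translate directly
into the p-distance magnitudes the barcode-gap analysis measures.

A companion helper, :func:`method_tree_suite`, assembles the per-locus gene
trees the concordance stage consumes: NJ trees are produced by actually
running the neighbor-joining module on the simulated alignments, while
parsimony/ML/Bayesian trees are stand-ins derived from the true genealogy,
optionally distorted (collapse a clade to a polytomy; force a support value)
to reproduce the failure modes a real analysis can show.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import yaml
from scipy.stats import gamma as _gamma_dist

from .errors import ValidationError
from .nj import bootstrap_support, neighbor_joining, observed_distance_matrix
from .seqio import Alignment, LocusSet, write_fasta
from .treeops import (
    GeneTreeEntry,
    GeneTreeSet,
    _split_nodes,
    leaf_labels,
    write_newick,
)

logger = logging.getLogger(__name__)

_DEFAULT_REGIONS: dict[str, dict[str, float]] = {
    "sebi-1": {"Europe": 0.5, "Micronesia": 0.2, "South_Asia": 0.2, "South_America": 0.1},
    "sebi-2": {"Europe": 0.4, "Micronesia": 0.2, "South_Asia": 0.3, "Canada": 0.1},
    "sebi-3": {"Canada": 1.0},
    "sebi-4": {"South_America": 0.4, "Micronesia": 0.3, "South_Asia": 0.3},
    "muriae": {"Europe": 1.0},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic data set.

    Depths are expected substitutions/site.  The last clade plays the
    distant-species role and sits at ``outgroup_depth``; the in-complex
    clades radiate at ``between_clade_depth`` with star-like backbone
    structure (zero-length internal backbone edges), mirroring a complex
    whose inter-clade relationships are poorly resolved.
    """

    seed: int = 0
    n_clades: int = 5
    clade_sizes: tuple[int, ...] = (25, 40, 4, 6, 15)
    clade_names: tuple[str, ...] = ("sebi-1", "sebi-2", "sebi-3", "sebi-4", "muriae")
    locus_names: tuple[str, ...] = ("ITS", "MCM7", "RPB1", "RPB2", "TSR1")
    locus_lengths: tuple[int, ...] = (513, 603, 610, 738, 607)
    kappa: float = 2.0
    gamma_shape: float = 0.5
    n_gamma_categories: int = 8
    between_clade_depth: float = 0.03
    within_clade_depth: float = 0.002
    outgroup_depth: float = 0.15
    missing_rates: tuple[float, ...] = (20 / 90, 0.0, 0.0, 5 / 90, 0.0)
    region_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_REGIONS.items()}
    )

    def __post_init__(self) -> None:
        if len(self.clade_sizes) != self.n_clades or len(self.clade_names) != self.n_clades:
            raise ValidationError("clade_sizes/clade_names must match n_clades")
        if len(self.locus_lengths) != len(self.locus_names):
            raise ValidationError("locus_lengths must match locus_names")
        if len(self.missing_rates) != len(self.locus_names):
            raise ValidationError("missing_rates must match locus_names")
        if any(s < 1 for s in self.clade_sizes):
            raise ValidationError("clade sizes must be >= 1")
        if any(not 0 <= r < 1 for r in self.missing_rates):
            raise ValidationError("missing rates must lie in [0, 1)")
        if min(self.between_clade_depth, self.within_clade_depth, self.outgroup_depth) < 0:
            raise ValidationError("depths must be >= 0")
        if self.gamma_shape <= 0:
            raise ValidationError("gamma_shape must be > 0")
        for clade in self.clade_names:
            w = self.region_weights.get(clade)
            if not w or sum(w.values()) <= 0 or any(x < 0 for x in w.values()):
                raise ValidationError(f"invalid region weights for clade {clade!r}")

    @property
    def n_taxa(self) -> int:
        return sum(self.clade_sizes)

    @property
    def outgroup_clade(self) -> str:
        return self.clade_names[-1]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    locus_set: LocusSet
    true_partition: dict[str, str]
    true_trees: dict[str, dendropy.Tree]
    species_tree: dendropy.Tree
    metadata: dict[str, str]

    @property
    def in_complex_partition(self) -> dict[str, str]:
        """True partition restricted to the species-complex clades."""
        out = self.config.outgroup_clade
        return {s: c for s, c in self.true_partition.items() if c != out}


# Genealogy -----------------------------------------------------------------


def _yule_subtree(
    rng: np.random.Generator, labels: Sequence[str], depth: float, tns: dendropy.TaxonNamespace
) -> dendropy.Node:
    """Random ultrametric subtree: Yule-style random joins, tips at ``depth``."""
    items: list[tuple[dendropy.Node, float]] = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        node.support = None
        items.append((node, 0.0))
    if len(items) == 1:
        anc = dendropy.Node()
        anc.support = None
        node, _ = items[0]
        anc.add_child(node)
        node.edge.length = depth
        return anc
    k = len(items)
    heights = np.sort(rng.uniform(0.0, depth, size=max(k - 2, 0)))
    heights = np.append(heights, depth)
    for h in heights:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (a, ha), (b, hb) = items[i], items[j]
        parent = dendropy.Node()
        parent.support = None
        parent.add_child(a)
        a.edge.length = float(h - ha)
        parent.add_child(b)
        b.edge.length = float(h - hb)
        items = [it for x, it in enumerate(items) if x not in (i, j)]
        items.append((parent, float(h)))
    return items[0][0]


def _species_tree(
    config: SimulationConfig,
    strains: dict[str, list[str]],
    rng: np.random.Generator,
) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace(
        [s for clade in config.clade_names for s in strains[clade]]
    )
    root = dendropy.Node()
    root.support = None
    for clade in config.clade_names:
        tip_depth = (
            config.outgroup_depth
            if clade == config.outgroup_clade
            else config.between_clade_depth
        )
        sub_depth = min(config.within_clade_depth, tip_depth)
        if len(strains[clade]) < 2 and config.within_clade_depth > 0:
            logger.warning("clade %s has a single member; no within-clade pairs", clade)
        anc = _yule_subtree(rng, strains[clade], sub_depth, tns)
        root.add_child(anc)
        anc.edge.length = tip_depth - sub_depth
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    tree.support_scale = None
    return tree


# K80 + discrete gamma ------------------------------------------------------


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rate of each of ``n_categories`` equal-probability gamma bins.

    The gamma has mean 1 (shape = ``shape``, scale = 1/shape); category means
    use the standard incomplete-gamma identity and are renormalised to mean
    exactly 1.
    """
    scale = 1.0 / shape
    edges = _gamma_dist.ppf(np.linspace(0, 1, n_categories + 1), shape, scale=scale)
    upper = _gamma_dist.cdf(edges, shape + 1, scale=scale)
    rates = n_categories * np.diff(upper)  # E[X | bin] since bins have mass 1/K
    return rates / rates.mean()


def k80_probabilities(distance: float, kappa: float) -> tuple[float, float, float]:
    """(P_same, P_transition, P_each_transversion) after ``distance`` subs/site."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * distance)
    e2 = np.exp(-2.0 * (alpha + beta) * distance)
    p_tv = 0.25 - 0.25 * e1
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def _evolve_locus(
    tree: dendropy.Tree,
    length: int,
    kappa: float,
    rates: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Simulate one locus down ``tree``; returns taxon → sequence."""
    site_rate = rates[rng.integers(0, len(rates), size=length)]
    seqs: dict[dendropy.Node, np.ndarray] = {
        tree.seed_node: rng.integers(0, 4, size=length, dtype=np.uint8)
    }
    out: dict[str, str] = {}
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[node.parent_node]
        d = node.edge.length or 0.0
        child = parent_seq.copy()
        if d > 0:
            p_same = np.empty(length)
            p_ts = np.empty(length)
            for k, r in enumerate(rates):
                mask = site_rate == r
                if not mask.any():
                    continue
                s, t, _ = k80_probabilities(d * r, kappa)
                p_same[mask] = s
                p_ts[mask] = t
            u = rng.random(length)
            tv_pick = rng.random(length) < 0.5
            ts_mask = (u >= p_same) & (u < p_same + p_ts)
            tv_mask = u >= p_same + p_ts
            child[ts_mask] = parent_seq[ts_mask] ^ 2
            tv1 = tv_mask & tv_pick
            tv2 = tv_mask & ~tv_pick
            child[tv1] = parent_seq[tv1] ^ 1
            child[tv2] = parent_seq[tv2] ^ 3
        seqs[node] = child
        if node.is_leaf():
            out[node.taxon.label] = lut[child].tobytes().decode("ascii")
    return out


# Scenario ------------------------------------------------------------------


def simulate_species_scenario(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full synthetic data set under the configured study conditions.

    Reproducible per seed: the seed feeds independent substreams for the
    genealogy, each locus's evolution, the dropout pattern and the region
    assignment, so outputs are byte-identical across runs.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(3 + len(config.locus_names))
    rng_tree = np.random.default_rng(streams[0])
    rng_missing = np.random.default_rng(streams[1])
    rng_region = np.random.default_rng(streams[2])

    width = len(str(config.n_taxa))
    strains: dict[str, list[str]] = {}
    counter = 0
    for clade, size in zip(config.clade_names, config.clade_sizes):
        strains[clade] = [
            f"{clade}_{counter + k + 1:0{width}d}" for k in range(size)
        ]
        counter += size
    true_partition = {s: c for c, ss_ in strains.items() for s in ss_}
    all_strains = [s for c in config.clade_names for s in strains[c]]

    species_tree = _species_tree(config, strains, rng_tree)
    rates = discrete_gamma_rates(config.gamma_shape, config.n_gamma_categories)

    loci: dict[str, Alignment] = {}
    true_trees: dict[str, dendropy.Tree] = {}
    for idx, (locus, length) in enumerate(
        zip(config.locus_names, config.locus_lengths)
    ):
        rng_locus = np.random.default_rng(streams[3 + idx])
        seqs = _evolve_locus(species_tree, length, config.kappa, rates, rng_locus)
        n_missing = int(round(config.missing_rates[idx] * config.n_taxa))
        dropped: set[str] = set()
        if n_missing:
            picks = rng_missing.choice(config.n_taxa, size=n_missing, replace=False)
            dropped = {all_strains[i] for i in picks}
        present = [s for s in all_strains if s not in dropped]
        loci[locus] = Alignment(
            tuple(present), tuple(seqs[s] for s in present)
        )
        sub = species_tree.extract_tree_with_taxa_labels(labels=present)
        sub.is_rooted = True
        for node in sub.preorder_node_iter():
            node.support = None
        sub.support_scale = None
        true_trees[locus] = sub

    metadata: dict[str, str] = {}
    for clade in config.clade_names:
        weights = config.region_weights[clade]
        regions = sorted(weights)
        p = np.array([weights[r] for r in regions], dtype=float)
        p /= p.sum()
        for s in strains[clade]:
            metadata[s] = regions[int(rng_region.choice(len(regions), p=p))]

    return SyntheticDataset(
        config=config,
        locus_set=LocusSet(loci),
        true_partition=true_partition,
        true_trees=true_trees,
        species_tree=species_tree,
        metadata=metadata,
    )


# Method-labeled gene trees -------------------------------------------------


@dataclass(frozen=True)
class DistortionSpec:
    """Perturbations applied to the stand-in (MP/ML/BI) gene trees.

    ``polytomies``: (locus, clade) pairs whose clade is collapsed into a
    polytomy with its parent's other children (the clade stops being
    monophyletic at that locus).  ``support_overrides``: (locus, method,
    clade, value-percent) entries forcing a clade's support value.
    """

    polytomies: tuple[tuple[str, str], ...] = ()
    support_overrides: tuple[tuple[str, str, str, float], ...] = ()


def _annotate(tree: dendropy.Tree, value: float | None) -> dendropy.Tree:
    out = tree.clone(depth=1)
    for node in out.preorder_node_iter():
        node.support = (
            value if (not node.is_leaf() and node is not out.seed_node) else None
        )
    return out


def _collapse_clade(tree: dendropy.Tree, members: set[str]) -> None:
    local = members & set(leaf_labels(tree))
    if len(local) < 2:
        return
    mrca = tree.mrca(taxon_labels=sorted(local))
    if mrca is None or mrca is tree.seed_node:
        return
    parent = mrca.parent_node
    for child in list(mrca.child_nodes()):
        mrca.remove_child(child)
        parent.add_child(child)
    parent.remove_child(mrca)


def _force_support(tree: dendropy.Tree, members: set[str], value: float) -> None:
    local = frozenset(members & set(leaf_labels(tree)))
    for split, nodes in _split_nodes(tree).items():
        for node in nodes:
            subtree = frozenset(l.taxon.label for l in node.leaf_iter())
            if subtree == local:
                node.support = value
                return
    raise ValidationError("clade not present in tree; cannot force support")


def method_tree_suite(
    dataset: SyntheticDataset,
    distortion: DistortionSpec | None = None,
    seed: int = 0,
    n_boot: int = 100,
) -> GeneTreeSet:
    """Per-locus gene trees labeled by inference method.

    NJ trees come from the real neighbor-joining + bootstrap machinery run on
    the simulated alignments; MP strict-consensus, ML and BI trees are
    derived from the true genealogy (full support, posterior 1.0) and then
    distorted per ``distortion``.
    """
    distortion = distortion or DistortionSpec()
    clades = set(dataset.true_partition.values())
    for locus, clade in distortion.polytomies:
        if clade not in clades or locus not in dataset.locus_set.loci:
            raise ValidationError(f"distortion references unknown {locus}/{clade}")
    for locus, method, clade, _ in distortion.support_overrides:
        if clade not in clades or locus not in dataset.locus_set.loci:
            raise ValidationError(f"distortion references unknown {locus}/{clade}")

    members: dict[str, set[str]] = {}
    for s, c in dataset.true_partition.items():
        members.setdefault(c, set()).add(s)

    entries: list[GeneTreeEntry] = []
    boot_streams = np.random.SeedSequence(seed).spawn(len(dataset.locus_set.loci))
    for idx, (locus, aln) in enumerate(dataset.locus_set.loci.items()):
        nj_tree = neighbor_joining(observed_distance_matrix(aln))
        nj_tree = bootstrap_support(
            aln, nj_tree, n_reps=n_boot,
            seed=int(boot_streams[idx].generate_state(1)[0] % (2**31 - 1)),
        )
        base = dataset.true_trees[locus]
        mp = _annotate(base, None)
        ml = _annotate(base, 100.0)
        bi = _annotate(base, 1.0)
        for locus_d, clade in distortion.polytomies:
            if locus_d == locus:
                for t in (mp, ml, bi):
                    _collapse_clade(t, members[clade])
        by_method = {"MP_strict": mp, "ML": ml, "BI": bi}
        for locus_d, method, clade, value in distortion.support_overrides:
            if locus_d == locus:
                tree = by_method.get(method)
                if tree is None:
                    raise ValidationError(f"cannot override support on {method}")
                scale_value = value / 100.0 if method == "BI" else value
                _force_support(tree, members[clade], scale_value)
        entries.append(GeneTreeEntry(locus, "NJ", nj_tree, "percent"))
        entries.append(GeneTreeEntry(locus, "MP_strict", mp, "percent"))
        entries.append(GeneTreeEntry(locus, "ML", ml, "percent"))
        entries.append(GeneTreeEntry(locus, "BI", bi, "posterior"))
    return GeneTreeSet(entries)


# Recovery experiment -------------------------------------------------------


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of one seeded end-to-end delimitation run."""

    seed: int
    candidates_contain_truth: bool
    all_clades_concordant: bool
    between_mean: float  # in-complex clades, averaged over loci
    within_mean: float

    @property
    def recovered(self) -> bool:
        return self.candidates_contain_truth and self.all_clades_concordant


def recovery_trial(
    seed: int,
    config: SimulationConfig | None = None,
    n_boot_concat: int = 200,
    n_boot_locus: int = 100,
    support_threshold: float = 80.0,
) -> RecoveryResult:
    """Simulate one data set and run the whole delimitation pipeline on it.

    The run counts as a recovery when (a) every true clade appears among the
    candidate clades proposed from the midpoint-rooted concatenated NJ tree
    and (b) every true clade is fully concordant (recovered in MP strict
    consensus, support > threshold in NJ/ML/BI) across all evaluable loci.
    Nested within-clade candidates may also pass; they do not contradict the
    partition, mirroring well-supported nodes internal to a species.
    """
    from .metrics import barcode_gap_summary, p_distance_matrix
    from .nj import midpoint_root
    from .seqio import concatenate
    from .treeops import (
        ConcordanceRule,
        assess_concordance,
        propose_clades_from_tree,
    )

    config = config if config is not None else SimulationConfig(seed=seed)
    streams = np.random.SeedSequence(seed).spawn(2)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in streams]

    dataset = simulate_species_scenario(config)
    supermatrix = concatenate(dataset.locus_set)
    tree = neighbor_joining(observed_distance_matrix(supermatrix))
    tree = bootstrap_support(
        supermatrix, tree, n_reps=n_boot_concat, seed=sub_seeds[0]
    )
    rooted = midpoint_root(tree)
    candidates = {
        frozenset(c) for c in propose_clades_from_tree(rooted, min_size=2)
    }
    members: dict[str, set[str]] = {}
    for s, c in dataset.true_partition.items():
        members.setdefault(c, set()).add(s)
    candidates_ok = all(
        frozenset(m) in candidates for m in members.values() if len(m) >= 2
    )

    suite = method_tree_suite(dataset, seed=sub_seeds[1], n_boot=n_boot_locus)
    report = assess_concordance(
        suite,
        dataset.true_partition,
        ConcordanceRule(support_threshold_percent=support_threshold),
    )
    concordant = all(v == "concordant" for v in report.verdicts.values())

    between, within = [], []
    hyp = dataset.in_complex_partition
    for aln in dataset.locus_set.loci.values():
        gap = barcode_gap_summary(p_distance_matrix(aln), hyp)
        between.append(gap.between_mean)
        within.append(gap.within_mean)
    return RecoveryResult(
        seed=seed,
        candidates_contain_truth=candidates_ok,
        all_clades_concordant=concordant,
        between_mean=float(np.mean(between)),
        within_mean=float(np.mean(within)),
    )


# Provenance output ---------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Emit per-locus FASTA, metadata/partition TSVs, true trees and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus, aln in dataset.locus_set.loci.items():
        write_fasta(aln, outdir / f"{locus}.fasta")
        (outdir / f"{locus}.true.nwk").write_text(
            write_newick(dataset.true_trees[locus])
        )
    with (outdir / "metadata.tsv").open("w") as fh:
        fh.write("strain\tregion\n")
        for s, r in dataset.metadata.items():
            fh.write(f"{s}\t{r}\n")
    with (outdir / "clades.tsv").open("w") as fh:
        fh.write("strain\tclade\n")
        for s, c in dataset.true_partition.items():
            fh.write(f"{s}\t{c}\n")
    cfg = asdict(dataset.config)
    cfg["region_weights"] = {k: dict(v) for k, v in cfg["region_weights"].items()}
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
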