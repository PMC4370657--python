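"""Newick ingestion, splits, consensus, monophyly and concordance scoring."""

import numpy as np
import pytest

from gcpsr import (
    ConcordanceReport,
    ConcordanceRule,
    FormatError,
    GeneTreeEntry,
    GeneTreeSet,
    ValidationError,
    assess_concordance,
    bipartitions,
    clade_support,
    is_monophyletic,
    parse_newick,
    propose_clades_from_tree,
    strict_consensus,
    write_newick,
)

from conftest import oracle_monophyletic, oracle_splits, random_tree


class TestNewick:
    def test_internal_label_read_as_support(self):
        t = parse_newick("((a:1,b:1)90:1,c:2);")
        sups = [n.support for n in t.preorder_node_iter() if not n.is_leaf()]
        assert 90.0 in sups
        assert t.support_scale == "percent"

    def test_posterior_autodetected_and_overridable(self):
        t = parse_newick("((a,b)0.99,c);")
        assert t.support_scale == "posterior"
        t2 = parse_newick("((a,b)0.99,c);", support_scale="percent")
        assert t2.support_scale == "percent"

    def test_round_trip_preserves_topology_lengths_supports(self, rng):
        t = random_tree(rng, 8)
        for i, n in enumerate(t.preorder_node_iter()):
            if not n.is_leaf() and n is not t.seed_node:
                n.support = float(50 + i)
        text = write_newick(t)
        back = parse_newick(text)
        assert bipartitions(back) == bipartitions(t)
        sup_by_split = {}
        from gcpsr.treeops import _split_nodes

        for split, nodes in _split_nodes(t).items():
            sup_by_split[split] = nodes[0].support
        for split, nodes in _split_nodes(back).items():
            assert nodes[0].support == sup_by_split[split]

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(FormatError):
            parse_newick("((a,b,c);")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(FormatError):
            parse_newick("((a,a),b);")


class TestBipartitions:
    def test_quartet_single_split(self):
        t = parse_newick("((a,b),(c,d));")
        assert bipartitions(t) == {frozenset({"c", "d"})}

    def test_star_tree_has_none(self):
        assert bipartitions(parse_newick("(a,b,c,d);")) == set()

    def test_binary_tree_has_n_minus_3_splits(self, rng):
        t = random_tree(rng, 8)
        assert len(bipartitions(t)) == 5

    def test_matches_dendropy_encoding(self, rng):
        for _ in range(10):
            t = random_tree(rng, int(rng.integers(4, 11)))
            assert bipartitions(t) == oracle_splits(t)


class TestStrictConsensus:
    def test_identical_inputs_identity(self, rng):
        t = random_tree(rng, 7)
        sc = strict_consensus([t, t])
        assert bipartitions(sc) == bipartitions(t)

    def test_conflicting_quartets_collapse_to_star(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,c),(b,d));")
        assert bipartitions(strict_consensus([t1, t2])) == set()

    def test_planted_split_survives(self, rng):
        # many random trees that all contain the split {x0..x3} | rest
        labels_a = [f"a{i}" for i in range(4)]
        labels_b = [f"b{i}" for i in range(4)]
        trees = []
        for _ in range(30):
            sub_a = random_tree(rng, 4, prefix="a")
            sub_b = random_tree(rng, 4, prefix="b")
            na = write_newick(sub_a).strip().rstrip(";")
            nb = write_newick(sub_b).strip().rstrip(";")
            trees.append(parse_newick(f"({na},{nb});"))
        shared = bipartitions(strict_consensus(trees))
        planted = frozenset(labels_b)  # canonical side omits a0
        assert planted in shared

    def test_consensus_splits_equal_intersection(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            ts = [random_tree(rng, n) for _ in range(3)]
            expected = set.intersection(*(oracle_splits(t) for t in ts))
            assert bipartitions(strict_consensus(ts)) == expected

    def test_mismatched_leaf_sets_rejected(self, rng):
        with pytest.raises(ValidationError):
            strict_consensus([random_tree(rng, 5), random_tree(rng, 6)])


class TestMonophyly:
    def test_quartet_cases(self):
        t = parse_newick("((a,b),(c,d));")
        assert is_monophyletic(t, {"a", "b"})
        assert not is_monophyletic(t, {"a", "c"})

    def test_singleton_is_monophyletic(self):
        t = parse_newick("((a,b),(c,d));")
        assert is_monophyletic(t, {"a"})

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValidationError):
            is_monophyletic(parse_newick("((a,b),c);"), {"z"})

    def test_matches_edge_removal_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 11))
            t = random_tree(rng, n)
            leaves = sorted(l.taxon.label for l in t.leaf_node_iter())
            k = int(rng.integers(1, n))
            taxa = set(
                np.array(leaves)[rng.choice(n, size=k, replace=False)]
            )
            assert is_monophyletic(t, taxa) == oracle_monophyletic(t, taxa)


class TestCladeSupport:
    def test_direct_lookup(self):
        t = parse_newick("((a,b)85,(c,d)92);")
        assert clade_support(t, {"a", "b"}) == 85

    def test_non_monophyletic_absent(self):
        t = parse_newick("((a,b)85,(c,d)92);")
        assert clade_support(t, {"a", "c"}) is None

    def test_posterior_scaled_for_thresholding(self):
        from gcpsr.treeops import support_as_percent

        t = parse_newick("((a,b)0.99,(c,d)0.5);")
        raw = clade_support(t, {"c", "d"})
        assert support_as_percent(raw, t.support_scale) == pytest.approx(50.0)
        assert support_as_percent(
            clade_support(t, {"a", "b"}), "posterior"
        ) == pytest.approx(99.0)


def _suite(newicks: dict[tuple[str, str], str], scales=None) -> GeneTreeSet:
    scales = scales or {}
    entries = []
    for (locus, method), text in newicks.items():
        scale = scales.get((locus, method), "posterior" if method == "BI" else "percent")
        entries.append(
            GeneTreeEntry(locus, method, parse_newick(text, support_scale=scale), scale)
        )
    return GeneTreeSet(entries)


class TestAssessConcordance:
    HYP = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def _good_locus(self, support="95", bi="0.97"):
        return {
            "NJ": f"((a1,a2){support},(b1,b2){support});",
            "MP_strict": "((a1,a2),(b1,b2));",
            "ML": f"((a1,a2){support},(b1,b2){support});",
            "BI": f"((a1,a2){bi},(b1,b2){bi});",
        }

    def test_all_supported_clades_are_concordant(self):
        trees = {}
        for locus in ("L1", "L2"):
            for method, nwk in self._good_locus().items():
                trees[(locus, method)] = nwk
        report = assess_concordance(_suite(trees), self.HYP)
        assert report.verdicts == {"A": "concordant", "B": "concordant"}
        assert report.exceptions == []

    def test_low_ml_support_recorded_as_exception(self):
        trees = {}
        for locus in ("L1", "L2"):
            for method, nwk in self._good_locus().items():
                trees[(locus, method)] = nwk
        trees[("L2", "ML")] = "((a1,a2)51,(b1,b2)95);"
        report = assess_concordance(_suite(trees), self.HYP)
        assert ("A", "L2") in [(c, l) for c, l, _ in report.exceptions]
        assert len(report.exceptions) == 1
        assert report.verdicts["A"] == "discordant"  # 1 of 2 loci passed
        assert report.verdicts["B"] == "concordant"

    def test_polytomy_fails_recovery(self):
        # three clades so the dissolved clade is not a complement split either
        hyp = {**self.HYP, "c1": "C", "c2": "C"}
        trees = {}
        for method in ("NJ", "ML"):
            trees[("L1", method)] = "((a1,a2)95,(b1,b2)95,(c1,c2)95);"
        trees[("L1", "BI")] = "((a1,a2)0.99,(b1,b2)0.99,(c1,c2)0.99);"
        trees[("L1", "MP_strict")] = "(a1,a2,(b1,b2),(c1,c2));"  # A dissolved
        report = assess_concordance(_suite(trees), hyp)
        cell = report.cell("A", "L1")
        assert cell.recovered_mp is False and cell.passed is False
        assert "MP_strict:not_recovered" in cell.failures
        assert report.cell("B", "L1").passed is True

    def test_strictly_greater_than_threshold(self):
        trees = dict(
            (("L1", m), nwk)
            for m, nwk in self._good_locus(support="80", bi="0.80").items()
        )
        report = assess_concordance(_suite(trees), self.HYP)
        assert report.cell("A", "L1").passed is False  # 80 is not > 80

    def test_taxa_missing_from_locus_are_dropped(self):
        # locus L2 lacks a2 entirely; clade A still evaluable via a1? no:
        # reduced to 1 member -> not evaluable; B evaluated normally
        trees = dict(
            (("L1", m), nwk) for m, nwk in self._good_locus().items()
        )
        for method in ("NJ", "MP_strict", "ML", "BI"):
            scale = "0.99" if method == "BI" else "99"
            label = "" if method == "MP_strict" else scale
            trees[("L2", method)] = f"(a1,(b1,b2){label});"
        report = assess_concordance(_suite(trees), self.HYP)
        assert report.cell("A", "L2").evaluable is False
        assert report.cell("B", "L2").passed is True
        # A passes every locus it can be evaluated on
        assert report.verdicts["A"] == "concordant"

    def test_report_round_trips_through_json(self):
        trees = dict(
            (("L1", m), nwk) for m, nwk in self._good_locus().items()
        )
        report = assess_concordance(_suite(trees), self.HYP)
        back = ConcordanceReport.from_json(report.to_json())
        assert back.to_dict() == report.to_dict()

    def test_invariant_to_entry_order(self):
        trees = dict(
            (("L" + str(k), m), nwk)
            for k in (1, 2)
            for m, nwk in self._good_locus().items()
        )
        suite = _suite(trees)
        reversed_suite = GeneTreeSet(list(reversed(suite.entries)))
        r1 = assess_concordance(suite, self.HYP)
        r2 = assess_concordance(reversed_suite, self.HYP)
        assert r1.verdicts == r2.verdicts
        assert {(c.clade, c.locus): c.passed for c in r1.cells} == {
            (c.clade, c.locus): c.passed for c in r2.cells
        }

    def test_duplicate_locus_method_rejected(self):
        e = GeneTreeEntry("L1", "NJ", parse_newick("((a,b),c);"), "percent")
        with pytest.raises(ValidationError):
            GeneTreeSet([e, e])


class TestProposeClades:
    def test_balanced_eight_leaf_tree_yields_six_candidates(self):
        t = parse_newick(
            "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
        )
        t.is_rooted = True
        cands = propose_clades_from_tree(t, min_size=2)
        assert len(cands) == 6
        sizes = [len(c) for c in cands]
        assert sizes == sorted(sizes)  # shallow cherries before deep nodes

    def test_star_tree_has_no_candidates(self):
        t = parse_newick("(a,b,c,d,e);")
        assert propose_clades_from_tree(t) == []

    def test_shallowest_cherry_comes_first(self):
        t = parse_newick("(((a:0.1,b:0.1):5,c:5):1,(d:3,e:3):3);")
        t.is_rooted = True
        cands = propose_clades_from_tree(t, min_size=2)
        assert cands[0] == ("a", "b")
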