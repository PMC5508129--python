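"""Hypergeometric enrichment, permutation FDR, essentiality and mechanism tallies."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from inhibnet import enrich, netcore

from conftest import build_network


def enumerate_upper_tail(k, K, n, N):
    """Oracle: P(X >= k) by enumerating all C(N, n) draws."""
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


class TestHypergeomUpperTail:
    def test_k_zero_is_whole_support(self):
        assert enrich.hypergeom_upper_tail(0, 5, 4, 10) == 1.0

    def test_exact_value_against_enumeration(self):
        assert enrich.hypergeom_upper_tail(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_full_draw_forced(self):
        assert enrich.hypergeom_upper_tail(3, 3, 10, 10) == pytest.approx(1.0)

    def test_inconsistent_parameters_raise(self):
        with pytest.raises(ValueError):
            enrich.hypergeom_upper_tail(5, 3, 4, 10)
        with pytest.raises(ValueError):
            enrich.hypergeom_upper_tail(1, 11, 4, 10)

    @given(st.integers(1, 12), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_enumeration_for_all_small_parameter_sets(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(K, n)))
        expected = enumerate_upper_tail(k, K, n, N)
        assert enrich.hypergeom_upper_tail(k, K, n, N) == pytest.approx(expected)


def planted_class_network(n_excess=30, n_uniform=3, seed=0):
    """Nucleotide inhibitors over-target transferases; everything else uniform."""
    rng = np.random.default_rng(seed)
    classes = ["Nucleosides, Nucleotides, and Analogues", "Lipids",
               "Organic Acids and Derivatives", "Others"]
    mets = {}
    for c_i, cls in enumerate(classes):
        for i in range(6):
            mets[f"m{c_i}_{i}"] = cls
    rxns = {f"{cls}.1.1.{i}": {} for cls in range(1, 7) for i in range(4)}
    ecs = sorted(rxns)
    edges = set()
    # uniform background
    for mid in mets:
        for ec in rng.choice(ecs, size=n_uniform, replace=False):
            edges.add((mid, str(ec), "unknown"))
    # planted excess: nucleotides -> transferases (class 2)
    transferases = [ec for ec in ecs if ec.startswith("2.")]
    nucs = [m for m, c in mets.items() if c.startswith("Nucleosides")]
    for _ in range(n_excess):
        edges.add((str(rng.choice(nucs)), str(rng.choice(transferases)), "unknown"))
    return build_network(mets, rxns, sorted(edges))


class TestClassEnrichment:
    def test_planted_excess_is_the_significant_pair(self):
        net = planted_class_network()
        results = enrich.class_enrichment(net)
        sig = {(r.from_group, r.to_group) for r in results if r.p < 0.05}
        assert ("Nucleosides, Nucleotides, and Analogues", "Transferases") in sig

    def test_single_class_network_is_flat(self):
        mets = {f"m{i}": "Lipids" for i in range(5)}
        rxns = {f"2.1.1.{i}": {} for i in range(3)}
        edges = [(m, ec, "unknown") for m in mets for ec in rxns]
        net = build_network(mets, rxns, edges)
        results = enrich.class_enrichment(net)
        assert all(r.p == 1.0 for r in results if r.k > 0)

    def test_empty_margin_pairs_are_flagged(self):
        net = planted_class_network()
        results = enrich.class_enrichment(net)
        lipid_free = [r for r in results if r.from_group == "Aromatic Cyclic Compounds"]
        assert all(r.flagged and r.p == 1.0 for r in lipid_free)

    def test_null_false_positive_rate_is_calibrated(self):
        """Shuffled class labels give ~5% of pairs at p < 0.05 (exact-test
        conservatism pulls the rate at or slightly below the nominal level)."""
        rng = np.random.default_rng(123)
        net = planted_class_network(n_excess=0, n_uniform=4, seed=5)
        inhibitors = sorted({e.metabolite_id for e in net.edges})
        labels = [net.metabolites[m].superclass for m in inhibitors]
        n_tests = 0
        n_sig = 0
        for _ in range(100):
            shuffled = list(labels)
            rng.shuffle(shuffled)
            for m, lab in zip(inhibitors, shuffled):
                net.metabolites[m].superclass = lab
            for r in enrich.class_enrichment(net):
                if not r.flagged:
                    n_tests += 1
                    n_sig += r.p < 0.05
        rate = n_sig / n_tests
        # 99% binomial band around 0.05, widened downward for discreteness
        se = math.sqrt(0.05 * 0.95 / n_tests)
        assert rate <= 0.05 + 2.58 * se
        assert rate >= 0.01


class TestPermutationFDR:
    def test_planted_pair_has_zero_fdr(self):
        net = planted_class_network()
        obs = enrich.class_enrichment(net)
        results = enrich.permutation_fdr(net, obs, n_perm=100, seed=0)
        planted = next(r for r in results
                       if r.from_group.startswith("Nucleosides")
                       and r.to_group == "Transferases")
        assert planted.fdr == 0.0

    def test_p_one_pair_has_fdr_one(self):
        net = planted_class_network()
        obs = enrich.class_enrichment(net)
        results = enrich.permutation_fdr(net, obs, n_perm=50, seed=0)
        for r in results:
            if r.p == 1.0:
                assert r.fdr == 1.0

    def test_seeded_fdr_is_reproducible(self):
        net = planted_class_network()
        obs = enrich.class_enrichment(net)
        f1 = [r.fdr for r in enrich.permutation_fdr(net, obs, n_perm=30, seed=4)]
        f2 = [r.fdr for r in enrich.permutation_fdr(net, obs, n_perm=30, seed=4)]
        assert f1 == f2

    def test_invalid_permutation_count(self):
        net = planted_class_network()
        with pytest.raises(ValueError):
            enrich.permutation_fdr(net, enrich.class_enrichment(net), n_perm=0)

    def test_fdr_stable_under_more_permutations(self):
        net = planted_class_network()
        obs = enrich.class_enrichment(net)
        f100 = enrich.permutation_fdr(net, obs, n_perm=100, seed=8)
        f1000 = enrich.permutation_fdr(net, obs, n_perm=1000, seed=8)
        for a, b in zip(f100, f1000):
            assert abs(a.fdr - b.fdr) < 0.15


class TestPathwayStatistics:
    def test_within_pathway_mean_is_bounded(self, synth_default):
        _, _, bundle, _ = synth_default
        score = enrich.pathway_pair_similarity(bundle.network, "PWY0", "PWY0")
        assert 0.0 <= score <= 1.0

    def test_fully_shared_pathways_are_undefined(self):
        mets = {"a": "Lipids", "b": "Lipids"}
        rxns = {"1.1.1.1": {"substrates": ["a"], "products": ["b"],
                            "pathways": ["P", "Q"]}}
        net = build_network(mets, rxns, [("a", "1.1.1.1", "unknown")])
        assert enrich.pathway_pair_similarity(net, "P", "Q") is None

    def test_within_family_similarity_beats_between(self, synth_default):
        """Within-pathway structural similarity exceeds the cross-family one."""
        _, _, bundle, _ = synth_default
        net = bundle.network
        within = enrich.pathway_pair_similarity(net, "PWY0", "PWY0", metric="mcs_overlap")
        between = enrich.pathway_pair_similarity(net, "PWY0", "PWY1", metric="mcs_overlap")
        assert within > between

    def test_no_edges_gives_empty_result(self):
        net = build_network({"a": "Lipids"}, {"1.1.1.1": {"pathways": ["P"]}}, [])
        assert enrich.pathway_inhibition_enrichment(net) == []

    def test_planted_self_inhibiting_pathways_significant(self, synth_default):
        _, _, bundle, _ = synth_default
        sig = enrich.pathway_inhibition_enrichment(bundle.network)
        diagonal = {r.from_group for r in sig if r.from_group == r.to_group}
        assert {"PWY0", "PWY2", "PWY4"} <= diagonal  # the cytosolic pathways

    def test_zero_threshold_empties_result(self, synth_default):
        _, _, bundle, _ = synth_default
        assert enrich.pathway_inhibition_enrichment(bundle.network, p_threshold=0.0) == []


class TestEssentiality:
    def toy(self):
        mets = {"a": "Lipids", "b": "Lipids"}
        rxns = {"1.1.1.1": {"substrates": ["a"], "products": ["b"], "genes": ["g1"]},
                "2.2.2.2": {"substrates": ["b"], "genes": ["g2"]}}
        net = build_network(mets, rxns, [("a", "2.2.2.2", "unknown")])
        return netcore.ModelBundle(network=net)

    def test_metabolite_inherits_gene_essentiality(self):
        bundle = self.toy()
        enrich.annotate_essentiality(bundle, {"g1"})
        net = bundle.network
        assert net.metabolites["a"].essential is True
        assert net.metabolites["b"].essential is True   # product of the g1 reaction
        assert net.reactions["1.1.1.1"].essential is True
        assert net.reactions["2.2.2.2"].essential is False

    def test_empty_essential_list_flags_everything_false(self):
        bundle = self.toy()
        enrich.annotate_essentiality(bundle, set())
        assert not any(m.essential for m in bundle.network.metabolites.values())

    def test_degenerate_split_returns_none(self):
        bundle = self.toy()
        enrich.annotate_essentiality(bundle, {"g1", "g2"})
        comp = enrich.compare_by_essentiality(bundle.network)
        assert comp["metabolites"] is None

    def test_essential_metabolites_inhibit_more_enzymes_not_vice_versa(self, synth_default):
        """Hub-driven fixture: essential metabolites are over-represented among
        frequent inhibitors, while enzyme essentiality is unrelated to being
        inhibited."""
        _, _, bundle, _ = synth_default
        comp = enrich.compare_by_essentiality(bundle.network)
        met = comp["metabolites"]
        assert met is not None
        assert met.group_means["essential"] > met.group_means["nonessential"]
        assert met.p < 0.05
        enz = comp["enzymes"]
        assert enz is not None
        assert enz.p > 0.05


class TestMechanismTally:
    def test_small_arithmetic(self):
        table = pd.DataFrame({"mechanism": ["competitive"] * 3 +
                              ["noncompetitive", "uncompetitive"]})
        tally = enrich.mechanism_tally(table)
        assert tally.fractions["competitive"] == pytest.approx(0.6)
        assert tally.fractions["noncompetitive"] == pytest.approx(0.2)
        assert tally.fractions["uncompetitive"] == pytest.approx(0.2)
        assert sum(tally.fractions.values()) == pytest.approx(1.0)

    def test_unrecognized_labels_are_dropped_and_counted(self):
        table = pd.DataFrame({"mechanism": ["competitive"] * 4 + ["mixed"]})
        tally = enrich.mechanism_tally(table)
        assert tally.dropped == 1
        assert tally.n == 4

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            enrich.mechanism_tally(pd.DataFrame({"mechanism": []}))
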